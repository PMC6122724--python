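"""TIL prediction models.

The modeling chain mirrors standard radiomics-signature practice: z-score
the feature table, select features by LASSO under tenfold cross-validation
repeated 100 times (a feature is kept if its coefficient is nonzero at the
CV-chosen penalty in more than 90% of repeats), then refit the retained
features by ordinary least squares.  The published five-feature imaging
signature and the composite imaging + cytolytic model are shipped as fixed
linear models:

    imaging  = 4.4*M1 - 3.14*TEX2 - 2.0*TSBPE2 - 2.62*BPE1 - 0.72*BPE3 + 13.02
    composite = 5.86*imaging_signature + 7.78*cytolytic_score + 13.0

both defined on standardized inputs.  Predicted or pathologist TIL
percentages fall into three categories: no/minimal (<= 10%), intermediate
(> 10% to <= 40%) and high (> 40% to <= 90%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

TIL_CATEGORIES = ("no/minimal", "intermediate", "high")
DEFAULT_CUTPOINTS = (10.0, 40.0)
TIL_MAX = 90.0


@dataclass
class SignatureModel:
    """A linear model over named features, optionally with z-scoring."""

    feature_names: list
    coefficients: np.ndarray
    intercept: float
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    cutpoints: tuple | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_names) != self.coefficients.size:
            raise ValueError("one coefficient per feature name required")
        for attr in ("means", "sds"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != self.coefficients.size:
                    raise ValueError(f"{attr} must align with feature names")
                setattr(self, attr, v)
        if self.sds is not None and np.any(self.sds <= 0):
            raise ValueError("standardization SDs must be positive")

    def predict(self, rows):
        """Linear prediction for a DataFrame / dict of feature columns."""
        if isinstance(rows, dict):
            rows = pd.DataFrame(rows if np.ndim(next(iter(rows.values()))) else
                                {k: [v] for k, v in rows.items()})
        missing = [f for f in self.feature_names if f not in rows.columns]
        if missing:
            raise KeyError(f"missing model features: {missing}")
        X = rows[self.feature_names].to_numpy(dtype=float)
        if self.means is not None and self.sds is not None:
            X = (X - self.means) / self.sds
        return X @ self.coefficients + self.intercept

    def to_json(self, path=None):
        payload = asdict(self)
        payload["coefficients"] = self.coefficients.tolist()
        for attr in ("means", "sds"):
            v = payload[attr]
            payload[attr] = None if v is None else np.asarray(v).tolist()
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source):
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        if payload.get("cutpoints") is not None:
            payload["cutpoints"] = tuple(payload["cutpoints"])
        return cls(**payload)


@dataclass
class SelectionReport:
    """Per-feature LASSO selection frequencies over repeated CV."""

    feature_names: list
    frequencies: np.ndarray
    threshold: float
    seed: int
    folds: int
    repeats: int

    @property
    def selected(self):
        return [f for f, q in zip(self.feature_names, self.frequencies)
                if q > self.threshold]


def standardize(table: pd.DataFrame):
    """Z-score every column (SD convention n-1).

    Returns ``(z_table, means, sds)``; the means/SDs are reusable on
    validation data.  A zero-variance column raises, naming the column.
    """
    table = pd.DataFrame(table)
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    means = table.mean(axis=0)
    sds = table.std(axis=0, ddof=1)
    dead = sds.index[sds <= 0].tolist()
    if dead:
        raise ValueError(f"zero-variance feature column(s): {dead}")
    return (table - means) / sds, means, sds


def _alpha_grid(X, y, n_alphas=50, ratio=1e-3):
    n = X.shape[0]
    alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    alpha_max = max(alpha_max, 1e-12)
    return np.geomspace(alpha_max, alpha_max * ratio, n_alphas)


def lasso_select(X, y, folds=10, repeats=100, threshold=0.9, seed=0,
                 n_alphas=50, one_se=False, tol=1e-6) -> SelectionReport:
    """LASSO feature-selection frequencies under repeated k-fold CV.

    Per repeat, fold assignment is reshuffled from a seeded stream, the
    penalty is chosen at the CV-minimum mean squared error over a
    logarithmic grid (optionally the one-standard-error rule), and a
    feature counts as selected if its full-data coefficient at that
    penalty is nonzero.  Frequencies are the fraction of repeats in which
    each feature was selected.  The coordinate-descent solver runs at
    tolerance ``tol``.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < folds:
        raise ValueError(f"need at least {folds} cases for {folds}-fold CV")
    rng = np.random.default_rng(seed)

    def centered_path(Xs, ys, alphas):
        # lasso_path solves without an intercept; center so the path matches
        # the intercept-fitted LASSO
        xm, ym = Xs.mean(axis=0), ys.mean()
        _, coefs, _ = lasso_path(Xs - xm, ys - ym, alphas=alphas, tol=tol)
        return coefs, xm, ym

    alphas = _alpha_grid(X - X.mean(axis=0), y, n_alphas=n_alphas)

    # full-data coefficients along the path are repeat-independent
    full_coefs, _, _ = centered_path(X, y, alphas)

    hits = np.zeros(p)
    for _ in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(2 ** 31 - 1)))
        sq_err = np.zeros((folds, alphas.size))
        for k, (tr, te) in enumerate(kf.split(X)):
            coefs, xm, ym = centered_path(X[tr], y[tr], alphas)
            pred = (X[te] - xm) @ coefs + ym
            sq_err[k] = ((pred - y[te, None]) ** 2).mean(axis=0)
        cv_mse = sq_err.mean(axis=0)
        best = int(np.argmin(cv_mse))
        if one_se:
            se = sq_err.std(axis=0, ddof=1)[best] / np.sqrt(folds)
            # alphas descend along the grid: earliest index = largest penalty
            best = int(np.argmax(cv_mse <= cv_mse[best] + se))
        # coordinate descent can leave O(1e-16) residue exactly at alpha_max
        hits += np.abs(full_coefs[:, best]) > 1e-10
    return SelectionReport(
        feature_names=names or [f"x{i + 1}" for i in range(p)],
        frequencies=hits / repeats, threshold=threshold, seed=seed,
        folds=folds, repeats=repeats)


def fit_linear(X, y, feature_names=None) -> SignatureModel:
    """Ordinary least-squares refit on the selected features."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("selected feature set is empty")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more cases than features for the OLS refit")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    names = feature_names or [f"x{i + 1}" for i in range(p)]
    return SignatureModel(feature_names=list(names), coefficients=beta[1:],
                          intercept=float(beta[0]))


def published_imaging_signature() -> SignatureModel:
    """The fixed five-feature imaging signature (standardized inputs)."""
    return SignatureModel(
        feature_names=["M1", "TEX2", "TSBPE2", "BPE1", "BPE3"],
        coefficients=[4.4, -3.14, -2.0, -2.62, -0.72],
        intercept=13.02)


def published_composite_model() -> SignatureModel:
    """The fixed composite model: imaging signature + cytolytic score."""
    return SignatureModel(
        feature_names=["imaging_signature", "cytolytic_score"],
        coefficients=[5.86, 7.78],
        intercept=13.0)


def evaluate_model(model: SignatureModel, rows):
    """Predicted TIL score per row (thin wrapper over ``model.predict``)."""
    return model.predict(rows)


def categorize_til(values, cutpoints=DEFAULT_CUTPOINTS, check_range=True):
    """Three-level TIL category for percentages or predicted scores.

    ``<= cutpoints[0]`` -> no/minimal, ``<= cutpoints[1]`` -> intermediate,
    above -> high (boundaries inclusive on the upper side).  With
    ``check_range`` (pathology percentages) values outside [0, 90] raise;
    disable it for predicted scores categorized at model cutpoints.
    """
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if check_range and (np.any(arr < 0) or np.any(arr > TIL_MAX)):
        raise ValueError(f"TIL percentage outside [0, {TIL_MAX}]")
    c1, c2 = cutpoints
    out = np.where(arr <= c1, TIL_CATEGORIES[0],
                   np.where(arr <= c2, TIL_CATEGORIES[1], TIL_CATEGORIES[2]))
    return out[0] if np.ndim(values) == 0 else out


def redundancy_filter(table_a: pd.DataFrame, table_b: pd.DataFrame,
                      icc_cut=0.85):
    """Drop redundant features, keeping the most contour-robust of each group.

    Features are grouped by pairwise between-feature ICC(2,1) above
    ``icc_cut`` on ``table_a`` (greedy single linkage in column order);
    within each group the feature with the highest manual-vs-automatic
    agreement — ICC between its ``table_a`` and ``table_b`` columns — is
    retained.  Output preserves the original column order.
    """
    from .evaluation import icc

    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("both tables must share the same feature columns")
    if len(table_a) < 3 or len(table_a) != len(table_b):
        raise ValueError("need >= 3 shared cases in both tables")
    cols = list(table_a.columns)

    groups = []  # list of lists of column names
    for col in cols:
        home = None
        for g in groups:
            if any(icc(np.column_stack([table_a[col], table_a[other]])) > icc_cut
                   for other in g):
                home = g
                break
        if home is None:
            groups.append([col])
        else:
            home.append(col)

    retained = set()
    for g in groups:
        robustness = {c: icc(np.column_stack([table_a[c], table_b[c]])) for c in g}
        retained.add(max(g, key=lambda c: (robustness[c], -g.index(c))))
    return [c for c in cols if c in retained]
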