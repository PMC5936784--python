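"""Two-group statistics for feature matrices.

Three layers, matching the standard metabolomics workflow:

* per-feature Welch t-tests (unequal variances, Welch-Satterthwaite degrees
  of freedom) at a raw-p threshold, with per-direction significant counts
  and an optional Benjamini-Hochberg FDR column for users who want it;
* two-group PLS-DA fit by the NIPALS/PLS1 algorithm on Pareto-scaled,
  mean-centered data against a +/-1-coded response, with a label-permutation
  test on the
  between/within sum-of-squares separation of the score space (1999
  permutations by default, so the smallest attainable p is 5e-4) and
  cross-validated predictive ability Q2 = 1 - PRESS/TSS from stratified
  k-fold CV;
* z-scored, hierarchically clustered matrices for heat maps (Euclidean
  distance, Ward linkage, deterministic leaf order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .containers import FeatureMatrix

DEFAULT_ALPHA = 0.05
DEFAULT_N_COMPONENTS = 2
DEFAULT_N_PERMUTATIONS = 1999
DEFAULT_CV_FOLDS = 10


# ---------------------------------------------------------------------------
# Welch t-tests
# ---------------------------------------------------------------------------

def t_test_feature(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns (t, df, two-sided p).

    Degenerate inputs follow explicit conventions: zero variance in both
    groups gives p = 1 for equal means and p = 0 for unequal means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return float(np.inf if a.mean() > b.mean() else -np.inf), float(
            a.size + b.size - 2
        ), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class DifferentialResult:
    """Per-feature Welch test results plus per-direction significant counts."""

    table: pd.DataFrame
    alpha: float
    conditions: tuple[str, str]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def n_significant_up_in(self, condition: str) -> int:
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        t = self.table
        return int((t["significant"] & (t["direction"] == condition)).sum())

    def significant_features(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "feature_id"])


def differential_features(
    fm: FeatureMatrix, alpha: float = DEFAULT_ALPHA
) -> DifferentialResult:
    """Welch-test every feature between the two conditions.

    Constant features get t = 0, p = 1 and a degenerate flag. ``direction``
    names the condition with the higher mean.
    """
    labels = fm.condition_labels()
    if len(labels) != 2:
        raise ValueError("differential testing needs exactly two conditions")
    mask_a = fm.group_mask(labels[0])
    mask_b = fm.group_mask(labels[1])
    X = fm.values.to_numpy()
    A, B = X[mask_a], X[mask_b]
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    va = A.var(axis=0, ddof=1)
    vb = B.var(axis=0, ddof=1)
    degenerate = (va == 0.0) & (vb == 0.0)

    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant noise features trigger scipy precision warnings; the
        # degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(A, B, axis=0, equal_var=False)
        t = np.array(res.statistic, dtype=float, copy=True)
        p = np.array(res.pvalue, dtype=float, copy=True)
        df = np.array(res.df, dtype=float, copy=True)
    equal_degen = degenerate & (mean_a == mean_b)
    unequal_degen = degenerate & (mean_a != mean_b)
    t[equal_degen] = 0.0
    p[equal_degen] = 1.0
    df[degenerate] = mask_a.sum() + mask_b.sum() - 2
    t[unequal_degen] = np.where(mean_a[unequal_degen] > mean_b[unequal_degen],
                                np.inf, -np.inf)
    p[unequal_degen] = 0.0

    significant = p < alpha
    direction = np.where(mean_a >= mean_b, labels[0], labels[1])
    q = _benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "feature_id": fm.feature_ids,
            "consensus_mz": fm.consensus_mz,
            f"mean_{labels[0]}": mean_a,
            f"mean_{labels[1]}": mean_b,
            "t": t,
            "df": df,
            "p": p,
            "q_bh": q,
            "significant": significant,
            "direction": direction,
            "degenerate": degenerate,
        }
    )
    return DifferentialResult(table=table, alpha=alpha, conditions=(labels[0], labels[1]))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

SCALING_MODES = ("pareto", "center", "auto")


def _scale_vector(X: np.ndarray, mode: str) -> np.ndarray:
    """Per-feature divisor applied before centering (1 for 'center')."""
    if mode == "center":
        return np.ones(X.shape[1])
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    if mode == "auto":
        return sd
    if mode == "pareto":
        return np.sqrt(sd)
    raise ValueError(f"unknown scaling mode {mode!r}; one of {SCALING_MODES}")


@dataclass
class PlsdaModel:
    """A fitted two-group PLS-DA model (NIPALS/PLS1).

    X is divided feature-wise by ``x_scale`` (Pareto scaling by default) and
    mean-centered before component extraction.
    """

    x_mean: np.ndarray  # mean of the scaled training matrix
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # features x components
    loadings: np.ndarray  # features x components
    y_loadings: np.ndarray  # components
    scores: np.ndarray  # cells x components
    explained_x_variance: np.ndarray  # fraction of scaled, centered X variance

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def coefficients(self) -> np.ndarray:
        W, P, q = self.weights, self.loadings, self.y_loadings
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) / self.x_scale - self.x_mean
        return self.y_mean + Xc @ self.coefficients()


def _encode_y(fm: FeatureMatrix) -> tuple[np.ndarray, tuple[str, str]]:
    labels = fm.condition_labels()
    if len(labels) != 2:
        raise ValueError("PLS-DA needs exactly two conditions")
    y = np.where(fm.conditions.to_numpy() == labels[0], -1.0, 1.0)
    return y, (labels[0], labels[1])


def plsda_fit(
    fm: FeatureMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
    scale: str = "pareto",
) -> "PlsdaResult":
    """Fit PLS-DA and package scores, loadings and explained variance.

    ``scale`` is the per-feature variance treatment applied before the fit:
    Pareto (divide by the square root of the standard deviation; the default,
    it damps the dominance of high-abundance features without inflating
    near-constant ones), plain mean-centering, or autoscaling.
    """
    y, labels = _encode_y(fm)
    X = fm.values.to_numpy(dtype=float)
    model = _pls1(X, y, n_components, scale)
    return PlsdaResult(model=model, conditions=labels, cell_ids=fm.cell_ids,
                       y=y, feature_ids=fm.feature_ids)


def _pls1(
    X: np.ndarray, y: np.ndarray, n_components: int, scale: str = "pareto"
) -> PlsdaModel:
    n, m = X.shape
    if not 1 <= n_components <= min(n - 1, m):
        raise ValueError(
            f"n_components must be in [1, min(n_cells-1, n_features)] = "
            f"[1, {min(n - 1, m)}]"
        )
    x_scale = _scale_vector(X, scale)
    X = X / x_scale
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    total_var = float((E ** 2).sum())
    if total_var == 0.0:
        raise ValueError("zero-variance data matrix: all cells identical")
    W = np.zeros((m, n_components))
    P = np.zeros((m, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    explained = np.zeros(n_components)
    for k in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm == 0.0:
            raise ValueError(f"PLS component {k + 1}: response carries no covariance")
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt == 0.0:
            raise ValueError(f"PLS component {k + 1}: degenerate score vector")
        p = E.T @ t / tt
        qk = float(f @ t) / tt
        E = E - np.outer(t, p)
        f = f - qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, p, qk, t
        explained[k] = float((np.outer(t, p) ** 2).sum()) / total_var
    return PlsdaModel(
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, weights=W, loadings=P,
        y_loadings=q, scores=T, explained_x_variance=explained,
    )


def separation_statistic(scores: np.ndarray, y: np.ndarray) -> float:
    """Between-group over within-group sum of squares of the score rows."""
    scores = np.atleast_2d(scores)
    groups = [scores[y < 0], scores[y > 0]]
    grand = scores.mean(axis=0)
    between = sum(g.shape[0] * float(((g.mean(axis=0) - grand) ** 2).sum())
                  for g in groups)
    within = sum(float(((g - g.mean(axis=0)) ** 2).sum()) for g in groups)
    if within == 0.0:
        return np.inf
    return between / within


@dataclass
class PlsdaResult:
    """Scores/loadings of a fitted PLS-DA model plus optional inference."""

    model: PlsdaModel
    conditions: tuple[str, str]
    cell_ids: list[str]
    feature_ids: list[str]
    y: np.ndarray
    permutation_p: float | None = None
    q2: float | None = None

    @property
    def scores(self) -> np.ndarray:
        return self.model.scores

    @property
    def loadings(self) -> np.ndarray:
        return self.model.loadings

    @property
    def explained_x_variance(self) -> np.ndarray:
        return self.model.explained_x_variance

    @property
    def separation(self) -> float:
        return separation_statistic(self.scores, self.y)

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"component_{k + 1}": self.scores[:, k]
                for k in range(self.model.n_components)}
        df = pd.DataFrame(cols, index=pd.Index(self.cell_ids, name="cell_id"))
        df.insert(0, "condition",
                  np.where(self.y < 0, self.conditions[0], self.conditions[1]))
        return df


def plsda_permutation_test(
    fm: FeatureMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    scale: str = "pareto",
) -> float:
    """Permutation p-value for group separation in PLS-DA score space.

    The observed between/within sum-of-squares ratio of the fitted scores is
    compared with the same statistic after refitting under randomly permuted
    labels; p = (1 + #{permuted >= observed}) / (1 + n_permutations), so the
    smallest attainable p is 1/(n_permutations + 1) — 5e-4 at the default
    1999 permutations.
    """
    if n_permutations < 19:
        raise ValueError("n_permutations must be >= 19")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y, _ = _encode_y(fm)
    X = fm.values.to_numpy(dtype=float)
    observed = separation_statistic(_pls1(X, y, n_components, scale).scores, y)
    n_extreme = 0
    n_identical = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        if np.array_equal(perm, y) or np.array_equal(perm, -y):
            n_identical += 1
        stat = separation_statistic(_pls1(X, perm, n_components, scale).scores, perm)
        if stat >= observed:
            n_extreme += 1
    if n_identical == n_permutations:
        import warnings

        warnings.warn("all permutations reproduce the original labeling; p = 1")
        return 1.0
    return (1 + n_extreme) / (1 + n_permutations)


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (cell index -> fold)."""
    assignment = np.zeros(y.size, dtype=int)
    for cls in (-1.0, 1.0):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            assignment[i] = pos % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def plsda_q2(
    fm: FeatureMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
    folds: int = DEFAULT_CV_FOLDS,
    seed: int | np.random.Generator = 0,
    scale: str = "pareto",
) -> float:
    """Cross-validated predictive ability Q2 = 1 - PRESS/TSS.

    Stratified k-fold CV on the +/-1-coded response: each fold's cells are
    predicted by a model trained on the remaining cells (centered on the
    training data). TSS is taken about the overall response mean. Q2 above
    ~0.5 conventionally indicates good predictability; shuffled labels give
    Q2 <= 0 in expectation.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y, _ = _encode_y(fm)
    X = fm.values.to_numpy(dtype=float)
    if n_components > X.shape[0] - 2:
        raise ValueError("n_components too large for cross-validation")
    fold_idx = _stratified_folds(y, folds, rng)
    press = 0.0
    y_hat = np.zeros_like(y)
    for test in fold_idx:
        if test.size == 0:
            continue
        train = np.setdiff1d(np.arange(y.size), test)
        if np.unique(y[train]).size < 2:
            # refold: push one test cell of the missing class into training
            raise ValueError("a fold left a single class in training; use fewer folds")
        model = _pls1(X[train], y[train], min(n_components, train.size - 1), scale)
        y_hat[test] = model.predict(X[test])
    press = float(((y - y_hat) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


# ---------------------------------------------------------------------------
# Heat-map matrices
# ---------------------------------------------------------------------------

@dataclass
class HeatmapData:
    """Z-scored feature x cell matrix with hierarchical-clustering orders."""

    matrix: pd.DataFrame  # features x cells, z-scored per feature
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None

    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def heatmap_data(
    fm: FeatureMatrix,
    features: list[str],
    method: str = "ward",
    metric: str = "euclidean",
) -> HeatmapData:
    """Z-score selected features across all cells and cluster rows/columns.

    Each feature row is centered on the mean over all cells and scaled to
    unit variance (constant features become all-zero rows and are placed
    last). Rows and columns are ordered by agglomerative clustering with
    deterministic leaf order.
    """
    if not features:
        raise ValueError("feature subset must be non-empty")
    sub = fm.values.loc[:, features].to_numpy(dtype=float).T  # features x cells
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0.0).ravel()
    z = np.where(sd > 0, (sub - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    matrix = pd.DataFrame(z, index=pd.Index(features, name="feature_id"),
                          columns=fm.cell_ids)

    variable = [f for f, c in zip(features, constant) if not c]
    const_feats = [f for f, c in zip(features, constant) if c]
    row_linkage = col_linkage = None
    if len(variable) > 1:
        row_linkage = hierarchy.linkage(matrix.loc[variable].to_numpy(),
                                        method=method, metric=metric)
        order = hierarchy.leaves_list(row_linkage)
        row_order = [variable[int(i)] for i in order] + const_feats
    else:
        row_order = variable + const_feats
    if fm.n_cells > 1 and len(features) > 0:
        col_linkage = hierarchy.linkage(matrix.to_numpy().T, method=method,
                                        metric=metric)
        col_order = [fm.cell_ids[int(i)] for i in hierarchy.leaves_list(col_linkage)]
    else:
        col_order = fm.cell_ids
    return HeatmapData(matrix=matrix, row_order=row_order, col_order=col_order,
                       row_linkage=row_linkage, col_linkage=col_linkage)
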