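"""Mixture resolution and classification for trapped-particle spectra.

Covers the population-level analyses: two-component univariate Gaussian
mixture EM on band intensities, PCA, Ward hierarchical clustering, PLS-DA
with venetian-blinds cross-validation, group band-area ratios and the
acquisition-order bias check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from ramantrap.spectra import Band, Spectrum, band_area


# ---------------------------------------------------------------------------
# Two-component univariate Gaussian mixture, expectation-maximisation


@dataclass
class GmmFit:
    weights: np.ndarray  # (2,), sums to 1
    means: np.ndarray  # (2,), component 1 has the lower mean
    variances: np.ndarray  # (2,)
    responsibilities: np.ndarray  # (n, 2)
    labels: np.ndarray  # hard assignment, argmax responsibility
    log_likelihood: np.ndarray  # trace over EM iterations
    converged: bool
    variance_floored: bool


def gmm2_em(
    values,
    tol: float = 1e-8,
    max_iter: int = 500,
    variance_floor_scale: float = 1e-12,
) -> GmmFit:
    """Fit a two-component 1-D Gaussian mixture by EM.

    Initialisation splits the sample at its median and takes per-half
    moments.  Convergence is declared when the relative log-likelihood
    change drops below ``tol``.  Variances are floored at
    ``variance_floor_scale * range(values)^2`` (collapse is flagged).
    Component 1 is the lower-mean component by convention.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("need >= 4 finite values")
    spread = np.ptp(x)
    if spread == 0:
        raise ValueError("degenerate sample: all values equal")
    floor = variance_floor_scale * spread**2

    median = np.median(x)
    lower, upper = x[x <= median], x[x > median]
    if upper.size == 0:  # ties at the median
        lower, upper = x[x < median], x[x >= median]
    weights = np.array([lower.size, upper.size], dtype=float) / x.size
    means = np.array([lower.mean(), upper.mean()])
    variances = np.maximum(np.array([lower.var(), upper.var()]), floor)

    trace = []
    converged = False
    floored = False
    resp = np.full((x.size, 2), 0.5)
    for _ in range(max_iter):
        # E step
        log_pdf = np.column_stack(
            [
                stats.norm.logpdf(x, means[k], np.sqrt(variances[k]))
                + np.log(weights[k])
                for k in (0, 1)
            ]
        )
        log_norm = np.logaddexp(log_pdf[:, 0], log_pdf[:, 1])
        ll = float(np.sum(log_norm))
        resp = np.exp(log_pdf - log_norm[:, None])
        if trace and abs(ll - trace[-1]) <= tol * max(abs(trace[-1]), 1.0):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M step
        n_k = resp.sum(axis=0)
        weights = n_k / x.size
        means = (resp * x[:, None]).sum(axis=0) / n_k
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / n_k
        if np.any(variances < floor):
            floored = True
            variances = np.maximum(variances, floor)

    if means[0] > means[1]:
        means, variances, weights = means[::-1], variances[::-1], weights[::-1]
        resp = resp[:, ::-1]
    labels = np.argmax(resp, axis=1)
    return GmmFit(
        weights, means, variances, resp, labels, np.asarray(trace), converged, floored
    )


def gmm_log_likelihood(values, weights, means, variances) -> float:
    """Direct mixture log-likelihood (used as an independent check on EM)."""
    x = np.asarray(values, dtype=float)
    pdf = sum(
        w * stats.norm.pdf(x, m, np.sqrt(v))
        for w, m, v in zip(weights, means, variances)
    )
    return float(np.sum(np.log(pdf)))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    mean: np.ndarray
    loadings: np.ndarray  # (n_components, n_channels), orthonormal rows
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) @ self.loadings.T


def pca(matrix, n_components: int = 2) -> PcaModel:
    """Mean-centred SVD decomposition.

    Components are ordered by explained variance; each loading's
    largest-magnitude element is made positive (sign convention).
    """
    x = np.asarray(matrix, dtype=float)
    n, _ = x.shape
    mean = x.mean(axis=0)
    centred = x - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    n_components = min(n_components, s.size)
    loadings = vt[:n_components]
    signs = np.sign(loadings[np.arange(n_components), np.argmax(np.abs(loadings), axis=1)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = centred @ loadings.T
    explained = s[:n_components] ** 2 / max(n - 1, 1)
    total_var = float(np.sum(s**2)) / max(n - 1, 1)
    ratio = explained / total_var if total_var > 0 else np.zeros_like(explained)
    return PcaModel(mean, loadings, scores, explained, ratio)


def pca_for_clustering(matrix, min_components: int = 2, variance_target: float = 0.95) -> PcaModel:
    """PCA keeping the smallest component count explaining >= 95% variance."""
    x = np.asarray(matrix, dtype=float)
    full = pca(x, n_components=min(x.shape))
    cumulative = np.cumsum(full.explained_variance_ratio)
    k = int(np.searchsorted(cumulative, variance_target) + 1)
    k = max(min_components, min(k, full.loadings.shape[0]))
    return pca(x, n_components=k)


# ---------------------------------------------------------------------------
# Ward hierarchical clustering


@dataclass
class LinkageTree:
    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    heights: np.ndarray
    labels: np.ndarray  # cluster labels at the requested cut (0-based)
    n_clusters: int


def ward_cluster(features, n_clusters: int = 2) -> LinkageTree:
    """Agglomerative Ward clustering with labels at the requested cut.

    Features are typically PCA scores covering >= 95% variance (see
    :func:`pca_for_clustering`) or raw normalised rows.  Merge heights are
    non-decreasing (Ward is reducible, so no inversions occur).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if n_clusters > x.shape[0]:
        raise ValueError("n_clusters exceeds number of samples")
    merges = linkage(x, method="ward")
    labels = fcluster(merges, t=n_clusters, criterion="maxclust") - 1
    return LinkageTree(merges, merges[:, 2].copy(), labels, n_clusters)


def unclassified_mask(features, tree: LinkageTree, percentile: float = 97.5) -> np.ndarray:
    """Flag samples unusually far from their Ward cluster centroid.

    A sample is "not classified" when its distance to the nearest cluster
    centroid exceeds the given percentile of within-cluster distances.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    centroids = np.stack(
        [x[tree.labels == k].mean(axis=0) for k in range(tree.n_clusters)]
    )
    dist_to_own = np.linalg.norm(x - centroids[tree.labels], axis=1)
    cutoff = np.percentile(dist_to_own, percentile)
    nearest = np.min(
        np.linalg.norm(x[:, None, :] - centroids[None, :, :], axis=2), axis=1
    )
    return nearest > cutoff


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS) with venetian-blinds cross-validation


@dataclass
class PlsdaModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (n_lv, n_channels)
    x_loadings: np.ndarray  # (n_lv, n_channels)
    y_loadings: np.ndarray  # (n_lv,)
    coefficients: np.ndarray  # regression vector on centred X
    n_lv: int
    classes: np.ndarray
    cv_confusion: np.ndarray  # rows: true class, cols: predicted
    cv_sensitivity: np.ndarray  # per class
    cv_specificity: np.ndarray


def _nipals_pls1(x: np.ndarray, y: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centred data; returns weights, loadings, coefficients."""
    weights, p_loadings, q_loadings = [], [], []
    xk = x.copy()
    yk = y.copy()
    for _ in range(n_lv):
        w = xk.T @ yk
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w = w / norm
        t = xk @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        p = xk.T @ t / tt
        q = float(yk @ t / tt)
        xk = xk - np.outer(t, p)
        yk = yk - q * t
        weights.append(w)
        p_loadings.append(p)
        q_loadings.append(q)
    w_mat = np.asarray(weights)
    p_mat = np.asarray(p_loadings)
    q_vec = np.asarray(q_loadings)
    # B = W (P^T W)^{-1} q
    if w_mat.size == 0:
        return w_mat, p_mat, q_vec, np.zeros(x.shape[1])
    coeff = w_mat.T @ np.linalg.solve(p_mat @ w_mat.T, q_vec)
    return w_mat, p_mat, q_vec, coeff


def venetian_blinds_folds(n_samples: int, n_folds: int) -> np.ndarray:
    """Interleaved fold assignment: sample i -> fold i mod n_folds."""
    return np.arange(n_samples) % n_folds


def plsda_train(matrix, labels, n_lv: int | None = None, cv_folds: int = 10) -> PlsdaModel:
    """Train a two-class PLS-DA model with venetian-blinds cross-validation.

    The response is a 0/1 class indicator; prediction thresholds the
    regression output at 0.5.  When ``n_lv`` is None the latent-variable
    count (1..10) maximising CV balanced accuracy is chosen.  Reported
    sensitivity/specificity are cross-validated, per class.
    """
    x = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"PLS-DA here is two-class; got {classes.size} classes")
    y = (labels == classes[1]).astype(float)
    counts = np.bincount(y.astype(int))
    if np.min(counts) < cv_folds:
        raise ValueError("each class needs >= cv_folds samples")

    folds = venetian_blinds_folds(x.shape[0], cv_folds)
    max_lv = min(10, x.shape[0] - 1, x.shape[1])
    candidates = [n_lv] if n_lv is not None else list(range(1, max_lv + 1))

    def cv_predict(k: int) -> np.ndarray:
        pred = np.empty(x.shape[0])
        for f in range(cv_folds):
            train, test = folds != f, folds == f
            xm, ym = x[train].mean(axis=0), y[train].mean()
            _, _, _, coeff = _nipals_pls1(x[train] - xm, y[train] - ym, k)
            pred[test] = (x[test] - xm) @ coeff + ym
        return pred

    best_k, best_acc, best_pred = candidates[0], -1.0, None
    for k in candidates:
        pred = cv_predict(k)
        hard = pred >= 0.5
        sens = np.mean(hard[y == 1]) if np.any(y == 1) else 0.0
        spec = np.mean(~hard[y == 0]) if np.any(y == 0) else 0.0
        acc = 0.5 * (sens + spec)
        if acc > best_acc + 1e-12:
            best_k, best_acc, best_pred = k, acc, pred
    hard = best_pred >= 0.5
    confusion = np.array(
        [
            [np.sum((y == 0) & ~hard), np.sum((y == 0) & hard)],
            [np.sum((y == 1) & ~hard), np.sum((y == 1) & hard)],
        ],
        dtype=int,
    )
    # per-class sensitivity (recall) and specificity
    sens = np.array(
        [confusion[0, 0] / max(confusion[0].sum(), 1), confusion[1, 1] / max(confusion[1].sum(), 1)]
    )
    spec = np.array([sens[1], sens[0]])

    xm, ym = x.mean(axis=0), float(y.mean())
    w_mat, p_mat, q_vec, coeff = _nipals_pls1(x - xm, y - ym, best_k)
    return PlsdaModel(
        xm, ym, w_mat, p_mat, q_vec, coeff, best_k, classes, confusion, sens, spec
    )


def plsda_predict(model: PlsdaModel, matrix) -> np.ndarray:
    """Classify spectra with a trained model; returns original class labels."""
    x = np.asarray(matrix, dtype=float)
    response = (x - model.x_mean) @ model.coefficients + model.y_mean
    return np.where(response >= 0.5, model.classes[1], model.classes[0])


# ---------------------------------------------------------------------------
# Group band-area ratios and acquisition-order bias


def band_area_ratio(
    group_a: list[Spectrum], group_b: list[Spectrum], bands: list[Band]
) -> float:
    """Ratio of mean summed band areas, group B relative to group A.

    Both groups must be area-normalised on a shared axis; the result pairs
    with the theoretical weight-fraction quotient for comparison.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")

    def mean_area(group):
        return float(
            np.mean([sum(band_area(s, b) for b in bands) for s in group])
        )

    return mean_area(group_b) / mean_area(group_a)


@dataclass
class TrendResult:
    correlation: float  # Spearman rank correlation vs acquisition order
    p_value: float  # permutation p-value
    trend_detected: bool
    alpha: float


def score_time_trend(
    scores,
    trap_indices,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> TrendResult:
    """Permutation test for a monotone drift of scores with acquisition order.

    A random class draw over time shows no trend; a significant rank
    correlation flags time bias in the trapping stream.
    """
    scores = np.asarray(scores, dtype=float)
    idx = np.asarray(trap_indices, dtype=float)
    observed = stats.spearmanr(scores, idx).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(scores)
        if abs(stats.spearmanr(perm, idx).statistic) >= abs(observed) - 1e-15:
            count += 1
    p_value = (count + 1) / (n_permutations + 1)
    return TrendResult(float(observed), float(p_value), p_value < alpha, alpha)
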