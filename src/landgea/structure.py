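"""Population structure: genotype PCA, cluster inference, Weir-Cockerham Fst
and two-level AMOVA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .genio import GenotypeMatrix, impute_modal


@dataclass
class PCAResult:
    """Scores (samples x axes), loadings (features x axes, orthonormal
    columns) and the fraction of variance explained per axis."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray  # 1-based group labels
    bic: np.ndarray  # BIC per candidate k = 1..k_max


def _pca_core(X: np.ndarray, n_axes: int | None = None) -> PCAResult:
    """SVD-based PCA of an already centered/scaled matrix."""
    n = X.shape[0]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    if n_axes is not None:
        u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
        explained = explained[:n_axes]
    return PCAResult(scores=u * s, loadings=vt.T, explained_fraction=explained)


def genotype_pca(
    g: GenotypeMatrix, scaling: str = "patterson", n_axes: int | None = None
) -> PCAResult:
    """PCA of the dosage matrix.

    Each locus is centered at 2*p_hat; ``"patterson"`` scaling divides by
    sqrt(p_hat * (1 - p_hat)) (EIGENSOFT convention), ``"unit"`` by the
    sample standard deviation. Zero-variance loci are dropped with a warning.
    """
    if np.any(~np.isfinite(g.dosage)):
        g = impute_modal(g)
    d = g.dosage
    p_hat = d.mean(axis=0) / 2.0
    centered = d - 2.0 * p_hat
    if scaling == "patterson":
        scale = np.sqrt(p_hat * (1.0 - p_hat))
    elif scaling == "unit":
        scale = d.std(axis=0, ddof=0)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    ok = scale > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-variance loci", stacklevel=2)
    X = centered[:, ok] / scale[ok]
    return _pca_core(X, n_axes=n_axes)


def infer_clusters(
    pca: PCAResult,
    k_max: int = 8,
    n_axes: int = 10,
    seed: int = 0,
    criterion: str = "elbow",
    elbow_fraction: float = 0.25,
) -> ClusterAssignment:
    """Infer the number of genetic groups by k-means + BIC on PC scores.

    For k = 1..k_max, k-means (20 restarts) minimizes the within-cluster sum
    of squares WSS_k; BIC(k) = n ln(WSS_k / n) + k ln(n). With
    ``criterion="elbow"`` (default) the chosen k is where the BIC curve
    flattens: the smallest k whose improvement toward k+1 falls below
    ``elbow_fraction`` of the largest single-step improvement. This mirrors
    how the find-clusters stage of DAPC is used in practice — on
    cluster-structured data the raw BIC keeps decreasing slowly past the
    true k, so its argmin over-splits. ``criterion="min"`` takes the argmin
    (ties to the smaller k). This is cluster inference only; no
    discriminant step is applied.
    """
    X = pca.scores[:, : min(n_axes, pca.scores.shape[1])]
    n = X.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of samples")
    bic = np.empty(k_max)
    labels_per_k = []
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(X)
            wss = float(km.inertia_)
            labels = km.labels_
        bic[k - 1] = n * np.log(max(wss, 1e-12) / n) + k * np.log(n)
        labels_per_k.append(labels)
    if criterion == "min" or k_max == 1:
        best_k = int(np.argmin(bic)) + 1
    elif criterion == "elbow":
        drops = bic[:-1] - bic[1:]  # improvement from k to k+1
        if drops.max() <= 0:
            best_k = 1
        else:
            thr = elbow_fraction * drops.max()
            below = np.flatnonzero(drops < thr)
            best_k = int(below[0]) + 1 if below.size else k_max
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return ClusterAssignment(k=best_k, labels=labels_per_k[best_k - 1] + 1, bic=bic)


def _wc_components(
    d1: np.ndarray, d2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-locus variance components a, b, c for two
    populations given dosage blocks (samples x loci, NaN = missing)."""
    r = 2.0
    comps = []
    for d in (d1, d2):
        n_i = np.sum(np.isfinite(d), axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.nansum(d, axis=0) / (2.0 * n_i)
            h_i = np.nansum(d == 1, axis=0) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    return a, b, c


def weir_cockerham_fst(g: GenotypeMatrix, labels: np.ndarray, g1, g2) -> float:
    """Multi-locus Weir-Cockerham theta between two groups: ratio of sums
    sum(a) / sum(a+b+c) over loci with a defined denominator (the VCFtools
    "weighted" convention)."""
    labels = np.asarray(labels)
    d1 = g.dosage[labels == g1]
    d2 = g.dosage[labels == g2]
    if d1.shape[0] < 2 or d2.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    a, b, c = _wc_components(d1, d2)
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        return float("nan")
    return float(np.sum(a[ok]) / np.sum(denom[ok]))


def pairwise_fst(g: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Symmetric matrix of multi-locus Weir-Cockerham Fst between all group
    pairs; diagonal is zero."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            fst = weir_cockerham_fst(g, labels, gi, gj)
            mat.loc[gi, gj] = fst
            mat.loc[gj, gi] = fst
    return mat


def amova(
    g: GenotypeMatrix,
    labels: np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Two-level AMOVA on squared Euclidean dosage distances.

    Sums of squares follow the Excoffier decomposition on the pairwise
    squared-distance matrix; variance components come from the mean squares
    with the usual unbalanced-design coefficient n0. Phi_ST is tested by
    permuting group labels.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    d = impute_modal(g).dosage if np.any(~np.isfinite(g.dosage)) else g.dosage
    dist2 = squareform(pdist(d, metric="sqeuclidean"))
    n = len(labels)
    G = len(groups)
    sizes = np.array([(labels == grp).sum() for grp in groups], dtype=float)

    def _phi(lab: np.ndarray) -> tuple[float, float, float]:
        ss_total = dist2.sum() / (2.0 * n)
        ss_within = 0.0
        for grp in groups:
            idx = np.flatnonzero(lab == grp)
            if idx.size:
                ss_within += dist2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        ss_among = ss_total - ss_within
        ms_among = ss_among / (G - 1)
        ms_within = ss_within / (n - G)
        n0 = (n - (sizes**2).sum() / n) / (G - 1)
        sigma_within = ms_within
        sigma_among = max((ms_among - ms_within) / n0, 0.0)
        total = sigma_among + sigma_within
        phi = sigma_among / total if total > 0 else 0.0
        return phi, sigma_among, sigma_within

    phi_obs, sig_a, sig_w = _phi(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _phi(perm)[0] >= phi_obs:
            exceed += 1
    p_perm = (1 + exceed) / (n_permutations + 1)
    total = sig_a + sig_w
    return {
        "sigma_among": sig_a,
        "sigma_within": sig_w,
        "pct_among": 100.0 * sig_a / total if total > 0 else float("nan"),
        "pct_within": 100.0 * sig_w / total if total > 0 else float("nan"),
        "phi_st": phi_obs,
        "p_perm": p_perm,
        "truncated": sig_a == 0.0,
    }
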