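"""Redundancy analysis (RDA/pRDA), four-model variance partitioning, and
Mahalanobis-distance outlier detection on the leading RDA axes.

The genotype matrix (individuals x loci, 0/1/2 dosages, imputed) is the
multivariate response. Total inertia is always the sum of squares of the
*unconditioned* centered genotype matrix, so R2 fractions from partial
models are directly comparable and the variance-partition identities hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfmm import storey_qvalues

CHI2_1_MEDIAN = 0.4549  # median of the chi-squared(1) distribution


@dataclass
class RDAFit:
    sample_scores: np.ndarray  # n x k constrained-axis scores
    snp_loadings: np.ndarray  # L x k
    eigenvalues: np.ndarray  # k, non-increasing
    r2: float
    adj_r2: float
    n_predictors: int
    conditioned: bool


@dataclass
class VariancePartition:
    full_model: float
    pure_structure: float
    pure_geography: float
    pure_climate: float
    confounded: float
    unexplained: float

    def as_frame(self) -> pd.DataFrame:
        rows = {
            "full_model": self.full_model,
            "pure_structure": self.pure_structure,
            "pure_geography": self.pure_geography,
            "pure_climate": self.pure_climate,
            "confounded": self.confounded,
            "unexplained": self.unexplained,
        }
        df = pd.DataFrame({"fraction": rows})
        df["pct_of_explainable"] = [
            100.0 * v / self.full_model if self.full_model > 0 else float("nan")
            for v in rows.values()
        ]
        return df


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of M after least-squares projection on [1, Z]."""
    q, _ = np.linalg.qr(_center(Z))
    Mc = _center(M)
    return Mc - q @ (q.T @ Mc)


def fit_rda(
    Y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    n_axes: int | None = None,
    allow_rank_deficient: bool = False,
) -> RDAFit:
    """Fit a (partial) redundancy analysis.

    With a condition matrix Z, both Y and X are residualized on Z first.
    Fitted values come from ordinary least squares of the (residualized)
    response on the (residualized) predictors; the constrained axes are the
    SVD of the fitted matrix. R2 is the fitted sum of squares over the total
    sum of squares of the original centered Y; the adjusted R2 uses
    Ezekiel's formula with the predictor count.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = Y.shape[0]
    Yc = _center(Y)
    total_ss = float(np.sum(Yc**2))
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Ystar = _residualize(Y, Z)
        Xstar = _residualize(X, Z)
    else:
        Ystar = Yc
        Xstar = _center(X)
    rank = np.linalg.matrix_rank(Xstar)
    if rank < Xstar.shape[1] and not allow_rank_deficient:
        norms = np.linalg.norm(Xstar, axis=0)
        q, r = np.linalg.qr(Xstar)
        dependent = np.flatnonzero(np.abs(np.diag(r)) < 1e-10 * max(norms.max(), 1))
        raise ValueError(
            f"predictor matrix is rank-deficient after conditioning "
            f"(rank {rank} < {Xstar.shape[1]} columns; "
            f"collinear columns: {dependent.tolist()})"
        )
    # project onto the column space of Xstar, discarding directions that
    # conditioning has numerically annihilated (tolerance anchored to the
    # pre-conditioning predictor scale, not to Xstar itself)
    ux, sx, _ = np.linalg.svd(Xstar, full_matrices=False)
    s_ref = np.linalg.svd(_center(X), compute_uv=False)[0]
    keep = sx > 1e-9 * max(s_ref, 1e-300)
    fitted = ux[:, keep] @ (ux[:, keep].T @ Ystar)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    k = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_axes is not None:
        k = min(k, n_axes)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    r2 = float(np.sum(fitted**2)) / total_ss if total_ss > 0 else 0.0
    p = X.shape[1]
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")
    return RDAFit(
        sample_scores=u * s,
        snp_loadings=vt.T,
        eigenvalues=s**2 / max(n - 1, 1),
        r2=r2,
        adj_r2=adj,
        n_predictors=p,
        conditioned=Z is not None,
    )


def variance_partition(
    Y: np.ndarray,
    climate: np.ndarray,
    geography: np.ndarray,
    structure3pc: np.ndarray,
) -> VariancePartition:
    """Partition genotype inertia among structure, geography and climate.

    Four pRDA models: the full model conditions on nothing; each pure
    fraction conditions the named block on the other two. The confounded
    fraction is whatever the full model explains beyond the three pure
    parts; it can be negative only by numerical error. Redundancy between
    blocks is tolerated (the projection onto the joint column space is
    well-defined even when blocks overlap), which is exactly the fully
    confounded case the partition is meant to expose.
    """
    full = fit_rda(
        Y, np.column_stack([climate, geography, structure3pc]),
        allow_rank_deficient=True,
    ).r2
    pure_structure = fit_rda(
        Y, structure3pc, np.column_stack([climate, geography]),
        allow_rank_deficient=True,
    ).r2
    pure_geography = fit_rda(
        Y, geography, np.column_stack([climate, structure3pc]),
        allow_rank_deficient=True,
    ).r2
    pure_climate = fit_rda(
        Y, climate, np.column_stack([geography, structure3pc]),
        allow_rank_deficient=True,
    ).r2
    confounded = full - (pure_structure + pure_geography + pure_climate)
    return VariancePartition(
        full_model=full,
        pure_structure=pure_structure,
        pure_geography=pure_geography,
        pure_climate=pure_climate,
        confounded=confounded,
        unexplained=1.0 - full,
    )


@dataclass
class OutlierResult:
    table: pd.DataFrame  # snp, chrom, pos, d2, p, q, bonferroni_flag
    gif: float
    df: int
    k_axes: int


def rda_outlier_scan(
    fit: RDAFit,
    loci: pd.DataFrame | None = None,
    k_axes: int = 4,
    df_mode: str = "axes",
    bonferroni_alpha: float = 0.1,
    robust: bool = True,
) -> OutlierResult:
    """Flag SNPs whose loadings on the first K RDA axes are Mahalanobis
    outliers.

    Loading columns are standardized across SNPs; D2 is the Mahalanobis
    distance to the across-SNP center. By default the center and covariance
    come from the minimum-covariance-determinant estimator (with a fixed
    internal seed, so the scan is deterministic): the adaptive loci being
    hunted are themselves outliers and would otherwise inflate a classical
    covariance and mask each other. ``robust=False`` uses the classical
    moments. The genomic inflation factor lambda = median(D2) /
    chi2_median(df) rescales D2 before chi-squared tail p-values.
    ``df_mode`` "axes" uses df = K; "two" uses df = 2 with the same K
    axes (both conventions circulate for this statistic). q-values are
    Storey's; the Bonferroni flag uses ``bonferroni_alpha`` / n_SNPs.
    """
    if fit.snp_loadings.shape[1] < k_axes:
        raise ValueError(
            f"fit has {fit.snp_loadings.shape[1]} axes, need {k_axes}"
        )
    V = fit.snp_loadings[:, :k_axes]
    V = (V - V.mean(axis=0)) / V.std(axis=0, ddof=0)
    if robust:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(V)
        cov, center = mcd.covariance_, mcd.location_
    else:
        cov, center = np.cov(V, rowvar=False), V.mean(axis=0)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular loading covariance; try fewer axes"
        ) from exc
    delta = V - center
    d2 = np.einsum("ij,jk,ik->i", delta, cov_inv, delta)
    df = k_axes if df_mode == "axes" else 2
    if df_mode not in ("axes", "two"):
        raise ValueError(f"unknown df_mode {df_mode!r}")
    gif = float(np.median(d2) / stats.chi2.median(df))
    p = stats.chi2.sf(d2 / gif, df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = storey_qvalues(p)
    L = len(p)
    table = pd.DataFrame(
        {
            "d2": d2,
            "p": p,
            "q": q,
            "bonferroni_flag": p < bonferroni_alpha / L,
        }
    )
    if loci is not None:
        table.insert(0, "snp", loci["id"].to_numpy())
        table.insert(1, "chrom", loci["chrom"].to_numpy())
        table.insert(2, "pos", loci["pos"].to_numpy())
    return OutlierResult(table=table, gif=gif, df=df, k_axes=k_axes)


def bonferroni_threshold(alpha: float, n_tests: int) -> dict:
    """Bonferroni-corrected p cutoff and its -log10, rounded to 3 decimals."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p_cut = alpha / n_tests
    return {"p_cut": p_cut, "neg_log10": round(-np.log10(p_cut), 3)}
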