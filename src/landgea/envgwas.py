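"""EnvGWAS: per-SNP association of environmental variables (the environment
treated as the trait) with genetic-PC correction.

This is a single-locus linear-model scan, env ~ dosage + PC1..PCk, with the
PC count chosen per variable by minimizing |genomic inflation factor - 1|
over a small grid. It deliberately replaces iterative multi-locus GWAS
machinery: the downstream products (significant-locus lists under
Bonferroni and FDR thresholds, and per-SNP variance explained) depend only
on per-SNP tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfmm import CHI2_1_MEDIAN, storey_qvalues


@dataclass
class EnvGWASResult:
    table: pd.DataFrame  # snp, variable, effect, t, p, q, flags, partial_r2
    chosen_pcs: dict  # variable -> n_pcs
    gif: dict  # (variable, n_pcs) -> lambda
    n_skipped_monomorphic: int


def _scan_one(
    env_values: np.ndarray, D: np.ndarray, pcs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP OLS of env on dosage plus fixed PC covariates.

    Residualizes the trait and every dosage column on [1, PCs] (by the
    Frisch-Waugh theorem this equals the full-regression coefficient) and
    returns (effect, t, p, partial_r2) arrays over SNPs.
    """
    n, L = D.shape
    k = pcs.shape[1]
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), pcs]))
    y_res = env_values - q @ (q.T @ env_values)
    D_res = D - q @ (q.T @ D)
    sxx = np.sum(D_res**2, axis=0)
    sxy = D_res.T @ y_res
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
    rss_cov = float(y_res @ y_res)
    rss_full = rss_cov - np.where(sxx > 0, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
    dof = n - k - 2
    sigma2 = rss_full / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
        partial = np.where(rss_cov > 0, (rss_cov - rss_full) / rss_cov, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, t, p, partial


def env_assoc_scan(
    dosage: np.ndarray,
    env_frame: pd.DataFrame,
    pc_scores: np.ndarray,
    loci: pd.DataFrame,
    pc_grid: tuple[int, ...] = (2, 3, 4),
    alpha: float = 0.05,
    fdr: float = 0.05,
) -> EnvGWASResult:
    """Scan every (SNP, variable) pair with PC-corrected linear models.

    For each variable the PC count from ``pc_grid`` with inflation factor
    closest to 1 is kept (an automated stand-in for QQ-plot inspection).
    Bonferroni flags use alpha / n_polymorphic_SNPs; FDR flags use Storey
    q-values. Monomorphic SNPs are skipped and counted.
    """
    D = np.asarray(dosage, dtype=float)
    poly = D.std(axis=0) > 0
    n_skipped = int((~poly).sum())
    Dp = D[:, poly]
    loci_p = loci.loc[poly].reset_index(drop=True)
    L = Dp.shape[1]

    rows = []
    chosen = {}
    gifs = {}
    for var in env_frame.columns:
        y = env_frame[var].to_numpy(dtype=float)
        best = None
        for k in pc_grid:
            beta, t, p, partial = _scan_one(y, Dp, pc_scores[:, :k])
            lam = float(np.median(t**2) / CHI2_1_MEDIAN)
            gifs[(var, k)] = lam
            if best is None or abs(lam - 1.0) < abs(best[0] - 1.0):
                best = (lam, k, beta, t, p, partial)
        lam, k, beta, t, p, partial = best
        chosen[var] = k
        q = storey_qvalues(p)
        rows.append(
            pd.DataFrame(
                {
                    "snp": loci_p["id"].to_numpy(),
                    "chrom": loci_p["chrom"].to_numpy(),
                    "pos": loci_p["pos"].to_numpy(),
                    "variable": var,
                    "n_pcs": k,
                    "gif": lam,
                    "effect": beta,
                    "t": t,
                    "p": p,
                    "q": q,
                    "partial_r2": partial,
                    "bonferroni_flag": p < alpha / L,
                    "fdr_flag": q < fdr,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return EnvGWASResult(
        table=table, chosen_pcs=chosen, gif=gifs, n_skipped_monomorphic=n_skipped
    )


def partial_r2(
    env_values: np.ndarray, snp_dosage: np.ndarray, pcs: np.ndarray | None
) -> float:
    """Fraction of trait variance explained by one SNP beyond the PC
    covariates: (RSS_cov - RSS_full) / RSS_cov."""
    y = np.asarray(env_values, dtype=float)
    x = np.asarray(snp_dosage, dtype=float)
    n = y.size
    base = np.ones((n, 1)) if pcs is None else np.column_stack([np.ones(n), pcs])
    full = np.column_stack([base, x])
    rss_cov = float(np.sum((y - base @ np.linalg.lstsq(base, y, rcond=None)[0]) ** 2))
    rss_full = float(np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2))
    if rss_cov == 0:
        return float("nan")
    return (rss_cov - rss_full) / rss_cov
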