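"""Latent factor mixed model (LFMM) genotype-environment association with
genomic-inflation-factor calibration, Storey q-values, and multi-run
consensus.

The default "pc-factors" mode fixes the latent factors to the first K
genotype principal components and tests each locus by ordinary least
squares on [env, factors]; it is deterministic. The "alternate" mode
estimates factors jointly with effects by alternating ridge updates and a
rank-K singular decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1_MEDIAN = 0.4549  # median of chi-squared with 1 df, 4 decimals


@dataclass
class LFMMResult:
    effects: np.ndarray  # per-locus effect of the env variable
    z: np.ndarray
    p_raw: np.ndarray
    p_cal: np.ndarray
    q: np.ndarray
    gif: float
    k_factors: int
    variable: str
    run_id: int = 0


def _ols_scan(Y: np.ndarray, design: np.ndarray, test_col: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus OLS of every column of Y on a shared design matrix.

    Returns (effect, z, p) for the coefficient at ``test_col``; z is the
    t-statistic (approximately normal at the sample sizes used here).
    """
    n, d = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    coefs = xtx_inv @ design.T @ Y  # d x L
    resid = Y - design @ coefs
    dof = n - d
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[test_col, test_col], 1e-300))
    effect = coefs[test_col]
    z = effect / se
    p = 2.0 * stats.t.sf(np.abs(z), dof)
    return effect, z, p


def fit_lfmm_ridge(
    Y: np.ndarray,
    x: np.ndarray,
    K: int = 2,
    mode: str = "pc-factors",
    ridge_lambda: float = 1e-5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    variable: str = "env",
    factors: np.ndarray | None = None,
) -> LFMMResult:
    """Per-locus association of dosages with one environmental variable,
    correcting for K latent factors of population structure.

    Model: Y = x b' + U V' + E. In "pc-factors" mode U is fixed to the
    first K genotype PC score axes (pass them via ``factors`` to avoid
    recomputation); in "alternate" mode U, V and the effects are estimated
    by alternating minimization with a small ridge penalty.
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    n, L = Y.shape
    Yc = Y - Y.mean(axis=0)
    xc = x - x.mean()

    if mode == "pc-factors":
        if K > 0:
            if factors is None:
                u, s, _ = np.linalg.svd(Yc, full_matrices=False)
                factors = (u * s)[:, :K]
            U = factors[:, :K]
            design = np.column_stack([np.ones(n), xc, U])
        else:
            design = np.column_stack([np.ones(n), xc])
    elif mode == "alternate":
        rng = np.random.default_rng(seed)
        B = np.zeros(L)
        U = rng.standard_normal((n, K)) * 0.01 if K > 0 else np.zeros((n, 0))
        V = np.zeros((L, K))
        denom = float(xc @ xc) + ridge_lambda
        prev = np.inf
        for it in range(max_iter):
            B = ((Yc - U @ V.T).T @ xc) / denom
            R = Yc - np.outer(xc, B)
            if K > 0:
                u, s, vt = np.linalg.svd(R, full_matrices=False)
                U = u[:, :K] * s[:K]
                V = vt[:K].T
            obj = float(np.sum((Yc - np.outer(xc, B) - U @ V.T) ** 2))
            if prev < np.inf and abs(prev - obj) <= tol * max(prev, 1e-12):
                break
            prev = obj
        else:
            warnings.warn(f"alternate mode did not converge in {max_iter} iterations", stacklevel=2)
        design = np.column_stack([np.ones(n), xc, U]) if K > 0 else np.column_stack([np.ones(n), xc])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # condition check: env collinear with factors inflates everything
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > 1e8:
        warnings.warn("design matrix ill-conditioned (env collinear with factors?)", stacklevel=2)

    effect, z, p_raw = _ols_scan(Yc, design, test_col=1)
    gif, p_cal = gif_calibrate(z)
    q = storey_qvalues(p_cal)
    return LFMMResult(
        effects=effect,
        z=z,
        p_raw=p_raw,
        p_cal=p_cal,
        q=q,
        gif=gif,
        k_factors=K,
        variable=variable,
    )


def gif_calibrate(z: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic inflation factor and recalibrated p-values.

    lambda = median(z^2) / 0.4549; calibrated p is the upper chi-squared(1)
    tail of z^2 / lambda. Warns below 100 tests (the median is noisy).
    """
    z = np.asarray(z, dtype=float)
    if np.all(z == 0):
        raise ValueError("all z-scores are zero; inflation factor undefined")
    if z.size < 100:
        warnings.warn("fewer than 100 tests; inflation factor is unstable", stacklevel=2)
    lam = float(np.median(z**2) / CHI2_1_MEDIAN)
    p = stats.chi2.sf(z**2 / lam, df=1)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return lam, p


def storey_qvalues(p: np.ndarray) -> np.ndarray:
    """Storey q-values with the Storey-Tibshirani pi0 smoother.

    pi0 is estimated from #{p > lambda} / (m (1 - lambda)) on the grid
    lambda = 0.05..0.95 (step 0.05) with a cubic smoother evaluated at the
    largest lambda, clamped to (0, 1]. Below 100 p-values pi0 falls back to
    1, which makes the q-values Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0,1]")
    m = p.size
    if m < 100:
        pi0 = 1.0
    else:
        grid = np.arange(0.05, 0.96, 0.05)
        pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
        # cubic polynomial smoother evaluated at the right end of the grid
        coef = np.polyfit(grid, pi0_lambda, 3)
        pi0 = float(np.polyval(coef, grid[-1]))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p)
    q = np.empty(m)
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q[order] = q_sorted
    return q


@dataclass
class LFMMScanResult:
    per_run: pd.DataFrame  # snp, variable, run, beta, z, p_raw, p_cal, q
    consensus: pd.DataFrame  # snp, variable, consensus_flag per (snp, variable)
    gif: dict  # (variable, run) -> lambda
    deterministic: bool


def lfmm_scan(
    Y: np.ndarray,
    env_frame: pd.DataFrame,
    loci: pd.DataFrame,
    K: int = 2,
    n_runs: int = 5,
    fdr: float = 0.05,
    mode: str = "pc-factors",
    seeds: list[int] | None = None,
) -> LFMMScanResult:
    """Run the LFMM scan for every climate variable with replicate runs.

    A (SNP, variable) pair is a consensus hit iff q < ``fdr`` in every run.
    In "pc-factors" mode the runs are deterministic and identical, which is
    recorded in the result.
    """
    if seeds is None:
        seeds = list(range(n_runs))
    if len(seeds) != n_runs:
        raise ValueError("need one seed per run")
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    u, s, _ = np.linalg.svd(Yc, full_matrices=False)
    factors = (u * s)[:, :K] if K > 0 else None

    snp_ids = loci["id"].to_numpy()
    rows = []
    sig = {}
    gifs = {}
    for var in env_frame.columns:
        x = env_frame[var].to_numpy(dtype=float)
        hits_per_run = []
        for run, seed in enumerate(seeds):
            res = fit_lfmm_ridge(
                Y, x, K=K, mode=mode, seed=seed, variable=var, factors=factors
            )
            gifs[(var, run)] = res.gif
            hits_per_run.append(res.q < fdr)
            rows.append(
                pd.DataFrame(
                    {
                        "snp": snp_ids,
                        "chrom": loci["chrom"].to_numpy(),
                        "pos": loci["pos"].to_numpy(),
                        "variable": var,
                        "run": run,
                        "beta": res.effects,
                        "z": res.z,
                        "p_raw": res.p_raw,
                        "p_cal": res.p_cal,
                        "q": res.q,
                    }
                )
            )
        sig[var] = np.logical_and.reduce(hits_per_run)
    per_run = pd.concat(rows, ignore_index=True)
    cons_rows = []
    for var, flags in sig.items():
        idx = np.flatnonzero(flags)
        for i in idx:
            cons_rows.append(
                {
                    "snp": snp_ids[i],
                    "chrom": loci["chrom"].iloc[i],
                    "pos": loci["pos"].iloc[i],
                    "variable": var,
                }
            )
    consensus = pd.DataFrame(cons_rows, columns=["snp", "chrom", "pos", "variable"])
    return LFMMScanResult(
        per_run=per_run,
        consensus=consensus,
        gif=gifs,
        deterministic=(mode == "pc-factors"),
    )
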