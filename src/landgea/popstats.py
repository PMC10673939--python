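"""Sliding-window diversity statistics (SNP density, pi, Watterson's theta,
Tajima's D), candidate-vs-noncandidate window comparison, and LD decay.

pi and theta_W are normalized per segregating site (not per bp): window pi
is the mean per-site heterozygosity over segregating sites and theta_W is
1/a1 at the window-average chromosome count. This is the normalization
under which SNP-panel (as opposed to full-sequence) data yield theta in the
0.1-0.2 range and pi around 0.3; a per-bp mode is exposed for completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .genio import GenotypeMatrix, r2_matrix


@dataclass
class GenomicWindow:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    partial: bool = False
    snp_count: int = 0
    pi: float = float("nan")
    theta_w: float = float("nan")
    tajima_d: float = float("nan")
    candidate: bool = False


def make_windows(
    chrom_lengths: dict[str, int], size: int = 20_000, step: int = 10_000
) -> list[GenomicWindow]:
    """Sliding windows starting at 1, advancing by ``step``; a trailing
    window that would overrun the chromosome is truncated and flagged."""
    if size < 1 or step < 1:
        raise ValueError("size and step must be >= 1")
    if step > size:
        warnings.warn("step > size leaves gaps between windows", stacklevel=2)
    windows = []
    for chrom, length in chrom_lengths.items():
        start = 1
        while start <= length:
            end = start + size - 1
            if end > length:
                windows.append(GenomicWindow(chrom, start, length, partial=True))
                break
            windows.append(GenomicWindow(chrom, start, end))
            if end == length:
                break
            start += step
    return windows


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima's a1, a2, b1, b2, c1, c2, e1, e2 for sample size n (chromosomes)."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _site_stats(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site chromosome counts, alt frequency and pairwise diversity.

    n_c = 2 x non-missing individuals; per-site pi = 2 p (1-p) n_c/(n_c-1),
    the unbiased mean pairwise difference at that site. Sites with n_c < 2
    get NaN.
    """
    n_c = 2.0 * np.sum(np.isfinite(d), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / n_c
        pi = 2.0 * p * (1.0 - p) * n_c / (n_c - 1.0)
    bad = n_c < 2
    pi[bad] = np.nan
    p[bad] = np.nan
    return n_c, p, pi


def window_stats(
    g: GenotypeMatrix,
    windows: list[GenomicWindow],
    normalization: str = "per_site",
) -> list[GenomicWindow]:
    """Fill windows with SNP count, pi, theta_W and Tajima's D.

    Per window: S = segregating sites; pi = mean per-site diversity over
    segregating sites ("per_site") or the summed diversity divided by the
    window length in bp ("per_bp"); theta_W = 1/a1 per segregating site (or
    S/(a1 * bp)); Tajima's D = (sum(pi) - S/a1) / sqrt(e1 S + e2 S (S-1))
    with the constants at n = rounded window-average chromosome count.
    Statistics are undefined when S = 0 (or S = 1 for D's variance).
    """
    if normalization not in ("per_site", "per_bp"):
        raise ValueError(f"unknown normalization {normalization!r}")
    n_c, p, pi_site = _site_stats(g.dosage)
    seg = np.isfinite(p) & (p > 0) & (p < 1)
    chrom = g.loci["chrom"].to_numpy()
    pos = g.loci["pos"].to_numpy()
    out = []
    for w in windows:
        w = GenomicWindow(w.chrom, w.start, w.end, partial=w.partial, candidate=w.candidate)
        mask = (chrom == w.chrom) & (pos >= w.start) & (pos <= w.end) & seg
        S = int(mask.sum())
        w.snp_count = S
        if S > 0:
            pi_sum = float(np.sum(pi_site[mask]))
            n_bar = int(round(float(np.mean(n_c[mask]))))
            span = w.end - w.start + 1
            if n_bar >= 2:
                k = tajima_constants(n_bar)
                if normalization == "per_site":
                    w.pi = pi_sum / S
                    w.theta_w = 1.0 / k["a1"]
                else:
                    w.pi = pi_sum / span
                    w.theta_w = S / (k["a1"] * span)
                var = k["e1"] * S + k["e2"] * S * (S - 1)
                if var > 0:
                    w.tajima_d = (pi_sum - S / k["a1"]) / np.sqrt(var)
        out.append(w)
    return out


def windows_frame(windows: list[GenomicWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "snp_count": w.snp_count,
                "pi": w.pi,
                "theta_w": w.theta_w,
                "tajima_d": w.tajima_d,
                "partial_flag": w.partial,
                "candidate_flag": w.candidate,
            }
            for w in windows
        ]
    )


def compare_candidate_windows(
    windows: list[GenomicWindow], candidate_intervals: pd.DataFrame
) -> pd.DataFrame:
    """Mean +/- sd of each window statistic for candidate-overlapping vs
    other windows.

    A window is candidate iff it overlaps any interval (columns
    ``chrom start end``) by >= 1 bp. Windows with undefined D are dropped
    from the D summary only; the dropped count is reported.
    """
    for w in windows:
        w.candidate = False
        sub = candidate_intervals[candidate_intervals["chrom"] == w.chrom]
        for iv in sub.itertuples(index=False):
            if iv.start <= w.end and iv.end >= w.start:
                w.candidate = True
                break
    df = windows_frame(windows)
    rows = []
    for cls, grp in (("candidate", df[df["candidate_flag"]]), ("noncandidate", df[~df["candidate_flag"]])):
        if grp.empty:
            rows.append({"class": cls, "empty": True})
            continue
        d_def = grp["tajima_d"].dropna()
        rows.append(
            {
                "class": cls,
                "empty": False,
                "n_windows": len(grp),
                "snp_count_mean": grp["snp_count"].mean(),
                "snp_count_sd": grp["snp_count"].std(),
                "pi_mean": grp["pi"].mean(),
                "pi_sd": grp["pi"].std(),
                "theta_w_mean": grp["theta_w"].mean(),
                "theta_w_sd": grp["theta_w"].std(),
                "tajima_d_mean": d_def.mean() if len(d_def) else float("nan"),
                "tajima_d_sd": d_def.std() if len(d_def) else float("nan"),
                "n_undefined_d": int(grp["tajima_d"].isna().sum()),
            }
        )
    return pd.DataFrame(rows)


def hill_weir_expected_r2(d: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Hill-Weir drift-recombination expectation of r2 at distance d (bp)
    with per-bp recombination-scale rho and sample size n chromosomes."""
    C = rho * np.asarray(d, dtype=float)
    term1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    term2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return term1 * term2


@dataclass
class LDDecayCurve:
    bins: pd.DataFrame  # chrom, bin_start, mean_r2, n_pairs
    rho: dict  # chrom -> fitted rho
    decay_distance: dict  # chrom -> bp (NaN when undefined)
    r2_at_zero: dict
    r2_floor: dict


def ld_decay(
    g: GenotypeMatrix,
    max_dist: int = 300_000,
    bin_size: int = 1_000,
    min_bins: int = 10,
    cutoff: float | None = None,
) -> LDDecayCurve:
    """Binned LD decay and per-chromosome decay distance.

    All within-chromosome pairs up to ``max_dist`` apart are scored by
    pairwise-complete r2 and averaged in distance bins. The Hill-Weir
    expected-r2 curve is fitted to the bin means by nonlinear least
    squares; the decay distance is the smallest distance where the fitted
    curve falls to halfway between its value near zero and its asymptote
    (or below ``cutoff`` when one is given). Chromosomes with fewer than
    ``min_bins`` populated bins get an undefined decay distance.
    """
    n_chrom = 2 * g.n_samples
    rows = []
    rho_fit = {}
    decay = {}
    r2_zero = {}
    r2_floor = {}
    chroms = pd.unique(g.loci["chrom"])
    for chrom in chroms:
        idx = np.flatnonzero((g.loci["chrom"] == chrom).to_numpy())
        pos = g.loci["pos"].to_numpy()[idx]
        if idx.size < 2:
            decay[chrom] = float("nan")
            continue
        r2 = r2_matrix(g.dosage[:, idx])
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = pos[jj] - pos[ii]
        keep = (dist <= max_dist) & np.isfinite(r2[ii, jj])
        dist = dist[keep]
        vals = r2[ii, jj][keep]
        if dist.size == 0:
            decay[chrom] = float("nan")
            continue
        bins = (dist - 1) // bin_size
        bdf = pd.DataFrame({"bin": bins, "r2": vals}).groupby("bin")["r2"].agg(["mean", "size"])
        for b, row in bdf.iterrows():
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": int(b) * bin_size + 1,
                    "mean_r2": row["mean"],
                    "n_pairs": int(row["size"]),
                }
            )
        if len(bdf) < min_bins:
            decay[chrom] = float("nan")
            continue
        bin_mid = (bdf.index.to_numpy() + 0.5) * bin_size
        means = bdf["mean"].to_numpy()
        try:
            popt, _ = curve_fit(
                lambda d, rho: hill_weir_expected_r2(d, rho, n_chrom),
                bin_mid,
                means,
                p0=[1e-4],
                bounds=(1e-12, 10.0),
                maxfev=10_000,
            )
            rho = float(popt[0])
        except RuntimeError:
            decay[chrom] = float("nan")
            continue
        rho_fit[chrom] = rho
        grid = np.arange(1, max(int(bin_mid.max()), 2) + 1, max(bin_size // 10, 1))
        curve = hill_weir_expected_r2(grid, rho, n_chrom)
        r0 = float(curve[0])
        floor = float(hill_weir_expected_r2(np.array([1e9]), rho, n_chrom)[0])
        r2_zero[chrom] = r0
        r2_floor[chrom] = floor
        target = cutoff if cutoff is not None else (r0 + floor) / 2.0
        below = np.flatnonzero(curve <= target)
        decay[chrom] = float(grid[below[0]]) if below.size else float("nan")
    return LDDecayCurve(
        bins=pd.DataFrame(rows, columns=["chrom", "bin_start", "mean_r2", "n_pairs"]),
        rho=rho_fit,
        decay_distance=decay,
        r2_at_zero=r2_zero,
        r2_floor=r2_floor,
    )
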