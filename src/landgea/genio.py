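"""Genotype I/O, per-locus QC, filtering, imputation, pairwise r2 and LD pruning.

Genotypes are held as an individuals x loci dosage matrix (alt-allele count
0/1/2, NaN for missing calls) with a per-locus metadata frame. Two filter
presets are provided: a "structure" set (for PCA / clustering / Fst) and a
more permissive "outlier" set (for the association scans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOCUS_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic dosage matrix with locus metadata.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    loci : pandas.DataFrame
        One row per locus with columns ``chrom, pos, id, ref, alt``;
        positions are 1-based and rows are sorted by (chrom, pos).
    dosage : numpy.ndarray, shape (n_samples, n_loci)
        Alt-allele counts in {0, 1, 2}; missing calls are NaN.
    """

    samples: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the loci at ``index`` (order preserved as given)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index].copy(),
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = self.loci.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        if np.array_equal(order, np.arange(self.n_loci)):
            return self
        return self.take_loci(order)


@dataclass
class LocusQC:
    """Per-locus QC summary table plus the thresholds applied."""

    table: pd.DataFrame = field(repr=False)

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def read_genotypes(vcf_path: str, skip_non_biallelic_snps: bool = True) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped when
    ``skip_non_biallelic_snps`` is true, otherwise they raise. Output loci
    are sorted by (chromosome, position) regardless of input order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosages = []
    for variant in vcf:
        biallelic_snp = (
            len(variant.ALT) == 1
            and len(variant.REF) == 1
            and len(variant.ALT[0]) == 1
        )
        if not biallelic_snp:
            if skip_non_biallelic_snps:
                continue
            raise ValueError(
                f"non-biallelic or non-SNP record at {variant.CHROM}:{variant.POS}"
            )
        rows.append(
            (
                variant.CHROM,
                int(variant.POS),
                variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}",
                variant.REF,
                variant.ALT[0],
            )
        )
        # gts012: 0/1/2 dosage, 3 = unknown
        gt = np.asarray(variant.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        dosages.append(gt)
    vcf.close()
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {vcf_path}")
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    g = GenotypeMatrix(samples=samples, loci=loci, dosage=np.column_stack(dosages))
    return g.sorted_by_position()


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT-only calls."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.loci["chrom"]):
            length = int(g.loci.loc[g.loci["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, row in enumerate(g.loci.itertuples(index=False)):
            calls = "\t".join(
                code.get(d, "./.") if np.isfinite(d) else "./." for d in g.dosage[:, j]
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{calls}\n"
            )


def locus_qc(g: GenotypeMatrix) -> LocusQC:
    """Per-locus MAF, heterozygosity rate and missing-call rate.

    MAF and het rate are computed over non-missing calls only; missing rate
    over all samples. Loci with zero non-missing calls get NaN MAF/het.
    """
    d = g.dosage
    n_nonmiss = np.sum(np.isfinite(d), axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_hat = np.nansum(d, axis=0) / (2.0 * n_nonmiss)
        het = np.nansum(d == 1, axis=0) / n_nonmiss
    maf = np.minimum(p_hat, 1.0 - p_hat)
    missing = 1.0 - n_nonmiss / g.n_samples
    table = g.loci[["id", "chrom", "pos"]].copy()
    table["maf"] = maf
    table["het_rate"] = het
    table["missing_rate"] = missing
    return LocusQC(table=table)


def filter_loci(
    g: GenotypeMatrix,
    filter_set: str = "structure",
    *,
    maf: float | None = None,
    het: float | None = None,
    missing: float | None = None,
) -> GenotypeMatrix:
    """Apply one of the two QC filter presets.

    ``"structure"`` keeps loci with missing_rate <= 0.2, het_rate <= 0.2 and
    MAF >= 0.1 (inclusive keeps). ``"outlier"`` removes loci with MAF <= 0.05,
    het_rate >= 0.2 or missing_rate >= 0.2, i.e. keeps strict inequalities.
    Thresholds can be overridden; locus order is preserved.
    """
    qc = locus_qc(g).table
    if filter_set == "structure":
        maf = 0.1 if maf is None else maf
        het = 0.2 if het is None else het
        missing = 0.2 if missing is None else missing
        keep = (
            (qc["missing_rate"] <= missing)
            & (qc["het_rate"] <= het)
            & (qc["maf"] >= maf)
        )
    elif filter_set == "outlier":
        maf = 0.05 if maf is None else maf
        het = 0.2 if het is None else het
        missing = 0.2 if missing is None else missing
        keep = (
            (qc["maf"] > maf)
            & (qc["het_rate"] < het)
            & (qc["missing_rate"] < missing)
        )
    else:
        raise ValueError(f"unknown filter set {filter_set!r}")
    keep = keep.fillna(False).to_numpy()
    if not keep.any():
        warnings.warn("all loci removed by filter", stacklevel=2)
    return g.take_loci(np.flatnonzero(keep))


def impute_modal(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the locus's most frequent observed dosage.

    Frequency ties are broken toward the dosage nearest 2*p_hat (the locus
    mean); an exactly equidistant tie goes to the lower dosage.
    """
    d = g.dosage.copy()
    miss_cols = np.flatnonzero(np.any(~np.isfinite(d), axis=0))
    for j in miss_cols:
        col = d[:, j]
        obs = col[np.isfinite(col)]
        if obs.size == 0:
            raise ValueError(f"locus {g.loci['id'].iloc[j]} has no observed calls")
        counts = np.array([(obs == k).sum() for k in (0, 1, 2)])
        best = np.flatnonzero(counts == counts.max())
        if best.size > 1:
            mean = obs.mean()
            dist = np.abs(best - mean)
            best = best[dist == dist.min()]
        mode = float(best.min())
        col[~np.isfinite(col)] = mode
        d[:, j] = col
    return GenotypeMatrix(samples=list(g.samples), loci=g.loci.copy(), dosage=d)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete observations; returns NaN when fewer than two
    complete pairs remain or either vector has zero variance on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise-complete r2 between all column pairs of a dosage block.

    Vectorized over the block: terms involving a missing call drop out of
    every sum, so each pair's statistic uses only its complete observations.
    Pairs with <2 complete observations or zero variance are NaN.
    """
    d = np.asarray(d, dtype=float)
    mask = np.isfinite(d).astype(float)
    z = np.where(np.isfinite(d), d, 0.0)
    n = mask.T @ mask
    sxy = z.T @ z
    sx = z.T @ mask
    sy = sx.T
    sxx = (z * z).T @ mask
    syy = sxx.T
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx * sx / n
        vary = syy - sy * sy / n
        r2 = (cov * cov) / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 150,
    step_snps: int = 5,
    r2_max: float = 0.5,
) -> GenotypeMatrix:
    """PLINK ``--indep-pairwise``-style LD pruning.

    Per chromosome, a window of ``window_snps`` markers slides forward by
    ``step_snps``. Within each window every remaining pair with r2 above the
    threshold loses its lower-MAF member (MAF tie: the later position is
    removed). Sweeps repeat until no window contains a violating pair.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    qc = locus_qc(g).table
    maf = qc["maf"].to_numpy()
    keep = np.ones(g.n_loci, dtype=bool)
    for chrom in pd.unique(g.loci["chrom"]):
        idx = np.flatnonzero((g.loci["chrom"] == chrom).to_numpy())
        changed = True
        while changed:
            changed = False
            for start in range(0, max(1, len(idx) - 1), step_snps):
                win = idx[start : start + window_snps]
                live = win[keep[win]]
                if live.size < 2:
                    continue
                r2 = r2_matrix(g.dosage[:, live])
                # local indices of violating pairs, scanned in order
                ii, jj = np.where(np.triu(r2 > r2_max, k=1))
                for a, b in zip(ii, jj):
                    ga, gb = live[a], live[b]
                    if not (keep[ga] and keep[gb]):
                        continue
                    if maf[ga] < maf[gb]:
                        victim = ga
                    elif maf[gb] < maf[ga]:
                        victim = gb
                    else:  # tie: drop the later position
                        victim = gb
                    keep[victim] = False
                    changed = True
                if start + window_snps >= len(idx):
                    break
    return g.take_loci(np.flatnonzero(keep))


def qc_report(g: GenotypeMatrix) -> pd.DataFrame:
    """QC table with per-preset keep flags, ready to write as TSV."""
    qc = locus_qc(g).table.copy()
    qc["kept_structure"] = (
        (qc["missing_rate"] <= 0.2) & (qc["het_rate"] <= 0.2) & (qc["maf"] >= 0.1)
    )
    qc["kept_outlier"] = (
        (qc["maf"] > 0.05) & (qc["het_rate"] < 0.2) & (qc["missing_rate"] < 0.2)
    )
    return qc
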