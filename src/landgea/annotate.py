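"""Candidate intervals from per-chromosome LD decay distances, gene mapping
with distance and orientation, and cross-method consensus / pleiotropy
bookkeeping."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene features from a GFF3 as a frame: gene_id, chrom, start, end, strand."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", attrs.get("Name", f"{parts[0]}:{parts[3]}")),
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def candidate_intervals(
    significant_snps: pd.DataFrame,
    decay_distances: dict[str, float],
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """One interval per significant SNP: position +/- the chromosome's LD
    decay distance, clipped at 1 and the chromosome end.

    ``significant_snps`` needs columns ``snp chrom pos`` and optionally
    ``methods`` / ``variables`` provenance columns, which are carried over.
    """
    rows = []
    for rec in significant_snps.itertuples(index=False):
        if rec.chrom not in decay_distances or not np.isfinite(decay_distances[rec.chrom]):
            raise ValueError(f"no LD decay distance for chromosome {rec.chrom}")
        d = int(round(decay_distances[rec.chrom]))
        start = max(1, int(rec.pos) - d)
        end = int(rec.pos) + d
        if chrom_lengths is not None and rec.chrom in chrom_lengths:
            end = min(end, chrom_lengths[rec.chrom])
        row = {
            "snp": rec.snp,
            "chrom": rec.chrom,
            "pos": int(rec.pos),
            "start": start,
            "end": end,
            "width": end - start + 1,
        }
        for extra in ("methods", "variables"):
            if hasattr(rec, extra):
                row[extra] = getattr(rec, extra)
        rows.append(row)
    return pd.DataFrame(rows)


def map_genes(intervals: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes overlapping each candidate interval, plus the nearest gene
    outside it.

    ``relation`` is resolved on the gene's strand: a SNP 5' of the gene
    start is upstream-of-gene, 3' of the gene end downstream-of-gene, and
    inside the gene "within" with distance 0. Intervals on chromosomes
    absent from the annotation are skipped with a warning.
    """
    known_chroms = set(genes["chrom"])
    rows = []
    for iv in intervals.itertuples(index=False):
        if iv.chrom not in known_chroms:
            warnings.warn(f"chromosome {iv.chrom} absent from annotation", stacklevel=2)
            continue
        sub = genes[genes["chrom"] == iv.chrom]
        overlapping = sub[(sub["start"] <= iv.end) & (sub["end"] >= iv.start)]
        for gene in overlapping.itertuples(index=False):
            rows.append(_gene_hit(iv, gene, in_interval=True))
        outside = sub.drop(overlapping.index)
        if not outside.empty:
            gaps = np.where(
                outside["start"] > iv.end,
                outside["start"] - iv.end,
                iv.start - outside["end"],
            )
            nearest = outside.iloc[int(np.argmin(gaps))]
            rows.append(_gene_hit(iv, nearest, in_interval=False))
    return pd.DataFrame(
        rows,
        columns=[
            "snp",
            "chrom",
            "pos",
            "gene_id",
            "gene_start",
            "gene_end",
            "strand",
            "in_interval",
            "distance",
            "relation",
        ],
    )


def _gene_hit(iv, gene, in_interval: bool) -> dict:
    pos = int(iv.pos)
    gstart, gend = int(gene.start), int(gene.end)
    if gstart <= pos <= gend:
        distance = 0
        relation = "within"
    else:
        if pos < gstart:
            distance = gstart - pos
            relation = "upstream-of-gene" if gene.strand == "+" else "downstream-of-gene"
        else:
            distance = pos - gend
            relation = "downstream-of-gene" if gene.strand == "+" else "upstream-of-gene"
    g_id = gene.gene_id if hasattr(gene, "gene_id") else gene[0]
    return {
        "snp": iv.snp,
        "chrom": iv.chrom,
        "pos": pos,
        "gene_id": g_id,
        "gene_start": gstart,
        "gene_end": gend,
        "strand": gene.strand,
        "in_interval": in_interval,
        "distance": distance,
        "relation": relation,
    }


def consensus_pleiotropy(method_tables: dict[str, pd.DataFrame]) -> dict:
    """Unify significant (SNP, variable) pairs across detection methods.

    Each input table needs columns ``snp chrom pos variable`` (variable may
    be "none" for methods without a driver attribution, e.g. the RDA
    outlier scan). A SNP is pleiotropic iff associated with >= 2 distinct
    named variables in the union; SNPs found by >= 2 methods are the
    cross-method common set. Conflicting positions for one SNP id raise.
    """
    frames = []
    for method, tab in method_tables.items():
        if tab is None or tab.empty:
            continue
        t = tab[["snp", "chrom", "pos", "variable"]].copy()
        t["method"] = method
        frames.append(t)
    if not frames:
        return {
            "pairs": pd.DataFrame(columns=["snp", "chrom", "pos", "variable", "methods"]),
            "snps": pd.DataFrame(columns=["snp", "chrom", "pos", "variables", "methods", "pleiotropic", "n_methods"]),
            "n_pleiotropic": 0,
            "n_common": 0,
        }
    allrows = pd.concat(frames, ignore_index=True)
    poscheck = allrows.groupby("snp")[["chrom", "pos"]].nunique()
    bad = poscheck[(poscheck["chrom"] > 1) | (poscheck["pos"] > 1)]
    if not bad.empty:
        raise ValueError(f"conflicting positions for SNP ids: {', '.join(bad.index)}")

    pairs = (
        allrows.groupby(["snp", "chrom", "pos", "variable"])["method"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"method": "methods"})
    )
    per_snp = []
    for snp, grp in allrows.groupby("snp"):
        variables = sorted(set(v for v in grp["variable"] if v not in ("none", "", None)))
        methods = sorted(set(grp["method"]))
        per_snp.append(
            {
                "snp": snp,
                "chrom": grp["chrom"].iloc[0],
                "pos": grp["pos"].iloc[0],
                "variables": ",".join(variables),
                "methods": ",".join(methods),
                "pleiotropic": len(variables) >= 2,
                "n_methods": len(methods),
            }
        )
    snps = pd.DataFrame(per_snp).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return {
        "pairs": pairs,
        "snps": snps,
        "n_pleiotropic": int(snps["pleiotropic"].sum()),
        "n_common": int((snps["n_methods"] >= 2).sum()),
    }
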