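"""End-to-end pipeline: simulate (or load) -> QC -> structure -> climate
selection -> pRDA -> LFMM -> EnvGWAS -> windows/LD decay -> candidate genes.

Every stage writes a TSV into the output directory and the manifest records
each file with a checksum, so two runs under the same seed are verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, envgwas, envmod, genio, lfmm, popstats, rda, structure, synthdata

log = logging.getLogger("landgea")


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the study settings:
    structure filter (missing 0.2, het 0.2, MAF 0.1); outlier filter (MAF
    0.05, het 0.2, missing 0.2); LD pruning 150/5/0.5; 3 structure PCs in
    pRDA; 4 RDA axes with Bonferroni alpha 0.1 for outliers; LFMM K=2 with
    5 runs at FDR 0.05; EnvGWAS PC grid {2,3,4} at alpha/FDR 0.05; 20 kb
    windows with 10 kb step; LD decay to 300 kb."""

    vcf: str | None = None
    env: str | None = None
    gff: str | None = None
    simulate: synthdata.LandscapeConfig | None = None
    outdir: str = "landgea_out"
    seed: int = 0
    exclude_samples: list[str] = field(default_factory=list)

    prune_window: int = 150
    prune_step: int = 5
    prune_r2: float = 0.5
    structure_axes: int = 3
    k_max: int = 8
    rda_axes: int = 4
    rda_bonferroni: float = 0.1
    lfmm_k: int = 2
    lfmm_runs: int = 5
    fdr: float = 0.05
    gwas_alpha: float = 0.05
    pc_grid: tuple[int, ...] = (2, 3, 4)
    window_size: int = 20_000
    window_step: int = 10_000
    ld_max_dist: int = 300_000
    forward_alpha: float = 0.05
    forward_perm: int = 199
    amova_perm: int = 199


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the manifest of result tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        tables[name] = path
        log.info("stage output %s: %d rows", name, len(frame))

    # --- inputs -----------------------------------------------------------
    if config.simulate is not None:
        g, env_frame, truth = synthdata.simulate_dataset(config.simulate)
        manifest = synthdata.emit_dataset(g, env_frame, truth, outdir / "data", config.simulate)
        gff_path = manifest["files"]["gff"]
        chrom_lengths = dict(zip(config.simulate.chrom_names, config.simulate.chrom_lengths))
    else:
        for path, label in ((config.vcf, "vcf"), (config.env, "env")):
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"missing {label} input: {path}")
        g = genio.read_genotypes(config.vcf)
        env_frame = pd.read_csv(config.env, sep="\t")
        gff_path = config.gff
        chrom_lengths = (
            g.loci.groupby("chrom")["pos"].max().astype(int).to_dict()
        )
    if config.exclude_samples:
        keep = [i for i, s in enumerate(g.samples) if s not in set(config.exclude_samples)]
        g = genio.GenotypeMatrix(
            samples=[g.samples[i] for i in keep], loci=g.loci, dosage=g.dosage[keep]
        )
        env_frame = env_frame[env_frame["sample"].isin(g.samples)].reset_index(drop=True)
    env_frame = env_frame.set_index("sample").loc[g.samples].reset_index()

    # --- QC and filter sets ----------------------------------------------
    emit("qc_report", genio.qc_report(g))
    g_structure = genio.filter_loci(g, "structure")
    g_outlier = genio.filter_loci(g, "outlier")
    g_pruned = genio.ld_prune(
        g_structure, config.prune_window, config.prune_step, config.prune_r2
    )
    log.info(
        "filters: %d loci -> structure %d -> pruned %d; outlier %d",
        g.n_loci, g_structure.n_loci, g_pruned.n_loci, g_outlier.n_loci,
    )

    # --- population structure --------------------------------------------
    g_pruned_imp = genio.impute_modal(g_pruned)
    pca = structure.genotype_pca(g_pruned_imp)
    emit(
        "pca_scores",
        pd.DataFrame(
            pca.scores[:, :10],
            columns=[f"PC{i+1}" for i in range(min(10, pca.scores.shape[1]))],
        ).assign(sample=g.samples),
    )
    clusters = structure.infer_clusters(
        pca, k_max=min(config.k_max, g.n_samples - 1), seed=config.seed
    )
    emit("clusters", pd.DataFrame({"sample": g.samples, "group": clusters.labels}))
    fst = structure.pairwise_fst(g_pruned, clusters.labels)
    emit("fst_matrix", fst.reset_index(names="group"))
    am = structure.amova(
        g_pruned_imp, clusters.labels, n_permutations=config.amova_perm, seed=config.seed
    )
    emit("amova", pd.DataFrame([am]))

    # --- climate handling and forward selection --------------------------
    env = envmod.EnvTable.from_frame(env_frame)
    env_std = envmod.standardize_env(env)
    epca = envmod.env_pca(env_std)
    emit(
        "env_pca",
        pd.DataFrame(
            {
                "variable": env_std.variables,
                **{
                    f"PC{i+1}_loading": epca.loadings[:, i]
                    for i in range(min(3, epca.loadings.shape[1]))
                },
            }
        ),
    )
    trace = envmod.forward_select(
        g_pruned_imp, env_std, alpha=config.forward_alpha,
        n_perm=config.forward_perm, seed=config.seed,
    )
    selected = trace.selected if trace.selected else list(env_std.variables)
    emit("selection_trace", trace.to_frame())

    # --- pRDA variance partitioning and outlier scan ----------------------
    g_outlier_imp = genio.impute_modal(g_outlier)
    Y = g_outlier_imp.dosage
    climate = env_std.table[selected].to_numpy(dtype=float)
    geography = env_std.geography_matrix()
    structure3 = pca.scores[:, : config.structure_axes]
    part = rda.variance_partition(Y, climate, geography, structure3)
    emit("variance_partition", part.as_frame().reset_index(names="component"))

    n_climate_axes = climate.shape[1]
    k_axes = min(config.rda_axes, n_climate_axes)
    fit = rda.fit_rda(Y, climate, Z=structure3)
    emit(
        "rda_summary",
        pd.DataFrame(
            {
                "r2": [fit.r2],
                "adj_r2": [fit.adj_r2],
                "n_axes": [fit.eigenvalues.size],
                "eigenvalues": [",".join(f"{e:.6g}" for e in fit.eigenvalues)],
            }
        ),
    )
    # outlier scan on per-locus standardized dosages so loading magnitude
    # is comparable across allele frequencies
    Y_std = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=0)
    fit_scan = rda.fit_rda(Y_std, climate, Z=structure3)
    outliers = rda.rda_outlier_scan(
        fit_scan, loci=g_outlier.loci, k_axes=k_axes,
        bonferroni_alpha=config.rda_bonferroni,
    )
    emit("rda_outliers", outliers.table)

    # --- LFMM --------------------------------------------------------------
    scan = lfmm.lfmm_scan(
        Y,
        env_std.table[env_std.variables],
        g_outlier.loci,
        K=config.lfmm_k,
        n_runs=config.lfmm_runs,
        fdr=config.fdr,
        seeds=[config.seed + r for r in range(config.lfmm_runs)],
    )
    emit("lfmm_results", scan.per_run)
    emit("lfmm_consensus", scan.consensus)

    # --- EnvGWAS ------------------------------------------------------------
    gwas = envgwas.env_assoc_scan(
        Y,
        env_std.table[env_std.variables],
        pca.scores,
        g_outlier.loci,
        pc_grid=config.pc_grid,
        alpha=config.gwas_alpha,
        fdr=config.fdr,
    )
    emit("envgwas_results", gwas.table)

    # --- windows, LD decay ---------------------------------------------------
    windows = popstats.make_windows(chrom_lengths, config.window_size, config.window_step)
    windows = popstats.window_stats(g_outlier, windows)
    decay = popstats.ld_decay(g_outlier, max_dist=config.ld_max_dist)
    emit("ld_decay", decay.bins)
    emit(
        "decay_distances",
        pd.DataFrame(
            [{"chrom": c, "decay_distance": d} for c, d in decay.decay_distance.items()]
        ),
    )

    # --- consensus, candidate intervals, gene mapping ------------------------
    rda_sig = outliers.table[outliers.table["q"] < config.fdr]
    rda_tab = rda_sig[["snp", "chrom", "pos"]].assign(variable="none")
    gwas_sig = gwas.table[gwas.table["bonferroni_flag"]][["snp", "chrom", "pos", "variable"]]
    cons = annotate.consensus_pleiotropy(
        {"rda": rda_tab, "lfmm": scan.consensus, "envgwas": gwas_sig}
    )
    emit("consensus", cons["snps"])

    fallback = float(np.nanmedian([v for v in decay.decay_distance.values()])) if decay.decay_distance else 50_000.0
    dd = {
        c: (decay.decay_distance.get(c, float("nan")))
        for c in chrom_lengths
    }
    dd = {c: (v if np.isfinite(v) else fallback) for c, v in dd.items()}
    if not cons["snps"].empty and all(np.isfinite(list(dd.values()))):
        intervals = annotate.candidate_intervals(cons["snps"], dd, chrom_lengths)
    else:
        intervals = pd.DataFrame(columns=["snp", "chrom", "pos", "start", "end", "width"])
    emit("candidate_intervals", intervals)

    if not intervals.empty:
        comparison = popstats.compare_candidate_windows(windows, intervals)
    else:
        comparison = popstats.compare_candidate_windows(windows, intervals.assign())
    emit("window_stats", popstats.windows_frame(windows))
    emit("window_comparison", comparison)

    if gff_path is not None and not intervals.empty:
        genes = annotate.read_gff3_genes(gff_path)
        emit("gene_hits", annotate.map_genes(intervals, genes))

    manifest = {
        "seed": config.seed,
        "tables": {name: {"path": str(p), "sha256": _checksum(p)} for name, p in sorted(tables.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
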