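"""Synthetic landscape-genomics data generator.

Produces geo-referenced sampling sites with correlated monthly climate
variables, hierarchically structured diploid genotypes (Balding-Nichols
groups) with a known subset of adaptive loci whose site-level allele
frequencies follow logistic clines on one climate variable, and matching
VCF / TSV / GFF3 output so that every downstream stage of the pipeline is
testable without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genio import GenotypeMatrix, write_vcf

_VAR_PREFIXES = ("tmax", "tavg", "prec", "srad")


@dataclass
class LandscapeConfig:
    """Parameters of one simulated landscape dataset.

    Defaults emulate a regional landrace diversity panel of a selfing
    crop: 200 individuals from 30 geo-referenced sites in 4 genetic
    groups, 5,000 biallelic SNPs on 7 chromosomes, moderate
    differentiation (Fst 0.2), inbreeding 0.9, and logistic
    allele-frequency clines of slope 1.5 (per SD of the driver variable)
    at 2% of loci. The driver variable carries site-level microclimate
    noise (sd 0.7 against a unit-SD broad gradient) so it is not collinear
    with the broad-scale population structure.
    """

    n_sites: int = 30
    n_individuals: int = 200
    n_groups: int = 4
    n_loci: int = 5000
    n_adaptive: int = 100
    fst_groups: float = 0.2
    inbreeding: float = 0.9
    cline_effect: float = 1.5
    n_env_vars: int = 6
    env_collinearity: float = 0.7
    env_noise: float = 0.7
    missing_rate: float = 0.02
    seed: int = 0
    chrom_lengths: tuple[int, ...] = field(default_factory=lambda: (500_000,) * 7)
    driver_index: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("need at least 2 sites to define a spatial gradient")
        if not 0 < self.fst_groups < 1:
            raise ValueError("fst_groups must be in (0,1)")
        if not 0 <= self.inbreeding <= 1:
            raise ValueError("inbreeding must be in [0,1]")
        if not 0 <= self.env_collinearity < 1:
            raise ValueError("env_collinearity must be in [0,1)")
        if not 0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must be in [0,0.5]")
        if self.n_adaptive > self.n_loci:
            raise ValueError("n_adaptive cannot exceed n_loci")
        if any(c <= 0 for c in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def chrom_names(self) -> list[str]:
        return [f"{i + 1}H" for i in range(len(self.chrom_lengths))]

    @property
    def var_names(self) -> list[str]:
        return [
            f"{_VAR_PREFIXES[i % 4]}{i // 4 + 4}" for i in range(self.n_env_vars)
        ]


def simulate_sites_env(config: LandscapeConfig) -> pd.DataFrame:
    """Simulate sampling sites on a lat/lon grid with climate variables.

    The first variable (the default cline driver) is a latitudinal gradient
    plus site-level noise of sd ``env_noise`` — the noise stands for
    microclimate (orographic precipitation, aspect) and decorrelates the
    driver from the broad-scale population structure. Later variables come
    in consecutive pairs sharing a gradient (latitude, longitude, or a
    Gaussian bump) with noise chosen so each pair's expected correlation
    clears the ``env_collinearity`` target, exercising collinearity
    handling in forward selection. Individuals are assigned to sites
    round-robin; altitude follows a coordinate gradient.

    Returns a per-individual table with columns
    ``sample site group lat lon alt <climate variables...>``.
    """
    rng = np.random.default_rng(config.seed)
    ns = config.n_sites
    # roughly even grid jittered so no two sites coincide
    grid = int(np.ceil(np.sqrt(ns)))
    cells = [(r, c) for r in range(grid) for c in range(grid)][:ns]
    lat = np.array([28.0 + 4.0 * r / max(grid - 1, 1) for r, _ in cells])
    lon = np.array([90.0 + 6.0 * c / max(grid - 1, 1) for _, c in cells])
    lat = lat + rng.uniform(-0.15, 0.15, ns)
    lon = lon + rng.uniform(-0.2, 0.2, ns)

    lat_z = (lat - lat.mean()) / (lat.std() if lat.std() > 0 else 1.0)
    lon_z = (lon - lon.mean()) / (lon.std() if lon.std() > 0 else 1.0)
    bump = np.exp(-((lat_z - 0.5) ** 2 + (lon_z + 0.5) ** 2))
    bump_z = (bump - bump.mean()) / (bump.std() if bump.std() > 0 else 1.0)
    gradients = [lat_z, lon_z, bump_z]

    # non-driver variables: a modest gradient share (0.4) plus a noise base
    # shared within each pair; the own-noise scale delta sets the pair's
    # expected correlation, with margin above the configured target
    rho = 0.5 + 0.5 * config.env_collinearity
    shared_var = 0.4**2 + 1.0
    delta = np.sqrt(shared_var * (1.0 - rho) / rho)

    env = np.empty((ns, config.n_env_vars))
    pair_base: dict[int, np.ndarray] = {}
    for j in range(config.n_env_vars):
        noise = rng.standard_normal(ns)
        if j == 0:
            # the driver: broad gradient plus microclimate noise
            env[:, j] = gradients[0] + config.env_noise * noise
        else:
            pair = (j - 1) // 2
            if pair not in pair_base:
                pair_base[pair] = 0.4 * gradients[pair % 3] + rng.standard_normal(ns)
            env[:, j] = pair_base[pair] + delta * noise
    # express on plausible climate scales
    scales = {"tmax": (18.0, 4.0), "tavg": (12.0, 3.0), "prec": (60.0, 25.0), "srad": (18000.0, 2500.0)}
    names = config.var_names
    for j, name in enumerate(names):
        mu, sd = scales[name.rstrip("0123456789")]
        env[:, j] = mu + sd * env[:, j]

    alt = 3000.0 + 350.0 * lat_z - 150.0 * lon_z + config.env_noise * 40.0 * rng.standard_normal(ns)

    # groups: spatially contiguous 2-D clusters of sites, so each genetic
    # group spans part of every environmental gradient (climate varies
    # within groups, as in a regional landrace panel)
    from sklearn.cluster import KMeans

    coords = np.column_stack([lat_z, lon_z])
    km = KMeans(n_clusters=config.n_groups, n_init=10, random_state=config.seed)
    group_of_site = km.fit_predict(coords)

    site_of_ind = np.arange(config.n_individuals) % ns
    table = pd.DataFrame(
        {
            "sample": [f"ind{i:04d}" for i in range(config.n_individuals)],
            "site": site_of_ind,
            "group": group_of_site[site_of_ind],
            "lat": lat[site_of_ind],
            "lon": lon[site_of_ind],
            "alt": alt[site_of_ind],
        }
    )
    for j, name in enumerate(names):
        table[name] = env[site_of_ind, j]
    return table


def simulate_genotypes(
    config: LandscapeConfig, env: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate genotypes with Balding-Nichols structure and planted clines.

    Neutral loci: ancestral frequency p0 ~ U(0.1, 0.9); each group draws its
    frequency from Beta(p0(1-F)/F, (1-p0)(1-F)/F) with F = ``fst_groups``;
    genotypes are Binomial(2, group frequency). Adaptive loci: the frequency
    at a site is logistic(logit(p0) + beta * z) with z the standardized
    driver variable at that site. Genotypes follow inbreeding-adjusted
    proportions (a fraction ``inbreeding`` of lineages carries two
    identical-by-descent gametes, emulating a predominantly selfing crop);
    the rest are Hardy-Weinberg draws. Missing calls are MCAR at
    ``missing_rate``. Loci sit at sorted uniform positions on the 7
    chromosomes.

    Returns the genotype matrix and a truth table
    ``locus chrom pos is_adaptive driver beta p0``.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_ind = len(env)
    L = config.n_loci
    F = config.fst_groups

    # locus placement proportional to chromosome length
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    per_chrom = np.floor(L * lengths / lengths.sum()).astype(int)
    per_chrom[: L - per_chrom.sum()] += 1
    chroms, positions = [], []
    for name, length, k in zip(config.chrom_names, config.chrom_lengths, per_chrom):
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=k, replace=False))
        chroms.extend([name] * k)
        positions.extend(pos.tolist())

    p0 = rng.uniform(0.1, 0.9, L)
    adaptive = np.zeros(L, dtype=bool)
    if config.n_adaptive > 0:
        adaptive[rng.choice(L, size=config.n_adaptive, replace=False)] = True

    groups = env["group"].to_numpy()
    driver = config.var_names[config.driver_index]
    z_ind = env[driver].to_numpy()
    z_ind = (z_ind - z_ind.mean()) / z_ind.std()

    neutral = ~adaptive
    freq = np.empty((n_ind, L))
    # group frequencies for neutral loci
    a = p0[neutral] * (1 - F) / F
    b = (1 - p0[neutral]) * (1 - F) / F
    group_freq = rng.beta(
        np.broadcast_to(a, (config.n_groups, neutral.sum())),
        np.broadcast_to(b, (config.n_groups, neutral.sum())),
    )  # (n_groups, n_neutral)
    freq[:, neutral] = group_freq[groups, :]
    # adaptive loci: logistic cline on the driver
    if adaptive.any():
        freq[:, adaptive] = expit(
            logit(p0[adaptive])[None, :] + config.cline_effect * z_ind[:, None]
        )
    # inbreeding-adjusted genotype draw: with probability `inbreeding` the
    # two gametes are identical by descent (selfing lineage), else HWE
    fis = config.inbreeding
    ibd = rng.random((n_ind, L)) < fis
    hom = 2.0 * (rng.random((n_ind, L)) < freq)
    hwe = rng.binomial(2, freq).astype(float)
    dosage = np.where(ibd, hom, hwe)

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    loci = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "id": [f"{c}_{p}" for c, p in zip(chroms, positions)],
            "ref": "A",
            "alt": "T",
        }
    )
    g = GenotypeMatrix(samples=env["sample"].tolist(), loci=loci, dosage=dosage)

    truth = pd.DataFrame(
        {
            "locus": loci["id"],
            "chrom": loci["chrom"],
            "pos": loci["pos"],
            "is_adaptive": adaptive,
            "driver": np.where(adaptive, driver, "none"),
            "beta": np.where(adaptive, config.cline_effect, 0.0),
            "p0": p0,
        }
    )
    return g, truth


def simulate_ld_haplotypes(
    n_ind: int,
    n_loci: int,
    chrom_length: int,
    corr_length_bp: float = 50_000.0,
    seed: int = 0,
    chrom: str = "1H",
) -> GenotypeMatrix:
    """Simulate genotypes whose pairwise LD decays with physical distance.

    Haplotypes follow a Markov copying process along the chromosome: the
    allele at the next locus copies the previous one with probability
    exp(-d / corr_length_bp), otherwise it is redrawn at that locus's
    frequency. This yields approximately exponential r2 decay for LD-decay
    estimation tests; the main generator produces linkage-equilibrium loci.
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, chrom_length + 1), n_loci, replace=False))
    freqs = rng.uniform(0.2, 0.8, n_loci)
    hap = np.empty((2 * n_ind, n_loci), dtype=np.int8)
    hap[:, 0] = rng.random(2 * n_ind) < freqs[0]
    for j in range(1, n_loci):
        stay = np.exp(-(pos[j] - pos[j - 1]) / corr_length_bp)
        copy = rng.random(2 * n_ind) < stay
        fresh = (rng.random(2 * n_ind) < freqs[j]).astype(np.int8)
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    dosage = hap[0::2] + hap[1::2]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"{chrom}_{p}" for p in pos],
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(
        samples=[f"ind{i:04d}" for i in range(n_ind)], loci=loci, dosage=dosage.astype(float)
    )


def emit_dataset(
    g: GenotypeMatrix,
    env: pd.DataFrame,
    truth: pd.DataFrame,
    outdir: str | Path,
    config: LandscapeConfig | None = None,
    n_background_genes: int = 50,
) -> dict:
    """Write VCF 4.2, env TSV, truth TSV and a synthetic GFF3; return a manifest.

    The GFF3 places one synthetic gene within 50 kb of every adaptive locus
    plus uniformly placed background genes, so candidate-gene mapping has
    known positives.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_path = outdir / "genotypes.vcf"
    env_path = outdir / "env.tsv"
    truth_path = outdir / "truth.tsv"
    gff_path = outdir / "genes.gff3"

    write_vcf(g, vcf_path)
    env.to_csv(env_path, sep="\t", index=False)
    truth.to_csv(truth_path, sep="\t", index=False)

    seed = config.seed if config is not None else 0
    rng = np.random.default_rng(seed + 2)
    chrom_len = {
        c: int(g.loci.loc[g.loci["chrom"] == c, "pos"].max()) + 10_000
        for c in pd.unique(g.loci["chrom"])
    }
    if config is not None:
        chrom_len = dict(zip(config.chrom_names, config.chrom_lengths))
    records = []
    gid = 0
    adaptive_rows = truth[truth["is_adaptive"].astype(bool)]
    for row in adaptive_rows.itertuples(index=False):
        length = int(rng.integers(2_000, 8_000))
        offset = int(rng.integers(-40_000, 40_000 - length))
        start = max(1, int(row.pos) + offset)
        end = min(chrom_len.get(row.chrom, start + length), start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        gid += 1
        records.append((row.chrom, start, end, strand, f"gene{gid:05d}"))
    for _ in range(n_background_genes):
        chrom = list(chrom_len)[int(rng.integers(len(chrom_len)))]
        length = int(rng.integers(2_000, 8_000))
        start = int(rng.integers(1, max(2, chrom_len[chrom] - length)))
        strand = "+" if rng.random() < 0.5 else "-"
        gid += 1
        records.append((chrom, start, start + length, strand, f"gene{gid:05d}"))
    records.sort(key=lambda r: (r[0], r[1]))
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, name in records:
            fh.write(
                f"{chrom}\tlandgea\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={name};Name={name}\n"
            )

    manifest = {
        "seed": seed,
        "files": {
            "vcf": str(vcf_path),
            "env": str(env_path),
            "truth": str(truth_path),
            "gff": str(gff_path),
        },
        "n_samples": g.n_samples,
        "n_loci": g.n_loci,
        "n_genes": len(records),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def simulate_dataset(config: LandscapeConfig) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: sites/env then genotypes; returns (g, env, truth)."""
    env = simulate_sites_env(config)
    g, truth = simulate_genotypes(config, env)
    return g, env, truth
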