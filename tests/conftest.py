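import numpy as np
import pytest
from hypothesis import settings

from landgea import genio, structure, synthdata
from landgea.envmod import EnvTable, standardize_env

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """60 individuals x 400 loci with 8 planted clines; quick module tests."""
    cfg = synthdata.LandscapeConfig(
        n_individuals=60, n_loci=400, n_adaptive=8, n_sites=12, seed=3
    )
    g, env, truth = synthdata.simulate_dataset(cfg)
    return cfg, g, env, truth


@pytest.fixture(scope="session")
def recovery_fixture():
    """The standard parameter-recovery dataset: 200 individuals, 5,000 SNPs,
    4 groups at Fst 0.2, 2% adaptive loci with cline slope 1.5."""
    cfg = synthdata.LandscapeConfig(seed=11)
    g, env, truth = synthdata.simulate_dataset(cfg)
    g_out = genio.filter_loci(g, "outlier")
    Y = genio.impute_modal(g_out).dosage
    envt = standardize_env(EnvTable.from_frame(env))
    g_pruned = genio.impute_modal(genio.ld_prune(genio.filter_loci(g, "structure")))
    pca = structure.genotype_pca(g_pruned)
    adaptive = (
        truth.set_index("locus")
        .loc[g_out.loci["id"], "is_adaptive"]
        .to_numpy()
        .astype(bool)
    )
    return {
        "cfg": cfg,
        "g": g,
        "env": env,
        "truth": truth,
        "g_out": g_out,
        "Y": Y,
        "envt": envt,
        "g_pruned": g_pruned,
        "pca": pca,
        "adaptive": adaptive,
    }


@pytest.fixture(scope="session")
def null_fixture():
    """Same design with zero adaptive loci (null calibration runs)."""
    cfg = synthdata.LandscapeConfig(seed=42, n_adaptive=0)
    g, env, truth = synthdata.simulate_dataset(cfg)
    g_out = genio.filter_loci(g, "outlier")
    Y = genio.impute_modal(g_out).dosage
    envt = standardize_env(EnvTable.from_frame(env))
    g_pruned = genio.impute_modal(genio.ld_prune(genio.filter_loci(g, "structure")))
    pca = structure.genotype_pca(g_pruned)
    return {
        "cfg": cfg,
        "g": g,
        "env": env,
        "g_out": g_out,
        "Y": Y,
        "envt": envt,
        "pca": pca,
    }


def toy_matrix(dosage, chrom="1H", start_pos=100, spacing=100, samples=None):
    """Build a GenotypeMatrix from a plain list-of-lists dosage array."""
    import pandas as pd

    d = np.asarray(dosage, dtype=float)
    n, L = d.shape
    pos = [start_pos + spacing * j for j in range(L)]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"{chrom}_{p}" for p in pos],
            "ref": "A",
            "alt": "T",
        }
    )
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    return genio.GenotypeMatrix(samples=samples, loci=loci, dosage=d)
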