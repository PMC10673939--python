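"""Genotype I/O, QC arithmetic, filters, imputation, r2 and LD pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from landgea import genio
from conftest import toy_matrix


M = np.nan


class TestLocusQC:
    def test_maf_arithmetic(self):
        g = toy_matrix(np.array([[0, 1, 2, 2, 2]]).T)
        qc = genio.locus_qc(g).table
        assert qc["maf"].iloc[0] == pytest.approx(0.3)

    def test_het_and_missing_rates(self):
        g = toy_matrix(np.array([[0, 1, 1, 2, M]]).T)
        qc = genio.locus_qc(g).table
        assert qc["het_rate"].iloc[0] == pytest.approx(0.5)
        assert qc["missing_rate"].iloc[0] == pytest.approx(0.2)

    def test_monomorphic_locus(self):
        g = toy_matrix(np.array([[0, 0, 0, 0]]).T)
        qc = genio.locus_qc(g).table
        assert qc["maf"].iloc[0] == 0.0
        assert qc["het_rate"].iloc[0] == 0.0


class TestFilterLoci:
    def _toy(self):
        # columns: ok, low maf (0.05), high het, high missing, monomorphic, ok
        d = np.array(
            [
                [0, 0, 1, 0, 0, 2],
                [2, 0, 1, M, 0, 2],
                [0, 0, 1, M, 0, 0],
                [2, 0, 1, 0, 0, 2],
                [0, 0, 1, 0, 0, 0],
                [2, 0, 1, 0, 0, 2],
                [0, 0, 1, 0, 0, 0],
                [2, 0, 1, 0, 0, 2],
                [0, 0, 1, 0, 0, 0],
                [2, 1, 1, 0, 0, 2],
            ],
            dtype=float,
        )
        return toy_matrix(d)

    def test_maf_boundary_removed_under_both_sets(self):
        g = self._toy()
        qc = genio.locus_qc(g).table
        assert qc["maf"].iloc[1] == pytest.approx(0.05)
        for fs in ("structure", "outlier"):
            kept = genio.filter_loci(g, fs).loci["id"].tolist()
            assert g.loci["id"].iloc[1] not in kept

    def test_survivors_match_brute_force_rules(self):
        g = self._toy()
        qc = genio.locus_qc(g).table
        expect_structure = [
            lid
            for lid, maf, het, miss in zip(
                qc["id"], qc["maf"], qc["het_rate"], qc["missing_rate"]
            )
            if miss <= 0.2 and het <= 0.2 and maf >= 0.1
        ]
        expect_outlier = [
            lid
            for lid, maf, het, miss in zip(
                qc["id"], qc["maf"], qc["het_rate"], qc["missing_rate"]
            )
            if maf > 0.05 and het < 0.2 and miss < 0.2
        ]
        assert genio.filter_loci(g, "structure").loci["id"].tolist() == expect_structure
        assert genio.filter_loci(g, "outlier").loci["id"].tolist() == expect_outlier

    def test_filter_idempotent(self):
        g = self._toy()
        once = genio.filter_loci(g, "structure")
        twice = genio.filter_loci(once, "structure")
        np.testing.assert_array_equal(once.dosage, twice.dosage)

    def test_filter_preserves_surviving_genotypes(self, small_dataset):
        _, g, _, _ = small_dataset
        kept = genio.filter_loci(g, "outlier")
        idx = {lid: j for j, lid in enumerate(g.loci["id"])}
        for j, lid in enumerate(kept.loci["id"]):
            np.testing.assert_array_equal(
                kept.dosage[:, j], g.dosage[:, idx[lid]]
            )


class TestImputeModal:
    def test_unique_mode(self):
        g = toy_matrix(np.array([[0, 0, 2, M]]).T)
        imp = genio.impute_modal(g)
        assert imp.dosage[3, 0] == 0

    def test_tie_break_to_lower_dosage_when_equidistant(self):
        g = toy_matrix(np.array([[0, 0, 2, 2, M]]).T)
        imp = genio.impute_modal(g)
        assert imp.dosage[4, 0] == 0

    def test_tie_break_toward_mean(self):
        # counts 0:2, 1:2, 2:1 -> tie {0,1}; mean dosage 0.8 -> nearer 1
        g = toy_matrix(np.array([[0, 0, 1, 1, 2, M]]).T)
        imp = genio.impute_modal(g)
        assert imp.dosage[5, 0] == 1

    def test_no_missing_identity(self):
        g = toy_matrix(np.array([[0, 1, 2, 2]]).T)
        imp = genio.impute_modal(g)
        np.testing.assert_array_equal(imp.dosage, g.dosage)

    def test_all_missing_locus_raises(self):
        g = toy_matrix(np.array([[M, M, M]]).T)
        with pytest.raises(ValueError, match="1H_100"):
            genio.impute_modal(g)


class TestPairwiseR2:
    def test_identical_vectors(self):
        assert genio.pairwise_r2([0, 0, 2, 2], [0, 0, 2, 2]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert genio.pairwise_r2([0, 2, 0, 2], [0, 0, 2, 2]) == pytest.approx(0.0)

    def test_zero_variance_undefined(self):
        assert np.isnan(genio.pairwise_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_matches_from_scratch_computation(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 50).astype(float)
        y = rng.integers(0, 3, 50).astype(float)
        x[rng.choice(50, 5, replace=False)] = np.nan
        ok = np.isfinite(x) & np.isfinite(y)
        xs, ys = x[ok], y[ok]
        cov = np.sum((xs - xs.mean()) * (ys - ys.mean())) / ok.sum()
        expected = cov**2 / (xs.var() * ys.var())
        assert genio.pairwise_r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_r2_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, (40, 6)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        mat = genio.r2_matrix(d)
        for i, j in itertools.combinations(range(6), 2):
            expected = genio.pairwise_r2(d[:, i], d[:, j])
            if np.isnan(expected):
                assert np.isnan(mat[i, j])
            else:
                assert mat[i, j] == pytest.approx(expected, abs=1e-12)


def _brute_force_prune(g, window, step, r2_max):
    """Direct restatement of the pruning rule for small instances."""
    qc = genio.locus_qc(g).table
    maf = qc["maf"].to_numpy()
    keep = np.ones(g.n_loci, dtype=bool)
    changed = True
    while changed:
        changed = False
        for start in range(0, max(1, g.n_loci - 1), step):
            win = list(range(start, min(start + window, g.n_loci)))
            for a, b in itertools.combinations(win, 2):
                if not (keep[a] and keep[b]):
                    continue
                r2 = genio.pairwise_r2(g.dosage[:, a], g.dosage[:, b])
                if np.isfinite(r2) and r2 > r2_max:
                    if maf[a] < maf[b]:
                        victim = a
                    else:
                        victim = b  # covers tie -> later position
                    keep[victim] = False
                    changed = True
    return g.loci["id"].to_numpy()[keep].tolist()


class TestLdPrune:
    def test_lower_maf_member_removed(self):
        # locus 0: maf 0.3; locus 1: same pattern with some alt calls
        # flipped to ref -> lower maf, still strongly correlated
        x = np.array([2] * 12 + [0] * 28, dtype=float)
        g = toy_matrix(np.column_stack([x, x]))
        g.dosage[8:12, 1] = 0.0
        qc = genio.locus_qc(g).table
        assert qc["maf"].iloc[0] > qc["maf"].iloc[1]
        r2 = genio.pairwise_r2(g.dosage[:, 0], g.dosage[:, 1])
        assert r2 > 0.5
        pruned = genio.ld_prune(g, window_snps=10, step_snps=5)
        assert pruned.loci["id"].tolist() == [g.loci["id"].iloc[0]]

    def test_no_surviving_pair_violates_threshold(self, small_dataset):
        _, g, _, _ = small_dataset
        pruned = genio.ld_prune(g, window_snps=20, step_snps=5)
        for chrom in pd.unique(pruned.loci["chrom"]):
            idx = np.flatnonzero((pruned.loci["chrom"] == chrom).to_numpy())
            for s in range(0, max(1, idx.size - 1), 5):
                win = idx[s : s + 20]
                r2 = genio.r2_matrix(pruned.dosage[:, win])
                iu = np.triu_indices(win.size, k=1)
                assert not np.any(r2[iu] > 0.5)

    def test_matches_brute_force_oracle_on_toy_chromosome(self):
        rng = np.random.default_rng(12)
        # 30 loci with blocks of correlated copies
        base = rng.integers(0, 3, (25, 10)).astype(float)
        cols = []
        for j in range(10):
            cols.append(base[:, j])
            for _ in range(2):
                c = base[:, j].copy()
                flip = rng.random(25) < 0.15
                c[flip] = rng.integers(0, 3, flip.sum())
                cols.append(c)
        g = toy_matrix(np.column_stack(cols))
        expected = _brute_force_prune(g, 8, 3, 0.5)
        got = genio.ld_prune(g, window_snps=8, step_snps=3).loci["id"].tolist()
        assert got == expected

    def test_step_size_irrelevant_when_window_spans_chromosome(self):
        rng = np.random.default_rng(9)
        d = rng.integers(0, 3, (30, 15)).astype(float)
        g = toy_matrix(d)
        a = genio.ld_prune(g, window_snps=50, step_snps=1).loci["id"].tolist()
        b = genio.ld_prune(g, window_snps=50, step_snps=10).loci["id"].tolist()
        assert a == b

    def test_window_too_small_raises(self):
        g = toy_matrix(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            genio.ld_prune(g, window_snps=1)


class TestVcfIO:
    def test_het_call_is_dosage_one(self, tmp_path):
        g = toy_matrix(np.array([[0, 1, 2, M]]).T)
        path = tmp_path / "t.vcf"
        genio.write_vcf(g, path)
        g2 = genio.read_genotypes(path)
        np.testing.assert_allclose(
            g2.dosage[:, 0], [0, 1, 2, np.nan], equal_nan=True
        )

    def test_unsorted_input_comes_back_sorted(self, tmp_path):
        path = tmp_path / "shuffled.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##contig=<ID=1H,length=1000>\n")
            fh.write("##contig=<ID=2H,length=1000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n")
            fh.write("2H\t500\t.\tA\tT\t.\t.\t.\tGT\t0/0\t1/1\n")
            fh.write("1H\t900\t.\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n")
            fh.write("1H\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\n")
        g = genio.read_genotypes(path)
        assert list(zip(g.loci["chrom"], g.loci["pos"])) == [
            ("1H", 100), ("1H", 900), ("2H", 500)
        ]

    def test_non_snp_records_skipped(self, tmp_path):
        path = tmp_path / "mixed.vcf"
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##contig=<ID=1H,length=1000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\n")
            fh.write("1H\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\n")
            fh.write("1H\t200\t.\tA\tTG\t.\t.\t.\tGT\t0/0\t0/1\n")
            fh.write("1H\t300\t.\tA\tT,G\t.\t.\t.\tGT\t0/0\t0/1\n")
        g = genio.read_genotypes(path)
        assert g.n_loci == 1 and g.loci["pos"].iloc[0] == 100


@given(
    st.lists(st.integers(min_value=0, max_value=2), min_size=5, max_size=40)
)
def test_qc_ranges_always_valid(calls):
    g = toy_matrix(np.array([calls], dtype=float).T)
    qc = genio.locus_qc(g).table
    assert 0 <= qc["maf"].iloc[0] <= 0.5
    assert 0 <= qc["het_rate"].iloc[0] <= 1
    assert qc["missing_rate"].iloc[0] == 0
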