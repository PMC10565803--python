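"""Instrument selection: p-value filtering and greedy LD clumping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrscreen.instruments import ClumpConfig, LDMatrix, filter_by_pvalue, ld_clump, select_instruments
from mrscreen.simulate import SimulationTruth, simulate_ld, simulate_taxon, apply_positions

from conftest import make_dataset


class TestPvalueFilter:
    def test_strict_inequality_at_threshold(self):
        ds = make_dataset(
            [{"pvalue": 1e-6}, {"pvalue": 1e-5}, {"pvalue": 1e-4}]
        )
        kept = filter_by_pvalue(ds, 1e-5)
        assert kept.snp_ids == ["rs0"]  # only p = 1e-6 survives p < 1e-5

    def test_threshold_one_keeps_everything(self, rng):
        ds = make_dataset([{"pvalue": p} for p in rng.uniform(1e-12, 0.999, 30)])
        assert len(filter_by_pvalue(ds, 1.0)) == 30

    def test_matches_brute_force_scan(self, rng):
        pvals = 10 ** rng.uniform(-9, 0, 100)
        ds = make_dataset([{"pvalue": p} for p in pvals])
        kept = filter_by_pvalue(ds, 1e-5)
        expected = [f"rs{i}" for i in range(100) if pvals[i] < 1e-5]
        assert kept.snp_ids == expected


def _block_instance(rng, block_sizes, within_r2=0.5):
    """Instruments partitioned into LD blocks with random p-values."""
    m = sum(block_sizes)
    ids = [f"rs{i}" for i in range(m)]
    ld, pos_map = simulate_ld(ids, block_sizes, within_r2)
    ds = make_dataset(
        [{"snp_id": s, "pvalue": 10 ** rng.uniform(-10, -6)} for s in ids]
    )
    return apply_positions(ds, pos_map), ld


class TestClump:
    def test_dominated_pair_keeps_better_p(self):
        ds = make_dataset(
            [
                {"snp_id": "a", "pos": 1, "pvalue": 1e-8},
                {"snp_id": "b", "pos": 5_000_000, "pvalue": 1e-6},
            ]
        )
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        out = ld_clump(ds, ld, ClumpConfig())
        assert out.snp_ids == ["a"]

    def test_r2_below_threshold_keeps_both(self):
        ds = make_dataset(
            [
                {"snp_id": "a", "pos": 1, "pvalue": 1e-8},
                {"snp_id": "b", "pos": 100, "pvalue": 1e-6},
            ]
        )
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.0005], [0.0005, 1.0]]))
        out = ld_clump(ds, ld, ClumpConfig())
        assert set(out.snp_ids) == {"a", "b"}

    def test_different_chromosomes_never_clumped(self):
        ds = make_dataset(
            [
                {"snp_id": "a", "chrom": "1", "pos": 100, "pvalue": 1e-8},
                {"snp_id": "b", "chrom": "2", "pos": 100, "pvalue": 1e-6},
            ]
        )
        ld = LDMatrix(["a", "b"], np.array([[1.0, 0.99], [0.99, 1.0]]))
        assert set(ld_clump(ds, ld, ClumpConfig()).snp_ids) == {"a", "b"}

    def test_block_structure_satisfies_pairwise_property(self, rng):
        """Exhaustive post-hoc check on a 12-SNP, 3-block instance:
        (a) no retained pair is within-window with r2 above threshold;
        (b) every removed SNP conflicts with a retained, better-ranked SNP."""
        ds, ld = _block_instance(rng, [4, 4, 4], within_r2=0.5)
        cfg = ClumpConfig()
        out = ld_clump(ds, ld, cfg)
        assert len(out) == 3  # one index SNP per block

        pos = dict(zip(ds.df.snp_id, ds.df.pos))
        pval = dict(zip(ds.df.snp_id, ds.df.pvalue))
        win = cfg.window_kb * 1000

        def conflict(a, b):
            return abs(pos[a] - pos[b]) <= win and ld.r2_between(a, b) > cfg.r2_threshold

        kept = out.snp_ids
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert not conflict(a, b)
        for s in set(ds.snp_ids) - set(kept):
            assert any(conflict(s, k) and pval[k] <= pval[s] for k in kept)

    @given(perm_seed=st.integers(0, 1000))
    def test_output_invariant_to_input_row_order(self, perm_seed):
        rng = np.random.default_rng(99)
        ds, ld = _block_instance(rng, [3, 2, 4], within_r2=0.7)
        baseline = ld_clump(ds, ld, ClumpConfig()).snp_ids
        perm = np.random.default_rng(perm_seed).permutation(len(ds))
        shuffled = ds.subset([ds.snp_ids[i] for i in perm])
        assert ld_clump(shuffled, ld, ClumpConfig()).snp_ids == baseline

    def test_equal_pvalue_ties_broken_deterministically(self):
        rows = [
            {"snp_id": "z", "chrom": "2", "pos": 10, "pvalue": 1e-8},
            {"snp_id": "a", "chrom": "1", "pos": 20, "pvalue": 1e-8},
            {"snp_id": "b", "chrom": "1", "pos": 10, "pvalue": 1e-8},
        ]
        ds = make_dataset(rows)
        ld = LDMatrix.identity(["z", "a", "b"])
        out = ld_clump(ds, ld, ClumpConfig())
        # ties: chrom "1" before "2", then position 10 before 20
        assert out.snp_ids == ["b", "a", "z"]

    def test_snps_missing_from_ld_are_dropped(self):
        ds = make_dataset([{"snp_id": "a", "pos": 1}, {"snp_id": "ghost", "pos": 2}])
        ld = LDMatrix.identity(["a"])
        out = ld_clump(ds, ld, ClumpConfig())
        assert out.snp_ids == ["a"]
        assert out.meta["clump_removed_missing_ld"] == 1

    def test_singleton_returns_itself(self):
        ds = make_dataset([{"snp_id": "only"}])
        out = ld_clump(ds, LDMatrix.identity(["only"]), ClumpConfig())
        assert out.snp_ids == ["only"]


class TestSelectInstruments:
    def test_recovers_exactly_the_true_instruments(self):
        truth = SimulationTruth(seed=11, theta=0.2, k_true=10)
        exposure, _, _ = simulate_taxon(truth)
        ld = LDMatrix.identity(exposure.snp_ids)
        selected = select_instruments(exposure, ld)
        true_ids = set(exposure.snp_ids[:10])
        assert set(selected.snp_ids) == true_ids

    def test_stage_counts_are_conserved(self):
        truth = SimulationTruth(seed=12, theta=0.2, k_true=8)
        exposure, _, _ = simulate_taxon(truth)
        ld = LDMatrix.identity(exposure.snp_ids)
        selected = select_instruments(exposure, ld)
        m = selected.meta
        assert m["n_input"] == (
            m["n_retained"] + m["removed_p"] + m["removed_ld"] + m["removed_missing_ld"]
        )

    def test_no_suggestive_snp_gives_empty_set(self):
        ds = make_dataset([{"pvalue": 0.5}, {"pvalue": 0.9}])
        out = select_instruments(ds, LDMatrix.identity(ds.snp_ids))
        assert len(out) == 0


class TestLDMatrixIO:
    def test_square_and_long_formats_agree(self, tmp_path):
        r2 = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 1.0]])
        ld = LDMatrix(["a", "b", "c"], r2)
        sq = tmp_path / "sq.tsv"
        ld.write(sq)
        back = LDMatrix.read(sq)
        assert back.snp_ids == ld.snp_ids
        np.testing.assert_allclose(back.r2, ld.r2)

        lg = tmp_path / "long.tsv"
        lg.write_text("snp_a\tsnp_b\tr2\na\tb\t0.3\nb\tc\t0.1\n")
        from_long = LDMatrix.read(lg)
        assert from_long.r2_between("a", "b") == 0.3
        assert from_long.r2_between("b", "a") == 0.3  # symmetrised
        assert from_long.r2_between("a", "c") == 0.0

    @pytest.mark.parametrize(
        "r2",
        [
            np.array([[1.0, 0.5], [0.2, 1.0]]),   # asymmetric
            np.array([[0.9, 0.1], [0.1, 1.0]]),   # bad diagonal
            np.array([[1.0, 1.5], [1.5, 1.0]]),   # out of range
        ],
    )
    def test_malformed_matrix_rejected(self, r2):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], r2)
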