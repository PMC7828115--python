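import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import fisher_exact

from kmodule import (
    ExpressionMatrix,
    SyntheticSpec,
    generate,
    overlap_fisher,
    preservation_count,
    split_stability,
    stability_report,
)
from kmodule.stability import log10_fisher_tail

from conftest import partition


class TestFisherTail:
    def test_classic_small_table(self):
        # n = 8, |A| = 4, |B| = 4, overlap 3 -> p = 17/70
        assert 10 ** -log10_fisher_tail(3, 8, 4, 4) == pytest.approx(17 / 70, rel=1e-10)

    def test_matches_scipy_one_sided_at_moderate_scale(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            ka = int(rng.integers(2, n - 2))
            kb = int(rng.integers(2, n - 2))
            o = int(rng.integers(max(0, ka + kb - n), min(ka, kb) + 1))
            table = [[o, ka - o], [kb - o, n - ka - kb + o]]
            expected = fisher_exact(table, alternative="greater")[1]
            ours = 10 ** -log10_fisher_tail(o, n, ka, kb)
            assert ours == pytest.approx(expected, rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        assert log10_fisher_tail(0, 100, 30, 40) == 0.0

    def test_identical_large_modules_survive_underflow(self):
        # p = 1 / C(1000, 500): far below the smallest positive double
        expected = (gammaln(1001) - 2 * gammaln(501)) / np.log(10)
        got = log10_fisher_tail(500, 1000, 500, 500)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 50

    def test_monotone_in_overlap_for_fixed_margins(self):
        vals = [log10_fisher_tail(o, 60, 20, 25) for o in range(21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestOverlapFisher:
    def test_counts_have_correct_margins(self):
        a = partition([1, 1, 1, 2, 2, 0, 0, 3, 3, 3])
        b = partition([1, 2, 1, 2, 2, 1, 0, 3, 3, 0])
        t = overlap_fisher(a, b)
        np.testing.assert_array_equal(
            t.overlap_counts.sum(axis=1).to_numpy(),
            [np.sum(a.labels == m) for m in t.modules_a],
        )
        np.testing.assert_array_equal(
            t.overlap_counts.sum(axis=0).to_numpy(),
            [np.sum(b.labels == m) for m in t.modules_b],
        )
        assert (t.neg_log10_p.to_numpy() >= 0).all()

    def test_swap_symmetry_is_transpose(self):
        a = partition([1, 1, 2, 2, 2, 0, 3, 3])
        b = partition([2, 1, 1, 2, 3, 3, 0, 2])
        t_ab = overlap_fisher(a, b)
        t_ba = overlap_fisher(b, a)
        np.testing.assert_array_equal(t_ab.overlap_counts.to_numpy(),
                                      t_ba.overlap_counts.T.to_numpy())
        np.testing.assert_allclose(t_ab.neg_log10_p.to_numpy(),
                                   t_ba.neg_log10_p.T.to_numpy(), atol=1e-12)

    def test_alignment_by_gene_id(self):
        from kmodule.clustering import ModulePartition
        a = ModulePartition(("g1", "g2", "g3", "g4"), np.array([1, 1, 2, 2]))
        b = ModulePartition(("g4", "g3", "g2", "g1"), np.array([2, 2, 1, 1]))
        t = overlap_fisher(a, b)
        assert t.overlap_counts.loc[1, 1] == 2
        assert t.overlap_counts.loc[1, 2] == 0

    def test_gene_set_mismatch_rejected(self):
        from kmodule.clustering import ModulePartition
        a = ModulePartition(("g1", "g2"), np.array([1, 2]))
        b = ModulePartition(("g1", "gX"), np.array([1, 2]))
        with pytest.raises(ValueError):
            overlap_fisher(a, b)

    def test_tsv_output_and_text_heat_summary(self, tmp_path):
        p = partition([1] * 300 + [2] * 300)
        t = overlap_fisher(p, p)
        t.write_tsv(tmp_path / "counts.tsv", tmp_path / "neglogp.tsv")
        assert (tmp_path / "counts.tsv").exists()
        assert (tmp_path / "neglogp.tsv").exists()
        rendered = t.render()
        assert "300*" in rendered  # diagonal cells are strongly preserved
        assert "0\t" in rendered or "\t0" in rendered


class TestPreservationCount:
    def test_identical_two_module_partitions_of_1000(self):
        p = partition([1] * 500 + [2] * 500)
        t = overlap_fisher(p, p)
        assert preservation_count(t) == 2

    def test_independent_random_partitions_rarely_preserved(self):
        count = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = partition(rng.integers(1, 4, size=200))
            b = partition(rng.integers(1, 4, size=200))
            count += preservation_count(overlap_fisher(a, b))
        assert count == 0

    def test_vacuous_cut_counts_modules_with_any_overlap_signal(self):
        p = partition([1] * 10 + [2] * 10)
        t = overlap_fisher(p, p)
        assert preservation_count(t, significance_cut=1e-9) == 2

    def test_grey_excluded_from_counting(self):
        p = partition([0] * 500 + [1] * 10)
        t = overlap_fisher(p, p)
        # grey overlaps grey massively, but only module 1 may count
        assert preservation_count(t) == preservation_count(t, 50.0) <= 1


class TestSplitStability:
    def test_duplicated_parts_fixture_maximal_preservation(self):
        expr, truth = generate(SyntheticSpec(seed=3))
        report, _ = stability_report([expr, expr])
        assert set(report["method"]) == {"wgcna", "k-module", "k-eigengene"}
        assert (report["mean"] == truth.n_modules).all()
        assert (report["min"] == report["max"]).all()

    def test_null_noise_datasets_preserve_nothing(self):
        def noise(seed):
            rng = np.random.default_rng(seed)
            return ExpressionMatrix(
                tuple(f"G{i}" for i in range(200)),
                tuple(f"S{j}" for j in range(24)),
                rng.standard_normal((200, 24)),
            )
        report, _ = stability_report([noise(1), noise(2)])
        assert (report["mean"] == 0).all()

    def test_two_part_split_preserves_planted_modules(self):
        expr, truth = generate(SyntheticSpec(seed=5))
        report, _ = split_stability(expr, n_parts=2, seed=42)
        km = report.set_index("method").loc["k-module"]
        assert km["mean"] == truth.n_modules

    def test_same_seed_reproduces_report(self):
        expr, _ = generate(SyntheticSpec(seed=6))
        r1, c1 = split_stability(expr, n_parts=2, seed=9)
        r2, c2 = split_stability(expr, n_parts=2, seed=9)
        assert r1.equals(r2)
        assert c1 == c2

    def test_five_fold_report_shape(self):
        expr, _ = generate(SyntheticSpec(seed=7))
        report, pair_counts = split_stability(expr, n_parts=5, seed=1)
        assert list(report.columns) == ["method", "mean", "min", "max"]
        assert all(len(v) == 10 for v in pair_counts.values())  # C(5, 2) pairs
        assert (report["min"] <= report["mean"]).all()
        assert (report["mean"] <= report["max"]).all()
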