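import numpy as np
import pytest

from kmodule import (
    ExpressionMatrix,
    SyntheticSpec,
    corrupt,
    generate,
    k_eigengene_refine,
    k_module_refine,
    mean_connectivity,
    module_eigengene,
    pairwise_similarity,
    adjacency,
)
from kmodule.clustering import ModulePartition
from kmodule.refine import RefinementResult, _iterate

from conftest import partition, random_expr
from oracles import mean_connectivity_naive


class TestMeanConnectivity:
    def test_non_member_hand_example(self):
        # S_m = {g2, g3}, a_12 = 0.8, a_13 = 0.4 -> (0.8 + 0.4) / 2 = 0.6
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.8
        a[0, 2] = a[2, 0] = 0.4
        part = partition([0, 1, 1])
        assert mean_connectivity(0, 1, a, part) == pytest.approx(0.6)

    def test_member_literal_denominator_counts_self(self):
        # g1 in S_m = {g1, g2}, a_12 = 0.8 -> self-term 0, n_m = 2 -> 0.4
        a = np.zeros((2, 2))
        a[0, 1] = a[1, 0] = 0.8
        part = partition([1, 1])
        assert mean_connectivity(0, 1, a, part) == pytest.approx(0.4)
        assert mean_connectivity(0, 1, a, part, denominator="exclude-self") == (
            pytest.approx(0.8)
        )

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.random((10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3, 0])
        part = partition(labels)
        for i in range(10):
            for m in (1, 2, 3):
                assert mean_connectivity(i, m, a, part) == pytest.approx(
                    mean_connectivity_naive(i, m, a, labels), abs=1e-12
                )

    def test_empty_module_rejected(self):
        a = np.zeros((2, 2))
        with pytest.raises(ValueError):
            mean_connectivity(0, 3, a, partition([1, 1]))


class TestKModuleRefine:
    def test_self_consistent_partition_is_fixed_point(self, two_block_adjacency):
        a, labels = two_block_adjacency
        res = k_module_refine(partition(labels), a)
        assert res.converged
        assert res.changes_per_iteration == (0,)
        np.testing.assert_array_equal(res.partition.labels, labels)

    def test_mislabeled_gene_restored_in_two_iterations(self, two_block_adjacency):
        a, true_labels = two_block_adjacency
        # gene 2 truly in block 1 but labeled into block 2
        bad = partition([1, 1, 2, 2, 2, 2])
        res = k_module_refine(bad, a)
        assert res.converged
        assert res.iterations == 2
        assert res.changes_per_iteration == (1, 0)
        np.testing.assert_array_equal(res.partition.labels, true_labels)

    def test_grey_frozen_by_default_and_reassignable(self, two_block_adjacency):
        a, _ = two_block_adjacency
        grey = partition([1, 1, 1, 2, 2, 0])
        frozen = k_module_refine(grey, a)
        assert frozen.partition.labels[5] == 0
        moved = k_module_refine(grey, a, reassign_grey=True)
        assert moved.partition.labels[5] == 2

    def test_emptied_module_is_retired_with_warning(self, caplog):
        # genes 4, 5 labeled module 2 but barely connected to each other and
        # strongly connected to module 1, whose members prefer staying put
        a = np.full((6, 6), 0.9)
        a[:4, 4:] = a[4:, :4] = 0.6
        np.fill_diagonal(a, 0.0)
        a[4, 5] = a[5, 4] = 0.05
        res = None
        with caplog.at_level("WARNING"):
            res = k_module_refine(partition([1, 1, 1, 1, 2, 2]), a)
        assert res.retired_modules == (2,)
        assert res.partition.n_modules == 1
        assert res.converged

    def test_deterministic(self, default_synthetic):
        expr, truth = default_synthetic
        adj = adjacency(pairwise_similarity(expr, "absolute-pearson"), 6).adjacency
        bad = corrupt(truth, 0.1, seed=4)
        r1 = k_module_refine(bad, adj)
        r2 = k_module_refine(bad, adj)
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)
        assert r1.changes_per_iteration == r2.changes_per_iteration

    def test_max_iter_validated(self, two_block_adjacency):
        a, labels = two_block_adjacency
        with pytest.raises(ValueError):
            k_module_refine(partition(labels), a, max_iter=0)

    def test_converged_result_requires_trailing_zero(self, two_block_adjacency):
        a, labels = two_block_adjacency
        res = k_module_refine(partition(labels), a)
        with pytest.raises(ValueError):
            RefinementResult(res.partition, 1, (3,), converged=True)


class TestModuleEigengene:
    def test_identical_profiles_capture_all_variance(self):
        base = np.arange(8.0)
        vals = np.vstack([base, base, base]) + np.array([[0.0], [1.0], [5.0]])
        expr = ExpressionMatrix(("a", "b", "c"), tuple(f"s{i}" for i in range(8)), vals)
        egs = module_eigengene(expr, partition([1, 1, 1]))
        assert egs.variance_proportion[1] == pytest.approx(1.0)

    def test_sign_flipped_pair_is_rank_one(self):
        x = np.array([1.0, -2, 0.5, 3, -1, 2])
        expr = ExpressionMatrix(("up", "down"), tuple(f"s{i}" for i in range(6)),
                                np.vstack([x, -x]))
        egs = module_eigengene(expr, partition([1, 1]))
        assert egs.variance_proportion[1] == pytest.approx(1.0)
        eg = egs.eigengenes[1]
        assert abs(np.corrcoef(x, eg)[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(eg) == pytest.approx(1.0)

    def test_variance_proportion_matches_covariance_eigenvalues(self):
        expr = random_expr(8, 12, seed=11)
        egs = module_eigengene(expr, partition([1] * 8))
        z = (expr.values - expr.values.mean(1, keepdims=True))
        z /= z.std(1, ddof=1, keepdims=True)
        w = np.linalg.eigvalsh(z @ z.T)
        assert egs.variance_proportion[1] == pytest.approx(w[-1] / w.sum(), abs=1e-12)

    def test_constant_gene_failure_names_module(self):
        vals = np.vstack([np.full(5, 3.0), np.arange(5.0)])
        expr = ExpressionMatrix(("c", "v"), tuple(f"s{i}" for i in range(5)), vals)
        with pytest.raises(ValueError, match="module 1"):
            module_eigengene(expr, partition([1, 1]))


class TestKEigengeneRefine:
    def test_single_module_converges_immediately(self):
        expr = random_expr(6, 10, seed=12)
        res = k_eigengene_refine(expr, partition([1] * 6))
        assert res.converged
        assert res.iterations == 1
        assert res.changes_per_iteration == (0,)

    def test_planted_correct_labels_are_stable(self):
        spec = SyntheticSpec(n_genes=60, n_samples=40, n_modules=3,
                             grey_fraction=0.0, noise_sd=0.3, seed=7)
        expr, truth = generate(spec)
        res = k_eigengene_refine(expr, truth)
        assert res.converged
        np.testing.assert_array_equal(res.partition.labels, truth.labels)

    def test_deterministic(self, default_synthetic):
        expr, truth = default_synthetic
        bad = corrupt(truth, 0.2, seed=5)
        r1 = k_eigengene_refine(expr, bad)
        r2 = k_eigengene_refine(expr, bad)
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)


class TestOscillationDetector:
    def test_injected_two_cycle_is_flagged_and_runs_to_max_iter(self):
        # drive the shared refinement loop with a score function that makes
        # genes 0 and 1 swap modules every iteration
        labels = np.array([1, 2, 1, 2])

        def swapping_scores(lab, mods):
            scores = np.zeros((4, 2))
            scores[2, 0] = scores[3, 1] = 1.0      # residents stay put
            scores[0, 0 if lab[0] == 2 else 1] = 1.0  # movers always prefer
            scores[1, 0 if lab[1] == 2 else 1] = 1.0  # the other module
            return scores

        res = _iterate(labels.copy(), [1, 2], 9, False, swapping_scores,
                       tuple(f"g{i}" for i in range(4)))
        assert res.oscillation_detected
        assert not res.converged
        assert res.iterations == 9
        assert all(c == 2 for c in res.changes_per_iteration)
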