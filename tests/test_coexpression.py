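import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import modulepivot as mp
from modulepivot.coexpression import UNASSIGNED

from .conftest import make_study
from .oracles import (
    average_linkage_naive,
    scale_free_regression_reference,
    tom_bruteforce,
)


class TestCorrelationMatrix:
    def test_hand_computed_pearson_value(self):
        study = make_study(
            np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]), ["a", "a", "b"]
        )
        corr = mp.correlation_matrix(study)
        assert corr.values[0, 1] == pytest.approx(0.9819805060619659, abs=1e-12)

    def test_duplicated_and_negated_profiles(self):
        x = np.array([1.0, 5.0, 2.0, 4.0])
        study = make_study(np.vstack([x, x, -x]), ["a"] * 4)
        corr = mp.correlation_matrix(study)
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_zero_variance_gene_is_named(self):
        study = make_study(
            np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]), ["a"] * 3
        )
        with pytest.raises(ValueError, match="g1"):
            mp.correlation_matrix(study)


class TestAdjacency:
    @pytest.fixture()
    def corr(self):
        genes = ["g1", "g2"]
        v = np.array([[1.0, -0.8], [-0.8, 1.0]])
        return mp.CorrelationMatrix(genes=genes, values=v)

    def test_unsigned_power_six(self, corr):
        a = mp.adjacency(corr, power=6)
        assert a[0, 1] == pytest.approx(0.262144, abs=1e-12)  # 0.8^6

    def test_power_one_is_absolute_value(self, corr):
        assert mp.adjacency(corr, power=1)[0, 1] == pytest.approx(0.8)

    def test_signed_perfect_anticorrelation_is_zero(self):
        v = np.array([[1.0, -1.0], [-1.0, 1.0]])
        corr = mp.CorrelationMatrix(genes=["a", "b"], values=v)
        for power in (1, 3, 6):
            assert mp.adjacency(corr, power, signed=True)[0, 1] == 0.0

    def test_unsigned_invariant_to_profile_sign_flip(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 10))
        flipped = x.copy()
        flipped[2] *= -1
        a = mp.adjacency(mp.correlation_matrix(make_study(x, ["a"] * 10)), 6)
        b = mp.adjacency(
            mp.correlation_matrix(make_study(flipped, ["a"] * 10)), 6
        )
        np.testing.assert_allclose(a, b, atol=1e-12)


def _clique_block(sizes_and_weights):
    """Disjoint uniformly-weighted cliques -> exactly controlled k values."""
    n = sum(s for s, _, reps in sizes_and_weights for _ in range(reps))
    a = np.zeros((n, n))
    pos = 0
    for size, weight, reps in sizes_and_weights:
        for _ in range(reps):
            block = np.full((size, size), weight)
            np.fill_diagonal(block, 0.0)
            a[pos : pos + size, pos : pos + size] = block
            pos += size
    return a


class TestScaleFreeFit:
    def test_exact_inverse_square_law_fits_perfectly(self):
        # node counts proportional to k^-2 at k = 10, 20, 30, 40 (each in
        # its own bin) make log10(freq) exactly linear in log10(k)
        a = _clique_block([
            (16, 10 / 15, 9),   # 144 nodes with k = 10
            (36, 20 / 35, 1),   # 36 nodes with k = 20
            (16, 30 / 15, 1),   # 16 nodes with k = 30
            (9, 40 / 8, 1),     # 9 nodes with k = 40
        ])
        r2, slope = mp.scale_free_fit(a)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert slope == pytest.approx(-2.0, abs=1e-10)

    def test_positive_slope_yields_non_positive_r2(self):
        # frequencies increasing with k: many high-k nodes, few low-k
        a = _clique_block([(3, 0.5, 2), (30, 0.9, 1)])
        r2, slope = mp.scale_free_fit(a, n_bins=5)
        assert slope > 0
        assert r2 <= 0

    def test_matches_independent_regression_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random((40, 40))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 0.0)
        r2, slope = mp.scale_free_fit(a, n_bins=10)
        ref_r2, ref_slope = scale_free_regression_reference(a.sum(axis=1), 10)
        assert r2 == pytest.approx(ref_r2, abs=1e-10)
        assert slope == pytest.approx(ref_slope, abs=1e-10)

    def test_degenerate_connectivity_errors(self):
        a = _clique_block([(5, 0.5, 2)])
        with pytest.raises(ValueError, match="degenerate"):
            mp.scale_free_fit(a)


@pytest.fixture(scope="module")
def corr(reference_study):
    study, _ = reference_study
    return mp.correlation_matrix(study)


class TestSelectSoftPower:
    def test_smallest_qualifying_power_is_chosen(self, corr):
        scan = mp.select_soft_power(corr, candidate_powers=tuple(range(1, 21)),
                                    r2_cutoff=0.5)
        qualifying = scan.scan[scan.scan["scale_free_r2"] >= 0.5]
        assert len(qualifying)
        assert scan.chosen_power == int(qualifying["power"].iloc[0])

    def test_fallback_to_best_fit_warns(self, corr):
        with pytest.warns(UserWarning, match="best fit"):
            scan = mp.select_soft_power(corr, candidate_powers=(1, 2),
                                        r2_cutoff=0.99)
        best = scan.scan.loc[scan.scan["scale_free_r2"].idxmax(), "power"]
        assert scan.chosen_power == int(best)

    def test_scan_is_deterministic_and_connectivity_decreasing(self, corr):
        s1 = mp.select_soft_power(corr)
        s2 = mp.select_soft_power(corr)
        pd.testing.assert_frame_equal(s1.scan, s2.scan)
        k = s1.scan["mean_connectivity"].to_numpy()
        assert (np.diff(k) <= 0).all()


class TestTOM:
    def test_complete_triangle_has_unit_overlap(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = mp.tom_similarity(a)
        assert tom.values[0, 1] == pytest.approx(1.0)  # (1+1)/(2+1-1)

    def test_isolated_nodes_have_zero_overlap(self):
        tom = mp.tom_similarity(np.zeros((2, 2)))
        assert tom.values[0, 1] == 0.0
        assert tom.values[0, 0] == 1.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.random((30, 30))
        a = (x + x.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = mp.tom_similarity(a)
        np.testing.assert_allclose(tom.values, tom_bruteforce(a), atol=1e-10)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[0.0, 1.2], [1.2, 0.0]]),  # out of range
            np.array([[0.5, 0.1], [0.1, 0.5]]),  # nonzero diagonal
            np.array([[0.0, 0.3], [0.4, 0.0]]),  # asymmetric
        ],
    )
    def test_invalid_adjacency_rejected(self, bad):
        with pytest.raises(ValueError):
            mp.tom_similarity(bad)


class TestClusterDendrogram:
    def _toy_tom(self, n, seed=2):
        rng = np.random.default_rng(seed)
        x = rng.random((n, n)) * 0.8
        t = (x + x.T) / 2
        np.fill_diagonal(t, 1.0)
        return mp.TOMatrix(genes=[f"g{i}" for i in range(n)], values=t)

    def test_identical_genes_merge_first_at_zero(self):
        t = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        z = mp.cluster_dendrogram(mp.TOMatrix(genes=["a", "b", "c"], values=t))
        assert z[0, 2] == pytest.approx(0.0)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_heights_are_monotone(self):
        z = mp.cluster_dendrogram(self._toy_tom(12))
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_matches_naive_average_linkage(self):
        tom = self._toy_tom(6)
        z = mp.cluster_dendrogram(tom)
        merges = average_linkage_naive(1.0 - tom.values)
        np.testing.assert_allclose(
            z[:, 2], [h for _, _, h in merges], atol=1e-12
        )

    def test_single_gene_errors(self):
        t = mp.TOMatrix(genes=["a"], values=np.array([[1.0]]))
        with pytest.raises(ValueError):
            mp.cluster_dendrogram(t)


class TestCutAndFilter:
    @pytest.fixture()
    def toy(self):
        rng = np.random.default_rng(3)
        x = rng.random((10, 10)) * 0.5
        t = (x + x.T) / 2
        np.fill_diagonal(t, 1.0)
        tom = mp.TOMatrix(genes=[f"g{i:02d}" for i in range(10)], values=t)
        return tom, mp.cluster_dendrogram(tom)

    def test_full_height_cut_gives_single_module(self, toy):
        tom, z = toy
        part = mp.cut_modules(z, tom.genes, cut_height=1.0, min_module_size=2)
        assert part.labels == ["M1"]
        assert part.sizes["M1"] == 10

    def test_oversized_min_size_unassigns_everything(self, toy):
        tom, z = toy
        part = mp.cut_modules(z, tom.genes, cut_height=0.5, min_module_size=99)
        assert part.labels == []
        assert part.sizes[UNASSIGNED] == 10

    def test_huge_size_bound_is_identity(self):
        part = mp.ModulePartition(
            module_of={"a": "M1", "b": "M1", "c": "M2", "d": "M2",
                       "e": "M3", "f": "unassigned"}
        )
        out = mp.filter_modules(part, max_module_size=10**6)
        assert out.module_of == part.module_of

    def test_cut_labels_ordered_by_size_then_member_id(self):
        # two clusters of 3 and one of 2; ties impossible here, but the
        # 2-cluster must come last and the 3-clusters order by smallest ID
        t = np.full((8, 8), 0.01)
        for block in ([0, 1, 2], [3, 4, 5], [6, 7]):
            for i in block:
                for j in block:
                    t[i, j] = 0.99
        np.fill_diagonal(t, 1.0)
        genes = ["b1", "b2", "b3", "a1", "a2", "a3", "c1", "c2"]
        tom = mp.TOMatrix(genes=genes, values=t)
        part = mp.cut_modules(mp.cluster_dendrogram(tom), genes,
                              cut_height=0.5, min_module_size=2)
        assert part.genes_in("M1") == {"a1", "a2", "a3"}  # tie -> "a1" < "b1"
        assert part.genes_in("M2") == {"b1", "b2", "b3"}
        assert part.genes_in("M3") == {"c1", "c2"}

    def test_size_filter_removes_oversized_module(self):
        module_of = {f"g{i:04d}": "M1" for i in range(600)}
        module_of.update({f"h{i:04d}": "M2" for i in range(100)})
        part = mp.ModulePartition(module_of=module_of)
        out = mp.filter_modules(part, max_module_size=500)
        assert out.labels == ["M1"]
        assert out.sizes["M1"] == 100  # the former M2, relabeled
        assert out.sizes[UNASSIGNED] == 600

    def test_structural_22_to_21_module_screen(self):
        # 22 modules, exactly one at or above the 500-gene bound -> 21 kept
        module_of = {}
        for m in range(1, 23):
            size = 520 if m == 5 else 40
            for i in range(size):
                module_of[f"m{m:02d}_{i:03d}"] = f"M{m}"
        out = mp.filter_modules(
            mp.ModulePartition(module_of=module_of), max_module_size=500
        )
        assert len(out.labels) == 21


class TestDetectModules:
    def test_default_power_table(self):
        assert mp.default_soft_power(10) == 10
        assert mp.default_soft_power(20) == 9
        assert mp.default_soft_power(35) == 8
        assert mp.default_soft_power(60) == 6
        assert mp.default_soft_power(20, signed=True) == 18

    def test_detection_is_deterministic(self, reference_study,
                                        reference_detection):
        study, _ = reference_study
        part1, scan1, _ = reference_detection
        part2, scan2, _ = mp.detect_modules(study)
        assert part1.module_of == part2.module_of
        pd.testing.assert_frame_equal(scan1.scan, scan2.scan)

    def test_recovers_planted_modules(self, reference_study,
                                      reference_detection):
        from sklearn.metrics import adjusted_rand_score

        _, truth = reference_study
        part, _, _ = reference_detection
        truth_labels = [truth.true_module_of[g] for g in part.genes]
        found_labels = [part.module_of[g] for g in part.genes]
        assert adjusted_rand_score(truth_labels, found_labels) >= 0.8
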