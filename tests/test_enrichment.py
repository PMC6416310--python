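import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import modulepivot as mp
from modulepivot.data_io import GeneSetCollection

from .oracles import bh_reference, hypergeom_tail_exact, hypergeom_tail_enumerated


class TestHypergeometricTail:
    def test_zero_overlap_has_unit_tail(self):
        assert mp.hypergeometric_tail(0, 4, 5, 10) == 1.0

    def test_hand_enumerated_examples(self):
        # P(X>=2) = 1 - 6/252 - 60/252 = 186/252
        assert mp.hypergeometric_tail(2, 4, 5, 10) == pytest.approx(
            186 / 252, abs=1e-12
        )
        # P(X>=4) = C(5,4)/C(20,4) = 5/4845
        assert mp.hypergeometric_tail(4, 5, 4, 20) == pytest.approx(
            5 / 4845, abs=1e-12
        )

    def test_exact_oracle_agrees_with_subset_enumeration(self):
        # validates the combinatorial oracle itself on a tiny urn
        for N in (5, 6, 7):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_tail_exact(k, K, n, N) == (
                            hypergeom_tail_enumerated(k, K, n, N)
                        )

    def test_agrees_with_exact_oracle_small_universe(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = mp.hypergeometric_tail(k, K, n, N)
                        assert got == pytest.approx(
                            float(hypergeom_tail_exact(k, K, n, N)), abs=1e-12
                        )

    @pytest.mark.parametrize(
        "k,K,n,N", [(3, 2, 5, 10), (1, 4, 5, 4), (-1, 4, 5, 10), (2, 11, 5, 10)]
    )
    def test_impossible_counts_error(self, k, K, n, N):
        with pytest.raises(ValueError):
            mp.hypergeometric_tail(k, K, n, N)


class TestBHAdjust:
    def test_single_test_is_identity(self):
        assert mp.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            mp.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_matches_quadratic_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(
                mp.bh_adjust(p), bh_reference(p), atol=1e-12
            )

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=30))
    def test_monotone_in_sorted_order(self, ps):
        q = mp.bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_out_of_range_p_errors(self, bad):
        with pytest.raises(ValueError):
            mp.bh_adjust(bad)


def _partition(mapping):
    return mp.ModulePartition(module_of=mapping)


class TestEnrichModule:
    def test_degenerate_identity_reports_p_one(self):
        genes = [f"g{i}" for i in range(12)]
        part = _partition({g: "M1" for g in genes})
        coll = GeneSetCollection(sets={"T1": ("d", frozenset(genes))})
        rows = mp.enrich_module(part, coll, p_cutoff=1.0, q_cutoff=1.0,
                                min_term_size=1, max_term_size=100)
        assert len(rows) == 1
        assert rows["p_value"].iloc[0] == pytest.approx(1.0)
        assert rows["k"].iloc[0] == 12

    def test_disjoint_term_yields_no_row(self):
        part = _partition({"a": "M1", "b": "M1", "c": "unassigned"})
        coll = GeneSetCollection(
            sets={"T1": ("d", frozenset({"c"})), "T2": ("d", frozenset({"a", "b"}))}
        )
        rows = mp.enrich_module(part, coll, p_cutoff=1.0, q_cutoff=1.0,
                                min_term_size=1, max_term_size=10)
        assert set(rows["term"]) == {"T2"}

    def test_planted_term_ranks_first_below_cutoff(self):
        # module of 100 genes fully annotated with a 120-member term inside
        # a 1000-gene universe
        rng = np.random.default_rng(4)
        genes = [f"g{i:04d}" for i in range(1000)]
        module = genes[:100]
        part = _partition(
            {g: ("M1" if g in set(module) else "unassigned") for g in genes}
        )
        t1 = frozenset(module) | frozenset(rng.choice(genes[100:], 20,
                                                      replace=False))
        decoys = {
            f"D{i}": ("d", frozenset(rng.choice(genes, 50, replace=False)))
            for i in range(10)
        }
        coll = GeneSetCollection(sets={"T1": ("planted", t1), **decoys})
        # universe must cover all genes for the planted maths to hold
        coll.sets["ALL"] = ("background", frozenset(genes))
        rows = mp.enrich_module(part, coll, p_cutoff=0.01, q_cutoff=0.01,
                                max_term_size=2000)
        assert rows["term"].iloc[0] == "T1"
        assert rows["q_value"].iloc[0] < 0.01
        expected_p = mp.hypergeometric_tail(100, 120, 100, 1000)
        assert rows["p_value"].iloc[0] == pytest.approx(expected_p, rel=1e-9)

    def test_p_values_invariant_under_gene_relabeling(self):
        genes = [f"g{i}" for i in range(40)]
        part = _partition(
            {g: ("M1" if i < 15 else "unassigned") for i, g in enumerate(genes)}
        )
        coll = GeneSetCollection(
            sets={"T1": ("d", frozenset(genes[5:25])),
                  "ALL": ("bg", frozenset(genes))}
        )
        rows = mp.enrich_module(part, coll, p_cutoff=1.0, q_cutoff=1.0,
                                min_term_size=1, max_term_size=100)
        rename = {g: f"x{g}" for g in genes}
        part2 = _partition({rename[g]: m for g, m in part.module_of.items()})
        coll2 = GeneSetCollection(
            sets={t: (d, frozenset(rename[g] for g in ms))
                  for t, (d, ms) in coll.sets.items()}
        )
        rows2 = mp.enrich_module(part2, coll2, p_cutoff=1.0, q_cutoff=1.0,
                                 min_term_size=1, max_term_size=100)
        np.testing.assert_allclose(rows["p_value"], rows2["p_value"])

    def test_empty_universe_errors(self):
        part = _partition({"a": "M1", "b": "M1"})
        coll = GeneSetCollection(sets={"T1": ("d", frozenset({"zz"}))})
        with pytest.raises(ValueError, match="universe"):
            mp.enrich_module(part, coll, min_term_size=1)


class TestCrossModuleTermCounts:
    def test_counts_distinct_modules(self):
        import pandas as pd

        rows = pd.DataFrame(
            {"term": ["T1", "T1", "T2"], "module": ["M1", "M3", "M1"]}
        )
        out = mp.cross_module_term_counts(rows)
        assert out.loc[out["term"] == "T1", "n_modules"].iloc[0] == 2
        assert out["n_modules"].tolist() == sorted(
            out["n_modules"], reverse=True
        )

    def test_empty_input_gives_empty_table(self):
        import pandas as pd

        out = mp.cross_module_term_counts(pd.DataFrame(columns=["term", "module"]))
        assert len(out) == 0

    def test_invariant_to_row_order(self):
        import pandas as pd

        rows = pd.DataFrame(
            {"term": ["T1", "T2", "T1"], "module": ["M1", "M2", "M2"]}
        )
        a = mp.cross_module_term_counts(rows)
        b = mp.cross_module_term_counts(rows.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)
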