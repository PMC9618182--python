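"""Altered-set derivation, specificity, Venn counts and rankings."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from synprot.errors import ConfigError
from synprot.sets import AlteredSets, altered_sets, specific_set, top_k, venn_counts
from synprot.transform import DOWN, UNCHANGED, UP


def ratio_frame(rows):
    return pd.DataFrame(rows, columns=["accession", "comparison", "norm_ratio", "change_class"])


def make_sets(**comps):
    """AlteredSets from comparison -> (up_iterable, down_iterable)."""
    return AlteredSets(
        up={k: frozenset(v[0]) for k, v in comps.items()},
        down={k: frozenset(v[1]) for k, v in comps.items()},
    )


class TestAlteredSets:
    def test_all_unchanged_gives_empty_sets(self):
        df = ratio_frame([("P1", "c1", 1.0, UNCHANGED), ("P2", "c1", 1.1, UNCHANGED)])
        sets = altered_sets(df)
        assert sets.up["c1"] == frozenset() and sets.down["c1"] == frozenset()

    def test_sets_reflect_class_labels(self):
        df = ratio_frame(
            [("P1", "c1", 1.5, UP), ("P2", "c1", 0.5, DOWN), ("P3", "c1", 1.0, UNCHANGED),
             ("P1", "c2", 1.0, UNCHANGED), ("P2", "c2", 2.0, UP), ("P3", "c2", 0.7, DOWN)]
        )
        sets = altered_sets(df)
        assert sets.up["c1"] == {"P1"} and sets.down["c1"] == {"P2"}
        assert sets.altered("c2") == {"P2", "P3"}

    def test_planted_truth_counts_recovered_at_zero_noise(self, study_design):
        from synprot.model import SynapticProteomeModel
        from synprot.simulate import EffectConfig, generate_pool_table

        table, truth = generate_pool_table(
            study_design, EffectConfig(n_proteins=400, frac_altered_per_comparison=0.25, seed=9)
        )
        results = SynapticProteomeModel(table, study_design).fit()
        retained = set(results.analysis_ready.index)
        truth = truth[truth["accession"].isin(retained)]
        for comp in study_design.names:
            t = truth[truth["comparison"] == comp]
            assert results.sets.up[comp] == set(t.loc[t["true_class"] == UP, "accession"])
            assert results.sets.down[comp] == set(t.loc[t["true_class"] == DOWN, "accession"])

    def test_unknown_comparison_raises(self):
        sets = make_sets(c1=({"P1"}, set()))
        with pytest.raises(KeyError):
            sets.altered("nope")


class TestSpecificSet:
    def test_empty_others_returns_full_altered_set(self):
        sets = make_sets(a=({"P1"}, {"P2"}), b=(set(), set()))
        res = specific_set("a", ["b"], sets)
        assert res.specific == {"P1", "P2"} and res.shared == frozenset()

    def test_forced_example(self):
        sets = make_sets(A=({"p1", "p2"}, {"p3"}), B=({"p2"}, set()))
        res = specific_set("A", ["B"], sets)
        assert res.specific == {"p1", "p3"} and res.shared == {"p2"}

    def test_target_among_others_rejected(self):
        sets = make_sets(a=({"P1"}, set()), b=(set(), set()))
        with pytest.raises(ConfigError):
            specific_set("a", ["a", "b"], sets)

    def test_partition_identity_on_random_sets(self):
        rng = np.random.default_rng(11)
        universe = [f"P{i}" for i in range(60)]
        for _ in range(20):
            comps = {
                name: (
                    set(rng.choice(universe, 15, replace=False)),
                    set(rng.choice(universe, 10, replace=False)),
                )
                for name in "abc"
            }
            # up/down within one comparison must be disjoint
            comps = {k: (u, d - u) for k, (u, d) in comps.items()}
            sets = make_sets(**comps)
            res = specific_set("a", ["b", "c"], sets)
            assert res.specific | res.shared == sets.altered("a")
            assert not res.specific & res.shared
            # cross-check against element-wise membership
            other = sets.altered("b") | sets.altered("c")
            assert res.specific == {p for p in sets.altered("a") if p not in other}


class TestVennCounts:
    def test_disjoint_pair(self):
        counts = venn_counts({"A": {"a"}, "B": {"b"}})
        assert counts[(True, False)] == 1
        assert counts[(False, True)] == 1
        assert counts[(True, True)] == 0

    def test_identical_sets_concentrate_in_full_intersection(self):
        counts = venn_counts({"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}})
        assert counts[(True, True, True)] == 2
        assert sum(counts.values()) == 2

    def test_random_instances_match_bruteforce_and_conserve_union(self):
        rng = np.random.default_rng(13)
        universe = list(range(40))
        for n_sets in (2, 3, 4):
            sets = {
                f"s{i}": set(rng.choice(universe, rng.integers(0, 25), replace=False))
                for i in range(n_sets)
            }
            counts = venn_counts(sets)
            values = list(sets.values())
            # brute-force: classify every universe element by membership tuple
            brute = {}
            for el in universe:
                mask = tuple(el in s for s in values)
                if any(mask):
                    brute[mask] = brute.get(mask, 0) + 1
            for mask in product([True, False], repeat=n_sets):
                if any(mask):
                    assert counts[mask] == brute.get(mask, 0)
            assert sum(counts.values()) == len(set().union(*values))

    def test_unsupported_arity(self):
        with pytest.raises(ConfigError):
            venn_counts({str(i): {i} for i in range(5)})


class TestTopK:
    def test_k_larger_than_table_returns_full_sorted_list(self):
        df = ratio_frame([("A", "c", 2.0, UP), ("B", "c", 1.5, UP), ("C", "c", 0.4, DOWN)])
        assert top_k(df, "c", k=10, direction=UP) == ["A", "B", "C"]
        assert top_k(df, "c", k=10, direction=DOWN) == ["C", "B", "A"]

    def test_forced_ranking(self):
        df = ratio_frame([("A", "c", 2.0, UP), ("B", "c", 1.5, UP), ("C", "c", 0.4, DOWN)])
        assert top_k(df, "c", k=2, direction=UP) == ["A", "B"]

    def test_tie_breaks_lexicographically(self):
        df = ratio_frame([("B", "c", 1.5, UP), ("A", "c", 1.5, UP)])
        assert top_k(df, "c", k=1, direction=UP) == ["A"]

    def test_invalid_k_and_unknown_comparison(self):
        df = ratio_frame([("A", "c", 2.0, UP)])
        with pytest.raises(ConfigError):
            top_k(df, "c", k=0)
        with pytest.raises(KeyError):
            top_k(df, "other", k=1)


class TestMonotonicity:
    def test_raising_up_threshold_never_grows_up_sets(self, make_table, two_pool_design):
        from synprot.transform import ratiometric_normalize

        rng = np.random.default_rng(17)
        table = make_table(
            {"pool_case": rng.lognormal(0, 0.5, 80), "pool_ctrl": rng.lognormal(0, 0.5, 80)}
        )
        prev = None
        for up in (1.1, 1.2, 1.4, 1.8):
            out = ratiometric_normalize(table, two_pool_design, up_threshold=up)
            ups = altered_sets(out).up["case_vs_ctrl"]
            if prev is not None:
                assert ups <= prev
            prev = ups
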