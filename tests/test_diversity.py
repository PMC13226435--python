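import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemchron import diversity


def brute_entropy(counts):
    """Independent evaluation: explicit sum over proportions."""
    n = sum(counts)
    return -sum((c / n) * math.log2(c / n) for c in counts if c)


class TestShannonEntropy:
    def test_single_scaffold_zero_bits(self):
        assert diversity.shannon_entropy({"A": 1}) == 0.0

    def test_hand_computed_value(self):
        # -(0.5 log2 0.5 + 2 * 0.25 log2 0.25) = 1.5
        assert diversity.shannon_entropy({"A": 2, "B": 1, "C": 1}) == pytest.approx(1.5, abs=1e-12)

    def test_uniform_is_log2_k(self):
        assert diversity.shannon_entropy({c: 5 for c in "ABCD"}) == pytest.approx(2.0, abs=1e-12)

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            diversity.shannon_entropy({})

    def test_all_compositions_of_six_match_brute_force(self):
        """Exhaustive oracle: every composition of 6 molecules into <= 3 scaffolds."""
        for k in (1, 2, 3):
            for combo in itertools.product(range(1, 7), repeat=k):
                if sum(combo) != 6:
                    continue
                table = {f"s{i}": c for i, c in enumerate(combo)}
                assert diversity.shannon_entropy(table) == pytest.approx(
                    brute_entropy(combo), abs=1e-12
                )
                # maximality at the uniform composition
                if len(set(combo)) == 1:
                    assert diversity.shannon_entropy(table) == pytest.approx(
                        math.log2(k), abs=1e-12
                    )

    def test_merging_classes_never_increases_entropy(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 8))
            counts = rng.integers(1, 50, size=k)
            table = {f"s{i}": int(c) for i, c in enumerate(counts)}
            merged = dict(table)
            a, b = rng.choice(k, size=2, replace=False)
            merged[f"s{a}"] = merged.pop(f"s{b}") + merged[f"s{a}"]
            assert diversity.shannon_entropy(merged) <= diversity.shannon_entropy(table) + 1e-12


class TestEquitability:
    @pytest.mark.parametrize("k", [2, 3, 10, 50])
    def test_uniform_distribution_gives_one(self, k):
        table = {f"s{i}": 7 for i in range(k)}
        assert diversity.equitability(table) == pytest.approx(1.0, abs=1e-12)

    def test_single_scaffold_defined_as_zero(self):
        assert diversity.equitability({"A": 9}) == 0.0

    def test_hand_computed_value(self):
        expected = 1.5 / math.log2(3)
        assert diversity.equitability({"A": 2, "B": 1, "C": 1}) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.9464, abs=5e-5)

    def test_scale_invariance(self, rng):
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.integers(1, 30, size=6))}
        scaled = {k: 13 * v for k, v in counts.items()}
        assert diversity.equitability(scaled) == pytest.approx(
            diversity.equitability(counts), abs=1e-12
        )

    def test_base_cancels(self, rng):
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.integers(1, 30, size=5))}
        assert diversity.equitability(counts, base=2) == pytest.approx(
            diversity.equitability(counts, base=math.e), abs=1e-12
        )

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=60))
    @settings(max_examples=200, derandomize=True)
    def test_bounded_between_zero_and_one(self, counts):
        table = {f"s{i}": c for i, c in enumerate(counts)}
        see = diversity.equitability(table)
        assert 0.0 <= see <= 1.0 + 1e-12


class TestScaffoldCounts:
    def test_direct_tally(self):
        t = diversity.scaffold_counts(["A", "A", "B"])
        assert t.counts == {"A": 2, "B": 1}
        assert t.n_molecules == 3 and t.n_scaffolds == 2

    def test_empty_marker_excluded_by_default(self):
        t = diversity.scaffold_counts(["A", "", "A"])
        assert t.counts == {"A": 2} and t.n_molecules == 2

    def test_empty_marker_included_on_request(self):
        t = diversity.scaffold_counts(["A", "", "A"], include_empty=True)
        assert t.n_molecules == 3

    def test_empty_input(self):
        t = diversity.scaffold_counts([])
        assert t.n_molecules == 0 and t.n_scaffolds == 0

    def test_proportions_sum_to_one(self, rng):
        keys = [f"s{i}" for i in rng.integers(0, 5, size=40)]
        t = diversity.scaffold_counts(keys)
        assert sum(t.proportions().values()) == pytest.approx(1.0, abs=1e-12)


class TestTopK:
    def test_direct_ranking_with_percent(self):
        t = {"benzene": 2, "X": 1, "Y": 1}
        assert diversity.top_k_scaffolds(t, 1) == [("benzene", 2, 50.0)]

    def test_k_larger_than_table(self):
        assert len(diversity.top_k_scaffolds({"A": 2, "B": 1}, 10)) == 2

    def test_tie_break_lexicographic(self):
        top = diversity.top_k_scaffolds({"zzz": 3, "aaa": 3}, 2)
        assert [s for s, _, _ in top] == ["aaa", "zzz"]

    def test_external_denominator(self):
        top = diversity.top_k_scaffolds({"A": 2}, 1, total_molecules=8)
        assert top[0][2] == pytest.approx(25.0)

    def test_percentages_non_increasing_and_bounded(self, rng):
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.integers(1, 99, size=20))}
        top = diversity.top_k_scaffolds(counts, 20)
        pcts = [p for _, _, p in top]
        assert all(a >= b for a, b in zip(pcts, pcts[1:]))
        assert sum(pcts) <= 100.0 + 1e-9

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            diversity.top_k_scaffolds({"A": 1}, 0)


class TestCoveragePercent:
    def test_structure_coverage_rounds_to_one_sig_fig(self):
        assert diversity.coverage_percent(251_806, 203_130_941, sig_figs=1) == 0.1

    def test_full_coverage(self):
        assert diversity.coverage_percent(1, 1) == 100.0

    def test_zero_part(self):
        assert diversity.coverage_percent(0, 5) == 0.0

    def test_zero_whole_rejected(self):
        with pytest.raises(ValueError):
            diversity.coverage_percent(1, 0)
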