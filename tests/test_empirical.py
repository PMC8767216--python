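"""Canalization statistics for heterogeneous model collections."""

import numpy as np
import pytest
from scipy import stats as sps

from boolcrit.empirical import (
    _hinge_quartiles,
    analyze_model_collection,
    filter_automata,
    summarize_set,
)
from boolcrit.rules import BooleanNetwork, BooleanRule, rule_from_string


def make_net(rules, seed=0):
    rng = np.random.default_rng(seed)
    n = len(rules)
    inputs = [tuple(rng.choice(n, r.k, replace=False)) for r in rules]
    return BooleanNetwork(inputs=inputs, rules=rules)


class TestFilter:
    def test_removes_constants_then_single_input(self, or2):
        const1 = rule_from_string("1111")
        copy = rule_from_string("01")
        res = filter_automata([or2, const1, copy])
        assert res.retained == (or2,)
        assert res.n_constant == 1 and res.n_single_input == 1

    def test_all_constant_input_flagged_empty(self):
        res = filter_automata([rule_from_string("00"),
                               rule_from_string("1111")])
        assert res.empty and res.n_constant == 2

    def test_counts_match_hand_tally(self, or2, and2, xor2):
        rules = ([or2] * 5 + [and2] * 4 + [xor2] * 3
                 + [rule_from_string("01")] * 4  # single-input copies
                 + [rule_from_string("0000")] * 2  # contradictions
                 + [rule_from_string("11")] * 2)  # constant single-input
        res = filter_automata(rules)
        assert res.n_total == 20
        assert res.n_constant == 4  # two k=2 and two k=1 constants
        assert res.n_single_input == 4
        assert len(res.retained) == 12

    def test_idempotent(self, or2, and2):
        rules = [or2, and2, rule_from_string("01"), rule_from_string("00")]
        once = filter_automata(rules)
        twice = filter_automata(once.retained)
        assert twice.retained == once.retained
        assert twice.n_constant == 0 and twice.n_single_input == 0


class TestQuartiles:
    def test_median_of_halves_odd(self):
        assert _hinge_quartiles(np.array([1, 2, 3, 4, 5])) == (1.5, 4.5)

    def test_median_of_halves_even(self):
        assert _hinge_quartiles(np.array([1, 2, 3, 4])) == (1.5, 3.5)


class TestSummarize:
    def test_identical_rules_zero_dispersion(self, or2):
        summary = summarize_set(filter_automata([or2] * 6))
        assert summary.k_stats.mean == 2.0
        assert summary.ke_stats.mean == 1.25
        assert summary.ke_stats.q1 == summary.ke_stats.q3 == 1.25

    def test_known_moments_of_five_element_set(self, or2, and3):
        """k sample {2,2,2,2,3}: moments computed in closed form."""
        rules = [or2] * 4 + [and3]
        summary = summarize_set(filter_automata(rules))
        ks = np.array([2, 2, 2, 2, 3], dtype=float)
        assert summary.k_stats.mean == ks.mean()
        assert summary.k_stats.median == 2.0
        assert summary.k_stats.skewness == pytest.approx(
            sps.skew(ks, bias=True))
        assert summary.k_stats.excess_kurtosis == pytest.approx(
            sps.kurtosis(ks, fisher=True, bias=True))
        # OR2 and AND3 share k_e = 1.25: degenerate k_e distribution
        assert summary.ke_stats.mean == 1.25

    def test_symmetric_sample_has_zero_skewness(self, or2, and3):
        # k values {2, 2, 3, 3} via two OR2 and two AND3: symmetric
        summary = summarize_set(filter_automata([or2, or2, and3, and3]))
        assert summary.k_stats.skewness == pytest.approx(0.0, abs=1e-12)

    def test_requires_two_rules(self, or2):
        with pytest.raises(ValueError):
            summarize_set(filter_automata([or2]))


class TestCollection:
    def test_regimes_of_contrasting_networks(self, xor2):
        near_const = rule_from_string("0001")  # AND: strongly canalizing
        chaotic_net = make_net([xor2] * 20, seed=1)
        stable_net = make_net([near_const] * 20, seed=2)
        analysis = analyze_model_collection(
            {"parity": chaotic_net, "canalized": stable_net},
            I=300, master_seed=3)
        table = analysis.table.set_index("name")
        assert table.loc["parity", "chaotic"] == 1
        assert table.loc["canalized", "chaotic"] == 0
        assert table.loc["parity", "mean_ke"] == 2.0
        # with a single network per regime the refit is skipped or fitted;
        # both labels are present here so boundaries must exist
        assert analysis.ct_boundary is not None

    def test_single_regime_skips_refit_with_notice(self, xor2):
        nets = [make_net([xor2] * 15, seed=s) for s in (4, 5)]
        analysis = analyze_model_collection(nets, I=200, master_seed=6)
        assert analysis.ct_boundary is None
        assert analysis.notes

    def test_mean_ke_never_exceeds_mean_k(self, or2, and3, xor2):
        net = make_net([or2, and3, xor2, and3, or2, or2], seed=7)
        analysis = analyze_model_collection([net], I=50, master_seed=8)
        row = analysis.table.iloc[0]
        assert row["mean_ke"] <= row["k"] + 1e-12
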