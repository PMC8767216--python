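"""Wildcard schemata, effective connectivity and sensitivity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boolcrit.canalization import (
    average_sensitivity,
    effective_connectivity,
    effective_connectivity_batch,
    network_mean_ke,
    prime_schemata,
)
from boolcrit.rules import BooleanNetwork, BooleanRule, rule_from_string

from conftest import brute_force_ke


def patterns(schemata):
    return {s.pattern for s in schemata}


class TestPrimeSchemata:
    def test_or2_worked_example(self, or2):
        on, off = prime_schemata(or2)
        assert patterns(on) == {"1#", "#1"}
        assert patterns(off) == {"00"}

    def test_constant_rule_all_wildcards(self):
        on, off = prime_schemata(rule_from_string("1111"))
        assert patterns(on) == {"##"}
        assert off == ()

    def test_and3_derived(self, and3):
        on, off = prime_schemata(and3)
        assert patterns(on) == {"111"}
        assert patterns(off) == {"0##", "#0#", "##0"}

    def test_cover_and_maximality_on_random_rules(self):
        """Every LUT row is covered by a schema of its class, and no
        schema can absorb one more wildcard (prime implicant property)."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            k = int(rng.integers(1, 5))
            rule = BooleanRule(
                k, tuple(int(b) for b in rng.integers(0, 2, size=1 << k)))
            on, off = prime_schemata(rule)
            for alpha in range(1 << k):
                side = on if rule.outputs[alpha] else off
                assert any(s.covers(alpha) for s in side)
            for schema in on + off:
                side = schema.output
                for pos in range(k):
                    if schema.pattern[pos] == "#":
                        continue
                    widened = (schema.pattern[:pos] + "#"
                               + schema.pattern[pos + 1:])
                    rows = [
                        alpha for alpha in range(1 << k)
                        if all(c == "#" or int(c) == (alpha >> (k - 1 - i)) & 1
                               for i, c in enumerate(widened))
                    ]
                    assert any(rule.outputs[a] != side for a in rows)


class TestEffectiveConnectivity:
    @pytest.mark.parametrize(
        "bits, expected",
        [
            ("0111", 1.25),  # OR2: (3 rows x 1 enput + 1 row x 2)/4
            ("0110", 2.0),  # parity has no redundancy
            ("00000001", 1.25),  # AND3: (7 x 1 + 1 x 3)/8
            ("0000", 0.0),  # constant
            ("01", 1.0),  # copy
        ],
    )
    def test_examples(self, bits, expected):
        assert effective_connectivity(rule_from_string(bits)) == expected

    def test_matches_brute_force_small_k(self):
        """Exhaustive oracle equivalence for every rule with k <= 2."""
        for k in (0, 1, 2):
            size = 1 << k
            for n in range(1 << size):
                rule = BooleanRule(
                    k, tuple((n >> i) & 1 for i in range(size)))
                assert effective_connectivity(rule) == pytest.approx(
                    brute_force_ke(rule), abs=1e-12)

    def test_matches_brute_force_random_k4_k5(self):
        rng = np.random.default_rng(17)
        for k in (4, 5):
            tables = rng.integers(0, 2, size=(40, 1 << k)).astype(np.uint8)
            fast = effective_connectivity_batch(tables, k)
            for table, ke in zip(tables, fast):
                rule = BooleanRule(k, tuple(int(b) for b in table))
                assert ke == pytest.approx(brute_force_ke(rule), abs=1e-12)

    def test_parity_attains_k(self):
        for k in (2, 3, 4, 6):
            bits = tuple(bin(a).count("1") % 2 for a in range(1 << k))
            assert effective_connectivity(BooleanRule(k, bits)) == k

    def test_bounded_by_k_with_parity_equality_only(self):
        """For k = 3, k_e = 3 exactly for the two parity rules."""
        attaining = []
        for n in range(256):
            rule = BooleanRule(3, tuple((n >> i) & 1 for i in range(8)))
            ke = effective_connectivity(rule)
            assert ke <= 3.0 + 1e-12
            if ke == 3.0:
                attaining.append(rule.outputs)
        parity = tuple(bin(a).count("1") % 2 for a in range(8))
        anti = tuple(1 - b for b in parity)
        assert sorted(attaining) == sorted([parity, anti])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.permutations([0, 1, 2, 3]),
           st.integers(0, 3))
    def test_symmetries(self, n, perm, neg_input):
        """k_e is invariant under output complementation, input
        permutation, and negation of any single input."""
        k = 4
        bits = tuple((n >> i) & 1 for i in range(16))
        rule = BooleanRule(k, bits)
        ke = effective_connectivity(rule)

        complemented = BooleanRule(k, tuple(1 - b for b in bits))
        assert effective_connectivity(complemented) == ke

        def reindex(alpha, mapping):
            out = 0
            for new_pos, old_pos in enumerate(mapping):
                bit = (alpha >> (k - 1 - old_pos)) & 1
                out |= bit << (k - 1 - new_pos)
            return out

        permuted = BooleanRule(
            k, tuple(bits[reindex(a, perm)] for a in range(16)))
        assert effective_connectivity(permuted) == ke

        flip = 1 << (k - 1 - neg_input)
        negated = BooleanRule(k, tuple(bits[a ^ flip] for a in range(16)))
        assert effective_connectivity(negated) == ke


class TestSensitivity:
    @pytest.mark.parametrize(
        "bits, expected",
        [("0001", 1.0), ("0111", 1.0), ("0110", 2.0), ("1111", 0.0),
         ("01", 1.0)],
    )
    def test_examples(self, bits, expected):
        assert average_sensitivity(rule_from_string(bits)) == expected

    def test_mean_sensitivity_of_random_rules_matches_2kpq(self):
        """E[s] over random rules at bias p is k * 2p(1-p), up to the
        exact finite-LUT factor M/(M-1) for rules with a fixed ON count
        (two distinct rows without replacement), within 3 SE."""
        from boolcrit.rules import random_rule

        rng = np.random.default_rng(23)
        k, p, reps = 4, 0.25, 400
        M = 1 << k
        vals = [average_sensitivity(random_rule(k, p, rng))
                for _ in range(reps)]
        expected = 2 * k * p * (1 - p) * M / (M - 1)
        se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - expected) < 3 * se


class TestNetworkMeanKe:
    def test_identical_rules(self, or2):
        net = BooleanNetwork(inputs=[(1, 2), (0, 2), (0, 1)], rules=[or2] * 3)
        assert network_mean_ke(net) == 1.25

    def test_mixture(self, or2, xor2):
        net = BooleanNetwork(
            inputs=[(1, 2), (0, 2), (0, 1), (1, 2)],
            rules=[or2, or2, xor2, xor2])
        assert network_mean_ke(net) == pytest.approx(1.625)

    def test_mixed_fixture_matches_per_rule_oracle(self):
        rng = np.random.default_rng(9)
        rules = [BooleanRule(
            2, tuple(int(b) for b in rng.integers(0, 2, size=4)))
            for _ in range(6)]
        inputs = [tuple(rng.choice(6, 2, replace=False)) for _ in range(6)]
        net = BooleanNetwork(inputs=inputs, rules=rules)
        expected = np.mean([brute_force_ke(r) for r in rules])
        assert network_mean_ke(net) == pytest.approx(expected, abs=1e-12)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            network_mean_ke(BooleanNetwork(inputs=[], rules=[]))
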