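"""Shared fixtures: canonical rules, small networks, and the reduced sweep.

The reduced-scale ensemble sweep (the package's main experiment) is
expensive (~2 min), so it is computed once per session and shared by the
acceptance-level tests.
"""

import itertools

import numpy as np
import pytest

from boolcrit.rules import BooleanNetwork, BooleanRule, rule_from_string


@pytest.fixture(scope="session")
def or2():
    return rule_from_string("0111")


@pytest.fixture(scope="session")
def and2():
    return rule_from_string("0001")


@pytest.fixture(scope="session")
def xor2():
    return rule_from_string("0110")


@pytest.fixture(scope="session")
def and3():
    return rule_from_string("00000001")


def brute_force_ke(rule: BooleanRule) -> float:
    """Independent k_e oracle: per LUT row, the minimal number of inputs
    whose fixation to the row's states forces the output; averaged over
    rows.  Pure subset enumeration, no schemata."""
    k, size = rule.k, 1 << rule.k
    outs = rule.outputs
    total = 0
    for alpha in range(size):
        found = None
        for n_fixed in range(k + 1):
            for subset in itertools.combinations(range(k), n_fixed):
                forced = True
                for beta in range(size):
                    if all((beta >> b) & 1 == (alpha >> b) & 1
                           for b in subset):
                        if outs[beta] != outs[alpha]:
                            forced = False
                            break
                if forced:
                    found = n_fixed
                    break
            if found is not None:
                break
        total += found
    return total / size


@pytest.fixture(scope="session")
def copy_ring8():
    """8-node directed ring of copy rules: each node copies its
    predecessor, so perturbations persist (rotate) forever."""
    copy = BooleanRule(1, (0, 1))
    inputs = [((i - 1) % 8,) for i in range(8)]
    return BooleanNetwork(inputs=inputs, rules=[copy] * 8)


@pytest.fixture(scope="session")
def reduced_sweep():
    """The reduced-scale ensemble sweep plus fitted boundaries and CV.

    Study conditions: N = 50 nodes, bias grid coarsened to step
    max(1/2**k, 1/16), 10 replicates per viable cell, 100 Derrida pairs,
    master seed 1.
    """
    from boolcrit.pipeline import PipelineConfig, fit_and_score, sweep_regimes

    config = PipelineConfig.reduced(master_seed=1)
    records, skipped = sweep_regimes(config)
    scored = fit_and_score(records, config)
    return {"config": config, "records": records, "skipped": skipped,
            **scored}
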