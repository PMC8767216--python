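"""Boolean automata, look-up tables and synchronous network dynamics.

A Boolean automaton with ``k`` inputs is represented by its look-up table
(LUT): a vector of ``2**k`` output bits indexed by the lexicographic order
of the input tuple, with the *first* listed input most significant.  Thus
row ``alpha`` of a 2-input rule corresponds to the input tuple
``(alpha >> 1 & 1, alpha & 1)``.

A Boolean network is a set of such automata wired together; the network is
advanced with the synchronous update policy (all nodes compute their next
state from the current configuration simultaneously).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BooleanRule",
    "BooleanNetwork",
    "evaluate_rule",
    "bias",
    "step_network",
    "hamming",
    "random_rule",
    "rule_from_string",
]


@dataclass(frozen=True)
class BooleanRule:
    """A ``k``-input Boolean automaton given by its full truth table.

    Parameters
    ----------
    k
        Number of inputs (``k >= 0``).
    outputs
        Sequence of ``2**k`` binary outputs, one per LUT row in
        lexicographic input order (first input most significant).
    """

    k: int
    outputs: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"rule arity must be non-negative, got k={self.k}")
        outs = tuple(int(o) for o in self.outputs)
        if any(o not in (0, 1) for o in outs):
            raise ValueError("rule outputs must be binary")
        if len(outs) != 2**self.k:
            raise ValueError(
                f"expected {2**self.k} outputs for k={self.k}, got {len(outs)}"
            )
        object.__setattr__(self, "outputs", outs)

    @property
    def table(self) -> np.ndarray:
        """LUT as a uint8 array of length ``2**k``."""
        return np.asarray(self.outputs, dtype=np.uint8)

    @property
    def n_on(self) -> int:
        return sum(self.outputs)

    def __call__(self, input_states: Sequence[int]) -> int:
        return evaluate_rule(self, input_states)

    def to_bitstring(self) -> str:
        return "".join(str(o) for o in self.outputs)


def rule_from_string(bits: str) -> BooleanRule:
    """Build a rule from a ``2**k`` bit string, e.g. ``"0111"`` for OR."""
    n = len(bits)
    k = n.bit_length() - 1
    if 2**k != n:
        raise ValueError(f"bit string length {n} is not a power of two")
    return BooleanRule(k, tuple(int(b) for b in bits))


def evaluate_rule(rule: BooleanRule, input_states: Sequence[int]) -> int:
    """Output of ``rule`` for one input tuple (first input most significant)."""
    if len(input_states) != rule.k:
        raise ValueError(
            f"rule expects {rule.k} inputs, got {len(input_states)}"
        )
    idx = 0
    for s in input_states:
        idx = (idx << 1) | int(s)
    return rule.outputs[idx]


def bias(rule: BooleanRule) -> float:
    """Fraction of LUT rows whose output is ON (the rule's bias ``p``)."""
    return rule.n_on / len(rule.outputs)


def random_rule(k: int, p: float, rng: np.random.Generator) -> BooleanRule:
    """Random ``k``-input rule with ``round(p * 2**k)`` ON rows.

    The ON rows are placed uniformly at random; biases not expressible as
    an integer count over ``2**k`` rows are rounded to the nearest
    attainable count.
    """
    if k < 0:
        raise ValueError(f"rule arity must be non-negative, got k={k}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bias must lie in [0, 1], got {p}")
    size = 2**k
    n_on = int(round(p * size))
    outputs = np.zeros(size, dtype=np.uint8)
    on_idx = rng.choice(size, size=n_on, replace=False)
    outputs[on_idx] = 1
    return BooleanRule(k, tuple(int(o) for o in outputs))


@dataclass
class BooleanNetwork:
    """Directed network of Boolean automata with synchronous dynamics.

    ``inputs[i]`` lists the (ordered) regulator indices of node ``i`` and
    ``rules[i]`` is its automaton; the rule arity must match the number of
    regulators.  Node names are optional and default to ``x1..xn``.
    """

    inputs: list[tuple[int, ...]]
    rules: list[BooleanRule]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.rules)
        if len(self.inputs) != n:
            raise ValueError("inputs and rules must have the same length")
        for i, (inp, rule) in enumerate(zip(self.inputs, self.rules)):
            if rule.k != len(inp):
                raise ValueError(
                    f"node {i}: rule arity {rule.k} != {len(inp)} inputs"
                )
            for j in inp:
                if not 0 <= j < n:
                    raise ValueError(f"node {i}: input {j} is not a node index")
        if not self.names:
            self.names = [f"x{i + 1}" for i in range(n)]
        elif len(self.names) != n:
            raise ValueError("names must match the number of nodes")
        # Dense LUT matrix for homogeneous-k fast stepping (built lazily).
        self._lut_cache: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    @property
    def n(self) -> int:
        return len(self.rules)

    def _fast_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(inputs matrix, padded LUT matrix, bit weights) for vector stepping.

        Only valid when every node has the same in-degree; callers check.
        """
        if self._lut_cache is None:
            k = self.rules[0].k
            inp = np.asarray(self.inputs, dtype=np.intp)
            luts = np.stack([r.table for r in self.rules])
            weights = 1 << np.arange(k - 1, -1, -1)
            self._lut_cache = (inp, luts, weights)
        return self._lut_cache

    def is_homogeneous(self) -> bool:
        k0 = self.rules[0].k
        return all(r.k == k0 for r in self.rules)

    def step(self, config: np.ndarray) -> np.ndarray:
        return step_network(self, config)

    def step_batch(self, configs: np.ndarray) -> np.ndarray:
        """Synchronously advance a ``(batch, n)`` block of configurations."""
        configs = np.asarray(configs, dtype=np.uint8)
        if configs.shape[-1] != self.n:
            raise ValueError("configuration length must equal network size")
        if self.is_homogeneous():
            inp, luts, weights = self._fast_tables()
            idx = configs[..., inp].astype(np.intp) @ weights
            return luts[np.arange(self.n), idx].astype(np.uint8)
        out = np.empty_like(configs)
        for i, (inp_i, rule) in enumerate(zip(self.inputs, self.rules)):
            idx = np.zeros(configs.shape[:-1], dtype=np.intp)
            for j in inp_i:
                idx = (idx << 1) | configs[..., j]
            out[..., i] = rule.table[idx]
        return out


def step_network(net: BooleanNetwork, config: np.ndarray) -> np.ndarray:
    """One synchronous update of every node; returns the next configuration."""
    config = np.asarray(config, dtype=np.uint8)
    if config.ndim != 1 or config.shape[0] != net.n:
        raise ValueError("configuration length must equal network size")
    return net.step_batch(config[None, :])[0]


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of differing positions between two equal-length configurations."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("configurations must have equal length")
    return int(np.count_nonzero(a != b))
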