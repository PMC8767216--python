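"""Canalization measures of Boolean automata.

A transition rule is *canalizing* when a subset of its inputs suffices to
settle the output, rendering the remaining inputs redundant for that
transition.  We quantify this by redescribing the look-up table as
*wildcard schemata* — patterns over ``{0, 1, #}`` where ``#`` marks a
redundant input state — and by the *effective connectivity* ``k_e``: the
mean, over LUT rows, of the minimal number of inputs (*enputs*) needed to
guarantee that row's transition.

``k_e <= k`` always, with equality exactly for parity functions (and for
non-constant rules of ``k <= 1``); constant rules have ``k_e = 0``.  The
*average sensitivity* ``s`` — the summed probability that flipping a
single input flips the output — is provided for comparison; unlike
``k_e`` it aggregates inputs independently and misses collective
canalization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .rules import BooleanNetwork, BooleanRule

__all__ = [
    "WildcardSchema",
    "CanalizationSummary",
    "prime_schemata",
    "effective_connectivity",
    "effective_connectivity_batch",
    "average_sensitivity",
    "network_mean_ke",
]


@dataclass(frozen=True)
class WildcardSchema:
    """A maximal wildcard pattern guaranteeing one output class.

    ``pattern`` is a length-``k`` string over ``{0, 1, #}``; position ``i``
    refers to the rule's ``i``-th input.  Every LUT row matching the
    pattern (``#`` matching either state) transitions to ``output``.
    """

    pattern: str
    output: int

    @property
    def k(self) -> int:
        return len(self.pattern)

    @property
    def n_wildcards(self) -> int:
        return self.pattern.count("#")

    @property
    def n_enputs(self) -> int:
        """Number of fixed (effective) input positions."""
        return self.k - self.n_wildcards

    def covers(self, row: int) -> bool:
        """Whether LUT row index ``row`` matches this pattern."""
        for i, ch in enumerate(self.pattern):
            if ch == "#":
                continue
            bit = (row >> (self.k - 1 - i)) & 1
            if bit != int(ch):
                return False
        return True

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"({self.pattern})->{self.output}"


def _merge_round(terms: set[tuple[int, int]], k: int):
    """One Quine-McCluskey merging pass over ``(value, wildcard-mask)`` terms."""
    merged: set[tuple[int, int]] = set()
    used: set[tuple[int, int]] = set()
    terms_list = sorted(terms)
    index = {}
    for t in terms_list:
        index.setdefault(t[1], []).append(t)
    for wc, group in index.items():
        group_set = set(v for v, _ in group)
        for v, _ in group:
            for b in range(k):
                bit = 1 << b
                if wc & bit:
                    continue
                partner = v ^ bit
                if v < partner and partner in group_set:
                    merged.add((v & ~bit, wc | bit))
                    used.add((v, wc))
                    used.add((partner, wc))
    primes = {t for t in terms if t not in used}
    return merged, primes


def _prime_terms(minterms: set[int], k: int) -> set[tuple[int, int]]:
    """All prime implicants of the set of minterms, as (value, wc-mask)."""
    current = {(m, 0) for m in minterms}
    primes: set[tuple[int, int]] = set()
    while current:
        current, finished = _merge_round(current, k)
        primes |= finished
    return primes


def _term_to_pattern(value: int, wc_mask: int, k: int) -> str:
    chars = []
    for i in range(k):
        bit = 1 << (k - 1 - i)  # first input is the most significant bit
        if wc_mask & bit:
            chars.append("#")
        else:
            chars.append("1" if value & bit else "0")
    return "".join(chars)


def prime_schemata(
    rule: BooleanRule,
) -> tuple[tuple[WildcardSchema, ...], tuple[WildcardSchema, ...]]:
    """Maximal wildcard schemata of the ON and OFF transitions of ``rule``.

    Returns ``(on_schemata, off_schemata)``: the prime implicants of the
    rule and of its complement.  Every LUT row is covered by at least one
    schema of its own output class.  A constant rule yields a single
    all-wildcard schema on one side and an empty set on the other.
    """
    k = rule.k
    table = rule.table
    on_set = {int(i) for i in np.flatnonzero(table == 1)}
    off_set = {int(i) for i in np.flatnonzero(table == 0)}
    on = tuple(
        sorted(
            (WildcardSchema(_term_to_pattern(v, wc, k), 1)
             for v, wc in _prime_terms(on_set, k)),
            key=lambda s: s.pattern,
        )
    ) if on_set else ()
    off = tuple(
        sorted(
            (WildcardSchema(_term_to_pattern(v, wc, k), 0)
             for v, wc in _prime_terms(off_set, k)),
            key=lambda s: s.pattern,
        )
    ) if off_set else ()
    return on, off


# delta-swap masks: bits whose LUT index has a 0 at distance-d position
_DELTA_MASKS = {
    1: 0x5555555555555555,
    2: 0x3333333333333333,
    4: 0x0F0F0F0F0F0F0F0F,
    8: 0x00FF00FF00FF00FF,
    16: 0x0000FFFF0000FFFF,
    32: 0x00000000FFFFFFFF,
}


def _pack(tables: np.ndarray, k: int) -> np.ndarray:
    """Pack ``(n_rules, 2**k)`` binary LUTs into uint64 words, bit per row."""
    n_rules = tables.shape[0]
    size = 1 << k
    if size <= 64:
        shifts = np.arange(size, dtype=np.uint64)
        words = np.bitwise_or.reduce(tables.astype(np.uint64) << shifts, axis=1)
        return words[:, None]
    n_words = size // 64
    shifts = np.arange(64, dtype=np.uint64)
    resh = tables.reshape(n_rules, n_words, 64).astype(np.uint64)
    return np.bitwise_or.reduce(resh << shifts, axis=2)


def _flip_input(x: np.ndarray, j: int) -> np.ndarray:
    """Permute packed LUT bits by flipping input-index bit ``j`` (alpha ^= 2^j)."""
    d = 1 << j
    if d < 64:
        m = np.uint64(_DELTA_MASKS[d])
        sh = np.uint64(d)
        return ((x & m) << sh) | ((x >> sh) & m)
    s = d // 64
    n_rules, n_words = x.shape
    return (x.reshape(n_rules, n_words // (2 * s), 2, s)[:, :, ::-1, :]
            .reshape(n_rules, n_words))


def effective_connectivity_batch(tables: np.ndarray, k: int) -> np.ndarray:
    """``k_e`` for a block of rules given as a ``(n_rules, 2**k)`` LUT array.

    Dynamic programme over input subsets on bit-packed LUTs: the rule is
    constant on the subcube spanned by ``W + {j}`` through row ``alpha``
    iff it is constant on both ``W``-halves and they agree.  Summing, per
    subset cardinality ``c``, the rows covered by *some* constant
    ``c``-subcube gives ``sum_alpha max_wildcards(alpha)`` without
    materialising per-row maxima.
    """
    tables = np.asarray(tables, dtype=np.uint8)
    if tables.ndim != 2 or tables.shape[1] != 1 << k:
        raise ValueError(f"expected shape (n_rules, {1 << k})")
    size = 1 << k
    packed = _pack(tables, k)
    valid = (np.uint64(0xFFFFFFFFFFFFFFFF) if size >= 64
             else np.uint64((1 << size) - 1))
    # eq[j]: rows whose output agrees with the row at flipped input j
    eq = [(~(packed ^ _flip_input(packed, j))) & valid for j in range(k)]
    prev_level = {0: np.full_like(packed, valid)}
    total_wild = np.zeros(packed.shape[0], dtype=np.float64)
    for card in range(1, k + 1):
        level: dict[int, np.ndarray] = {}
        union = np.zeros_like(packed)
        for positions in itertools.combinations(range(k), card):
            mask = 0
            for b in positions:
                mask |= 1 << b
            j = positions[0]
            base = prev_level[mask ^ (1 << j)]
            const = base & _flip_input(base, j) & eq[j]
            level[mask] = const
            union |= const
        total_wild += np.bitwise_count(union).sum(axis=1)
        prev_level = level
    return k - total_wild / size


def effective_connectivity(rule: BooleanRule) -> float:
    """Expected number of effective inputs (enputs) of ``rule``.

    For each LUT row, take the schema covering it with the most wildcard
    symbols; the row contributes ``k`` minus that wildcard count.  ``k_e``
    is the average contribution over all ``2**k`` rows.
    """
    if rule.k == 0:
        return 0.0
    return float(effective_connectivity_batch(rule.table[None, :], rule.k)[0])


def average_sensitivity(rule: BooleanRule) -> float:
    """Summed per-input activity: ``sum_j Pr[f(x) != f(x ^ e_j)]``."""
    k = rule.k
    if k == 0:
        return 0.0
    table = rule.table
    size = 1 << k
    s = 0.0
    for j in range(k):
        flip = np.arange(size) ^ (1 << j)
        s += float(np.count_nonzero(table != table[flip])) / size
    return s


def network_mean_ke(net: BooleanNetwork) -> float:
    """Mean effective connectivity over the nodes of a network."""
    if net.n == 0:
        raise ValueError("network has no nodes")
    return float(np.mean([effective_connectivity(r) for r in net.rules]))


@dataclass(frozen=True)
class CanalizationSummary:
    """Per-rule canalization profile: arity, ``k_e`` and sensitivity."""

    k: int
    k_e: float
    sensitivity: float

    @classmethod
    def from_rule(cls, rule: BooleanRule) -> "CanalizationSummary":
        return cls(
            k=rule.k,
            k_e=effective_connectivity(rule),
            sensitivity=average_sensitivity(rule),
        )
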