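"""Catalogues of Boolean rules indexed by (k, bias, k_e bin).

Ensemble networks draw their automata from catalogues so that effective
connectivity can be controlled as a tuning parameter.  ``k_e`` values are
binned with half-width ``EPSILON = 0.25`` into bins centred on multiples
of 0.5 (half-open intervals ``[c - 0.25, c + 0.25)``).

For small arities (``k <= 4``) — or whenever the number of rules with the
requested ON count fits under ``cap`` — the catalogue enumerates every
output vector exhaustively.  Otherwise it holds ``cap`` distinct rules
sampled uniformly.  Bins that random generation essentially never reaches
(e.g. very low ``k_e`` at large ``k``) are filled by a genetic algorithm
that searches output vectors at fixed ON count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .canalization import effective_connectivity_batch
from .rules import BooleanRule

__all__ = [
    "EPSILON",
    "BIN_WIDTH",
    "CatalogueEntry",
    "Catalogue",
    "EmptyCatalogueError",
    "ke_bin_centre",
    "build_catalogue",
    "ga_fill_bins",
    "build_catalogue_with_ga",
]

EPSILON = 0.25
BIN_WIDTH = 0.5
DEFAULT_CAP = 10_000


class EmptyCatalogueError(ValueError):
    """No rule exists (or was found) for the requested parameters."""


def ke_bin_centre(k_e: float) -> float:
    """Centre (multiple of 0.5) of the half-open bin ``[c-0.25, c+0.25)``."""
    return math.floor(k_e / BIN_WIDTH + 0.5) * BIN_WIDTH


@dataclass(frozen=True)
class CatalogueEntry:
    """One catalogued rule with its attained bias, exact ``k_e`` and bin."""

    rule: BooleanRule
    k: int
    p: float
    k_e: float
    bin_centre: float


@dataclass
class Catalogue:
    """All catalogued rules for one ``(k, p)`` cell, grouped by k_e bin."""

    k: int
    p: float
    entries: list[CatalogueEntry]
    exhaustive: bool
    unreachable_bins: list[float] = field(default_factory=list)

    def by_bin(self) -> dict[float, list[CatalogueEntry]]:
        """Entries grouped by their primary (nearest-centre) bin."""
        groups: dict[float, list[CatalogueEntry]] = {}
        for e in self.entries:
            groups.setdefault(e.bin_centre, []).append(e)
        return groups

    def bin_entries(self, centre: float) -> list[CatalogueEntry]:
        """Entries eligible for a bin: ``|k_e - centre| <= EPSILON``.

        Membership is the closed interval ``centre +/- EPSILON``, so a
        rule whose ``k_e`` falls exactly on a bin edge (common, since
        ``k_e`` is a multiple of ``1/2**k``) is eligible for both
        adjacent bins.
        """
        return [e for e in self.entries
                if abs(e.k_e - centre) <= EPSILON + 1e-9]

    def __len__(self) -> int:
        return len(self.entries)


def _entries_from_tables(tables: np.ndarray, k: int, p: float) -> list[CatalogueEntry]:
    kes = effective_connectivity_batch(tables, k)
    out = []
    for row, ke in zip(tables, kes):
        rule = BooleanRule(k, tuple(int(b) for b in row))
        out.append(
            CatalogueEntry(rule=rule, k=k, p=p, k_e=float(ke),
                           bin_centre=ke_bin_centre(float(ke)))
        )
    return out


def build_catalogue(
    k: int,
    p: float,
    cap: int = DEFAULT_CAP,
    rng: np.random.Generator | None = None,
) -> Catalogue:
    """Catalogue of ``k``-input rules with ON count ``round(p * 2**k)``.

    Exhaustive when ``k <= 4`` or when ``C(2**k, n_on) <= cap``; otherwise
    ``cap`` distinct rules are rejection-sampled uniformly (duplicates
    discarded), which requires ``rng``.
    """
    if k < 1:
        raise ValueError(f"catalogue arity must be >= 1, got k={k}")
    size = 1 << k
    n_on = int(round(p * size))
    if not 0 <= n_on <= size:
        raise EmptyCatalogueError(f"no k={k} rule with bias {p}")
    attained_p = n_on / size
    total = math.comb(size, n_on)
    if k <= 4 or total <= cap:
        tables = np.zeros((total, size), dtype=np.uint8)
        for i, ones in enumerate(itertools.combinations(range(size), n_on)):
            tables[i, list(ones)] = 1
        return Catalogue(k, attained_p, _entries_from_tables(tables, k, attained_p),
                         exhaustive=True)
    if rng is None:
        raise ValueError("sampled catalogues need an rng")
    seen: set[bytes] = set()
    rows: list[np.ndarray] = []
    while len(rows) < cap:
        tab = np.zeros(size, dtype=np.uint8)
        tab[rng.choice(size, size=n_on, replace=False)] = 1
        key = tab.tobytes()
        if key in seen:
            continue
        seen.add(key)
        rows.append(tab)
    tables = np.stack(rows)
    return Catalogue(k, attained_p, _entries_from_tables(tables, k, attained_p),
                     exhaustive=False)


@dataclass(frozen=True)
class GAParams:
    """Search settings for bin filling at fixed (k, ON count)."""

    population: int = 100
    generations: int = 2000
    tournament: int = 3
    per_bin: int = 20  # rules to collect per target bin
    seeded_fraction: float = 0.5  # share of canalizing seeds in generation 0
    patience: int = 250  # stop after this many stagnant generations


def _canalizing_seed(k: int, n_on: int, target: float,
                     rng: np.random.Generator) -> np.ndarray:
    """A table whose output depends on ~``round(target)`` random inputs.

    The subfunction's ON count is chosen to approximate ``n_on``; the
    table is then repaired to the exact ON count by random flips.  Such
    seeds put the population near the low-``k_e`` needle that uniform
    tables (whose ``k_e`` concentrates well above it) essentially never
    reach.
    """
    size = 1 << k
    r = int(np.clip(round(target) + rng.integers(-1, 2), 1, k))
    subset = rng.choice(k, size=r, replace=False)
    sub_size = 1 << r
    block = size // sub_size
    sub_on = int(np.clip(round(n_on / block), 0, sub_size))
    sub_table = np.zeros(sub_size, dtype=np.uint8)
    if sub_on:
        sub_table[rng.choice(sub_size, size=sub_on, replace=False)] = 1
    alphas = np.arange(size)
    sub_idx = np.zeros(size, dtype=np.intp)
    for pos, b in enumerate(sorted(subset, reverse=True)):
        sub_idx |= ((alphas >> b) & 1) << pos
    table = sub_table[sub_idx].copy()
    # repair to the exact ON count
    diff = int(table.sum()) - n_on
    if diff > 0:
        on_idx = np.flatnonzero(table == 1)
        table[rng.choice(on_idx, size=diff, replace=False)] = 0
    elif diff < 0:
        off_idx = np.flatnonzero(table == 0)
        table[rng.choice(off_idx, size=-diff, replace=False)] = 1
    return table


def _ga_search_bin(
    k: int,
    n_on: int,
    target: float,
    params: GAParams,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Evolve output vectors with ``n_on`` ON rows towards ``k_e ~ target``.

    Generation 0 mixes uniform tables with canalizing seeds; mutation
    swaps one ON and one OFF row, preserving the bias exactly; no
    crossover (it would break the ON-count constraint).  Returns all
    distinct tables found with ``|k_e - target| <= EPSILON``, up to
    ``params.per_bin``.
    """
    size = 1 << k
    pop = np.zeros((params.population, size), dtype=np.uint8)
    n_seeded = int(round(params.population * params.seeded_fraction))
    for i in range(params.population):
        if i < n_seeded:
            pop[i] = _canalizing_seed(k, n_on, target, rng)
        else:
            pop[i, rng.choice(size, size=n_on, replace=False)] = 1
    hits: dict[bytes, np.ndarray] = {}

    def fitness(tables: np.ndarray) -> np.ndarray:
        kes = effective_connectivity_batch(tables, k)
        for tab, ke in zip(tables, kes):
            if abs(ke - target) <= EPSILON and len(hits) < params.per_bin:
                hits.setdefault(tab.tobytes(), tab.copy())
        return -np.abs(kes - target)

    fit = fitness(pop)
    best_fit = float(fit.max())
    stagnant = 0
    for _ in range(params.generations):
        if len(hits) >= params.per_bin or stagnant >= params.patience:
            break
        # tournament selection of parents
        contenders = rng.integers(0, params.population,
                                  size=(params.population, params.tournament))
        winners = contenders[np.arange(params.population),
                             np.argmax(fit[contenders], axis=1)]
        children = pop[winners].copy()
        # bias-preserving swap mutation on every child
        for child in children:
            on_idx = np.flatnonzero(child == 1)
            off_idx = np.flatnonzero(child == 0)
            if len(on_idx) == 0 or len(off_idx) == 0:
                continue
            child[on_idx[rng.integers(len(on_idx))]] = 0
            child[off_idx[rng.integers(len(off_idx))]] = 1
        n_hits_before = len(hits)
        child_fit = fitness(children)
        # elitist replacement: keep the better of parent/child slots
        replace = child_fit > fit
        pop[replace] = children[replace]
        fit[replace] = child_fit[replace]
        new_best = float(fit.max())
        if new_best > best_fit or len(hits) > n_hits_before:
            best_fit = new_best
            stagnant = 0
        else:
            stagnant += 1
    return list(hits.values())


def ga_fill_bins(
    k: int,
    p: float,
    target_bins: list[float],
    ga_params: GAParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[CatalogueEntry], list[float]]:
    """Search rules for the requested k_e bins at exact bias ``p``.

    Returns ``(entries, unreachable)`` where ``unreachable`` lists bins
    for which the generation budget produced no rule.  Bins outside
    ``[1 - EPSILON, k + EPSILON]`` are rejected outright.
    """
    if rng is None:
        rng = np.random.default_rng()
    params = ga_params or GAParams()
    size = 1 << k
    n_on = int(round(p * size))
    attained_p = n_on / size
    entries: list[CatalogueEntry] = []
    unreachable: list[float] = []
    for centre in target_bins:
        if not (1 - EPSILON <= centre <= k + EPSILON):
            raise ValueError(f"target bin {centre} outside [1-eps, k+eps]")
        tables = _ga_search_bin(k, n_on, centre, params, rng)
        found = [
            e for e in _entries_from_tables(
                np.stack(tables) if tables else np.zeros((0, size), np.uint8),
                k, attained_p)
            if abs(e.k_e - centre) <= EPSILON + 1e-9
        ] if tables else []
        if found:
            entries.extend(found)
        else:
            unreachable.append(centre)
    return entries, unreachable


def build_catalogue_with_ga(
    k: int,
    p: float,
    target_bins: list[float],
    cap: int = DEFAULT_CAP,
    ga_params: GAParams | None = None,
    rng: np.random.Generator | None = None,
) -> Catalogue:
    """Catalogue covering ``target_bins``: random/exhaustive build, then GA.

    Bins among ``target_bins`` still empty after random generation are
    handed to the genetic algorithm; bins it cannot fill are recorded in
    ``unreachable_bins`` rather than fabricated.
    """
    if rng is None:
        rng = np.random.default_rng()
    cat = build_catalogue(k, p, cap=cap, rng=rng)
    if cat.exhaustive:
        cat.unreachable_bins = [c for c in target_bins
                                if not cat.bin_entries(c)]
        return cat
    missing = [c for c in target_bins if not cat.bin_entries(c)]
    if missing:
        extra, unreachable = ga_fill_bins(k, p, missing, ga_params, rng)
        existing = {e.rule.to_bitstring() for e in cat.entries}
        cat.entries.extend(
            e for e in extra if e.rule.to_bitstring() not in existing
        )
        cat.unreachable_bins = unreachable
    return cat
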