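"""Random Boolean network ensembles homogeneous in (k, p, k_e bin).

Each ensemble cell is a parameter combination ``(k, p, <k_e> bin)``.  A
network in a cell has ``N`` nodes, each wired to ``k`` distinct random
inputs and carrying a rule drawn uniformly from the catalogue entries of
that cell's bin, so every node shares the arity and bias exactly and its
``k_e`` lies within the bin (half-width 0.25).

Cells for which no rule exists (e.g. high ``k_e`` at strong bias) are
*non-viable* and reported as skipped rather than fabricated.  All
randomness is driven hierarchically from a master seed so any single
network can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .catalogue import (
    Catalogue,
    GAParams,
    build_catalogue_with_ga,
)
from .rules import BooleanNetwork

__all__ = [
    "EnsembleSpec",
    "CellParams",
    "GeneratedNetwork",
    "generate_rbn",
    "generate_ensemble",
    "build_catalogues",
    "cell_rng",
]

# stage tags for hierarchical seeding
_STAGE_CATALOGUE = 1
_STAGE_NETWORK = 2
_STAGE_DERRIDA = 3


@dataclass(frozen=True)
class CellParams:
    """One ensemble cell: arity, attained bias and k_e bin centre."""

    k: int
    p: float
    bin_centre: float

    @property
    def n_on(self) -> int:
        return int(round(self.p * (1 << self.k)))


@dataclass(frozen=True)
class GeneratedNetwork:
    """A generated network annotated with its cell, replicate and seed."""

    cell: CellParams
    replicate: int
    network: BooleanNetwork
    mean_ke: float


@dataclass
class EnsembleSpec:
    """Grid definition for the ensemble sweep.

    Defaults mirror the study conditions: ``N = 100`` nodes, arities
    ``{2, 3, 4, 6, 8}``, biases on the attainable grid ``i / 2**k``
    restricted to ``[0.01, 0.5]``, k_e bin centres ``1.0, 1.5, ..., k``.
    ``p_step_floor`` coarsens the bias grid to multiples of that value
    (used for reduced-scale sweeps); it must itself be attainable for
    every ``k`` in the grid.
    """

    N: int = 100
    k_values: tuple[int, ...] = (2, 3, 4, 6, 8)
    p_min: float = 0.01
    p_max: float = 0.5
    p_step_floor: float | None = None
    replicates: int = 10
    cap: int = 10_000
    master_seed: int = 0
    ga_params: GAParams = field(default_factory=GAParams)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.p_max <= 0.5:
            raise ValueError("p_max must lie in (0, 0.5]")

    def p_grid(self, k: int) -> list[float]:
        """Attainable biases for arity ``k`` within ``[p_min, p_max]``.

        Multiples of ``max(1/2**k, p_step_floor)``; tautologies and
        contradictions (p = 0 or 1) never appear since the grid stops at
        ``p_max <= 0.5``.
        """
        step = 1.0 / (1 << k)
        if self.p_step_floor is not None:
            step = max(step, self.p_step_floor)
        n_steps = int(math.floor(self.p_max / step + 1e-9))
        grid = [step * i for i in range(1, n_steps + 1)]
        return [p for p in grid if p >= self.p_min]

    def ke_bins(self, k: int) -> list[float]:
        """Bin centres ``1.0, 1.5, ..., k``."""
        return [1.0 + 0.5 * i for i in range(int(round((k - 1) / 0.5)) + 1)]

    def cells(self) -> Iterator[CellParams]:
        for k in self.k_values:
            for p in self.p_grid(k):
                for c in self.ke_bins(k):
                    yield CellParams(k=k, p=p, bin_centre=c)


def _rng_for(master_seed: int, stage: int, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence((master_seed, stage) + key)
    return np.random.default_rng(ss)


def cell_rng(spec_or_seed, stage: str, cell: CellParams,
             replicate: int = 0) -> np.random.Generator:
    """Reproducible per-(cell, replicate) generator for a pipeline stage."""
    master = (spec_or_seed.master_seed
              if isinstance(spec_or_seed, EnsembleSpec) else int(spec_or_seed))
    tags = {"catalogue": _STAGE_CATALOGUE, "network": _STAGE_NETWORK,
            "derrida": _STAGE_DERRIDA}
    return _rng_for(master, tags[stage], cell.k, cell.n_on,
                    int(round(cell.bin_centre * 2)), replicate)


def _draw_network(
    N: int,
    k: int,
    bin_centre: float,
    catalogue: Catalogue,
    rng: np.random.Generator,
) -> tuple[BooleanNetwork, np.ndarray]:
    entries = catalogue.bin_entries(bin_centre)
    if not entries:
        raise ValueError(
            f"catalogue has no entries in bin {bin_centre} for "
            f"(k={k}, p={catalogue.p})"
        )
    inputs = [tuple(int(j) for j in rng.choice(N, size=k, replace=False))
              for _ in range(N)]
    picks = rng.integers(0, len(entries), size=N)
    rules = [entries[int(i)].rule for i in picks]
    kes = np.array([entries[int(i)].k_e for i in picks])
    return BooleanNetwork(inputs=inputs, rules=rules), kes


def generate_rbn(
    N: int,
    k: int,
    p: float,
    bin_centre: float,
    catalogue: Catalogue,
    rng: np.random.Generator,
) -> BooleanNetwork:
    """One random network of ``N`` nodes drawn from a catalogue bin.

    Each node receives ``k`` distinct random inputs (self-input allowed)
    and a rule drawn uniformly from the bin's catalogue entries.
    """
    net, _ = _draw_network(N, k, bin_centre, catalogue, rng)
    return net


def build_catalogues(spec: EnsembleSpec,
                     progress: bool = False) -> dict[tuple[int, int], Catalogue]:
    """Catalogues for every ``(k, p)`` in the grid, GA-filling sparse bins."""
    catalogues: dict[tuple[int, int], Catalogue] = {}
    for k in spec.k_values:
        for p in spec.p_grid(k):
            n_on = int(round(p * (1 << k)))
            rng = _rng_for(spec.master_seed, _STAGE_CATALOGUE, k, n_on)
            cat = build_catalogue_with_ga(
                k, p, target_bins=spec.ke_bins(k), cap=spec.cap,
                ga_params=spec.ga_params, rng=rng,
            )
            catalogues[(k, n_on)] = cat
            if progress:  # pragma: no cover - logging only
                print(f"catalogue k={k} p={p:.4f}: {len(cat)} rules, "
                      f"bins={sorted(cat.by_bin())}")
    return catalogues


def generate_ensemble(
    spec: EnsembleSpec,
    catalogues: dict[tuple[int, int], Catalogue] | None = None,
) -> Iterator[GeneratedNetwork]:
    """Yield every network of the sweep (lazily; cells with an empty bin
    are skipped silently — use :meth:`EnsembleSpec.cells` plus the
    catalogues to enumerate skipped cells explicitly)."""
    if catalogues is None:
        catalogues = build_catalogues(spec)
    for cell in spec.cells():
        cat = catalogues[(cell.k, cell.n_on)]
        if not cat.bin_entries(cell.bin_centre):
            continue
        for rep in range(spec.replicates):
            rng = cell_rng(spec, "network", cell, rep)
            net, kes = _draw_network(spec.N, cell.k, cell.bin_centre, cat, rng)
            yield GeneratedNetwork(cell=cell, replicate=rep, network=net,
                                   mean_ke=float(kes.mean()))
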