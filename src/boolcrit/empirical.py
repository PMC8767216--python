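"""Canalization statistics for user-supplied Boolean network models.

Curated systems-biology models (e.g. logical models of signalling and
regulation) are typically heterogeneous in in-degree.  This module
summarizes the distributions of structural connectivity ``k`` and
effective connectivity ``k_e`` over a set of automata after the standard
filtering (drop constant rules, then single-input rules, for which
``k_e = k = 1`` trivially), and analyses a collection of networks:
per-network mean features, Derrida regime, and refitted class-2
criticality boundaries in both the structural and the effective space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .canalization import effective_connectivity
from .derrida import measure_derrida
from .models import FittedBoundary, fit_model
from .rules import BooleanNetwork, BooleanRule, bias

__all__ = [
    "FilterResult",
    "AutomataSetSummary",
    "CollectionAnalysis",
    "filter_automata",
    "summarize_set",
    "analyze_model_collection",
]


@dataclass(frozen=True)
class FilterResult:
    """Rules retained for canalization analysis plus removal counts."""

    retained: tuple[BooleanRule, ...]
    n_total: int
    n_constant: int
    n_single_input: int

    @property
    def empty(self) -> bool:
        return not self.retained


def filter_automata(rules) -> FilterResult:
    """Drop tautologies/contradictions, then rules with a single input."""
    rules = list(rules)
    non_constant = [r for r in rules if 0 < r.n_on < len(r.outputs)]
    n_constant = len(rules) - len(non_constant)
    retained = [r for r in non_constant if r.k > 1]
    n_single = len(non_constant) - len(retained)
    return FilterResult(
        retained=tuple(retained),
        n_total=len(rules),
        n_constant=n_constant,
        n_single_input=n_single,
    )


def _hinge_quartiles(values: np.ndarray) -> tuple[float, float]:
    """(Q1, Q3) by the median-of-halves rule (odd n: median excluded)."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    half = n // 2
    lower = v[:half]
    upper = v[half + (n % 2):]
    return float(np.median(lower)), float(np.median(upper))


@dataclass(frozen=True)
class DistributionStats:
    """Moments and order statistics of one sample."""

    mean: float
    median: float
    q1: float
    q3: float
    skewness: float  # Pearson's moment coefficient m3 / m2^(3/2)
    excess_kurtosis: float  # normal = 0

    @property
    def iqr(self) -> tuple[float, float]:
        """(Q3, Q1) pair, reported upper endpoint first."""
        return (self.q3, self.q1)


def _dist_stats(values) -> DistributionStats:
    v = np.asarray(values, float)
    q1, q3 = _hinge_quartiles(v)
    if np.ptp(v) == 0.0:
        # moment coefficients are undefined for a degenerate sample
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, fisher=True, bias=True))
    return DistributionStats(
        mean=float(v.mean()),
        median=float(np.median(v)),
        q1=q1,
        q3=q3,
        skewness=skew,
        excess_kurtosis=kurt,
    )


@dataclass(frozen=True)
class AutomataSetSummary:
    """Distribution statistics of k and k_e over a retained automata set."""

    n_total: int
    n_constant: int
    n_single_input: int
    n_retained: int
    k_stats: DistributionStats
    ke_stats: DistributionStats


def summarize_set(filtered: FilterResult) -> AutomataSetSummary:
    """Summary statistics of the retained set (needs at least 2 rules)."""
    if len(filtered.retained) < 2:
        raise ValueError("need at least 2 retained automata to summarize")
    ks = [r.k for r in filtered.retained]
    kes = [effective_connectivity(r) for r in filtered.retained]
    return AutomataSetSummary(
        n_total=filtered.n_total,
        n_constant=filtered.n_constant,
        n_single_input=filtered.n_single_input,
        n_retained=len(filtered.retained),
        k_stats=_dist_stats(ks),
        ke_stats=_dist_stats(kes),
    )


@dataclass
class CollectionAnalysis:
    """Per-network feature table and refitted class-2 boundaries."""

    table: pd.DataFrame
    st_boundary: FittedBoundary | None = None
    ct_boundary: FittedBoundary | None = None
    notes: list[str] = field(default_factory=list)


def analyze_model_collection(
    networks: dict[str, BooleanNetwork] | list[BooleanNetwork],
    I: int = 250,
    t: int = 1,
    master_seed: int = 0,
) -> CollectionAnalysis:
    """Features, Derrida regime and refitted boundaries for a collection.

    Each network contributes one row with node-mean ``k``, ``p`` and
    ``k_e`` plus its Derrida parameter and regime label.  If both regime
    labels are present, class-2 boundaries are refitted on the rows: the
    structural instance on ``<k> p(1-p)`` and the canalization instance
    on ``<k_e> p(1-p)`` (means over nodes, heterogeneity and all).
    Otherwise the refits are skipped with a notice.
    """
    if not isinstance(networks, dict):
        networks = {f"network_{i + 1}": net for i, net in enumerate(networks)}
    rows = []
    for idx, (name, net) in enumerate(networks.items()):
        rng = np.random.default_rng(
            np.random.SeedSequence((master_seed, 4, idx)))
        res = measure_derrida(net, I=I, t=t, rng=rng)
        rows.append({
            "name": name,
            "n": net.n,
            "k": float(np.mean([r.k for r in net.rules])),
            "p": float(np.mean([bias(r) for r in net.rules])),
            "mean_ke": float(np.mean(
                [effective_connectivity(r) for r in net.rules])),
            "zeta": res.zeta,
            "chaotic": int(res.chaotic),
        })
    table = pd.DataFrame(rows)
    analysis = CollectionAnalysis(table=table)
    if table["chaotic"].nunique() < 2:
        analysis.notes.append(
            "single regime label in collection; class-2 refits skipped")
        return analysis
    analysis.st_boundary = fit_model(table, class_id=2, kappa="k")
    analysis.ct_boundary = fit_model(table, class_id=2, kappa="ke")
    return analysis
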