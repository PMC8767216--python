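"""Canalization statistics for user-supplied Boolean network models.

Writes two small logical-expression model files (synthetic stand-ins for
curated signalling/regulation models), then runs the empirical analysis:
automata filtering, k / k_e distribution statistics, per-network Derrida
regimes and, when both regimes occur, refitted class-2 boundaries.
"""

import tempfile
from pathlib import Path

from boolcrit import read_network
from boolcrit.empirical import (
    analyze_model_collection,
    filter_automata,
    summarize_set,
)

# synthetic toy models: a canalizing cascade and a parity-heavy circuit
MODELS = {
    "cascade.bnet": """\
targets, factors
Signal, Signal
A, Signal
B, A & !C
C, A | B
D, B & C & !A
E, C | (D & B)
""",
    "parity.bnet": """\
targets, factors
X1, X2 & !X3 | !X2 & X3
X2, X1 & !X3 | !X1 & X3
X3, X1 & !X2 | !X1 & X2
X4, X1 & !X4 | !X1 & X4
""",
}

with tempfile.TemporaryDirectory() as tmp:
    paths = []
    for name, text in MODELS.items():
        path = Path(tmp) / name
        path.write_text(text)
        paths.append(path)
    networks = {p.stem: read_network(p) for p in paths}

    all_rules = [r for net in networks.values() for r in net.rules]
    filtered = filter_automata(all_rules)
    summary = summarize_set(filtered)
    print(f"{summary.n_total} automata: {summary.n_constant} constant and "
          f"{summary.n_single_input} single-input removed, "
          f"{summary.n_retained} retained")
    print(f"k  : mean={summary.k_stats.mean:.2f} "
          f"median={summary.k_stats.median:.2f} "
          f"IQR={summary.k_stats.q3:.2f}-{summary.k_stats.q1:.2f}")
    print(f"k_e: mean={summary.ke_stats.mean:.2f} "
          f"median={summary.ke_stats.median:.2f} "
          f"IQR={summary.ke_stats.q3:.2f}-{summary.ke_stats.q1:.2f}")

    analysis = analyze_model_collection(networks, I=250, master_seed=1)
    print(analysis.table.round(3).to_string(index=False))
    for note in analysis.notes:
        print("note:", note)

print()
print("The canalizing cascade has far lower effective than structural"
      " connectivity (stable dynamics); the parity circuit keeps"
      " k_e = k and tips chaotic.")
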