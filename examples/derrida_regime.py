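"""Order versus chaos from perturbation spreading.

Builds two homogeneous 50-node random networks whose rules share the
SAME in-degree (k = 8) and bias (p = 1/8) but differ in canalization,
and measures their Derrida parameter: the slope at the origin of mean
Hamming divergence after one synchronous step versus perturbation size.
zeta > 1 means perturbations grow (chaotic regime).

Structural theory sees identical networks (2kp(1-p) = 1.75 > 1: both
"chaotic"); the measured regimes differ and follow effective
connectivity.
"""

import numpy as np

from boolcrit import BooleanNetwork, BooleanRule, effective_connectivity
from boolcrit import measure_derrida

K, N = 8, 50


def lut(formula):
    """Truth table over (i1..i8), i1 most significant."""
    bits = []
    for alpha in range(1 << K):
        i = [(alpha >> (K - 1 - pos)) & 1 for pos in range(K)]
        bits.append(int(formula(i)))
    return BooleanRule(K, tuple(bits))


RULES = {
    "canalizing i1&i2&i3": lut(lambda i: i[0] and i[1] and i[2]),
    "parity (i1^i2^i3)&i4&i5": lut(
        lambda i: (i[0] ^ i[1] ^ i[2]) and i[3] and i[4]),
}

rng = np.random.default_rng(7)
for name, rule in RULES.items():
    inputs = [tuple(rng.choice(N, K, replace=False)) for _ in range(N)]
    net = BooleanNetwork(inputs=inputs, rules=[rule] * N)
    res = measure_derrida(net, I=250, t=1, rng=rng)
    curve = {m: round(h, 2) for m, h in sorted(res.table.items())}
    print(f"{name:26s} p={rule.n_on / 256:.3f}  "
          f"k_e={effective_connectivity(rule):.2f}  "
          f"zeta={res.zeta:.3f} -> {res.label}")
    print(f"{'':26s} mean divergence per m flips: {curve}")

print()
print("Same k and p, opposite regimes: in-degree and bias cannot separate"
      " these ensembles, but the rule with low effective connectivity"
      " buffers perturbations (zeta < 1) while the parity-driven one"
      " amplifies them.")
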