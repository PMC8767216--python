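"""Canalization of single Boolean automata.

Redescribes small truth tables as wildcard schemata and compares
effective connectivity (k_e) with average sensitivity.  k_e counts how
many inputs are, on average, minimally sufficient to settle a
transition; the gap k - k_e is the rule's dynamical redundancy.
"""

from boolcrit import (
    average_sensitivity,
    effective_connectivity,
    prime_schemata,
    rule_from_string,
)

RULES = {
    "OR(i1, i2)": "0111",
    "AND(i1, i2)": "0001",
    "XOR(i1, i2)": "0110",
    "AND(i1, i2, i3)": "00000001",
    "copy(i1)": "01",
    "constant 1": "1111",
}

for name, bits in RULES.items():
    rule = rule_from_string(bits)
    on, off = prime_schemata(rule)
    ke = effective_connectivity(rule)
    s = average_sensitivity(rule)
    print(f"{name:18s} k={rule.k}  k_e={ke:5.2f}  s={s:4.2f}  "
          f"ON schemata: {sorted(sc.pattern for sc in on)}  "
          f"OFF: {sorted(sc.pattern for sc in off)}")

print()
print("OR needs both inputs only for its all-zero row: k_e = (3*1 + 1*2)/4"
      " = 1.25, while parity (XOR) has no redundancy at all (k_e = k)."
      " Sensitivity cannot tell OR from copy (both s = 1); k_e can.")
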