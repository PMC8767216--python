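"""A small ensemble sweep and the fitted criticality boundaries.

Generates random Boolean networks over a (k, p, k_e-bin) grid at modest
size, labels each network's regime by its Derrida parameter, and fits
the two class-2 logistic boundaries: structural (c1 * k * p(1-p) = 1)
and canalization-based (c1 * <k_e> * p(1-p) = 1).  Runs in ~1 minute.
"""

import numpy as np

from boolcrit.models import paired_one_sided_t_test
from boolcrit.pipeline import PipelineConfig, fit_and_score, sweep_regimes

config = PipelineConfig(
    N=30, k_values=(2, 3, 4), replicates=8, derrida_pairs=100,
    master_seed=11)
records, skipped = sweep_regimes(config)
print(f"{len(records)} networks over {records.groupby(['k','p','bin']).ngroups}"
      f" viable cells ({len(skipped)} cells had no admissible rules)")
print(f"chaotic fraction: {records['chaotic'].mean():.2f}")

scored = fit_and_score(records, config)
c_st = scored["boundaries"][(2, "k")].boundary["kappa*pq"]
c_ct = scored["boundaries"][(2, "ke")].boundary["kappa*pq"]
print(f"structural boundary:    {c_st:.2f} * k * p(1-p) = 1"
      f"   (theory: 2 k p(1-p) = 1)")
print(f"canalization boundary:  {c_ct:.2f} * <k_e> * p(1-p) = 1")

cv = scored["cv_means"]
for kappa in ("k", "ke"):
    row = cv[(cv["class"] == 2) & (cv.kappa == kappa)].iloc[0]
    print(f"class-2 ({kappa:2s}) cross-validated: MCC={row.mcc:.3f} "
          f"AUC={row.auc:.3f} R2={row.r2:.3f}")

st = [r.mcc for r in scored["cv_reports"][(2, "k")]]
ct = [r.mcc for r in scored["cv_reports"][(2, "ke")]]
print(f"one-sided paired t-test (canalization > structural): "
      f"p = {paired_one_sided_t_test(st, ct).p_value:.2e}")
print()
print("The effective-connectivity boundary separates the regimes far"
      " more cleanly than in-degree: same model class, different notion"
      " of connectivity.")
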