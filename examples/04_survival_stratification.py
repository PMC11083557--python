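"""Composite-risk survival stratification with from-scratch KM/log-rank.

Subjects are split at the median marker methylation and expression;
the high-risk stratum is hypomethylated AND highly expressed (the
ATP1A1-style rule).  Kaplan-Meier curves of the two strata are
compared with the Mantel-Haenszel log-rank test, and a minimum-p
cutoff scan with permutation adjustment is shown for the expression
values alone.
"""

import numpy as np

from methylquad import (
    RiskRule,
    SimulationConfig,
    composite_risk,
    km_estimate,
    logrank_test,
    median_split,
    optimal_cutoff,
    simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(seed=1))
clin = cohort.clinical
marker = cohort.truth.marker_gene

meth_labels = median_split(clin[f"meth_{marker}"])
expr_labels = median_split(clin[f"expr_{marker}"])
rule = RiskRule(marker, "hypo", "high")
risk = composite_risk(meth_labels, expr_labels, rule)

chi2, p = logrank_test(clin["time"], clin["event"], risk)
print(f"high risk: {(risk == 'high_risk').sum()} subjects, "
      f"low risk: {(risk == 'low_risk').sum()}")
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.3g}")

for label in ("high_risk", "low_risk"):
    mask = risk == label
    curve = km_estimate(clin.loc[mask, "time"], clin.loc[mask, "event"])
    t5 = curve.probability_at(5.0)
    print(f"  S(t=5) {label}: {t5:.2f}")
# The high-risk curve should sit well below the low-risk curve: the
# generator gave marker-hypomethylated/high-expression subjects a 3x hazard.

res = optimal_cutoff(clin[f"expr_{marker}"], clin["time"], clin["event"],
                     n_permutations=200, seed=0)
print(f"\noptimal expression cutoff {res['cutoff']:.2f}: "
      f"uncorrected p = {res['p_uncorrected']:.3g}, "
      f"permutation-adjusted p = {res['p_permutation']:.3g}")
# The uncorrected minimum p is anti-conservative by construction; report
# the permutation-adjusted value.
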