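"""Kaplan-Meier curves, log-rank tests and adjusted Cox models.

Reproduces the analysis pattern of the study: dichotomize CD8_IM, compare
survival of the high/low groups, then estimate the adjusted hazard ratio
controlling for clinical covariates, and test the Immunoscore for trend.
"""

import pandas as pd

from tilscore import (DEFAULT_CUTOFFS, SimulationConfig, cox_fit,
                      generate_cohort, km_estimate, logrank_test,
                      logrank_trend, score_cohort)

cohort = generate_cohort(SimulationConfig(seed=42, n_patients=300))
scored = score_cohort(cohort, DEFAULT_CUTOFFS)

high = scored[scored.cd8_im_call == "high"]
low = scored[scored.cd8_im_call == "low"]
for name, grp in (("high", high), ("low", low)):
    curve = km_estimate(grp.os_months, grp.os_event)
    print(f"CD8_IM {name:4s} (n={len(grp):3d}): "
          f"S(24 mo) = {curve.survival_at(24):.2f}, "
          f"S(48 mo) = {curve.survival_at(48):.2f}")

lr = logrank_test(scored.os_months, scored.os_event, scored.cd8_im_call)
print(f"log-rank high vs low: chi2 = {lr.chi_square:.1f}, p = {lr.p:.2e}\n")

adjust = ["organ_confined", "margin", "lvi", "intravesical", "chemo"]
X = pd.DataFrame({"cd8_im_high": (scored.cd8_im_call == "high").astype(int)})
for cov in adjust:
    X[cov] = scored[cov]
model = cox_fit(X, scored.os_months, scored.os_event)
row = model.summary().iloc[0]
print(f"adjusted Cox: CD8_IM high HR {row.hr:.2f} "
      f"(95% CI {row.ci_lower:.2f}-{row.ci_upper:.2f}), p = {row.p:.1e}")
print("An HR below 1 means high marginal CD8 infiltration is protective "
      "(the generator's truth is HR 0.35).\n")

trend = logrank_trend(scored.os_months, scored.os_event,
                      scored.immunoscore.astype(int))
print(f"Immunoscore trend (I0..I4): chi2 = {trend.chi_square:.1f} on 1 df, "
      f"p = {trend.p:.2e}")
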