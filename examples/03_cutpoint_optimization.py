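"""Outcome-based cutoff optimization and why it needs correcting.

The minimum-p-value approach scans every admissible split of a density
marker and keeps the one with the smallest log-rank p. On a cohort with a
real CD8_IM effect the recovered cutoff lands near the true threshold of
70 cells/mm²; on a null cohort the *uncorrected* minimum p looks
significant far too often, which the Miller–Siegmund bound and the
permutation correction repair.
"""

from tilscore import (SimulationConfig, generate_cohort,
                      generate_null_cohort, optimize_cutpoint)

cohort = generate_cohort(SimulationConfig(seed=3, n_patients=200))
res = optimize_cutpoint(cohort.cd8_im, cohort.os_months, cohort.os_event,
                        compartment="cd8_im", correction="miller_siegmund")
print("cohort with a true CD8_IM effect (threshold 70 cells/mm²):")
print(f"  optimized cutoff {res.cutoff:.1f} cells/mm² "
      f"({res.n_low} low / {res.n_high} high patients, "
      f"{res.n_candidates} candidates scanned)")
print(f"  chi-square {res.chi_square:.1f}, raw p {res.raw_p:.2e}, "
      f"Miller-Siegmund corrected p {res.corrected_p:.2e}\n")

null = generate_null_cohort(SimulationConfig(seed=3, n_patients=200))
res0 = optimize_cutpoint(null.cd8_im, null.os_months, null.os_event,
                         compartment="cd8_im", correction="permutation",
                         n_perm=499, seed=1)
print("null cohort (densities independent of survival):")
print(f"  best-looking cutoff {res0.cutoff:.1f}, raw min-p {res0.raw_p:.3f} "
      f"-> permutation-corrected p {res0.corrected_p:.3f}")
print("\nThe raw minimum p overstates the evidence because the cutoff was "
      "chosen to minimize it; the corrected p is the honest one.")
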