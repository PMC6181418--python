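# tilscore

Tumor-infiltrating lymphocyte (TIL) density scoring and outcome-based
cutpoint analysis for muscle-invasive bladder cancer (MIBC) cohorts.

## The problem

In MIBC treated by radical cystectomy, the density and *location* of T-cell
infiltration carry prognostic information: CD3⁺ (pan-T) and CD8⁺
(cytotoxic) cell densities, measured separately in the tumor core (CT) and
at the invasive margin (IM), can be dichotomized into high/low calls and
combined into the Immunoscore, an integer grade

```
I = #{ c ∈ {CD3_CT, CD3_IM, CD8_CT, CD8_IM} : density_c > cutoff_c }  ∈ {0,…,4}
```

with I4 (all four high) carrying the best prognosis and I0 the worst. The
high/low cutoffs themselves are usually chosen by the *minimum-p-value*
approach: scan every admissible split of a density marker and keep the one
minimizing the two-group log-rank p. That selection makes the naive p-value
strongly anti-conservative, so the package reports both the raw p and a
selection-corrected p (the Miller–Siegmund asymptotic bound, or an exact
permutation null that re-runs the whole scan).

`tilscore` implements that pipeline for analysts working with
compartment-wise density tables: density computation from raw field counts,
cutpoint optimization, Immunoscore assignment, the associated survival
statistics (Kaplan–Meier, k-group and trend log-rank, multivariable Cox
with Efron/Breslow ties), a two-group differential-expression stage with
Benjamini–Hochberg false-discovery control, and a seeded synthetic-cohort
generator that emulates the statistical structure of a cystectomy series
(correlated log-normal densities, Weibull proportional-hazards survival,
realistic covariate prevalences) so every stage can be exercised and tested
without access to patient data.

## Worked example

```python
import pandas as pd
from tilscore import (DEFAULT_CUTOFFS, SimulationConfig, cox_fit,
                      generate_cohort, km_estimate, logrank_test, score_cohort)

cohort = generate_cohort(SimulationConfig(seed=42, n_patients=300))
scored = score_cohort(cohort, DEFAULT_CUTOFFS)   # published 490/290/116/70

lr = logrank_test(scored.os_months, scored.os_event, scored.cd8_im_call)
X = pd.DataFrame({"cd8_im_high": (scored.cd8_im_call == "high").astype(int),
                  **{c: scored[c] for c in
                     ["organ_confined", "margin", "lvi", "intravesical", "chemo"]}})
model = cox_fit(X, scored.os_months, scored.os_event)
```

Running `python examples/04_survival_analysis.py` (the same analysis)
prints:

```
CD8_IM high (n=211): S(24 mo) = 0.76, S(48 mo) = 0.51
CD8_IM low  (n= 89): S(24 mo) = 0.46, S(48 mo) = 0.18
log-rank high vs low: chi2 = 46.9, p = 7.36e-12
adjusted Cox: CD8_IM high HR 0.32 (95% CI 0.24-0.44), p = 4.6e-13
Immunoscore trend (I0..I4): chi2 = 48.6 on 1 df, p = 3.19e-12
```

High CD8 density at the invasive margin roughly triples 48-month survival
in this simulated cohort; the adjusted hazard ratio of 0.32 brackets the
generator's true effect (HR 0.35), and survival improves monotonically with
the Immunoscore.

The other scripts under `examples/` each demonstrate one capability:
simulation, density scoring, cutpoint optimization with both corrections,
differential expression, and the full pipeline (also available as the
`tilscore` command with `simulate`, `density`, `cutpoint`, `score`,
`survival`, `de` and `run-all` subcommands).

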