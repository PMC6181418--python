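# Methods

This note documents the statistical model behind each stage of `tilscore`,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic data do and do not establish about real cohorts.

## Density quantification and dichotomization

A compartment density is the arithmetic mean of per-field densities
`count_i / area_i` over the selected high-density fields (default 3). The
mean-of-ratios estimator is used rather than pooled `Σcount / Σarea`; the
two coincide for equal field areas, and the mean-of-ratios form matches
how multi-field averages are reported in the Immunoscore literature. Field
areas must be supplied explicitly — there is no standard field size to
assume. Fewer fields than expected are averaged with a logged warning.

Dichotomization is strict-greater: `high ⇔ density > cutoff`, ties to
`low`. This convention is fixed by the published group compositions
(low ≤ 70 vs high > 70 for CD8_IM) and is applied consistently in the
cutpoint scan, so optimized cutoffs reproduce exactly the group sizes
they were selected with. Missing densities propagate as missing calls and
exclude the patient from that compartment's analyses (complete-case per
analysis); they are never imputed.

## Immunoscore

The grade is the count of high calls among CD3_CT, CD3_IM, CD8_CT, CD8_IM
— the standard Galon counting rule, consistent with every published worked
example (all-high → I4, exactly one low → I3, all-low → I0). A patient
with any missing compartment gets an undefined grade with an explicit
missing-count flag. The rule is checked exhaustively over all 2⁴ call
vectors in the tests.

## Minimum-p-value cutpoint optimization

Candidates are the distinct observed density values `v` for which both
`#{d ≤ v}` and `#{d > v}` are at least `ceil(min_group_frac · n)`
(`min_group_frac` default 0.10; the smallest published group is ≈ 0.25 of
the cohort, comfortably above it). Candidates sit at observed values, not
midpoints, so the ≤/> convention reproduces printed group compositions.
For each candidate a df=1 two-group log-rank chi-square is computed from
the hypergeometric moments at each distinct event time (variance with the
standard tie correction `(n−d)/(n−1)`), vectorized across all candidates
via an at-risk-indicator matrix product. The optimum is the candidate with
maximal chi-square; ties break toward the smallest cutoff.

Because the cutoff is chosen to minimize p, the raw minimum p is
anti-conservative: on null cohorts of n = 150 the uncorrected rejection
rate at α = 0.05 is ≈ 40% in this package's calibration tests. Two
corrections are provided:

* **Miller–Siegmund bound** (default — deterministic and fast): with
  `z = Φ⁻¹(1 − p_min/2)`,

  ```
  p_cor = φ(z)(z − 1/z)·ln[(1−ε_l)ε_h / (ε_l(1−ε_h))] + 4φ(z)/z
  ```

  where `(ε_l, ε_h) = (min_group_frac, 1 − min_group_frac)` is the
  admissible split-fraction range. The bound is clamped into `(p_min, 1]`
  and returned as 1 whenever `z ≤ 1` (there the `z − 1/z` term goes
  negative and the asymptotic bound is vacuous). It is conservative for
  moderate candidate counts (observed null rejection ≈ 4–5% at α = 0.05).
* **Permutation** (exact calibration): the whole scan is re-run on density
  labels permuted against the (time, event) pairs;
  `p_cor = (1 + #{permuted min-p ≤ observed}) / (n_perm + 1)`. The
  candidate set depends only on the density multiset and is computed once.
  Default `n_perm` 999; a minimum of 100 is enforced.

The endpoint used for optimization is configurable (OS default; the
original analysis does not state which endpoint its cutoffs optimized).
The pipeline reports raw and corrected p side by side, since published
downstream p-values are conventionally the uncorrected log-rank ones.

## Survival statistics

*Kaplan–Meier* uses lifelines' product-limit estimator; the Greenwood
variance `S(t)²·Σ d_i/(n_i(n_i−d_i))` is computed from the event table.
With no censoring the curve equals 1 − ECDF (tested as a closed form).

*Log-rank* (k-group, df = k−1) is computed from per-time hypergeometric
moments with the covariance matrix `Σ_t d_t(n_t−d_t)/(n_t−1)·
(diag(p_t) − p_t p_tᵀ)`, inverting on k−1 groups via least squares. The
*trend* variant scores ordered groups 0..k−1 and uses
`(sᵀ(O−E))²/(sᵀVs)` with df = 1; with two groups it reduces exactly to
the ordinary log-rank. Both are cross-checked against lifelines and a
brute-force per-event-time oracle in the tests.

*Cox proportional hazards* is fit by Newton iteration on the partial
likelihood with step-halving, supporting Efron (default, less biased under
ties) and Breslow tie handling. The explicit solver exists because the
two tie conventions must both be selectable and because monotone
likelihoods (perfect separation) should raise an error rather than return
drifting estimates; it reproduces lifelines (Efron) and R's
`survival::coxph` (both conventions) to ~1e-6 or better on fixed test
data. Convergence is declared when the gradient infinity-norm falls below
`1e-8 · max(1, |loglik|)` — a relative criterion, since at n in the
thousands float64 accumulation puts the gradient floor near 1e-7 even at
the optimum. Estimates with any |log-HR| exceeding 15 abort as monotone
likelihood. Wald 95% intervals are `exp(β ± 1.96·SE)`; constant covariate
columns are rejected by name.

*Two-group density comparisons* (NAC responders vs non-responders, BCG
exposure) default to the Wilcoxon rank-sum test — density distributions
are right-skewed — with a Welch t alternative. All tests are two-sided at
α = 0.05.

The adjusted models mirror the published adjustment set: one model per
immune marker (marker indicator + organ-confined, surgical margin, LVI,
prior intravesical therapy, perioperative chemotherapy), plus one model
entering the Immunoscore as indicator levels against the lowest observed
grade. For Immunoscore curves both the heterogeneity (df = k−1) and trend
(df = 1) statistics are reported, since the source analysis does not say
which k-group test it used.

## Differential expression

Per gene, a two-sided Welch (unequal-variance) t-test on log-scale values
between basal and luminal samples; the exact method behind the original
comparison is unspecified beyond "R/Bioconductor", and the Welch test is a
fully specified, method-agnostic choice that behaves well on normalized
log expression. Multiplicity is gene-level Benjamini–Hochberg across all
genes tested in the run (step-up, `q_(i) = min_{j≥i} m·p_(j)/j`). Genes
with zero variance in both groups get p = 1 with a warning. The gene-set
summary counts members at q < 0.05 split by sign of the basal − luminal
difference and exports the member rows ordered by q as the heatmap slice
(data only; rendering is out of scope).

## Synthetic data

The generator emulates a single-center radical-cystectomy series and a
luminal/basal expression comparison so that the full pipeline is testable
without patient data.

* **Densities**: correlated log-normals (strictly positive, right-skewed,
  default pairwise log-scale correlation 0.5 — TILs co-infiltrate). The
  log-means place the published cutoffs (490/290/116/70 cells/mm² for
  CD3_CT/CD3_IM/CD8_CT/CD8_IM) at quantiles matching the published
  high/low group sizes (e.g. CD8_IM 70 near the lower quartile, 17/48
  low/high; CD3_IM 290 near the upper quartile, 49/18); log-SD 1.0.
* **Survival**: Weibull proportional hazards, shape 1.2, scale 23 months
  — calibrated so ≈ 50% of deaths occur by 36 months under the default
  linear predictor, matching the short follow-up typical of such series.
  The linear predictor adds per-compartment log-HRs for densities above
  their true cutoffs (default −1.05 for CD8_IM, i.e. HR ≈ 0.35, the
  published adjusted effect; smaller protective effects elsewhere) and
  covariate log-HRs (organ-confined protective, LVI and positive margins
  adverse).
* **Covariates**: Bernoulli draws at the published prevalences (LVI 0.701,
  margins 0.104, prior intravesical therapy 0.261, perioperative
  chemotherapy 0.40 combined). The organ-confined (≤T2N0) prevalence is
  not printed in the source characteristics table; 0.24 is used (~24% of
  that cohort is ≤pT2).
* **DFS coupling**: each patient recurs with probability
  `logit⁻¹(0.2 + 0.8·lp)` increasing in the hazard linear predictor; the
  recurrence time is the death time scaled by a Beta(5, 2) draw. This
  guarantees DFS ≤ OS row-wise and the event-count ordering (every death
  within the window is also a DFS event).
* **Censoring**: administrative at 60 months plus 10% uniform early
  dropout.
* **NAC response**: defined only for chemo-treated patients, with response
  probability `logit⁻¹(slope·(ln d_CD8_IM − ln 70))`, slope 1.0 — giving
  the responders-have-higher-CD8_IM pattern.
* **Expression**: genes × (121 luminal + 68 basal) log-scale matrix,
  per-gene baselines N(6, 1.5²), noise SD 1.0; a randomly chosen 113-gene
  cytotoxicity set is shifted by `effect_size` (default 2.0 log units) in
  basal samples; all other genes are exchangeable between groups.

One `numpy` Generator seeded from the single config seed drives every
draw; identical config + seed is bit-identical output. The null-cohort
variant forces all density log-HRs to zero, leaving densities independent
of survival — the harness for the type-I-error studies.

**What the synthetic data do not capture**: real density distributions
need not be log-normal or share one correlation; hazards need not be
proportional or Weibull; informative censoring, inter-observer variation
in field selection, and missing-not-at-random patterns are absent; the
expression matrix has independent genes (no co-expression structure) and
a homogeneous shift rather than gene-specific effects. Passing tests
therefore establish the correctness and calibration of the *procedures*
under the stated model, not the clinical conclusions of any real cohort.

## Problem sizes and numerical choices

Calibration and recovery checks use 1,000 null cohorts of n = 150
(permutation correction with n_perm = 199 per replicate), 200 recovery
cohorts of n = 400, 500 coverage cohorts of n = 300, and a single
n = 2,000 cohort for Cox recovery — sizes at which the Monte-Carlo error
of each check is small against its acceptance band. Degenerate inputs are
errors, not silent results: empty groups, zero events, constant Cox
covariates, non-positive-definite correlation matrices, p-values outside
(0, 1]. Log-rank variance terms at risk sets of size ≤ 1 contribute zero.
Chi-square p-values are floored at the smallest positive float to keep
them in (0, 1].

## Known limitations

* No proportional-hazards diagnostics, time-varying covariates or
  competing risks.
* The Miller–Siegmund bound is asymptotic; for very small cohorts or very
  few candidates the permutation correction is the reliable one.
* The Breslow path exists for compatibility with older software defaults;
  Efron is the better estimator under heavy ties and is the default.
* The expression stage tests location shifts gene by gene; it is not a
  substitute for moderated-variance methods (limma) or count models
  (DESeq2) on raw counts.
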