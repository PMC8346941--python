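# Methods

This note documents the statistical models implemented in `hbref`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer should know.

## 1. The estimand

Anemia cutoffs are lower reference limits: the fifth percentile (P5) of Hb
in a population free of conditions that depress Hb.  The package estimates
that P5 per survey, asks whether surveys can be pooled (variance
decomposition at the quantile), pools them (random-effects meta-analysis),
and corroborates the resulting threshold with an independent physiological
signal (the Hb–sTfR curve).

## 2. Hb adjustment

Altitude correction subtracts c(A) = −0.032·A + 0.022·A², A = altitude in
thousands of feet (metres × 0.0032808), applied only at ≥ 1000 m — below
that the correction is within instrument resolution and conventionally
skipped.  Women who smoke get a flat −0.3 g/dL.  Records without altitude
or smoking data pass through unchanged, mirroring real survey-by-survey
availability.  All coefficients live in `AdjustmentPolicy` / the YAML
`adjustment:` section; zeroing them makes the stage an identity.
Adjustment tags records; re-adjusting raises — a corrected value must never
be corrected twice.  An adjustment that would drive Hb ≤ 0 raises rather
than clips, because a clipped value would silently poison the lower tail
that the whole analysis is about.

## 3. Apparently healthy cohort

Thresholds (all inclusive on the healthy side): ferritin ≥ 12 (child) /
15 (woman) ng/mL; RBP/retinol ≥ 20.1 µg/dL; CRP ≤ 0.5 mg/dL; AGP ≤ 1 g/L;
no malaria.  Semantics of "where measured": an unmeasured optional marker
never excludes; ferritin and at least one inflammation marker are
mandatory (their absence is an error, not a pass).  When both CRP and AGP
are present, both must pass.  Ferritin and vitamin A are deliberately not
inflammation-regression-adjusted: inflamed individuals are excluded
outright, so the adjustment would be circular.  Surveys retaining fewer
than `min_healthy_per_survey` (default 100) healthy members are dropped
whole, keeping order-statistic P5 estimates stable.  The filter is
monotone: tightening any threshold can only shrink the healthy set
(property-tested), and deleting an optional column can only grow it.

## 4. Survey P5 and Woodruff CI

The quantile convention is fixed to the inverse empirical CDF
(left-continuous; order statistic ⌈np⌉).  This makes the Woodruff
construction self-consistent: a Wald interval on the proportion below the
quantile, SE(p̂) = √(p(1−p)/n) at design effect 1 (the cohort is treated
as simple random sampling), is mapped through the same quantile function
back to the Hb scale; se_q is reported as (CI width)/(2z) for downstream
inverse-variance weighting.  Ties at the 0.1 g/dL instrument resolution
follow the same order-statistic rule; no jittering.  If p ± z·SE leaves
(0, 1) — possible near n ≈ 100 — the CI is declared undefined and an error
raised rather than truncated, which would understate uncertainty.
Simulation places the interval's coverage at ~95 % for normal samples of
n ≥ 500 (tested at n = 1000, 2000 replicates, band [93 %, 97 %]).

## 5. REML random-effects pooling

Model yᵢ = µ + uᵢ + eᵢ with Var(uᵢ) = τ² (true between-survey spread of
the P5) and Var(eᵢ) = vᵢ = se_qᵢ².  τ² maximises the restricted
likelihood via Fisher scoring (score ½[Σw²r² − Σw + Σw²/Σw], expected
information ½[Σw² − 2Σw³/Σw + (Σw²/Σw)²], projection onto τ² ≥ 0,
tolerance 1e-8, ≤ 200 iterations, bounded scalar maximisation as a
safeguard).  The scoring fixed point is verified against a brute-force
likelihood grid (step 1e-4) in the tests.  µ̂ is the inverse-variance
weighted mean at weights 1/(vᵢ+τ̂²); its CI uses the normal quantile (not
Knapp–Hartung), matching Wald-style forest-plot intervals; τ is reported
as √τ̂² as an SD-scale heterogeneity summary.  Cochran's Q uses
fixed-effect weights 1/vᵢ — the conventional choice; which weights the
original analyses used for Q is generally unstated, so this assumption is
recorded here.

## 6. Linear quantile mixed model and ICC

Working likelihood: y_ij | u_j ~ ALD(x'β + u_j, σ, p) with
u_j ~ N(0, ψ²); the ALD location is the p-th conditional quantile, so β
describes the conditional P5 (p = 0.05 default; 0.95 supported for the
upper-tail check).  Covariates: mean-centred age and age² (child ages are
months/12, so slopes are per year for both groups), plus sex for children;
sex among women is rejected as singular.  The marginal likelihood
integrates u_j by **adaptive** Gauss–Hermite quadrature (default 11
nodes): nodes are centred and scaled per survey at a Gaussian
approximation of the conditional posterior of u_j — location from the
within-survey residual p-quantile, precision n_j·p(1−p)/σ² + 1/ψ² — and
reweighted exactly.  Adaptivity is not cosmetic: at realistic survey sizes
(n_j ≈ 150+) the u_j-integrand is an order of magnitude narrower than the
prior, and fixed nodes collapse ψ̂² toward zero.  Optimisation is
Nelder–Mead from a `statsmodels` QuantReg start, with seeded restarts that
deliberately ladder the weakly identified ψ across basins (×2, ×½, ×4, …)
and an L-BFGS-B polish; the tests certify the reached maximum against an
independent brute-force grid of the same integrated likelihood to 1e-3.

Variance decomposition: ICC_between = ψ²/(ψ² + σ_e²) with
σ_e² = σ²(1−2p+2p²)/(p²(1−p)²), the ALD residual variance.  The source
analyses do not print their ICC formula; this is the standard construction
for quantile mixed models and is an assumption of this package.  Two
consequences are documented deliberately: (i) when individual errors are
truly ALD, the decomposition consistently recovers the planted
between-survey variance fraction (parameter-recovery tests use that
family); (ii) under lighter-tailed (e.g., Gaussian) errors the fitted ALD
scale inflates σ_e² (~4× at p = 0.05), attenuating the between-survey
share — a caveat for interpreting small ICCs on real data.  ψ̂² is also
downward-biased at small numbers of surveys (ML, not REML); recovery tests
use 25 surveys, where the bias is negligible.

The likelihood-ratio test of ψ² = 0 refers 2Δloglik to the boundary-null
50:50 mixture of χ²₀ and χ²₁.

## 7. Restricted cubic spline and inflection points

Basis (5 knots t₁ < … < t₅):
C_j(x) = (x−t_j)₊³ − (x−t₄)₊³(t₅−t_j)/(t₅−t₄) + (x−t₅)₊³(t₄−t_j)/(t₅−t₄),
j = 1..3, plus intercept and linear term; linear beyond the boundary
knots, hence f″ ≡ 0 outside [t₁, t₅].  Knots default to the sample sTfR
quantiles (0.05, 0.275, 0.50, 0.725, 0.95); explicit knots are accepted
(used by recovery studies).  The least-squares solve scales columns to
unit max before forming the 5×5 normal equations — unscaled cubic columns
cost ~6 digits and break noiseless recovery.  f″ is piecewise linear with
breaks at the knots, so inflection points are exact segment roots;
"the first two" means the two smallest-sTfR roots.  The original analyses
phrase this step as solving differential equations; with an analytic
piecewise-linear f″ exact root-finding is the faithful implementation and
no numerical ODE solver is warranted.  A fit whose knot-value curvature
moves fitted values by less than ~1e-9 of their scale (effectively linear
data, machine-noise curvature) raises "insufficient curvature" instead of
reporting meaningless roots.

## 8. BCa bootstrap

Nonparametric pairs resampling at the original n.  Median-bias correction
z₀ = Φ⁻¹(#{θ* < θ̂}/B) (proportion clamped to (0.5/B, 1−0.5/B));
acceleration a = Σd³ᵢ / (6(Σd²ᵢ)^{3/2}) from delete-one jackknife;
endpoints Φ(z₀ + (z₀ ± z_{α/2})/(1 − a(z₀ ± z_{α/2}))) applied to the
bootstrap distribution.  Resamples where the statistic fails (an
inflection vanishing under resampling) are dropped and counted; > 10 %
failures aborts with a diagnostic rather than returning a biased interval.
A degenerate (constant) statistic yields a zero-width interval.  For a
symmetric statistic (sample mean) z₀ ≈ 0 and a ≈ 0, and BCa collapses to
the percentile interval — tested.  Default B = 5000; B ≥ 999 is accepted
for smoke runs and coverage studies.  The bootstrap pools all
observations; a within-survey stratified variant is a flag
(`run_hb_stfr_analysis` operates on the pooled pairs by default, matching
the pooled curve fit).

## 9. Synthetic generator

`generate_cohort` draws, per survey j: size n_j ~ U{500..3000}, intercept
u_j ~ N(0, τ²), ages uniform in the group window, and individual Hb

  µ + u_j + slope·(age_y − āge) + quad·(…)² + sex·1[male] + shift·1[unhealthy] + ε

with ε either Gaussian (default; realistic survey noise) or ALD located at
the analysis quantile (the quantile mixed model's own generative family,
used by recovery tests; `sigma_within` is always the SD of ε).  Unhealthy
members (fraction `frac_unhealthy`) are shifted down and receive biomarker
values violating one healthy criterion, chosen among the markers their
survey measures; healthy members' biomarkers always pass.  Optional
survey-level features: altitude (effect planted via the same polynomial
the adjustment removes) and smoking among women (+0.3 for smokers, so
adjustment inverts it).  Defaults echo a ~22-survey multinational setting
with anemia-range means (children µ = 11.5, σ = 1.1, τ = 0.4, 60 %
unhealthy; women µ = 12.5, σ = 1.05, τ = 0.4, 44 %); these calibration
constants are illustrative, not reproduction targets.

`generate_stfr` draws sTfR from a truncated lognormal (right-skewed,
spanning both planted inflections; truncation at `stfr_max` represents the
assay's physiological range and keeps the planted curve's linear tail out
of impossible Hb values) and sets Hb = curve(sTfR) + N(0, noise).  The
planted curve is constructed by `make_two_phase_curve` from target
curvature values at the three interior knots with a (−, +, −) sign
pattern — exactly two inflections, validated at construction — an anchor
Hb at the second inflection, and a starting slope.  Curvature magnitudes
are sized so the sign pattern stays resolvable when analysis knots are
re-placed at sample quantiles.

The truth table records every planted parameter plus derived truths: the
analytic healthy-component P5 (quadrature over the age distribution and
survey intercepts + root-finding, checked against a 10⁶-draw simulation to
0.01 g/dL), the between-survey variance fraction τ²/(τ²+σ²), and the
conditional-P5 intercept.  Recovery tests read truths only from this
table.

What the generator does **not** emulate: country-specific Hb shapes, assay
error structures (HemoCue vs analyzer), inflammation-dependent ferritin,
survey weights, age-dependent biomarker prevalences, hemoglobinopathies.
Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed hierarchical model, not robustness to those
real-data complications.

Randomness: counter-based Philox generators seeded explicitly; every
artifact's manifest carries the seed, and identical (config, seed, input)
reproduce outputs bit-for-bit.

## 10. Problem sizes used in the checks

The reproduction script (`scripts/acceptance.py`) runs both groups at the
generator defaults (~22 surveys, ~35–40k records per group), fits the
quantile mixed model on the resulting healthy cohorts (~13–23k records, 11
adaptive nodes), and bootstraps the second-inflection Hb with B = 1999 at
n = 5000 sTfR pairs.  The simulation-based tests use 2000 replicates
(Woodruff coverage, n = 1000), 200 replicates (REML recovery, k = 25; BCa
mean coverage, n = 100, B = 999), 100 replicates (inflection BCa coverage,
n = 5000, B = 999) and 20 replicates (ICC recovery, 25 × 150).  These
sizes were chosen to give Monte-Carlo error comfortably inside each
acceptance band on a single core.

## 11. Known limitations

- The ICC construction is ALD-variance-based (Section 6); its absolute
  level under non-ALD errors is attenuated and should be read
  comparatively, not literally.
- Woodruff CIs are undefined for very small healthy surveys instead of
  truncated; such surveys abort the pipeline explicitly.
- Negative adjusted Hb raises rather than truncates; whether the original
  analyses truncated is unknown.
- Duplicate individuals or repeated surveys per country are keyed strictly
  by `survey_id`; no de-duplication heuristics.
- No survey-design weights anywhere (the analyses are deliberately
  unweighted); no SPSS/Stata ingestion; no pregnancy adjustments; no sTfR
  assay harmonisation beyond a user-supplied pre-transformation hook.
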