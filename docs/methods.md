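# Methods

## The problem

Cross-country comparisons of national HIV programmes ask how much service
output — coverage of antiretroviral therapy (ART) among people living with
HIV (PLHIV), and coverage of antiretrovirals for prevention of
mother-to-child transmission (PMTCT) among HIV-positive pregnant women — a
country obtains per dollar of HIV spending. `swdea` measures this as
*technical efficiency*: the ratio of achieved outputs to the maximum
outputs attainable at the same spending level, where the attainable maximum
is estimated non-parametrically from the data themselves.

## Stage 1: output-oriented VRS DEA

Each country-year observation is a decision-making unit (DMU) with one
input x (total HIV spending per PLHIV, constant USD) and two outputs
y = (ART coverage, PMTCT coverage), both on the 0–100 scale.  All
country-years enter a single pooled frontier, so scores are comparable
across both countries and years.  The output distance of unit i solves the
envelopment linear program

    max δ   s.t.  Σ_j λ_j x_j ≤ x_i,
                  Σ_j λ_j y_jm ≥ δ y_im   (m = 1, 2),
                  Σ_j λ_j = 1,  λ ≥ 0.

δ ≥ 1 is the feasible proportional expansion of both outputs; efficiency is
1/δ ∈ (0, 1].  The convexity constraint Σλ = 1 imposes variable returns to
scale (VRS); dropping it gives the CRS variant, used here only as a test
reference (VRS δ ≤ CRS δ).  Output orientation is the natural choice for
programmes that aim to maximise coverage from a given budget; weak
efficiency in the input direction (input slack) is deliberately ignored.

### Solution paths

`score_dmu` solves the LP (scipy/HiGHS) and returns the intensity weights
λ, identifying each unit's peer set.  Scoring the bootstrap volumes this
way is impractical (~1e6 LPs at 3–7 ms each), so `score_against` exploits
the 1-input/2-output geometry: the VRS production set is the convex hull of
the points (x_j, y_j1, y_j2) extended by free disposal (more input, fewer
outputs allowed).  Its facets are enumerated once per reference set with
Qhull — the unbounded disposal cone is clipped by ghost vertices at every
disposal combination — and every query unit's distance is the minimum over
facets with positive output-normal of (b − a_x x_i)/(a_y · y_i), a single
vectorised matrix operation.  The two paths agree to below 1e-13 on random
instances (tested); degenerate geometries (coplanar points, tiny n) fall
back to the LP automatically.  Scores from self-referential problems are
clamped to δ ≥ 1 to absorb solver noise; rescoring against bootstrap
pseudo-frontiers is *not* clamped, because a unit can legitimately lie
outside a pseudo-frontier (δ < 1).

## Stage 2: truncated regression of inefficiency

The distances are modelled as δ_i = z_i'β + ε_i with ε_i ~ N(0, σ²)
left-truncated so that δ_i ≥ 1, where z_i collects country covariates
(governance, health financing, HIV prevalence, development indices...).
The likelihood per observation is

    log φ((δ_i − z_i'β)/σ) − log σ − log Φ((z_i'β − 1)/σ),

maximised over (β, log σ) by L-BFGS-B with the analytic score, OLS start,
and a damped-Newton polish (finite-difference Hessian) that drives the
score norm below 1e-5.  Units with δ = 1 (boundary tolerance 1e-9) are
excluded from the fit — the estimator conditions on strictly inefficient
units — with an `include_boundary` flag for sensitivity.  Coefficients are
on the inefficiency scale: positive β means the covariate is associated
with larger distance, i.e. lower efficiency.

Truncated-normal draws use inversion of the upper-tail probability
(ndtri of p·(1−u), stable far into the tail); when the tail mass
underflows (≳ 38σ) an exponential-proposal rejection sampler takes over,
and beyond 1e8σ the law is treated as degenerate at the bound.

## Double bootstrap

The empirical DEA frontier lies inside the true frontier, so raw
efficiencies are biased upward.  The two-loop bootstrap both corrects this
bias and provides inference for β:

* **Loop 1** (default L1 = 1,000): fit the truncated regression of δ̂ on Z;
  per replication, draw δ*_i = z_i'β̃ + ε*_i (truncated ≥ 1), shrink
  outputs onto the implied pseudo-frontier (y*_i = y_i δ̂_i/δ*_i), rescore
  all original units against the pseudo reference set, and estimate
  bias_i = mean_b(δ̂*_ib) − δ̂_i.  The corrected distance is
  δ̂_i − bias_i = 2δ̂_i − mean_b(δ̂*_ib), clamped at 1 (clamp events
  counted in the result).  Per-unit 95% CIs are percentile intervals of
  the bootstrap distances re-centred at the corrected score (draws shifted
  by −2·bias so their mean equals δ_bc), clamped at 1, and reciprocated to
  the efficiency scale with bounds swapped.
* **Loop 2** (default L2 = 3,000): refit on the corrected distances, then
  parametrically bootstrap that fit — simulate δ**_i from the fitted
  truncated model, refit, collect (β, σ) — and report percentile CIs and
  bootstrap SEs.  Setting L2 = 0 skips this loop, which the sensitivity
  comparisons use since they only need mean corrected scores.  Regression
  p-values are two-sided normal-reference tests on coefficient/bootstrap-SE.

One master seed spawns independent substreams per replication
(`numpy.random.SeedSequence`), so results are bit-reproducible and the
loops could be parallelised without changing output.

## Missing covariates

Inputs and outputs are never imputed; records lacking them are excluded
(counts logged in the study manifest).  Covariates are completed in two
steps: (1) within each country's yearly series, interior gaps take the
within-country mean of observed values and years outside the observed span
carry the nearest value (provenance tags `temporal_fill` / `edge_carry`);
(2) remaining gaps are imputed from a multivariate-normal model fitted to
the standardized covariate matrix by EM (ridge 1e-6 on the covariance,
tolerance 1e-6, max 200 iterations), drawing M = 50 completed datasets from
the conditionals of missing given observed and averaging them cell-wise
into one analysis panel.  Averaging rather than analysing the M datasets
separately trades Rubin-style variance propagation for a single analysis
panel; imputation uncertainty is therefore *not* propagated into the DEA.
A covariate with no observations at all carries no correlation information
and falls back to the pooled mean, flagged.

## Synthetic panels and what passing tests show

The generator emulates the study's shape: 78 countries × 9 years, spending
per PLHIV log-normal clipped to [45, 3502] USD, 10 base + 4 auxiliary
covariates from a Gaussian copula with a random correlation matrix rejected
until max |ρ| < 0.7, inefficiency δ = z'β + ε (truncated ≥ 1) with default
β = (1.5, 0.4, −0.4), σ = 0.3 — giving mean efficiency ≈ 0.66, the scale
reported for real HIV-spending panels — and 15% MCAR covariate missingness.
Outputs sit below a monotone concave frontier g_m(x) = a_m x^{b_m} with
b = (0.14, 0.10), a_m set so the frontier peaks at 100; the exponents were
calibrated once so the pooled input–output Pearson correlation falls in the
weak-positive band (≈ 0.18–0.31) characteristic of such panels.  Optional
knobs add a calendar-year trend or group-level shifts to the linear
predictor for trend/grouping tests.

The generator shares the second-stage model family with the estimator, so
recovery tests validate the machinery, not the model's realism.  Features
of real panels it does not emulate: serial correlation within countries
(covariate cells are drawn i.i.d. over country-years), non-MCAR
missingness, measurement error in outputs, and heterogeneous (e.g.
regional) frontiers.  Passing tests therefore demonstrate correct
algorithmic behaviour under the stated model, not robustness to those
violations.

## Study pipeline

`run_study` chains load → exclusion → imputation → optional trimming → DEA
→ double bootstrap → tables: pooled descriptives (mean, SD, P25/P75,
min/max; percentiles by linear interpolation between order statistics),
annual mean corrected efficiency with normal-approximation 95% CIs
(mean ± 1.96·SD/√n; groups of one get their CI suppressed), grouped
summaries by WHO region, UNAIDS region and World Bank income group, the
regression table, and a sensitivity table.  Sensitivity variants extend
the ten-covariate base model with workforce/infrastructure covariates
(model A), funding-source covariates (model B), or both (A+B), and/or trim
observations strictly below the 5th or above the 95th percentile of the
input or either output; variants are compared by mean corrected efficiency
with Welch two-sample t-tests against the base model, restricted to the
intersection of units when panels differ.  A JSON manifest (config hash,
seed, exclusion/clamp counts) makes every table reproducible
bit-identically.

Income groups follow the World Bank FY2022 GNI-per-capita thresholds
(low ≤ 1,045 < lower-middle ≤ 4,095 < upper-middle ≤ 12,695 < high, 2020
USD); boundary values belong to the lower group.  Region labels are data
columns, not computed — they come from external classifications.

## Problem sizes in the checked runs

The test suite and `scripts/acceptance.py` run the simulation studies at
sizes chosen to finish in minutes while keeping Monte-Carlo error well
inside the asserted margins: DEA oracle agreement on instances of 2–5
units at grid resolution 1/400; truncated-regression recovery with 50–100
replicates of n = 1,000; the double-bootstrap recovery design (n = 120,
β = (1.5, 0.6, −0.6), σ = 0.3) with L1 = 200 / L2 = 500 over 10–20 seeds;
loop-2 CI calibration with 40–50 replicates at L2 = 300; and the
sensitivity comparison on the full 78 × 9 default panel at L1 = 200.
Production analyses should use the default L1 = 1,000 / L2 = 3,000.

## Known limitations

* Pooled (single) frontier in the pipeline; `score_within_groups` offers
  per-year frontiers for exploration, but no metafrontier analysis.
* No input orientation, slack-based or super-efficiency models.
* Percentile CIs only (the basic-bootstrap alternative is not offered).
* Imputation uncertainty is not propagated (see above).
* The loop-2 parametric bootstrap assumes the truncated-normal second
  stage is correctly specified; misspecification (e.g. heteroskedastic
  σ(z)) will make its CIs optimistic.
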