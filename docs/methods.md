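# Methods

## The measurement problem

A body posture expressing one emotion biases how the facial expression it
accompanies is categorized: a disgusted face on an angry body is often called
angry. Whether this integration of face and body signals happens *early*
(before the visual stage whose adaptation drives facial-expression
aftereffects) or *late* (after it) is decidable psychophysically: adapt
observers to a disgusted face in a disgusted vs an angry body context and
measure the aftereffect on an anger–disgust morph continuum. Early
integration predicts context-dependent (even sign-reversed) aftereffects;
late integration predicts identical aftereffects in both contexts. This
package implements the full measurement and inference chain for that design
and exercises it on synthetic observers generated under each hypothesis.

## Psychometric model

All 2AFC test data are modelled by a cumulative-Gaussian psychometric
function on the morph axis x ∈ [0, 1] (0 = fully disgusted, 1 = fully
angry), giving the probability of an "anger" response:

    P(anger | x) = γ + (1 − γ − λ) Φ((x − α)/σ)

* **α** (PSE, morph units): the point of subjective equality, the primary
  outcome. Fitted within [−0.5, 1.5] so PSEs slightly outside the morph
  range are representable without unbounded drift.
* **σ** (spread, morph units): Gaussian SD; sensitivity is reported as the
  slope 1/σ. Fitted within [0.01, 1.0]. Absolute slope values are only
  comparable within this package; toolbox slope parameterizations differ.
* **γ** (guess rate) and **λ** (lapse rate): fixed at 0 and 0.03. The task
  has two response labels and no asymmetric forced guess, so γ = 0; λ = 0.03
  absorbs stimulus-independent errors at the upper asymptote.

Fitting maximizes the binomial log-likelihood of level-binned counts over
(α, log σ): a 10×10 coarse grid over the bounds seeds one bounded L-BFGS-B
polish, which is deterministic given the data. Deviance is
2(ℓ_saturated − ℓ_fit) with the saturated model at the observed per-level
proportions and 0·log 0 ≡ 0. Patterns with all-identical responses across
levels are rejected as non-identifiable rather than fitted.

**Goodness-of-fit screen.** A parametric bootstrap simulates 400 datasets
(100 in the large Monte-Carlo calibration runs; see *Problem sizes*) from
the fitted parameters at the observed stimulus placements, refits each, and
compares deviances. The p-value uses the smoothed estimator
(1 + #{D_sim ≥ D_obs})/(n_kept + 1), which cannot return 0. Fits with
p < 0.05 are flagged and the observer is excluded from all adaptation
analyses (any one bad condition excludes the observer). Replicates whose
refit is non-identifiable are dropped; more than 10% drops is an error.

**Aftereffect.** baseline PSE − adapted PSE, in morph units. On this axis a
positive value means adaptation to disgust (targets look more angry). When
several baseline sessions exist their PSEs are averaged before differencing.

## Psi adaptive procedure

Each test trial's morph level is the candidate minimizing the expected
Shannon entropy (natural log) of the posterior over an (α, σ) grid:

    E[H](x) = Σ_r p(r|x) H(posterior | x, r)

with the response probabilities marginalized over the current posterior.
Defaults: 41 α values on [0, 1], 21 log-spaced σ values on [0.02, 0.5],
41 candidate levels on [0, 1], uniform prior, γ and λ equal to the fitting
values. Ties in expected entropy (within 1e-12) break to the lowest
candidate, making sessions fully deterministic given the observer's
response stream. Every session (each baseline, each adapted condition)
starts from a fresh uniform prior; no posterior carry-over is modelled.
Interim estimates are marginal posterior means; final PSEs come from the
MLE refit of the binned session data, with the Psi posterior mean recorded
alongside (the two agree to ~2e-4 morph units in median under the default
conditions).

Implementation note: expected entropy is computed via
p·H(w/p) = p·log p − Σ w log w with per-candidate likelihood tables
(and their x·log x transforms) cached at initialization, so a 144-trial
session costs a few tens of milliseconds.

## Bias indices

Categorization data (4 alternatives: disgust, anger, fear, sad) are reduced
to disgust/anger responses within disgust/anger body contexts. With p_c the
proportion of face-congruent responses among disgust+anger responses in
context c:

* **Index 1** = p_con / p_incon (undefined, not infinite, when p_incon = 0;
  the ratio form is outlier-prone, which is why Index 2 exists).
* **Index 2** = z(p_con) − z(p_incon), a d′-style measure; proportions of
  exactly 0 or 1 are adjusted to 1/N and 1 − 1/N first. N is the
  disgust+anger response count in that context — the denominator of the
  proportion being adjusted — not the trial count; this choice is recorded
  in report metadata. No-response trials are excluded from all counts.

## Group statistics

* Paired and one-sample t tests with Hedges-corrected effect sizes
  (J = 1 − 3/(4(n−1) − 1)). The paired effect size divides by the SD of the
  difference scores (switchable convention; the pooled-SD convention used by
  some toolboxes gives different g for the same t).
* The 2×2 within-subject ANOVA (face present/absent × body context) is
  computed through its three single-df contrasts, so F = t² holds exactly
  and p-values equal the contrast t tests'.
* **Directional JZS Bayes factor** for the congruent-vs-incongruent
  contrast: Cauchy(0, 0.707) prior on the standardized effect size,
  truncated to the direction the early-integration hypothesis predicts
  (congruent > incongruent); BF01 > 1 favours the null. The marginal is an
  arctan-substituted adaptive quadrature of noncentral-t densities
  (relative tolerance 1e-9). Robustness sweeps evaluate BF01 over a grid of
  prior scales and report the smallest scale with BF01 ≥ 3 ("substantial").
  The direction is always an explicit argument, never inferred from data.
* **Bayesian Pearson correlation**: exact sampling density of r (Gaussian
  hypergeometric form) under a stretched Beta(1/w, 1/w) prior on ρ,
  default width 1 (uniform), integrated by adaptive quadrature.
* All p-values are two-sided; a Bonferroni utility exists but is off by
  default in every report.

## Synthetic observers

An observer is (α₀, σ, λ, γ; δ, κ; base rates; hypothesis). Cohorts draw
α₀ ~ TN(0.5, 0.05), σ ~ TN(0.12, 0.03), δ ~ TN(0.08, 0.02),
κ ~ TN(0.5, 0.2) (truncated normals with type-respecting bounds), chosen to
give baseline PSEs near the morph midpoint, spreads that 144 trials resolve
to ~0.01, and aftereffects of a few morph-percent — the magnitudes typical
of facial-expression adaptation work. Protocol counts follow the design:
144 baseline trials, 144 adapted test trials per condition after 24
adaptation trials, 48 categorization trials per body context, 24 observers.

* **Categorization**: multinomial draws; in an incongruent pair context a
  fraction κ of the face-emotion probability mass moves to the body
  emotion (κ/2 for the perceptually more distant fear/sad contexts).
* **Adaptation**: responses are Bernoulli draws from the true psychometric
  function with PSE α₀ + s·δ_eff, where s = −1 for disgust adaptors and +1
  for anger adaptors (disgust adaptation lowers the PSE, making ambiguous
  morphs look angrier, hence positive aftereffects). Under `late`,
  δ_eff = δ in every context. Under `early`, δ_eff = δ(2q − 1) with q the
  probability the adaptor face is *perceived* as its physical emotion:
  q = 1 congruent, 1 − κ incongruent, 1 − κ/2 off-pair. q is defined from
  the bias construction, not from raw response rates, because baseline
  confusion (calling a clearly disgusted face angry 15% of the time) is
  response noise rather than a percept change; with full reversal (κ = 1)
  this yields an equal-magnitude opposite aftereffect and a
  congruent-incongruent contrast of 2δ. The linear percept weighting is the
  model's key free assumption — only the qualitative predictions are
  dictated by the hypotheses — and is the first thing to vary in
  sensitivity analyses. Body-only adaptors (blurred face) have δ_eff = 0.
* **Reproducibility**: one global seed fans out per observer and stream via
  numpy's seed-sequence lists, so cohorts are byte-identical under
  regeneration and stable under partial regeneration. The sham red-dot
  detection task present in the real protocol carries no information and is
  not simulated.

What the generator does *not* emulate: real observers' session-order and
day effects (the design counterbalances them; sessions here are
independent), sequential dependencies and RT structure, lapse-rate
heterogeneity, and any nonlinear mapping from categorization bias to
early-integration adaptation. Passing recovery tests therefore shows the
estimation chain is correct and well-calibrated, not that real data meet
these assumptions.

## Problem sizes and calibration outcomes

The test suite runs the study conditions at desk scale: 100 observers for
Psi recovery (median |α̂ − α| ≈ 0.011, vs the 0.02 tolerance), 500 datasets
× 100 bootstrap replicates for GOF calibration (false-exclusion rate ~0.05),
50 cohort replicates per hypothesis for discrimination, 2000 null cohorts
for type-I control. The analysis scripts use 10 discrimination replicates
for a readable summary.

One discrimination clause is knowingly not met and intentionally left
failing: demanding BF01 ≥ 3 in ≥ 80% of null (late-hypothesis) replicates
is incompatible with the directional JZS test itself. At n = 24 and scale
0.707, BF01 ≥ 3 requires t ≤ 0.518, an event of probability
P(T₂₃ ≤ 0.518) ≈ 0.695 under the null for *any* measurement-noise scale.
The BF implementation is validated separately against published directional
BF values and an independent quadrature oracle; the ~70% rate is a property
of the Bayes factor at this sample size, not an implementation defect.

## Known limitations

* The early-integration percept weighting is linear in κ by assumption.
* Slope values are internally consistent but not comparable to other
  toolboxes' slope parameterizations.
* The GOF screen's bootstrap p is conservative near deviance 0 by
  construction of the smoothed estimator.
* Psi grids bound the posterior: true PSEs outside [0, 1] or spreads
  outside [0.02, 0.5] would be projected onto the grid.
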