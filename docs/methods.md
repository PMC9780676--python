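# Methods

This note documents the models and procedures implemented in `fnirslat`,
the defaults they ship with, and what the synthetic cohorts do and do not
establish about real recordings.

## Synthetic cohorts

The generator emulates a home-based motor-task study: by default 11
participants, each performing 10 trials of 10 s fist squeezing followed
by 40 s rest, with a 30 s lead-in rest so filters settle, sampled at
5.4 Hz on the headband montage (16 long-path locations in 8 homotopic
pairs, 5 short-path channels).

**Latent structure.** Each participant draws a latent
upper-extremity impairment/function trait η ~ Student-t(15, 0, 1)
(scale 1, matching the SEM prior; at 15 DF the variance is 15/13).
Sub-traits for FM-12, SIS-Hand, and M1-LAT are ρ·η + √(1−ρ²)·ε with
default generative correlations 0.8, 0.85, and 0.44. Item responses use
a unit-variance normal propensity centred on the sub-trait against
per-item ordered cutpoints (FM-12: 12 items × 3 categories scored 0–2;
SIS-Hand: 5 items × 5 categories scored 1–5; cutpoint defaults span a
realistic difficulty range). The M1-LAT sub-trait feeds eight
per-pair location latents through loadings rising linearly from 0.3
(most medial) to 0.9 (most lateral), reflecting the lateral position of
the hand representation.

**Recordings.** The per-pair truth is mapped to µM/s laterality means
(0.02 µM/s common offset + 0.04 µM/s per unit location latent) and
injected as opposite-signed evoked-gain asymmetries around a 1 µM
double-gamma response (configurable peak, default 6 s) convolved with
the task boxcar; the per-trial gain jitter is Student-t with 8 DF and a
per-(participant, location) SD that is lognormal around 0.04 µM/s
(spread 0.3), because optode coupling and movement vary across people
and sites. Evoked ΔHb is −ΔHbO/3. One sinusoid per physiological band
(defaults: 1.1, 0.22, 0.095 Hz at 0.8, 0.4, 0.6 µM) is shared across
channels with per-channel delays drawn within ±0.2/±0.5/±1.0 s and
leaks into ΔHb at ratio 0.5 with a roughly quarter-period chromophore
lag — without that lag CBSI alone would remove systemic physiology
perfectly, which real data does not permit. Short channels carry full
physiology and 10% of the evoked gain. Concentrations pass through the
forward modified Beer–Lambert model (standard compiled extinction
coefficients; DPF 6) to optical density and are exponentiated onto
channel-specific baselines, with Gaussian OD sensor noise (SD 0.002)
and Poisson motion artifacts (0.6/min; exponential transients or steps,
~0.03 OD, channel-correlated).

**What the cohorts do not emulate:** non-sinusoidal/amplitude-modulated
physiology, optode-scalp coupling optics, hair and skin chromophores,
motor-imagery substitution on failed trials, missing items, and lesion
heterogeneity beyond side. Passing recovery tests therefore shows the
pipeline is a correct inverse of this forward model and that the SEM is
well calibrated under its own assumptions — not that the instrument or
model is valid for arbitrary real recordings.

## Preprocessing

Stages run in the order listed in the README. Design points:

- **TDDR** follows the published algorithm exactly (0.5 Hz split;
  iterated Tukey-biweight reweighting of the slow derivative;
  re-integration; fast component passed through). Consequences worth
  knowing: baseline steps are suppressed almost entirely, ~1 s
  transients only partially (their high-frequency content is preserved
  by design), and a strictly noise-free slow signal is flattened because
  the robust derivative spread is then zero — `run_pipeline`
  accepts `motion_correction=False` for such degenerate inputs.
- **Filters** are zero-phase order-4 Butterworth applied as second-order
  sections (numerically necessary at a 0.01 Hz edge on a 5.4 Hz series);
  zero phase protects slope estimates.
- **Delays** are estimated per band from short-path 850 nm optical
  densities (systemic physiology is what the short channels measure)
  against the across-channel mean (robust to one bad channel;
  a channel reference is available), searching ± one period of the band
  centre capped at ±2 s, with parabolic sub-sample refinement. Estimated
  delays are removed from the band-filtered latent-estimation inputs by
  linear interpolation with endpoint padding (padding avoids steps the
  motion stage would misread); a `shift_targets` flag additionally
  aligns the band latents to each target channel's own timing.
- **Latent common signals** are the leading eigencomponent of the
  standardized short-channel correlation matrix (a deterministic
  one-factor estimate), computed separately per chromophore and for each
  of the four permutations, sign-fixed to positive mean loading, and
  regressed out of all channels jointly (joint OLS is order-invariant;
  collinear columns are dropped by a rank-revealing solve).
- **mBLL** constants are configurable; absolute concentration scale is
  irrelevant because M1-LAT is a within-recording difference.
- **CBSI** uses the closed form x₀ = (x − αy)/2, α = sd(x)/sd(y); the
  implied corrected ΔHb is −x₀/α so the corrected pair correlation is
  −1 by identity.
- **Baseline correction** subtracts the onset-sample value on each
  [onset, next-onset) segment, so every epoch starts at exactly 0.

## Laterality

Task windows are half-open [onset, onset + 10 s) for sample-count
stability; slopes are OLS against time with origin at onset; M1-LAT is
contralesional minus ipsilesional per homotopic pair (ipsilesional =
lesion-side hemisphere). Swapping lesion side negates all values.
Missing pair members yield NaN, never silent zeros. Under this
convention a typically lateralized response is negative, and the
positive posterior correlation with the latent function trait in
recovery runs means better function ↔ higher (more contralesional-
shifted) values exactly as the raw difference defines them; any
interpretive sign flips belong to reporting, not to the statistic.

## The latent-trait SEM

Data enter as per-item ordinal responses and a trial × pair M1-LAT
matrix pre-scaled per pair by median and 1.4826×MAD (per-pair scaling
starts the location shift/scale parameters near (0, 1); a global mode
is available by scaling outside `ModelData`). The model is as in the
README; both DF parameters are scalars by default (the latent-trait DF
can be switched to per-participant via
`FitConfig(per_participant_latent_df=True)`).

Priors: influence parameters flat on their constraint interval (proper);
cutpoints induced-Dirichlet with unit concentration and anchor 0
(matching the zero-mean propensity scale; the density is then
proportional to the product of standard-normal densities at the
cutpoints); DF/30 ~ Beta(2, 2); N(0, 1) on mean-encoding parameters;
Weibull(shape 2, scale 1) on SD-encoding parameters. Sub-trait residual
SDs are √(1−ρ²) so sub-traits have unit marginal variance for any ρ.

**Sampler.** Blocked Gibbs with data augmentation:

- ordinal propensities: truncated-normal draws (Albert–Chib);
  cutpoints: per-item Metropolis moves on the propensity-marginalized
  ordinal likelihood with sequential truncated-normal proposals
  (adapted during warmup to ~30% acceptance, then frozen) — purely
  augmented cutpoint updates stall as participants accumulate;
- Student-t parts: gamma scale-mixture weights, refreshed immediately
  after each DF update (the DF moves use the mixture-collapsed density);
- latents, shifts, noise hyper mean: conjugate normal updates;
- influences, loadings, scales, DFs, hierarchy SD: univariate slice
  sampling on their constrained intervals;
- per-(participant, location) log-variances: random-walk Metropolis on
  the mixture-collapsed Student-t likelihood (step adapted to ~44%
  acceptance in warmup);
- two interweaving (ancillarity–sufficiency) passes per sweep: the
  location shift/scale pair is re-drawn holding the per-location means
  fixed, and the noise hyper mean/SD are re-drawn holding the
  standardized log-variances fixed — these break the centered-
  parameterization couplings that otherwise dominate the autocorrelation;
- the cheap ordinal/trait blocks are iterated twice per sweep.

Defaults are 4 chains × 1000 warmup + 1000 draws; all settings are in
`FitConfig`. Chains run sequentially from seeds spawned off one
`SeedSequence`, so a fixed seed reproduces every draw bit-for-bit.
Initialization is mildly jittered per chain; cutpoints start at normal
quantiles of the empirical category frequencies. A `prior_only` mode
detaches the data terms (every conditional falls back to its prior),
used to verify that e.g. the trial-DF posterior reproduces the scaled
Beta(2, 2) prior.

**Diagnostics.** `diagnose` computes rank-normalized split-rhat and tail
ESS with arviz over every stored parameter and requires zero
divergences, max rhat < 1.01, and tail ESS at or above a configurable
floor (default 100; the floor is a convention — no canonical value
exists). Gibbs transitions have no divergence mechanism, so the
divergence count is a pass-through that is zero for this backend; the
field exists so reports from gradient-based backends are comparable.
Single-chain posteriors are flagged unusable.

**Degenerate inputs.** Zero-MAD pairs abort prescaling with the pair
named; non-increasing cutpoints have −∞ prior density; flat ordinal
traits are handled by the truncated draws' clipping at machine-precision
tail mass.

## Problem sizes used in the checks

Parameter recovery runs 30 participants × 20 trials per cohort with
true ρ_M1LAT ∈ {−0.6, 0, +0.6}, 7 seeded replicates each, fit with
2 chains × (500 warmup + 500 draws); pooled 95% CrI coverage must be
≥ 90% and the null cohorts may exclude zero at most twice in seven.
Spatial-ordering recovery fits one such cohort and requires the mean
posterior loading of the four lateral pairs to exceed the medial four,
with a positive rank correlation across the eight pairs. End-to-end
determinism re-runs the orchestrated pipeline twice at 4 participants ×
6 trials and compares outputs byte-for-byte. These sizes were chosen so
the whole suite remains a desk-scale computation.

## Known limitations

- The latent-common "SEM" of the preprocessing chain is a deterministic
  one-factor eigen-estimate, chosen for testability; a full maximum-
  likelihood factor model would differ slightly in weighting.
- The Gibbs sampler mixes more slowly than a well-tuned Hamiltonian
  sampler on the same model; short runs can show rhat slightly above
  1.01 on cutpoints even when influence-parameter summaries are stable.
  Use more draws (or chains) when the diagnostics gate matters.
- At 11 participants the influence posteriors are wide; the package
  reports intervals rather than point estimates for a reason.
- The generator's physiological oscillations are single sinusoids per
  band; spectral-suppression results transfer to broadband physiology
  only qualitatively.
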