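# Methods

This note documents the statistical machinery, the synthetic-data model,
the numerical choices, and the known limitations of the `gazemind`
pipeline.

## Data model

A *dyad session* is 20 min of mother–infant free play seen through the
mother's head-mounted eye tracker, reduced to:

- a 1 Hz frame stream — per integer second: face present in view? pupils
  detected? gaze point (px)? face region (px polygon)? face-looking?
- a comment stream — onset (s) and category
  (`appropriate_mr` / `nonattuned_mr` / `other`) per comment.

Frames are anchored at integer seconds from session start. Raw 50 Hz gaze
is reduced to the grid by nearest-sample selection with a 0.5 s maximum gap
(ties go to the earlier sample); seconds without a usable sample count as
pupil-not-detected. Sessions losing more than 30% of frames to pupil
detection failure are flagged excludable (report-only; the caller decides).
Comment onsets stay real-valued; windows are anchored on onsets and
durations, if present in inputs, are ignored.

## Face-looking geometry

Pixels map to degrees per axis linearly: `x_deg = (x − w/2)·hfov/w` (95°
over 1920 px horizontally, 63° over 1080 px vertically). The gaze AOI is a
disc of radius 4° in *degree* space — an ellipse of ≈80.8 × 68.6 px
semi-axes in pixel space. A frame is face-looking iff the distance in
degree space from the gaze point to the face polygon (zero inside it) is at
most the radius; the face region is any coder- or detector-supplied simple
polygon (a bounding box is the 4-vertex case). Distance is to the region
boundary/interior, never to the centroid. Frames without face-and-pupil
never count as face-looking, and only face-and-pupil frames enter the
denominator of the face-looking tendency (and later the GLM trials). The
4° radius and the angle-space convention are configurable; manual coding
conventions that rendered the cursor on video may differ slightly at the
boundary, which is why the radius is exposed for sensitivity analysis.

## Inference

**Between dyads** — binomial GLM (logit link) of face-looking counts on
the MM score, fitted by IRLS (statsmodels), LRT of the slope on 1 df. The
model is intentionally the plain binomial GLM with no overdispersion
adjustment, mirroring the reported analysis. Note that real between-dyad
heterogeneity in looking propensity (SD ≈ 12.5 percentage points) makes
binomial trials of ~300 per dyad strongly overdispersed, so this LRT is
anticonservative as a test; the package reports it as specified and leaves
calibration-aware modeling to the user.

**Within dyads** — logistic random-intercept model of per-comment
coincidence on comment class (appropriate vs everything else; non-attuned
comments are pooled into "other"). The marginal likelihood integrates one
normal random intercept per mother; it factorizes over mothers and, within
a mother, depends on the data only through binomial counts per covariate
value. The implementation therefore aggregates to (group, x, n, k) cells:

- inner problem: per-group mode of the joint log-density by Newton
  iterations (strictly concave; vectorized across groups; tolerance 1e-11);
- Laplace approximation of each group's integral at the mode (default), or
  adaptive Gauss–Hermite quadrature centered/scaled at the mode
  (verification mode, ≥9 nodes; 15 by default);
- outer maximization over (β, σ) by L-BFGS-B with an analytic gradient
  (envelope theorem at the inner mode), σ bounded below at 1e-6; fits
  landing on the floor report σ = 0, a valid boundary estimate. Fits are
  accepted as converged when the optimizer succeeds or the projected
  gradient is < 1e-2.

The Bernoulli-level log-likelihood (no binomial coefficients) is reported,
matching what lme4's `glmer` returns for 0/1 data; the implementation
agrees with lme4 to ~1e-3 on coefficients, σ and log-likelihood (tested),
and its quadrature mode agrees with direct numerical integration to 1e-5.
LRTs use `χ² = 2Δll` on the difference in parameter count; the null model
retains the random intercept. Window boundaries are closed on both ends
for the overall indicator; the frame at exactly the onset belongs to the
"before" half (the convention is documented here because onsets are
real-valued and frames integer, so exact collisions are rare). Windows
truncated by session boundaries are kept.

**Halves contrast** — appropriate comments only, two rows per comment
(looked in [onset−w/2, onset] vs (onset, onset+w/2]), same GLMM machinery
with a half indicator, LRT on 1 df. Because the two halves of one comment
share the local face-presence state, the paired outcomes are positively
correlated beyond the dyad intercept; treating them as independent makes
this test mildly conservative.

**Randomization null** — B randomized datasets per study; each permutes a
mother's face-looking labels uniformly over her *eligible* (face ∧ pupil)
frames by default, or over all frames (`domain='all'`), preserving her
face-looking count exactly. Each dataset is refitted (warm-started from
the observed fit; non-converging refits are dropped and counted, with the
result flagged unreliable above 10% failures); the "95% CI" of the null is
the 2.5–97.5 percentile range of the null coefficients, and the empirical
p is `(1 + #{|β*| ≥ |β̂|})/(B_eff + 1)`. Per-dyad RNG streams are derived
from (master seed, dyad id, replicate), so results are reproducible and
invariant to session order. Effect size means the GLMM comment-class
coefficient on the log-odds scale.

**Design power** — the minimum n for the correlation test is computed by
upward search over a power function. Three formulations ship: `exact`
integrates the exact density of the sample correlation under bivariate
normality (hypergeometric-function form; validated against Monte-Carlo to
<0.01); `fisher` uses the z-transform; `nct` uses the noncentral-t
formulation of the correlation t-test, which is what the conventional
design figure of n = 37 at ρ = 0.432 comes from. The exact method is
slightly more demanding (n = 39 for the same query); the package treats
`nct` as the design-software convention and `exact` as the reference
computation.

## Synthetic studies

The generator emulates the marginal structure of a 40-dyad corpus:

| parameter | default | meaning |
|---|---|---|
| `n_dyads`, `duration` | 40, 1200 s | study size |
| `face_present_stationary` | 0.2941 | stationary P(face in view) |
| `face_dwell_mean` | 10 s | mean in-view dwell of the face Markov chain |
| `pupil_rate` | 0.9215 | i.i.d. P(pupils detected) |
| `looking_mean`, `looking_sd` | 0.4453, 0.125 | mean/SD of conditional face-looking across dyads (proportion scale) |
| `comment_rate`, `comment_count_sd` | 343.3/1200 s⁻¹, 102.68 | comment volume, gamma-mixed Poisson |
| `p_appropriate`, `appropriate_sd` | 0.0577, 0.0307 | MM score mean/SD across dyads |
| `p_nonattuned` | 0.0041 | non-attuned proportion |
| `beta_couple`, `couple_window`, `couple_side` | 0, 5 s, both | within-window log-odds bump near appropriate onsets |
| `rho_link` | 0 | corr(latent MM propensity, latent looking propensity) |

Per-dyad looking intercepts and MM propensities are logit-normal; the
(μ, σ) of each are calibrated numerically (Gauss–Hermite moments + root
finding) so the *proportion-scale* mean and SD hit their targets. The face
Markov chain starts from its stationary law, so time-averages are
unbiased; the 10 s dwell is a free choice (within-dyad autocorrelation of
face presence is not otherwise constrained by the descriptives). Comment
onsets are uniform given a gamma-mixed Poisson count whose mixing matches
the observed count SD. The coupling mechanism is deliberately minimal — a
log-odds bump on eligible frames within `couple_window/2` of an
appropriate-comment onset — and encodes no claim about causal direction
(monitoring vs signaling). With `with_geometry=True` the generator also
synthesizes gaze points and face boxes exactly consistent with the flags,
so the geometric classifier can be validated end-to-end.

What the generator does **not** emulate: gaze kinematics (saccades,
fixations), autocorrelated face-looking beyond the coupling bump, infant
behavior, or any semantic content. Two consequences matter for
interpreting green tests. First, because generated face-looking is
conditionally independent across frames, label permutation is a perfectly
calibrated null here; on real gaze streams with dwell autocorrelation, a
label-permutation null is anticonservative, and a block or circular-shift
null (not implemented) would be the cautious alternative. Second, passing
calibration tests says the pipeline recovers the structure this generator
produces, not that real data meet these assumptions.

### Saturation of the window-level effect

The coincidence outcome is *any* face-looking among the k eligible frames
of a window. Its class contrast on the log-odds scale is not the
frame-level bump: windows with k = 0 are failures for both classes
(dilution), and for k ≈ 5–6 the baseline probability 1−(1−p)^k is already
near 1 (saturation). At default rates, a frame-level coupling of 1.0
log-odds induces a window-level comment-class coefficient of only ≈0.21,
an attenuation that no estimator of the window-level model can undo. The
GLMM estimate is consistent for the window-level contrast (its mean across
simulated studies matches the large-study value), but it does not and
cannot recover `beta_couple` itself; simulation studies planning to
"recover the coupling" should target the window-level estimand or code
coincidence at the frame level instead.

## Numerical conventions and degenerate inputs

- Downsampling tie-break: earlier sample; output length always equals the
  integer duration; empty streams yield all-missing entries, not errors.
- An exactly-1 s silence does not split a comment (the rule is strictly
  "more than").
- Zero comments make the MM score undefined (error); dyads with no
  eligible frames are excluded from the between-dyad model and flagged.
- Perfect separation in the GLM and non-convergence in the GLMM are
  reported via `converged=False`; LRTs refuse unconverged fits.
- Paired t with zero-variance differences reports ±∞ (p = 0) or 0 (p = 1);
  Cohen's kappa on two constant identical coders is an error.
- All reported p-values are two-sided; empirical p-values use the
  add-one convention and can never be 0.

## Problem sizes used in the test suite

Unit tests run on small fixtures (≤10 dyads, ≤600 s). Calibration and
power checks in `tests/test_acceptance.py` use the default study scale —
40 dyads × 1200 s — with 100–200 simulated studies per check and B = 200
shuffle replicates, sizes at which the Monte-Carlo error of the checked
rates is a small fraction of the acceptance bands.
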