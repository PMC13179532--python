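# Methods

This note documents the models, parameter choices and numerical details
behind `soundturn`, and what the synthetic data can and cannot establish.

## 1. Analysis model

### Per-trial feature extraction

Each trial contributes a single 55-feature frame, the one nearest
`onset + 2 s`. The matching tolerance is half the median frame interval
(for 30 Hz video, ±16.7 ms); if the nearest frame is further away the trial
is *invalid* and excluded (this is a value, not an error — invalid trials
are counted and reported). Equidistant frames resolve to the earlier one.
The 2-s offset is justified empirically by the group-mean |yaw| timecourse,
which peaks 2–3 s after onset (`mean_abs_yaw_timecourse`, analysis 02).

### Feature sets

`head_rot` (yaw, pitch), `gaze_left` (left-eye world *x*, *y*),
`gaze_angle` (both-eye horizontal/vertical angle), `pca2` (top-2 PCA of all
55 features). For PCA the features are z-scored first — they mix radians,
millimetres and dimensionless activations, and unscaled PCA would be
dominated by head position — and the projection is fitted **on the toddler
training split only**, then applied to validation data; both choices are
configuration options (`pca_standardize`, and the fit is wired structurally
into the pipeline). Constant features get unit scale with a warning.
Component signs are fixed (largest-magnitude loading positive) so results
are reproducible. Whether the original analysis standardised, or fitted on
training only, is unknown; leakage avoidance decided both defaults here.

### Mixture fitting protocol

Three bivariate Gaussians with full covariances, fitted by EM
(log-sum-exp E-step; closed-form weighted M-step). The protocol:

1. **Exhaustive initialisation** — 5 starts; each draws 3 distinct data
   points as means, pooled covariance, uniform weights, and runs EM to the
   short tolerance (cap 200 iterations); highest log-likelihood wins.
   Judging candidates after convergence rather than after a fixed burn-in
   matters: burn-in log-likelihood order does not predict converged order,
   and a 10-iteration cut-off mis-selects basins often enough to break
   parameter recovery on well-separated mixtures.
2. **Short EM** to relative log-likelihood tolerance 10⁻⁴ (the tolerance is
   |Δℓ| ≤ 10⁻⁴·|ℓ| between successive iterations).
3. **Sign-opposition criterion** on all six mean coordinates:
   accept iff `m < 0 < M`, `M ≥ |m|/2`, `|m| ≥ M/2`. Applied literally to
   all three clusters (a switch excludes the smallest-norm cluster);
   disabled for `pca2`. On failure, restart from step 1 with seed
   `base_seed + restart`, up to 100 times; if no restart satisfies it, the
   highest-likelihood solution is used and flagged.
4. **Final EM** to relative tolerance 10⁻⁶, max 1000 iterations.

Numerical safeguards: covariance eigenvalues are floored at
`10⁻⁸ × mean data variance` (warning on trigger), weights at 10⁻³⁰⁰ inside
logs. Everything is driven by one integer seed; fits are bit-for-bit
reproducible, and models serialise to JSON.

"Best performing" among starts is taken as the plain data log-likelihood
(not a classification likelihood); this was an open choice.

### Labelling and statistics

*Centre* = smallest-norm mean (ties within 10⁻⁹ are an error). The decision
axis is the axis with the largest absolute difference between the two
lateral means. Left/right assignment maximises training agreement between
predicted class and speaker side; exact ties fall back to the sign
convention (negative axis coordinate → left; positive yaw means the head
turned toward the right speaker from the child's perspective — readers take
`flip_yaw` for mirrored camera frames). Prediction is argmax posterior
responsibility.

The *correct-decision rate* (the study's "specificity", its "sensitivity"
when averaged across feature sets) is `n_correct / n_decisions` over
non-centre predictions; with no decisions it is undefined and reported as
such. The binomial test is the exact upper tail
P(X ≥ k | n, ½) (scipy `binom.sf`; the test suite checks it against full
2ⁿ enumeration). No multiple-testing correction is applied — raw per-
feature-set p-values are reported. Reported percentages round to integers
and p-values to 3 significant figures. Head/gaze combination: a trial's
decision comes from whichever source decided; on conflict the gaze wins by
default (`conflict_policy`), and conflicts are counted.

Two published p-values do not reproduce from the published counts: the
exact tail for 44-of-76 is 0.103 (reported as 0.07) and for 32-of-48 is
0.0147 (reported as < 0.001). The package reports the exact tails.

### Train/validation split

The published split counts trials (226 + 56 toddler trials), so the default
is a seeded trial-level 80/20 split of valid toddler trials
(`n_train = round(0.8 n)`); a participant-level split is available
(`split_unit`). Infant trials are never trainable — this is structural, not
configurable.

## 2. Synthetic-session generator

The generator emulates the study conditions: 28 infants + 30 toddlers,
10 trials each (each of 5 stimuli twice, shuffled; side i.i.d.; onset gaps
6 s + Exp(4 s), so the ISI floor is respected and sessions last ~100 s),
30 Hz frames over [onset − 1 s, onset + 5 s].

**Response model.** A trial is an overt responder with probability
`responder_prob` (default 0.25 for both groups, consistent with reported
unreinforced head-turn rates of 25–32% in this age range); a response is
toward the speaker side with probability `correct_side_prob` (0.8 toddler,
0.65 infant). Head yaw follows a *turn-and-hold* envelope: a fast (~0.3 s)
turn away from the resting angle to the target, a hold, and a return, with
total support 2.7 s centred on a per-trial latency ~ N(2.5 s, 0.3 s)
(clipped to [1.5, 4] s):

yaw(t) = b·(1 − w(t)) + s·A·w(t) + ε(t),

where `b` is the resting yaw, `s = ±1` the responded side, `A` the
per-trial amplitude (`peak_yaw_rad` × clipped-normal jitter, CV 0.2), and
`w` the Tukey envelope. Individual head-orienting movements are fast; the
smooth unimodal group-mean |yaw| curve peaking 2–3 s post onset emerges
from the latency spread, and its peak height equals `peak_yaw_rad` for
responding trials (0.30 rad ≈ 17° toddler, 0.21 rad ≈ 12° infant). An
earlier slow per-trial raised-cosine bump was abandoned: at a fixed 2-s
extraction frame it smears trials along a baseline–peak continuum instead
of producing the left/centre/right geometry the clustering assumes.

**Resting yaw** is zero-mean Gaussian with E|b| = `baseline_yaw_rad`
(default 10°, i.e. σ = 10°·√(π/2)): the children fixate the centring screen
on average, with a mean absolute off-centre angle of 10°.

**Gaze** angles follow yaw with correlation `gaze_head_corr` (0.8) plus
independent fixational noise; per-eye world direction vectors are unit
vectors built from the angles with small per-eye jitter. **AU and
head-shape channels** are stationary noise around fixed profiles (an
optional `facial_reaction` mode adds stimulus-locked bumps to brow/lid/jaw
AUs). With probability `missing_frame_prob` (default 20/580, matching the
study's 20 missing cases out of 580) the frame nearest onset + 2 s is
dropped.

### What the generator does not emulate

* The real children's tight central fixation: with E|resting yaw| = 10°
  comparable to the response amplitudes, the synthetic lateral tails of the
  resting distribution draw more (and noisier) left/right decisions than
  the study's ~7–27% decision rates. Default-condition runs therefore show
  lower validation specificity than the published tables; the pipeline's
  discriminative behaviour is instead certified under the perfect-responder
  conditions (below).
* Habituation across the session, reinforcement, test-assistant
  re-centring, caregiver interference, and any stimulus-type dependence of
  the response.
* Facial-identity structure — AU channels are noise by default, so `pca2`
  on synthetic data carries less information than on real faces.

Consequently, green synthetic tests certify the *machinery* (extraction,
EM protocol, labelling, statistics) and the generator's stated structure,
not clinical performance on real recordings.

## 3. Test and acceptance problem sizes

The suite exercises: schedule invariants over 1000 seeds; Monte-Carlo
response amplitude at 500 trials; EM oracles (posterior vs direct density,
10⁻¹²; log-likelihood vs an independent mixture implementation at identical
parameters, 10⁻⁶); binomial vs 2ⁿ enumeration up to n = 20; parameter
recovery of a 3-component mixture at n = 900 over 20 seeds (≥ 19 must
recover means within 0.03 — one seed's five starts can all land in a merged
basin that narrowly passes the sign criterion, which is accepted
stochastic behaviour); and 20 full end-to-end cohorts (58 children each)
with `responder_prob = correct_side_prob = 1`, `peak_yaw_rad = 0.5`,
`noise_sd = 0.02`, requiring median combined head+gaze validation
specificity ≥ 0.95 and decision rate ≥ 0.9. The acceptance script uses the
same sizes and runs in ~1–2 minutes on one CPU.
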