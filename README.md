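# soundturn

Unsupervised detection of the **direction of infant and toddler behavioural
reactions to lateralized sounds** from non-identifiable, video-derived facial
features.

Paediatric behavioural hearing tests (behavioural observation audiometry,
visual reinforcement audiometry) depend on a trained human observer judging
subtle reactions — eye shifts, head turns, facial movements — after each
sound. This package implements, end to end, a machine-analysis alternative:
a camera's per-frame OpenFace-style feature table (35 facial action units,
8 gaze features, 6 head-pose and 6 head-shape parameters — 55 standardised
scalars per frame, none of them identity-bearing) is reduced to one analysis
frame per trial, 2 s after sound onset, and clustered **without labels** into
three groups interpreted as *reaction to the left*, *reaction to the right*,
and *no decision*. The cluster labelling is then validated against the known
speaker side of each presentation.

Because no public recordings exist for this paradigm, the package includes a
first-class synthetic-session generator (`soundturn.synth`) that emulates the
study design: 58 children (28 infants aged 2–5 months, 30 toddlers aged 2–4
years), 10 trials each (five stimuli — 0.5/1/2 kHz warble tones, "ba", "da"
— twice each in random order, random side, inter-stimulus interval ≥ 6 s),
head-turn responses peaking 2–3 s post onset, gaze correlated with head yaw,
and occasional missing frames at the extraction point.

## The model

For each of four 2-D feature sets —

1. `head_rot` — head yaw and pitch (rad),
2. `gaze_left` — left-eye gaze direction (world *x*, *y*),
3. `gaze_angle` — gaze angles averaged over both eyes,
4. `pca2` — first two principal components of all 55 z-scored features
   (fitted on the training split only),

— the trial points *x*ᵢ ∈ ℝ² are modelled as a three-component Gaussian
mixture

p(x) = Σₖ₌₁³ πₖ 𝒩(x; μₖ, Σₖ),  full covariances Σₖ,

fitted by expectation maximisation with a replicability protocol: 5 random
starts run to a loose tolerance, best log-likelihood kept; short EM to
relative tolerance 10⁻⁴; then a **sign-opposition restart criterion** — with
M = max and m = min over all six mean coordinates, accept only if
m < 0 < M, M ≥ |m|/2 and |m| ≥ M/2 (two clusters must sit on opposite sides
of the origin, in whatever dimension), else restart, up to 100 times (the
criterion is skipped for `pca2`); finally EM to tolerance 10⁻⁶.

The cluster with the smallest-norm mean is labelled *centre* (no decision);
the two lateral clusters take the left/right assignment that maximises
agreement with the speaker side over the training trials. Per feature set
and validation split the package reports a 3 (class) × 2 (speaker side)
contingency table, the correct-decision rate ("specificity": fraction of
non-centre decisions matching the side), an exact one-sided binomial test
P(X ≥ k | n, ½), cross-feature-set averages, and a head+gaze decision
combination. Training always uses toddler trials only (80% of them); the
remaining toddlers and **all** infants are validation.

## Worked example

The recorded prediction tables of the original study are shipped in
`soundturn.reference_counts`; all of its validation statistics rederive from
those counts:

```bash
$ python analysis/05_reference_statistics.py
training: average correct-decision rate 84%
validation_toddler: average correct-decision rate 96%
validation_infant: average correct-decision rate 68%
            split feature_set  n_trials  n_decisions  n_correct  specificity_pct  p_one_sided
validation_infant    head_rot       278           76         44             57.9     0.103368
validation_infant   gaze_left       278           20         16             80.0     0.005909
validation_infant  gaze_angle       278           48         32             66.7     0.014652
validation_infant        pca2       278           38         25             65.8     0.036476
```

Reading: of the 278 infant validation trials, the head-rotation clustering
made 76 left/right decisions of which 44 (57.9%) matched the speaker side;
left-eye gaze decided only 20 trials but got 16 right (80%, exact one-sided
binomial p = 0.0059 against guessing). Averaged over the four feature sets
the correct-decision rate is 68% for infants and 96% for held-out toddlers.

The same pipeline runs end to end on synthetic sessions:

```bash
$ python analysis/03_fit_and_validate.py
568 valid of 580 trials; splits {'training': 234, 'validation_toddler': 59, 'validation_infant': 275}
head_rot   infant validation: specificity 55% (129/235), p = 0.0755, decision rate 0.85, restarts 0
...
```

(the synthetic cohort is noisier than the real one — see
`docs/methods.md` for what the generator does and does not emulate), and a
fully scripted variant is available as `soundturn run --seed 1 --out out/`.

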