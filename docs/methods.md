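# Methods

This note documents the models and estimators implemented in `surgskill`,
the choices made where the procedure admitted more than one reading, and
what the synthetic-data validation does and does not establish.

## EEG pre-processing

The chain is fixed: common average reference → 60 Hz notch (IIR, quality
factor Q = 30) → 0.2 Hz Butterworth high-pass (4th order, 24 dB/octave) →
amplitude-threshold artifact flagging (default 500 µV on 1-s windows) →
Hjorth surface Laplacian. All filters are applied forward–backward and are
therefore zero-phase. The nominal acquisition band-pass extends to the
Nyquist frequency of the 500 Hz recording, so only its low edge is
realizable; together with the notch it preserves every analysis band
(≤ 65 Hz). The Laplacian subtracts from each channel the mean of its k = 4
nearest montage neighbours (unit-sphere Euclidean distance); it was chosen
over spherical-spline current-source density for transparency — its output
on a known source configuration can be written down by hand. The packaged
montage takes standard 10-05 positions projected to the unit sphere; FP3 and
FP4 are vendor-specific labels interpolated between their neighbours
(Fp1/AF3 and Fp2/AF4). Channels F8, POz, AF4, AF8, F6, FC3, M1, M2 are
excluded at load time (poor signal quality in the recording set-up this
package models).

## Coherence networks

Edges are band-averaged **magnitude coherence** (not squared; the squared
variant is behind a flag). Welch cross-spectra use Hann tapers with 50%
overlap and mean detrending; the implementation is vectorized over all
channel pairs and agrees with `scipy.signal.csd`/`welch` to machine
precision. Band averaging uses a closed interval on both edges, so a bin at
8 Hz contributes to both theta and alpha; the rule is applied uniformly and
documented so results are reproducible. Whole-recording adjacencies use 1-s
Welch segments; per-window adjacencies (1-s windows) use 250-sample
segments, i.e. 2 Hz resolution and three segments per window — the maximum
segment count that still resolves theta with three bins.

Two estimator properties matter downstream and are documented rather than
hidden. First, the magnitude-coherence estimator is positively biased at low
true coherence (≈ √(π/4L) for L independent segments at zero coherence), so
between-community entries of estimated adjacencies sit above their planted
values at short record lengths; the planting tests therefore check the
quantitative ±0.05 contract in the wide bands (beta, gamma), where many
in-band bins keep the bias small, and the ordering contract everywhere.
Second, per-window estimates in theta/alpha rest on ~9 strongly correlated
looks (3 bins × 3 segments) and are intrinsically noisy; see Flexibility
below.

## Search information

For an ordered pair (i, j), the shortest path is computed on edge lengths
1/w (a −log w transform is available). The walker's cost is
`SI(i→j) = −log₂ ∏ w_uv / s_u` over the path's steps, where `s_u` is node
strength; this is the memoryless variant (no path-memory correction). A
channel's value is the mean over all reachable targets; disconnected pairs
are excluded with a warning and isolated nodes yield a flagged missing
value. Shortest-path ties are broken deterministically: walking back from
the target, the smallest predecessor index is chosen, which selects the
lexicographically smallest reversed path. The implementation is verified
against a brute-force oracle that enumerates all simple paths on graphs of
up to 8 nodes.

## Community detection and temporal flexibility

Per-window partitions maximize Newman–Girvan modularity with the C-level
Louvain implementation of `igraph`, wrapped so that node order is shuffled
by an explicit seed (the shuffle, not library internals, carries the
stochasticity; runs are exactly reproducible). A **consensus partition**
repeats Louvain (100 times in production, fewer in tests), forms the
co-assignment agreement matrix, zeroes entries below a null threshold — the
maximum agreement obtained after independently permuting each run's labels
over nodes, which preserves community sizes — re-clusters the thresholded
matrix, and iterates until all runs agree.

**Flexibility** of a channel is the fraction of consecutive windows in
which its community assignment changes. The defining equation in the
toolbox convention counts changes (high value = frequent switching); the
implementation follows that interpretation. Within a recording, detected
community labels are canonicalized by first occurrence, so stable structure
yields stable labels and near-zero flexibility.

A caveat that shapes the validation: community labels from *independent*
per-window detection are identifiable only up to permutation, so no
labelling convention can register a planted schedule in which all channels
swap oscillator identities simultaneously (co-membership — the only
observable — is unchanged). Ground-truth recovery tests therefore align
each window's detected partition to the planted assignment by majority
overlap (`align_partition`) before applying the flexibility function. Under
that alignment, recovery at 20-s recordings with 10 consensus repetitions
is exact in beta and gamma (static schedules → 0.00, per-window switching
→ 1.00 for every Brodmann-area feature) and accurate to the band mean in
theta and alpha (static ≈ 0.01–0.04), where the per-window estimator noise
described above occasionally splits a true community.

## Oculometrics

A centered 3-point moving average is applied per eye over valid samples
only; invalid samples stay invalid, and smoothed gaze vectors are
re-normalized. Angular velocity is the angle between consecutive gaze unit
vectors divided by the sampling interval; the I-VT rule labels samples
below 30 deg/s fixations and at-or-above saccades (the boundary goes to
saccade, since fixations are defined by being *below* threshold).
Fixation/saccade rates divide by the total number of recorded samples,
including invalid ones, per the feature definitions; a valid-only
denominator is available because blinks otherwise deflate the rates, and
the four direction-change rates share the same total-sample denominator.
Pupil entropy uses 16 equal-width bins spanning each eye's valid range
(deterministic and scale-free; the count is configurable and logged).
"Direction change" is a sign reversal of the first difference of the gaze
x (horizontal) or y (vertical) component, zero steps skipped. Trajectory
length sums Euclidean distances between consecutive valid 3-D pupil
positions, bridging blink gaps directly (logged). Per-eye features are
reported under dominant/nondominant names; velocities are computed per eye
and the rates use the dominant eye. Subject-wise standardization z-scores
each feature within subject × task using the population SD (exact
mean-0/SD-1 contract; sample SD behind a flag); both EEG and gaze feature
families are standardized by default, each scope configurable.

## Performance and learning-rate models

The performance model is `score = β₀ + Σ β_k x_k + u_subject + ε` with
`u ~ N(0, σ_u²)`, fitted by maximum likelihood. The fitter profiles the
variance ratio λ = σ_u²/σ_e²: for fixed λ the GLS coefficients and residual
variance are closed-form, leaving a one-dimensional likelihood
maximization. It reproduces `statsmodels` MixedLM (ML) to optimizer
tolerance — the test suite asserts agreement of coefficients, standard
errors, variances and log-likelihood — while running two orders of
magnitude faster, which the selection loop (thousands of refits) requires.
Fixed effects are reported with Wald z-tests; the random effect with a
likelihood-ratio test against OLS using the 50:50 χ²₀/χ²₁ boundary mixture.
In-sample fit statistics (Efron pseudo-R², MAE, RMSE) use subject-specific
(BLUP-shifted) predictions.

**Forward selection with grouped cross-validation.** Folds partition
subjects, so all attempts of a subject share a fold and selection is not
driven by individual subjects. Within a fold's training set, candidates are
scored simultaneously on a fixed λ grid via a Schur-complement update of
the GLS normal equations (the incumbent model is then refit exactly); at
each step the feature minimizing in-sample BLUP RMSE enters among those
passing the entry test, stopping when none passes or at five predictors.
Features selected in ≥ 2 of the 7 folds form the final model, fitted on all
data. The entry test is the package's own design (the procedure it models
does not state one): because each step effectively tests the best of K ≈
180 candidates, the threshold is Bonferroni-adjusted (α/K) and uses a
t reference with df-corrected residual variance — the plain Wald-z-at-α
rule admits a spurious predictor from a pure-noise pool in essentially
every replicate, defeating the purpose of the two-fold rule. Under the
default rule, synthetic cohorts (26 subjects, 180 features) give 100%
power for a strong planted effect and an empty selection on pure noise in
roughly 90–95% of replicates; the unadjusted rule remains available
(`entry_adjust="none"`).

The learning rate is the OLS slope of score on 1-based attempt index
(defined for ≥ 2 attempts). The learning-rate model is OLS of the slope on
forward-selected first-attempt features, with the unstandardized baseline
(first-attempt) score always included and age a candidate; the same
Bonferroni entry rule applies.

## Synthetic cohorts

The generator's defaults mirror the study layout this package models:
26 subjects whose demographics, dominant eye/hand, experience hours and
per-task attempt counts (totalling 61, 66 and 66 attempts for the three
tasks) are fixed package data; scores around a 65-point intercept with
σ_u = 5, σ_e = 5, learning-rate slopes drawn N(2, 1.5²) points/attempt, and
planted standardized-feature coefficients {pupil diameter (nondominant)
−8.13, saccade rate −5.87, BA-18 beta flexibility +0.52}.

*EEG*: each channel sums four band-limited unit-variance components
(4th-order Butterworth band-pass of white noise per band). Within a
community, channels share an oscillator; mixing weights are the closed-form
solution for target coherence — with `x_i = ±(√b·u + √(w−b)·s_c) +
√(1−w)·n_i`, expected magnitude coherence is `w` within and `b` between
communities. The per-channel random sign models source orientation:
magnitude coherence is sign-invariant, but signed sources survive the
common average reference and the Laplacian, which would cancel an identical
shared signal outright. Community membership switches at scheduled 1-s
boundaries, making ground-truth flexibility exact. Amplitudes are 10 µV per
band component; no 1/f background or forward head model is attempted, so
the generator validates the estimators, not physiological realism.

*Gaze*: alternating fixation/saccade segments with gamma-distributed
durations (means 0.25 s and 0.06 s — typical fixation and saccade scales;
at 50 Hz saccades span 1–4 samples, which is why 3-point smoothing smears
their onsets, and why classifier-recovery checks run on the unsmoothed
signal). Fixations jitter ≈ 5 deg/s with a centering pull; saccades fly at
≈ 175 deg/s toward random targets within ±12°. Pupil diameter follows a
stationary AR(1) (φ = 0.9, σ = 0.05 mm) around a per-eye mean that is
shifted by the attempt's latent pupil feature (0.3 mm per SD), coupling the
score model to actually extractable features; pupil positions drift as a
mean-reverting walk. Blinks (Poisson, 0.1/s, 150 ms) mark both eyes invalid
with NaN sentinels — downstream code must honour validity flags, and the
containers enforce it.

*Scores*: each attempt draws a latent 180-vector of standardized features
z ~ N(0, 1) (recorded in the ground-truth ledger); the score adds the
planted β·z, the subject intercept, attempt × learning-rate and residual
noise, clipped to [0, 100] with clipping logged. Statistical-recovery tests
run on the latent table, which *is* the model's design matrix; EEG features
are not coupled to scores, so full-pipeline model fits on extracted
features are smoke/determinism checks, not effect-recovery checks.

All randomness flows from one seed through a keyed `SeedSequence` hierarchy
(stage, subject, task, attempt, band, window), so identical configurations
reproduce datasets bit for bit and any single recording or window can be
re-run in isolation.

## Validation scales and limitations

Test and acceptance runs use reduced scales chosen as the package's own
operating points: 20-s recordings and 10 consensus repetitions for
community/flexibility recovery, 50 synthetic cohorts for coverage and
selection studies, 2–5-s recordings for structural contracts. Production
defaults (100 repetitions, full durations) change runtime, not code paths.
Known limitations: the mixed model supports a single random intercept (no
random slopes); per-window coherence in narrow bands is noisy by
construction at 1-s windows; the generator's planted effects bypass the
EEG feature chain; and nonlinear learning curves are out of scope — the
learning rate is a straight-line slope.
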