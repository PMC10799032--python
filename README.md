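# surgskill

Objective evaluation of robot-assisted surgery (RAS) skill and learning rate
from EEG functional brain networks and eye tracking.

Trainees practicing on a surgical simulator receive a performance score
(0–100) per attempt. `surgskill` asks which physiological markers track that
score and how fast a trainee improves. It implements a complete, tested
analysis pipeline:

- **EEG pre-processing** — common average reference, 60 Hz notch, 0.2 Hz
  high-pass (24 dB/octave), amplitude-based artifact flagging, and a Hjorth
  nearest-neighbour surface Laplacian to curb volume conduction.
- **Functional networks** — magnitude coherence
  `|S_xy(f)| / sqrt(S_xx(f) S_yy(f))` between all 116 channel pairs, averaged
  over theta (4–8), alpha (8–12), beta (13–35) and gamma (35–65 Hz), as a
  whole-recording adjacency Γ and as a stack of per-1-s-window adjacencies.
- **Network features** — *search information*
  `SI(i→j) = −log₂ ∏ w_uv / s_u` along the shortest path (bits a random
  walker needs to follow it), and *temporal flexibility*
  `f_i = (#{t : A_{i,t} ≠ A_{i,t+1}}) / (T−1)`, where per-window community
  assignments `A` come from consensus clustering over repeated Louvain
  modularity maximization against a label-permutation null. Channel values
  are averaged within 21 Brodmann areas × 4 bands → **168 EEG features**.
- **Oculometrics** — 3-point smoothing, I-VT fixation/saccade classification
  at 30 deg/s, and **12 features**: fixation/saccade rates, per-eye mean and
  Shannon entropy of pupil diameter, horizontal/vertical gaze-direction
  change rates, and 3-D pupil trajectory length, with subject-wise
  standardization `(X − µ)/σ`.
- **Models** — a linear random-intercept model
  `score = β₀ + Σ β_k x_k + u_subject + ε` fitted by maximum likelihood, with
  predictor screening by 7-fold subject-grouped cross-validated forward
  selection (features kept when selected in ≥ 2 folds); Efron's pseudo-R²,
  MAE and RMSE; per-subject learning rate as the OLS slope of score on
  attempt index, modelled by forward-selected OLS on first-attempt features
  with the baseline score always included.
- **Synthetic cohorts** — a first-class generator that plants known
  community structure and coherence levels into band-limited EEG, known
  fixation/saccade structure and AR(1) pupil dynamics into gaze, and known
  regression coefficients, random-intercept variance and learning-rate
  slopes into scores, so every stage is validated against ground truth.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from surgskill import (SimulationConfig, generate_cohort, preprocess,
                       extract_eeg_features, extract_gaze_features,
                       fit_random_intercept)

cfg = SimulationConfig(seed=0, eeg_duration_s=10.0)   # 26-subject cohort
cohort = generate_cohort(cfg)

rec = preprocess(cohort.eeg(1, "Tubes", 1))
eeg_feats = extract_eeg_features(rec, n_consensus=10, seed=0)   # 168 values
gaze_feats = extract_gaze_features(cohort.gaze(1, "Tubes", 1))  # 12 values

table = cohort.feature_frame().xs("Tubes", level="task")
fit = fit_random_intercept(table["score"], table[list(cfg.true_betas)],
                           table.index.get_level_values("subject"))
print(fit.params.round(3))
print(f"n = {fit.n}; pseudo R^2 = {fit.pseudo_r2:.2f}; "
      f"MAE = {fit.mae:.2f}; RMSE = {fit.rmse:.2f}; "
      f"random-effect p = {fit.random_effect_pvalue:.3f}")
```

prints

```
                                estimate     se      p
intercept                         65.915  1.100  0.000
avg_pupil_diameter_nondominant    -6.879  0.843  0.000
rate_of_saccade                   -5.538  0.920  0.000
flexibility_ba18_beta              0.810  0.759  0.286
n = 61; pseudo R^2 = 0.80; MAE = 4.35; RMSE = 5.59; random-effect p = 0.044
```

The cohort plants coefficients −8.13 (nondominant pupil diameter), −5.87
(saccade rate) and 0.52 (flexibility in BA 18, beta band) on standardized
features, an intercept of 65 and a subject-level random intercept; the
fitted estimates recover the planted pupil and saccade effects well within
two standard errors on 61 attempts, the small flexibility effect is (as
expected at this sample size) not individually significant, and the
random-intercept likelihood-ratio test detects the subject effect
(p = 0.044).

## Command line

```bash
surgskill simulate --config config.yaml --out runs/sim
surgskill run --config config.yaml --out runs/full      # simulate → report
surgskill features eeg  --eeg eeg.csv --out feats.csv
surgskill features gaze --gaze gaze.csv --out gfeats.csv
surgskill validate --eeg eeg.csv --gaze gaze.csv
```

`run` writes the attempt table, the 180-column feature table (raw and
subject-wise standardized), per-task performance and learning-rate model
summaries, correlation and residual reports, and a manifest whose checksum
makes the run reproducible bit for bit.

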