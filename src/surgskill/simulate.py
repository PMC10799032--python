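"""Synthetic surgical-training cohorts with known ground truth.

Every downstream stage is exercised against data generated here: band-limited
EEG with planted, time-varying community structure and controlled pairwise
coherence; fixation/saccade-alternating gaze with AR(1) pupil dynamics and
blink gaps; and performance scores from a linear random-intercept model with
known coefficients and per-subject learning-rate slopes. All randomness flows
from a single seed through a keyed generator hierarchy, so an identical
configuration reproduces the dataset bit for bit.

EEG coherence planting: within a community, channels mix a shared band-limited
oscillator with independent channel noise. For unit-variance components
x_i = sqrt(b)*u + sqrt(w-b)*s_c + sqrt(1-w)*n_i, the expected magnitude
coherence is w within a community and b across communities (the closed form
for shared-signal-plus-noise mixtures), so the generator solves for the mixing
weights analytically. Community membership switches at scheduled 1-s window
boundaries, which makes ground-truth flexibility exact.

Scores: score = intercept + subject effect + sum_k beta_k * z_k +
attempt * learning_rate + noise, clipped to [0, 100] (clipping logged). The
z_k are latent subject-wise-standardized feature values drawn N(0, 1) per
attempt and recorded in the ground-truth ledger; the gaze generator couples
its pupil-diameter means to the pupil latents so the planted pupil effects
survive actual feature extraction.

The packaged cohort layout (26 subjects; per-task attempt counts summing to
61, 66 and 66) mirrors the study demographics table and is the default.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal as sps

from .channels import default_channel_order
from .gaze_features import GAZE_FEATURE_NAMES
from .network_features import eeg_feature_names, flexibility
from .recordings import (BANDS, TASKS, AttemptRecord, EegRecording,
                         GazeRecording, gaze_columns)

# study demographics: subject, age, sex, hand, eye, hours of experience,
# attempts at (Tubes, SutureSponge, DotsAndNeedles)
STUDY_DEMOGRAPHICS = (
    (1, 32, "M", "right", "right", 500, 2, 2, 2),
    (2, 36, "M", "right", "left", 100, 2, 2, 2),
    (3, 22, "F", "right", "right", 0, 2, 2, 2),
    (4, 26, "M", "right", "right", 0, 3, 2, 2),
    (5, 33, "M", "right", "right", 120, 2, 2, 5),
    (6, 35, "M", "right", "right", 100, 2, 2, 2),
    (7, 33, "M", "right", "right", 10, 2, 2, 2),
    (8, 61, "M", "right", "right", 30, 2, 2, 2),
    (9, 44, "M", "right", "left", 500, 3, 2, 2),
    (10, 24, "F", "right", "left", 0, 3, 4, 4),
    (11, 34, "F", "right", "left", 80, 2, 2, 2),
    (12, 44, "M", "right", "right", 1000, 2, 2, 2),
    (13, 67, "M", "right", "right", 1000, 3, 2, 2),
    (14, 23, "F", "right", "left", 0, 2, 3, 2),
    (15, 47, "M", "right", "right", 1000, 2, 2, 2),
    (16, 22, "F", "right", "right", 0, 2, 2, 2),
    (17, 36, "F", "right", "right", 0, 4, 9, 2),
    (18, 23, "F", "right", "right", 0, 2, 2, 2),
    (19, 28, "M", "right", "right", 0, 2, 3, 5),
    (20, 32, "M", "right", "right", 15, 2, 3, 3),
    (21, 20, "M", "right", "left", 0, 4, 2, 2),
    (22, 34, "M", "right", "right", 0, 2, 2, 2),
    (23, 32, "F", "right", "right", 40, 2, 2, 2),
    (24, 42, "M", "left", "left", 55, 2, 2, 2),
    (25, 54, "M", "right", "right", 0, 2, 3, 7),
    (26, 39, "M", "right", "left", 0, 3, 3, 2),
)

_STAGES = {"eeg": 1, "gaze": 2, "scores": 3, "latent": 4, "subject": 5,
           "tlx": 6}


def _rng(seed: int, stage: str, *keys) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGES[stage]] +
                               [int(k) for k in keys]))


@dataclass(frozen=True)
class PartitionSchedule:
    """Planted community membership per channel per 1-s window.

    ``segments`` is a tuple of ``(start_window, stop_window, assignments)``;
    ``stop_window`` of None extends to the end of the recording.
    """

    segments: tuple

    def matrix(self, n_channels: int, n_windows: int) -> np.ndarray:
        a = np.zeros((n_channels, n_windows), dtype=int)
        for start, stop, assign in self.segments:
            stop = n_windows if stop is None else stop
            assign = np.asarray(assign, dtype=int)
            if len(assign) != n_channels:
                raise ValueError("schedule assignment length does not match "
                                 "channel count")
            if np.any(assign < 1):
                raise ValueError("community ids must be positive")
            a[:, start:stop] = assign[:, None]
        if np.any(a == 0):
            raise ValueError("partition schedule does not cover all windows")
        return a

    def ground_truth_flexibility(self, n_channels: int,
                                 n_windows: int) -> np.ndarray:
        return flexibility(self.matrix(n_channels, n_windows))

    @classmethod
    def static(cls, assignments) -> "PartitionSchedule":
        return cls(((0, None, tuple(assignments)),))

    @classmethod
    def blocks(cls, n_channels: int,
               n_communities: int = 2) -> "PartitionSchedule":
        assign = 1 + (np.arange(n_channels) * n_communities) // n_channels
        return cls.static(assign)

    @classmethod
    def alternating(cls, n_channels: int, n_windows: int,
                    n_communities: int = 2,
                    period: int = 1) -> "PartitionSchedule":
        """Every channel cycles through the communities every ``period``
        windows (ground-truth flexibility 1 for period=1)."""
        base = 1 + (np.arange(n_channels) * n_communities) // n_channels
        segs = []
        for k, start in enumerate(range(0, n_windows, period)):
            assign = (base - 1 + k) % n_communities + 1
            segs.append((start, min(start + period, n_windows),
                         tuple(assign)))
        return cls(tuple(segs))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults mirror the study layout."""

    seed: int = 0
    n_subjects: int = 26
    attempts_per_subject: int | None = None   # None -> study attempt counts
    tasks: tuple = TASKS
    eeg_duration_s: float = 20.0
    eeg_fs_hz: float = 500.0
    gaze_fs_hz: float = 50.0
    n_channels: int = 116
    planted_partition_schedule: PartitionSchedule | None = None
    within_community_coherence: float = 0.6
    between_community_coherence: float = 0.1
    band_amplitude_uv: float = 10.0
    true_betas: dict = field(default_factory=lambda: {
        "avg_pupil_diameter_nondominant": -8.13,
        "rate_of_saccade": -5.87,
        "flexibility_ba18_beta": 0.52,
    })
    score_intercept: float = 65.0
    random_intercept_sd: float = 5.0
    residual_sd: float = 5.0
    true_learning_rates: dict | float | None = None  # None -> N(2, 1.5) draws
    learning_rate_mean: float = 2.0
    learning_rate_sd: float = 1.5
    pupil_ar1_coeff: float = 0.9
    pupil_noise_sd_mm: float = 0.05
    pupil_mean_mm: tuple = (3.5, 3.6)     # (L, R)
    pupil_latent_scale_mm: float = 0.3
    fixation_dur_s: float = 0.25
    saccade_dur_s: float = 0.06
    blink_rate_hz: float = 0.1
    blink_dur_s: float = 0.15

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.attempts_per_subject is not None \
                and self.attempts_per_subject < 2:
            raise ValueError("attempts_per_subject must be >= 2 "
                             "(learning-rate slope undefined otherwise)")
        w, b = self.within_community_coherence, \
            self.between_community_coherence
        if not (0 <= b <= w <= 1):
            raise ValueError("coherence targets must satisfy "
                             "0 <= between <= within <= 1")
        if self.fixation_dur_s <= 0:
            raise ValueError("fixation duration must be positive")
        if self.saccade_dur_s < 0:
            raise ValueError("saccade duration must be nonnegative")
        if not -1 < self.pupil_ar1_coeff < 1:
            raise ValueError("pupil AR(1) coefficient must lie in (-1, 1)")
        if self.eeg_duration_s < 1:
            raise ValueError("EEG duration must be at least 1 s")
        bad = set(self.true_betas) - set(latent_feature_names())
        if bad:
            raise ValueError(f"unknown feature names in true_betas: "
                             f"{sorted(bad)}")

    @property
    def n_windows(self) -> int:
        return int(self.eeg_duration_s)

    def channel_labels(self) -> list:
        return default_channel_order()[:self.n_channels]

    def schedule(self) -> PartitionSchedule:
        if self.planted_partition_schedule is not None:
            return self.planted_partition_schedule
        return PartitionSchedule.blocks(self.n_channels)

    def subject_rows(self) -> list:
        rows = []
        for s in range(self.n_subjects):
            base = STUDY_DEMOGRAPHICS[s % len(STUDY_DEMOGRAPHICS)]
            rows.append((s + 1,) + base[1:])
        return rows

    def n_attempts(self, subject_row, task: str) -> int:
        if self.attempts_per_subject is not None:
            return self.attempts_per_subject
        return subject_row[6 + TASKS.index(task)]


def latent_feature_names() -> list:
    """Names of the 180-entry latent standardized feature vector."""
    return eeg_feature_names() + list(GAZE_FEATURE_NAMES)


def _latent_features(config: SimulationConfig, subject: int, task: str,
                     attempt: int) -> pd.Series:
    rng = _rng(config.seed, "latent", subject, TASKS.index(task), attempt)
    names = latent_feature_names()
    return pd.Series(rng.standard_normal(len(names)), index=names)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _band_limited(rng: np.random.Generator, n: int, sos) -> np.ndarray:
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_eeg(config: SimulationConfig, subject: int, attempt: int,
                 task: str = "Tubes") -> EegRecording:
    """Band-limited EEG with the planted community/coherence structure."""
    fs = config.eeg_fs_hz
    n = int(round(config.eeg_duration_s * fs))
    n_win = config.n_windows
    wlen = int(round(fs))
    labels = config.channel_labels()
    n_ch = config.n_channels
    A = config.schedule().matrix(n_ch, n_win)
    # per-sample community index (samples beyond the last window reuse it)
    win_of_sample = np.minimum(np.arange(n) // wlen, n_win - 1)
    w = config.within_community_coherence
    b = config.between_community_coherence
    rng = _rng(config.seed, "eeg", subject, TASKS.index(task), attempt)
    out = np.zeros((n_ch, n))
    for band in BANDS:
        sos = sps.butter(4, [band.low_hz, band.high_hz], btype="bandpass",
                         fs=fs, output="sos")
        comms = np.unique(A)
        shared = {c: _band_limited(rng, n, sos) for c in comms}
        common = _band_limited(rng, n, sos)
        # per-channel random source orientation: magnitude coherence is
        # invariant to the sign, but signed sources survive re-referencing
        # (CAR/Laplacian would cancel an identical shared signal outright)
        signs = rng.choice([-1.0, 1.0], size=n_ch)
        for i in range(n_ch):
            noise = _band_limited(rng, n, sos)
            # membership may switch per window: splice the oscillator of
            # whichever community the channel belongs to at each sample
            comm_series = A[i, win_of_sample]
            mix = np.empty(n)
            for c in comms:
                m = comm_series == c
                mix[m] = shared[c][m]
            sig = signs[i] * (np.sqrt(b) * common + np.sqrt(w - b) * mix) \
                + np.sqrt(1.0 - w) * noise
            out[i] += config.band_amplitude_uv * sig
    return EegRecording(labels, fs, out, subject_id=subject, task_id=task,
                        attempt_index=attempt)


# ---------------------------------------------------------------------------
# gaze
# ---------------------------------------------------------------------------

def _segment_labels(config: SimulationConfig, rng, n: int) -> np.ndarray:
    """Alternating fixation/saccade segment label per sample."""
    from .gaze_features import FIXATION, SACCADE
    labels = np.empty(n, dtype=np.int8)
    pos, kind = 0, FIXATION
    while pos < n:
        mean = config.fixation_dur_s if kind == FIXATION \
            else config.saccade_dur_s
        if mean <= 0:           # saccades disabled
            labels[pos:] = FIXATION
            break
        dur = max(1, int(round(rng.gamma(4.0, mean / 4.0) * config.gaze_fs_hz)))
        labels[pos:pos + dur] = kind
        pos += dur
        kind = SACCADE if kind == FIXATION else FIXATION
    return labels


def generate_gaze(config: SimulationConfig, subject: int, attempt: int,
                  task: str = "Tubes") -> GazeRecording:
    """Fixation/saccade gaze with AR(1) pupils, drifting 3-D pupil
    positions, and blink gaps carrying NaN sentinels."""
    from .gaze_features import FIXATION, INVALID, SACCADE
    fs = config.gaze_fs_hz
    n = int(round(config.eeg_duration_s * fs))
    rng = _rng(config.seed, "gaze", subject, TASKS.index(task), attempt)
    truth = _segment_labels(config, rng, n)

    # angular position (deg), horizontal and vertical
    p = np.zeros((n, 2))
    target = rng.uniform(-12, 12, size=2)
    for t in range(1, n):
        if truth[t] == SACCADE:
            if truth[t - 1] != SACCADE:
                target = rng.uniform(-12, 12, size=2)
            step_to = target - p[t - 1]
            dist = np.linalg.norm(step_to)
            if dist < 1.0:      # target reached mid-saccade: fly onward
                target = rng.uniform(-12, 12, size=2)
                step_to = target - p[t - 1]
                dist = np.linalg.norm(step_to)
            step = max(3.5 + 0.5 * rng.standard_normal(), 1.2)
            p[t] = p[t - 1] + (step_to / max(dist, 1e-9)) * step
        else:
            jitter = rng.normal(0.0, 0.08, size=2)
            p[t] = p[t - 1] + jitter - 0.02 * p[t - 1]
    h, v = np.radians(p[:, 0]), np.radians(p[:, 1])
    gaze = np.column_stack([np.cos(v) * np.sin(h), np.sin(v),
                            np.cos(v) * np.cos(h)])

    sub_row = config.subject_rows()[(subject - 1) % config.n_subjects]
    dominant_eye = sub_row[4]
    latents = _latent_features(config, subject, task, attempt)
    dom = "L" if dominant_eye == "left" else "R"
    data = {"time_s": np.arange(n) / fs}
    # blink gaps (both eyes invalid)
    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(config.blink_rate_hz * config.eeg_duration_s)
    blen = max(1, int(round(config.blink_dur_s * fs)))
    for start in rng.integers(0, max(1, n - blen), size=n_blinks):
        valid[start:start + blen] = False
    truth = truth.copy()
    truth[~valid] = INVALID

    for k, e in enumerate(("L", "R")):
        role = "dominant" if e == dom else "nondominant"
        mu = (config.pupil_mean_mm[k] + config.pupil_latent_scale_mm *
              latents[f"avg_pupil_diameter_{role}"])
        phi, sd = config.pupil_ar1_coeff, config.pupil_noise_sd_mm
        diam = np.empty(n)
        diam[0] = mu + (sd / np.sqrt(1 - phi ** 2) *
                        rng.standard_normal() if sd > 0 else 0.0)
        eps = rng.standard_normal(n)
        for t in range(1, n):
            diam[t] = mu + phi * (diam[t - 1] - mu) + sd * eps[t]
        diam = np.maximum(diam, 0.5)
        base = np.array([-30.0 if e == "L" else 30.0, 0.0, 40.0])
        pos = np.empty((n, 3))
        pos[0] = base
        steps = rng.normal(0.0, 0.03, size=(n, 3))
        for t in range(1, n):
            pos[t] = pos[t - 1] + 0.05 * (base - pos[t - 1]) + steps[t]
        # small vergence offset between the eyes
        g = gaze + (0.002 if e == "L" else -0.002)
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        g[~valid] = np.nan
        pos_e = pos.copy()
        pos_e[~valid] = np.nan
        diam_e = diam.copy()
        diam_e[~valid] = np.nan
        data[f"gaze_{e}_x"], data[f"gaze_{e}_y"], data[f"gaze_{e}_z"] = g.T
        (data[f"pupil_pos_{e}_x"], data[f"pupil_pos_{e}_y"],
         data[f"pupil_pos_{e}_z"]) = pos_e.T
        data[f"pupil_diam_{e}"] = diam_e
        data[f"valid_{e}"] = valid.astype(int)

    df = pd.DataFrame(data)[gaze_columns()]
    return GazeRecording(df, fs, dominant_eye, subject_id=subject,
                         task_id=task, attempt_index=attempt,
                         ground_truth_labels=truth)


# ---------------------------------------------------------------------------
# scores and cohorts
# ---------------------------------------------------------------------------

def _learning_rate_for(config: SimulationConfig, subject: int) -> float:
    if isinstance(config.true_learning_rates, dict):
        return float(config.true_learning_rates[subject])
    if config.true_learning_rates is not None:
        return float(config.true_learning_rates)
    rng = _rng(config.seed, "subject", subject, 1)
    return float(rng.normal(config.learning_rate_mean,
                            config.learning_rate_sd))


def generate_scores(config: SimulationConfig):
    """Attempt records from the planted random-intercept score model.

    Returns ``(records, ledger)``; the ledger holds every planted quantity
    (random intercepts, learning rates, latent features, clipping events).
    """
    records = []
    intercepts, rates = {}, {}
    latent_rows, latent_keys, clipped = [], [], []
    for row in config.subject_rows():
        s = row[0]
        u = _rng(config.seed, "subject", s, 0).normal(
            0.0, config.random_intercept_sd) \
            if config.random_intercept_sd > 0 else 0.0
        intercepts[s] = float(u)
        rates[s] = _learning_rate_for(config, s)
        for task in config.tasks:
            for a in range(1, config.n_attempts(row, task) + 1):
                z = _latent_features(config, s, task, a)
                rng = _rng(config.seed, "scores", s, TASKS.index(task), a)
                eps = rng.normal(0.0, config.residual_sd) \
                    if config.residual_sd > 0 else 0.0
                score = (config.score_intercept + u
                         + sum(beta * z[name]
                               for name, beta in config.true_betas.items())
                         + a * rates[s] + eps)
                if not 0 <= score <= 100:
                    clipped.append((s, task, a, float(score)))
                    score = float(np.clip(score, 0.0, 100.0))
                tlx_rng = _rng(config.seed, "tlx", s, TASKS.index(task), a)
                base = tlx_rng.uniform(4, 14)
                domains = tuple(int(np.clip(round(base + tlx_rng.normal(0, 3)),
                                            1, 20)) for _ in range(6))
                records.append(AttemptRecord(
                    subject_id=s, task_id=task, attempt_index=a,
                    performance_score=float(score),
                    surg_tlx_domains=domains,
                    hours_of_ras=float(row[5]), age=float(row[1]),
                    dominant_eye=row[4], dominant_hand=row[3]))
                latent_rows.append(z)
                latent_keys.append((s, task, a))
    if clipped:
        warnings.warn(f"{len(clipped)} score(s) clipped to [0, 100]")
    latent = pd.DataFrame(
        latent_rows, index=pd.MultiIndex.from_tuples(
            latent_keys, names=["subject", "task", "attempt"]))
    ledger = {
        "random_intercepts": intercepts,
        "learning_rates": rates,
        "latent_features": latent,
        "clipped": clipped,
        "true_betas": dict(config.true_betas),
        "score_intercept": config.score_intercept,
        "schedule_flexibility": config.schedule().ground_truth_flexibility(
            config.n_channels, config.n_windows),
    }
    return records, ledger


@dataclass
class StudyDataset:
    """A full synthetic cohort: metadata plus lazily generated recordings."""

    config: SimulationConfig
    attempts: pd.DataFrame
    ledger: dict

    def eeg(self, subject: int, task: str, attempt: int) -> EegRecording:
        return generate_eeg(self.config, subject, attempt, task)

    def gaze(self, subject: int, task: str, attempt: int) -> GazeRecording:
        return generate_gaze(self.config, subject, attempt, task)

    def iter_keys(self):
        for row in self.attempts.itertuples(index=False):
            yield row.subject, row.task, row.attempt

    def feature_frame(self) -> pd.DataFrame:
        """Latent standardized features joined with attempt metadata."""
        meta = self.attempts.set_index(["subject", "task", "attempt"])
        return meta.join(self.ledger["latent_features"])


def generate_cohort(config: SimulationConfig) -> StudyDataset:
    """One EEG + gaze + score record per (subject, task, attempt)."""
    records, ledger = generate_scores(config)
    rows = []
    for r in records:
        row = {"subject": r.subject_id, "task": r.task_id,
               "attempt": r.attempt_index, "score": r.performance_score,
               "surg_tlx_total": sum(r.surg_tlx_domains),
               "hours_of_ras": r.hours_of_ras, "age": r.age,
               "dominant_eye": r.dominant_eye,
               "dominant_hand": r.dominant_hand}
        row.update({f"tlx_{i + 1}": d
                    for i, d in enumerate(r.surg_tlx_domains)})
        rows.append(row)
    return StudyDataset(config, pd.DataFrame(rows), ledger)
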