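"""Oculometric features: I-VT classification and the 12 gaze features.

Processing follows the eye-tracker convention: a 3-point moving average over
valid samples, angular velocity between consecutive gaze direction vectors,
and a velocity-threshold (I-VT) rule at 30 deg/s -- samples below the
threshold are fixations, samples at or above it saccades. The twelve features
are the fixation and saccade rates, per-eye average pupil diameter and
Shannon entropy of pupil diameter, per-eye horizontal/vertical
direction-change rates, and per-eye 3-D pupil trajectory length, with per-eye
features labelled by dominance. Rate denominators count all recorded samples,
including invalid ones (a valid-only denominator is available).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .recordings import GAZE_EYES, GazeRecording

FIXATION, SACCADE, INVALID = 1, 2, 0

GAZE_FEATURE_NAMES = (
    "rate_of_fixation",
    "rate_of_saccade",
    "avg_pupil_diameter_dominant",
    "avg_pupil_diameter_nondominant",
    "pupil_entropy_dominant",
    "pupil_entropy_nondominant",
    "gaze_dir_change_rate_horizontal_dominant",
    "gaze_dir_change_rate_vertical_dominant",
    "gaze_dir_change_rate_horizontal_nondominant",
    "gaze_dir_change_rate_vertical_nondominant",
    "trajectory_length_dominant",
    "trajectory_length_nondominant",
)


def _masked_moving_average(values: np.ndarray, valid: np.ndarray,
                           window: int) -> np.ndarray:
    """Centered moving average over valid samples only; invalid stay NaN."""
    v = np.where(valid, np.nan_to_num(values, nan=0.0), 0.0)
    m = valid.astype(float)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(m, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def smooth(rec: GazeRecording, window: int = 3) -> GazeRecording:
    """Moving-average noise reduction (window of three points by default).

    Averaging uses valid samples only; invalid samples remain invalid.
    Gaze direction vectors are re-normalized after averaging.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    df = rec.samples.copy()
    for e in GAZE_EYES:
        valid = rec.valid_mask(e)
        cols = [f"gaze_{e}_x", f"gaze_{e}_y", f"gaze_{e}_z",
                f"pupil_pos_{e}_x", f"pupil_pos_{e}_y", f"pupil_pos_{e}_z",
                f"pupil_diam_{e}"]
        for c in cols:
            df[c] = _masked_moving_average(df[c].to_numpy(), valid, window)
        g = df[[f"gaze_{e}_x", f"gaze_{e}_y", f"gaze_{e}_z"]].to_numpy()
        norms = np.linalg.norm(g, axis=1)
        ok = valid & (norms > 0)
        g[ok] = g[ok] / norms[ok, None]
        df[[f"gaze_{e}_x", f"gaze_{e}_y", f"gaze_{e}_z"]] = g
    return GazeRecording(df, rec.fs_hz, rec.dominant_eye, rec.subject_id,
                         rec.task_id, rec.attempt_index,
                         rec.ground_truth_labels)


def angular_velocity(rec: GazeRecording, eye: str) -> np.ndarray:
    """Per-sample angular speed in deg/s for one eye.

    Element ``t`` is the rotation between samples t-1 and t divided by the
    inter-sample interval; NaN where either sample is invalid (and at t=0).
    """
    g = rec.gaze_vectors(eye)
    valid = rec.valid_mask(eye)
    t = rec.samples["time_s"].to_numpy()
    vel = np.full(len(g), np.nan)
    dots = np.clip(np.einsum("ij,ij->i", g[:-1], g[1:]), -1.0, 1.0)
    ang = np.degrees(np.arccos(dots))
    dt = np.diff(t)
    ok = valid[:-1] & valid[1:]
    vel[1:][ok] = ang[ok] / dt[ok]
    return vel


def classify_ivt(velocities: np.ndarray,
                 threshold_deg_s: float = 30.0) -> np.ndarray:
    """I-VT labels: below threshold -> fixation, at/above -> saccade,
    undefined velocity -> invalid."""
    v = np.asarray(velocities, dtype=float)
    labels = np.full(len(v), INVALID, dtype=np.int8)
    defined = ~np.isnan(v)
    labels[defined & (v < threshold_deg_s)] = FIXATION
    labels[defined & (v >= threshold_deg_s)] = SACCADE
    return labels


def rate_features(labels: np.ndarray, valid_only: bool = False):
    """(rate_of_fixation, rate_of_saccade), denominator = all recorded
    samples by default (valid-only behind the flag)."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty recording")
    denom = int((labels != INVALID).sum()) if valid_only else len(labels)
    if denom == 0:
        warnings.warn("no valid samples; fixation/saccade rates set to 0")
        return 0.0, 0.0
    return (float((labels == FIXATION).sum()) / denom,
            float((labels == SACCADE).sum()) / denom)


def shannon_entropy(values: np.ndarray, bins: int = 16) -> float:
    """Entropy (bits) of the empirical distribution over equal-width bins
    spanning the observed range; 0 for a constant series."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no values for entropy")
    lo, hi = v.min(), v.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(v, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / len(v)
    return float(-(p * np.log2(p)).sum())


def pupil_features(rec: GazeRecording, eye: str, bins: int = 16):
    """(mean diameter, Shannon entropy of diameter) over valid samples."""
    d = rec.pupil_diameters(eye)[rec.valid_mask(eye)]
    if len(d) == 0:
        warnings.warn(f"eye {eye}: no valid pupil samples; features missing")
        return np.nan, np.nan
    return float(np.mean(d)), shannon_entropy(d, bins)


def _sign_change_count(series: np.ndarray) -> int:
    """Count of sign reversals of the first difference, zero steps skipped."""
    d = np.diff(series)
    d = d[d != 0]
    if len(d) < 2:
        return 0
    return int((np.sign(d[1:]) != np.sign(d[:-1])).sum())


def direction_change_rate(rec: GazeRecording, eye: str):
    """(horizontal, vertical) direction-change rates for one eye.

    A change is a sign reversal of the first difference of the gaze-direction
    x (horizontal) or y (vertical) component; counts are divided by the
    total number of recorded samples.
    """
    valid = rec.valid_mask(eye)
    g = rec.gaze_vectors(eye)[valid]
    n_total = rec.n_samples
    if len(g) < 3:
        warnings.warn(f"eye {eye}: fewer than 3 valid samples")
        return np.nan, np.nan
    return (_sign_change_count(g[:, 0]) / n_total,
            _sign_change_count(g[:, 1]) / n_total)


def trajectory_length(rec: GazeRecording, eye: str) -> float:
    """Total 3-D path length (mm) of the pupil over consecutive valid
    positions; gaps across invalid samples are bridged directly."""
    valid = rec.valid_mask(eye)
    p = rec.pupil_positions(eye)[valid]
    if len(p) < 2:
        warnings.warn(f"eye {eye}: fewer than 2 valid pupil positions")
        return np.nan
    n_gaps = int((np.diff(np.flatnonzero(valid)) > 1).sum())
    if n_gaps:
        warnings.warn(f"eye {eye}: {n_gaps} invalid gap(s) bridged in "
                      "trajectory length")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def extract_gaze_features(rec: GazeRecording,
                          smooth_window: int = 3,
                          ivt_threshold_deg_s: float = 30.0,
                          entropy_bins: int = 16,
                          valid_only_rates: bool = False,
                          presmoothed: bool = False) -> pd.Series:
    """The 12 oculometric features for one recording.

    Fixation/saccade rates use the dominant eye's angular velocity; per-eye
    features are reported under dominant/nondominant names resolved from the
    recording's dominant eye.
    """
    if not presmoothed:
        rec = smooth(rec, smooth_window)
    dom = rec.eye_for_role("dominant")
    labels = classify_ivt(angular_velocity(rec, dom), ivt_threshold_deg_s)
    fix_rate, sac_rate = rate_features(labels, valid_only_rates)
    out = {"rate_of_fixation": fix_rate, "rate_of_saccade": sac_rate}
    for role in ("dominant", "nondominant"):
        e = rec.eye_for_role(role)
        diam, ent = pupil_features(rec, e, entropy_bins)
        out[f"avg_pupil_diameter_{role}"] = diam
        out[f"pupil_entropy_{role}"] = ent
        h, v = direction_change_rate(rec, e)
        out[f"gaze_dir_change_rate_horizontal_{role}"] = h
        out[f"gaze_dir_change_rate_vertical_{role}"] = v
        out[f"trajectory_length_{role}"] = trajectory_length(rec, e)
    return pd.Series(out).reindex(list(GAZE_FEATURE_NAMES))


class GazeFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping gaze recordings to 12-feature rows."""

    def __init__(self, smooth_window=3, ivt_threshold_deg_s=30.0,
                 entropy_bins=16, valid_only_rates=False):
        self.smooth_window = smooth_window
        self.ivt_threshold_deg_s = ivt_threshold_deg_s
        self.entropy_bins = entropy_bins
        self.valid_only_rates = valid_only_rates

    def fit(self, X=None, y=None):
        return self

    def transform_one(self, rec: GazeRecording) -> pd.Series:
        return extract_gaze_features(
            rec, self.smooth_window, self.ivt_threshold_deg_s,
            self.entropy_bins, self.valid_only_rates)

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, GazeRecording):
            X = [X]
        rows, keys = [], []
        for rec in X:
            rows.append(self.transform_one(rec))
            keys.append((rec.subject_id, rec.task_id, rec.attempt_index))
        return pd.DataFrame(
            rows, index=pd.MultiIndex.from_tuples(
                keys, names=["subject", "task", "attempt"]))


# ---------------------------------------------------------------------------
# subject-wise standardization
# ---------------------------------------------------------------------------

def subjectwise_standardize(table: pd.DataFrame, columns,
                            scope=("subject", "task"),
                            ddof: int = 0):
    """Z-score feature columns within each (subject, task) group.

    Returns the standardized table and a ledger DataFrame of the group
    means and SDs applied. Population SD (ddof=0) by default so each group
    attains mean 0 / SD 1 exactly; zero-variance columns and singleton
    groups are flagged and set missing.
    """
    scope = list(scope)
    out = table.copy()
    ledger_rows = []
    for keys, idx in table.groupby(scope).groups.items():
        keys = keys if isinstance(keys, tuple) else (keys,)
        sub = table.loc[idx, columns]
        mu = sub.mean()
        sd = sub.std(ddof=ddof)
        degenerate = (sd == 0) | sd.isna() | (len(sub) < 2)
        for col in columns:
            if degenerate if isinstance(degenerate, bool) else degenerate[col]:
                warnings.warn(
                    f"group {keys}: column {col!r} has no variance or a "
                    "single row; standardized value set missing")
                out.loc[idx, col] = np.nan
            else:
                out.loc[idx, col] = (sub[col] - mu[col]) / sd[col]
            ledger_rows.append(dict(zip(scope, keys), column=col,
                                    mean=mu[col], sd=sd[col], n=len(sub)))
    return out, pd.DataFrame(ledger_rows)


class SubjectwiseStandardizer(BaseEstimator, TransformerMixin):
    """Estimator wrapper over :func:`subjectwise_standardize`.

    ``fit_transform`` standardizes within groups of the given scope and
    stores the applied means/SDs in ``ledger_`` for reporting.
    """

    def __init__(self, columns=None, scope=("subject", "task"), ddof=0):
        self.columns = columns
        self.scope = scope
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        cols = (list(self.columns) if self.columns is not None
                else [c for c in X.columns
                      if c not in self.scope and
                      pd.api.types.is_numeric_dtype(X[c])])
        self.columns_ = cols
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out, ledger = subjectwise_standardize(
            X, self.columns_, self.scope, self.ddof)
        self.ledger_ = ledger
        return out
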