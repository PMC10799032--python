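"""Core data containers: EEG recordings, gaze recordings, bands, attempts.

An :class:`EegRecording` is a channels x time matrix in microvolts with montage
labels; a :class:`GazeRecording` wraps a per-sample table of binocular gaze
direction vectors, 3-D pupil positions, pupil diameters and validity flags.
Invalid gaze samples carry NaN sentinels and must never be read directly --
every consumer is required to honour the validity flags.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TASKS = ("Tubes", "SutureSponge", "DotsAndNeedles")

#: channels excluded from the 124-channel headset for poor signal quality
EXCLUDED_CHANNELS = ("F8", "POz", "AF4", "AF8", "F6", "FC3", "M1", "M2")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low_hz, high_hz], closed on both edges."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges for {self.name!r}: "
                             f"{self.low_hz}-{self.high_hz} Hz")


#: analysis bands: theta, alpha, beta, gamma
BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 35.0),
    BandDefinition("gamma", 35.0, 65.0),
)


@dataclass
class EegRecording:
    """Multichannel EEG time series.

    Parameters
    ----------
    channel_labels : list of str
        Montage channel names, one per row of ``samples``.
    fs_hz : float
        Sampling rate in Hz.
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    artifact_windows : tuple of int
        Indices of 1-s analysis windows flagged by artifact rejection;
        windowed analyses exclude them.
    """

    channel_labels: list
    fs_hz: float
    samples: np.ndarray
    subject_id: int | str | None = None
    task_id: str | None = None
    attempt_index: int | None = None
    artifact_windows: tuple = ()

    def __post_init__(self):
        self.channel_labels = list(self.channel_labels)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but "
                f"{self.samples.shape[0]} sample rows")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if self.duration_s < 1.0 - 1e-9:
            raise ValueError("recording must be at least 1 s long")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs_hz

    def n_windows(self, window_s: float = 1.0) -> int:
        return int(self.n_times // round(window_s * self.fs_hz))

    def with_samples(self, samples: np.ndarray, **updates) -> "EegRecording":
        """Copy of this recording with new sample data (metadata preserved)."""
        return dataclasses.replace(self, samples=samples, **updates)


GAZE_EYES = ("L", "R")


def gaze_columns():
    """Column schema of the gaze sample table."""
    cols = ["time_s"]
    for e in GAZE_EYES:
        cols += [f"gaze_{e}_x", f"gaze_{e}_y", f"gaze_{e}_z",
                 f"pupil_pos_{e}_x", f"pupil_pos_{e}_y", f"pupil_pos_{e}_z",
                 f"pupil_diam_{e}", f"valid_{e}"]
    return cols


@dataclass
class GazeRecording:
    """Binocular eye-tracker samples with validity flags.

    ``samples`` holds one row per time point with the columns from
    :func:`gaze_columns`. Invalid samples carry NaN in the signal columns and
    0 in the per-eye validity column.
    """

    samples: pd.DataFrame
    fs_hz: float = 50.0
    dominant_eye: str = "right"
    subject_id: int | str | None = None
    task_id: str | None = None
    attempt_index: int | None = None
    ground_truth_labels: np.ndarray | None = None

    def __post_init__(self):
        missing = set(gaze_columns()) - set(self.samples.columns)
        if missing:
            raise ValueError(f"gaze table missing columns: {sorted(missing)}")
        t = self.samples["time_s"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.dominant_eye not in ("left", "right"):
            raise ValueError("dominant_eye must be 'left' or 'right'")
        for e in GAZE_EYES:
            valid = self.samples[f"valid_{e}"].to_numpy().astype(bool)
            if not valid.any():
                continue
            g = self.samples.loc[valid, [f"gaze_{e}_x", f"gaze_{e}_y",
                                         f"gaze_{e}_z"]].to_numpy()
            norms = np.linalg.norm(g, axis=1)
            if np.any(np.abs(norms - 1) > 1e-3):
                raise ValueError(f"gaze direction vectors for eye {e} are "
                                 "not unit-norm within 1e-3")
            d = self.samples.loc[valid, f"pupil_diam_{e}"].to_numpy()
            if np.any(~(d > 0)):
                raise ValueError(f"pupil diameters for eye {e} must be "
                                 "positive where valid")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def valid_mask(self, eye: str) -> np.ndarray:
        return self.samples[f"valid_{eye}"].to_numpy().astype(bool)

    def gaze_vectors(self, eye: str) -> np.ndarray:
        return self.samples[[f"gaze_{eye}_x", f"gaze_{eye}_y",
                             f"gaze_{eye}_z"]].to_numpy()

    def pupil_positions(self, eye: str) -> np.ndarray:
        return self.samples[[f"pupil_pos_{eye}_x", f"pupil_pos_{eye}_y",
                             f"pupil_pos_{eye}_z"]].to_numpy()

    def pupil_diameters(self, eye: str) -> np.ndarray:
        return self.samples[f"pupil_diam_{eye}"].to_numpy()

    def eye_for_role(self, role: str) -> str:
        """Map 'dominant'/'nondominant' to the physical eye ('L'/'R')."""
        dom = "L" if self.dominant_eye == "left" else "R"
        other = "R" if dom == "L" else "L"
        return dom if role == "dominant" else other


@dataclass(frozen=True)
class AttemptRecord:
    """One task attempt: simulator score, workload, demographics."""

    subject_id: int
    task_id: str
    attempt_index: int
    performance_score: float
    surg_tlx_domains: tuple
    hours_of_ras: float
    age: float
    dominant_eye: str
    dominant_hand: str

    def __post_init__(self):
        if self.task_id not in TASKS:
            raise ValueError(f"unknown task {self.task_id!r}")
        if self.attempt_index < 1:
            raise ValueError("attempt_index is 1-based")
        if not 0 <= self.performance_score <= 100:
            raise ValueError("performance score must lie in [0, 100]")
        if len(self.surg_tlx_domains) != 6 or any(
                not 1 <= d <= 20 for d in self.surg_tlx_domains):
            raise ValueError("SURG-TLX needs six domain scores in [1, 20]")
        if self.hours_of_ras < 0:
            raise ValueError("hours of experience must be nonnegative")
        if self.dominant_eye not in ("left", "right"):
            raise ValueError("dominant_eye must be 'left' or 'right'")
        if self.dominant_hand not in ("left", "right"):
            raise ValueError("dominant_hand must be 'left' or 'right'")
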