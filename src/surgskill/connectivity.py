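"""Magnitude-coherence functional connectivity.

Edges of the functional brain network are band-averaged magnitude coherence
values |S_xy(f)| / sqrt(S_xx(f) S_yy(f)) estimated with Welch cross-spectra
(Hann taper, 50% overlap) and averaged over the frequency bins falling inside
the band, closed on both edges. Band-edge bins shared by two bands (e.g. 8 Hz
for theta and alpha) therefore contribute to both.

Two granularities are produced: a single adjacency over the whole recording
(input to search information) and a stack of per-1-s-window adjacencies
(input to temporal flexibility). For 1-s windows at 500 Hz the default Welch
segments are 250 samples with 50% overlap: 2 Hz resolution, three segments
per window.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal as sps

from .recordings import BandDefinition, EegRecording


@dataclass
class AdjacencyMatrix:
    """Symmetric, zero-diagonal coherence weights in [0, 1]."""

    weights: np.ndarray
    band: BandDefinition
    channel_labels: list

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if len(self.channel_labels) != w.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        if np.abs(w - w.T).max(initial=0.0) > 1e-9:
            raise ValueError("weights must be symmetric within 1e-9")
        if np.abs(np.diag(w)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        if w.min(initial=0.0) < 0 or w.max(initial=0.0) > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


@dataclass
class AdjacencyStack:
    """Per-window adjacency matrices sharing band and channel order."""

    matrices: list
    window_s: float = 1.0
    window_indices: tuple = ()

    def __post_init__(self):
        if not self.matrices:
            raise ValueError("empty adjacency stack")
        first = self.matrices[0]
        for m in self.matrices:
            if m.band != first.band or m.channel_labels != first.channel_labels:
                raise ValueError("stack matrices must share band and channels")
        if not self.window_indices:
            self.window_indices = tuple(range(len(self.matrices)))

    def __len__(self):
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    @property
    def band(self):
        return self.matrices[0].band


def _segment_ffts(x: np.ndarray, nperseg: int, noverlap: int):
    """Hann-tapered, mean-detrended segment rFFTs, shape (n, nseg, nfreq)."""
    x = np.asarray(x, dtype=float)
    step = nperseg - noverlap
    n_seg = (x.shape[-1] - noverlap) // step
    if n_seg < 1:
        raise ValueError("signal shorter than one Welch segment")
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = x[..., idx]                                   # (n, nseg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    win = sps.get_window("hann", nperseg)
    return np.fft.rfft(segs * win, axis=-1), n_seg


def coherence_spectrum_matrix(samples: np.ndarray, fs: float,
                              nperseg: int, noverlap: int):
    """All-pairs magnitude coherence per frequency bin.

    Returns ``(coh, freqs)`` with ``coh`` of shape (n, n, n_freqs). Zero-power
    bins yield NaN coherence (handled by callers).
    """
    Z, _ = _segment_ffts(samples, nperseg, noverlap)
    S = np.einsum("isf,jsf->ijf", Z, np.conj(Z))
    auto = np.real(np.einsum("iif->if", S))
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(S) / denom
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return coh, freqs


def band_bins(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Frequency-bin mask for a band, closed interval on both edges."""
    mask = (freqs >= band.low_hz - 1e-12) & (freqs <= band.high_hz + 1e-12)
    if not mask.any():
        raise ValueError(
            f"band {band.name} ({band.low_hz}-{band.high_hz} Hz) has no "
            f"resolvable bins at resolution {freqs[1] - freqs[0]:g} Hz")
    return mask


def _band_adjacency(samples, fs, band, nperseg, noverlap, squared):
    coh, freqs = coherence_spectrum_matrix(samples, fs, nperseg, noverlap)
    mask = band_bins(freqs, band)
    w = np.nanmean(coh[:, :, mask] ** (2 if squared else 1), axis=2)
    w = np.clip(w, 0.0, 1.0)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


def magnitude_coherence(x, y, fs: float, band: BandDefinition,
                        nperseg: int | None = None,
                        noverlap: int | None = None,
                        squared: bool = False) -> float:
    """Band-averaged magnitude coherence between two equal-length signals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    nperseg = int(nperseg if nperseg is not None else round(fs))
    noverlap = int(noverlap if noverlap is not None else nperseg // 2)
    if len(x) < 2 * nperseg - noverlap:
        raise ValueError("signals must cover at least two Welch segments")
    w = _band_adjacency(np.vstack([x, y]), fs, band, nperseg, noverlap,
                        squared)
    return float(w[0, 1])


def full_record_adjacency(rec: EegRecording, band: BandDefinition,
                          nperseg: int | None = None,
                          noverlap: int | None = None,
                          squared: bool = False) -> AdjacencyMatrix:
    """Coherence adjacency over the entire recording (1-s Welch segments)."""
    nperseg = int(nperseg if nperseg is not None else round(rec.fs_hz))
    noverlap = int(noverlap if noverlap is not None else nperseg // 2)
    w = _band_adjacency(rec.samples, rec.fs_hz, band, nperseg, noverlap,
                        squared)
    if np.any(np.isnan(w)):
        raise ValueError("zero-power channel: coherence undefined")
    return AdjacencyMatrix(w, band, list(rec.channel_labels))


def windowed_adjacency(rec: EegRecording, band: BandDefinition,
                       window_s: float = 1.0,
                       nperseg: int | None = None,
                       noverlap: int | None = None,
                       squared: bool = False) -> AdjacencyStack:
    """One adjacency per retained window; artifact-flagged windows skipped.

    Windows in which a channel has no in-band power (coherence undefined)
    are dropped with a warning rather than producing NaN weights.
    """
    wlen = int(round(window_s * rec.fs_hz))
    n_win = rec.n_times // wlen
    if n_win < 1:
        raise ValueError("recording shorter than one window")
    nperseg = int(nperseg if nperseg is not None else wlen // 2)
    noverlap = int(noverlap if noverlap is not None else nperseg // 2)
    matrices, kept = [], []
    for t in range(n_win):
        if t in rec.artifact_windows:
            continue
        chunk = rec.samples[:, t * wlen:(t + 1) * wlen]
        w = _band_adjacency(chunk, rec.fs_hz, band, nperseg, noverlap,
                            squared)
        if np.any(np.isnan(w)):
            warnings.warn(f"window {t}: degenerate (zero-power) channel; "
                          "window dropped")
            continue
        matrices.append(AdjacencyMatrix(w, band, list(rec.channel_labels)))
        kept.append(t)
    if not matrices:
        raise ValueError("no retained windows")
    return AdjacencyStack(matrices, window_s, tuple(kept))
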