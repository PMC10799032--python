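"""Montage geometry and the channel-to-Brodmann-area map.

The packaged montage provides unit-sphere positions for the 116 retained
channels of the 124-channel headset; positions come from the standard 10-05
layout projected onto the unit sphere (FP3/FP4 are vendor-specific names and
are interpolated between their neighbours). Positions are used only to build
nearest-neighbour sets for the Hjorth surface Laplacian.

The Brodmann-area map groups the 116 channels into 21 areas; per-channel
network features are averaged within each area.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd


def _data_path(name: str):
    return resources.files("surgskill").joinpath("data", name)


@dataclass
class Montage:
    """Channel label -> 3-D unit-sphere position, with k-NN neighbour sets."""

    labels: list
    positions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self):
        self.labels = list(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(np.abs(norms - 1) > 1e-6):
            raise ValueError("montage positions must be unit-norm within 1e-6")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def position(self, label: str) -> np.ndarray:
        return self.positions[self._index[label]]

    def neighbors(self, label: str, k: int = 4) -> tuple:
        """The ``k`` nearest channels to ``label`` (Euclidean, excluding self)."""
        i = self._index[label]
        d = np.linalg.norm(self.positions - self.positions[i], axis=1)
        order = np.argsort(d, kind="stable")
        picked = [j for j in order if j != i][:k]
        if len(picked) < k:
            raise ValueError(f"montage too small for k={k} neighbours")
        return tuple(self.labels[j] for j in picked)

    def subset(self, labels) -> "Montage":
        idx = [self._index[lab] for lab in labels]
        return Montage(list(labels), self.positions[idx])


def load_montage(path) -> Montage:
    """Read a delimited ``label,x,y,z`` montage file."""
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"montage file needs columns {sorted(required)}")
    return Montage(df["label"].tolist(), df[["x", "y", "z"]].to_numpy())


def default_montage() -> Montage:
    """The packaged 116-channel montage."""
    with resources.as_file(_data_path("montage_116.csv")) as p:
        return load_montage(p)


@dataclass
class ChannelBaMap:
    """Brodmann area id -> tuple of channel labels."""

    groups: dict

    def __post_init__(self):
        self.groups = {int(k): tuple(v) for k, v in self.groups.items()}
        seen = {}
        for ba, chans in self.groups.items():
            if not chans:
                raise ValueError(f"BA {ba} has no channels")
            for c in chans:
                if c in seen:
                    raise ValueError(
                        f"channel {c!r} appears in BA {seen[c]} and BA {ba}")
                seen[c] = ba

    @property
    def ba_ids(self) -> list:
        return sorted(self.groups)

    @property
    def channels(self) -> list:
        return [c for ba in self.ba_ids for c in self.groups[ba]]

    def validate_default_shape(self):
        """Assert the packaged layout: 21 areas covering 116 channels."""
        if len(self.groups) != 21:
            raise ValueError(f"expected 21 Brodmann areas, got "
                             f"{len(self.groups)}")
        if len(self.channels) != 116:
            raise ValueError(f"expected 116 channels, got "
                             f"{len(self.channels)}")
        return self


def load_ba_map(path) -> ChannelBaMap:
    """Read a delimited ``ba,channel`` mapping file."""
    df = pd.read_csv(path)
    if not {"ba", "channel"} <= set(df.columns):
        raise ValueError("BA map file needs columns ba,channel")
    groups = {}
    for ba, sub in df.groupby("ba"):
        groups[int(ba)] = tuple(sub["channel"])
    return ChannelBaMap(groups)


def default_ba_map() -> ChannelBaMap:
    """The packaged 21-area, 116-channel map."""
    with resources.as_file(_data_path("ba_channel_map.csv")) as p:
        return load_ba_map(p).validate_default_shape()


def default_channel_order() -> list:
    """Canonical channel ordering used by the synthetic generator."""
    return default_ba_map().channels
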