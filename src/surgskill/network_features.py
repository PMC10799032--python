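"""EEG network features: search information and temporal flexibility.

Search information quantifies, in bits, how much information a memoryless
random walker needs to follow the shortest path between two nodes of the
coherence-weighted network: along the shortest path i -> ... -> j (edge
lengths 1/weight) the walker takes each step u -> v with probability
w_uv / strength(u), and SI(i -> j) = -log2 of the product of those step
probabilities. A channel's value is the mean over all ordered targets.
Shortest-path ties are broken deterministically (lexicographically smallest
node order, applied backward from the target).

Temporal flexibility of a channel is the fraction of consecutive 1-s windows
in which its community assignment changes, where per-window communities come
from consensus clustering over repeated Louvain modularity maximization
against a size-preserving label-permutation null.

Per-channel values are averaged within each Brodmann area; with 21 areas and
four bands this yields 84 search-information + 84 flexibility features.
"""
from __future__ import annotations

import random as _pyrandom
import warnings

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .channels import ChannelBaMap, default_ba_map
from .connectivity import (AdjacencyMatrix, full_record_adjacency,
                           windowed_adjacency)
from .recordings import BANDS, EegRecording


def _weights(adj) -> np.ndarray:
    w = adj.weights if isinstance(adj, AdjacencyMatrix) else np.asarray(
        adj, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(w < 0):
        raise ValueError("adjacency weights must be nonnegative")
    return w


# ---------------------------------------------------------------------------
# search information
# ---------------------------------------------------------------------------

def _edge_lengths(w: np.ndarray, transform: str) -> np.ndarray:
    with np.errstate(divide="ignore"):
        if transform == "inverse":
            return np.where(w > 0, 1.0 / w, np.inf)
        if transform == "neglog":
            return np.where(w > 0, -np.log(w), np.inf)
    raise ValueError(f"unknown length transform {transform!r}")


def search_information_matrix(adj, length_transform: str = "inverse"
                              ) -> np.ndarray:
    """Pairwise SI(i -> j) in bits; NaN on the diagonal and for
    disconnected pairs."""
    w = _weights(adj)
    n = w.shape[0]
    strength = w.sum(axis=1)
    lengths = _edge_lengths(w, length_transform)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(w, 1))
    g.add_weighted_edges_from(
        ((int(i), int(j), lengths[i, j]) for i, j in zip(ii, jj)),
        weight="length")
    si = np.full((n, n), np.nan)
    with np.errstate(divide="ignore"):
        logp = np.log2(np.where(w > 0, w, 1.0)) - np.log2(
            np.where(strength > 0, strength, 1.0))[:, None]
    for src in range(n):
        preds, dist = nx.dijkstra_predecessor_and_distance(
            g, src, weight="length")
        for tgt in dist:
            if tgt == src:
                continue
            # walk back choosing the smallest predecessor: deterministic,
            # lexicographically minimal among tied shortest paths
            bits, node = 0.0, tgt
            while node != src:
                prev = min(preds[node])
                bits -= logp[prev, node]
                node = prev
            si[src, tgt] = bits
    return si


def search_information(adj, length_transform: str = "inverse") -> np.ndarray:
    """Per-channel mean SI over reachable targets (NaN for isolated nodes)."""
    si = search_information_matrix(adj, length_transform)
    n = si.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_missing = int(np.isnan(si[off]).sum())
    if n_missing:
        warnings.warn(f"{n_missing} disconnected ordered pairs excluded "
                      "from search information")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        values = np.nanmean(np.where(off, si, np.nan), axis=1)
    if np.any(np.isnan(values)):
        warnings.warn("isolated node(s): search information undefined")
    return values


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

def modularity(adj, partition, resolution: float = 1.0) -> float:
    """Newman-Girvan modularity of an assignment vector (labels 1..g)."""
    w = _weights(adj)
    part = np.asarray(partition)
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    k = w.sum(axis=1)
    same = part[:, None] == part[None, :]
    return float(((w - resolution * np.outer(k, k) / two_m) * same).sum()
                 / two_m)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 1..g by first occurrence."""
    out = np.empty(len(labels), dtype=int)
    mapping = {}
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(lab, len(mapping) + 1)
    return out


def louvain_partition(adj, resolution: float = 1.0,
                      seed=None) -> np.ndarray:
    """One greedy modularity-maximizing partition (labels 1..g).

    Node order is shuffled by ``seed``; an all-zero adjacency yields the
    all-singletons partition.
    """
    w = _weights(adj)
    n = w.shape[0]
    if w.sum() == 0:
        return np.arange(1, n + 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    g = ig.Graph.Weighted_Adjacency(w[np.ix_(perm, perm)],
                                    mode="undirected", attr="weight")
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(int(rng.integers(2 ** 31)))
        cl = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    labels = np.empty(n, dtype=int)
    labels[perm] = np.asarray(cl.membership)
    return _canonical(labels)


def _agreement(partitions: np.ndarray) -> np.ndarray:
    agree = np.zeros((partitions.shape[1],) * 2)
    for p in partitions:
        agree += p[:, None] == p[None, :]
    agree /= len(partitions)
    np.fill_diagonal(agree, 0.0)
    return agree


def consensus_partition(adj, n_reps: int = 100, seed=None,
                        resolution: float = 1.0,
                        max_iter: int = 50) -> np.ndarray:
    """Consensus community assignment over ``n_reps`` Louvain runs.

    The agreement matrix (fraction of runs co-assigning each node pair) is
    thresholded at the maximum agreement produced by a null in which each
    run's labels are independently permuted over nodes (community sizes
    preserved), then re-clustered; this repeats until all runs agree.
    Deterministic given the master seed.
    """
    rng = np.random.default_rng(seed)
    w = _weights(adj)
    n = w.shape[0]
    current = w
    for _ in range(max_iter):
        seeds = rng.integers(2 ** 31, size=n_reps)
        parts = np.array([louvain_partition(current, resolution, s)
                          for s in seeds])
        if np.all(parts == parts[0]):
            return parts[0]
        agree = _agreement(parts)
        null = np.array([p[rng.permutation(n)] for p in parts])
        tau = _agreement(null).max()
        current = np.where(agree >= tau, agree, 0.0)
        np.fill_diagonal(current, 0.0)
    raise RuntimeError(
        f"consensus did not converge in {max_iter} iterations "
        f"(n={n}, n_reps={n_reps}, last threshold {tau:.3f})")


def align_partition(partition: np.ndarray,
                    reference: np.ndarray) -> np.ndarray:
    """Relabel a detected partition onto reference community ids.

    Each detected community is mapped to the reference community it overlaps
    most (majority/purity mapping, ties to the smaller reference id).
    Community labels from independent per-window detection are arbitrary;
    this alignment makes detected assignments comparable to a planted
    ground-truth schedule, e.g. for flexibility-recovery checks.
    """
    p = np.asarray(partition)
    ref = np.asarray(reference)
    if p.shape != ref.shape:
        raise ValueError("partition and reference must have equal length")
    out = np.empty_like(p)
    for c in np.unique(p):
        mask = p == c
        ids, cnt = np.unique(ref[mask], return_counts=True)
        out[mask] = ids[cnt.argmax()]
    return out


# ---------------------------------------------------------------------------
# flexibility and BA averaging
# ---------------------------------------------------------------------------

def flexibility(partition_matrix: np.ndarray) -> np.ndarray:
    """Fraction of consecutive windows in which each channel switches
    community; in [0, 1] and invariant to community relabeling."""
    a = np.asarray(partition_matrix)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("partition matrix needs at least 2 windows")
    return (a[:, 1:] != a[:, :-1]).mean(axis=1)


def ba_average(values, channel_labels, ba_map: ChannelBaMap) -> pd.Series:
    """Unweighted mean of a per-channel quantity within each Brodmann area.

    Channels carrying NaN are excluded with a warning; an area whose
    channels are all excluded yields NaN.
    """
    values = np.asarray(values, dtype=float)
    index = {lab: i for i, lab in enumerate(channel_labels)}
    for ba in ba_map.ba_ids:
        for c in ba_map.groups[ba]:
            if c not in index:
                raise KeyError(f"BA {ba} references unknown channel {c!r}")
    out = {}
    for ba in ba_map.ba_ids:
        vals = values[[index[c] for c in ba_map.groups[ba]]]
        if np.isnan(vals).any():
            warnings.warn(f"BA {ba}: {int(np.isnan(vals).sum())} channel(s) "
                          "excluded from averaging")
        out[ba] = np.nan if np.isnan(vals).all() else np.nanmean(vals)
    return pd.Series(out, name="ba_average")


def eeg_feature_names(ba_map: ChannelBaMap | None = None,
                      bands=BANDS) -> list:
    """Ordered names of the EEG feature vector (2 x areas x bands)."""
    ba_map = ba_map if ba_map is not None else default_ba_map()
    names = []
    for kind in ("search_info", "flexibility"):
        for band in bands:
            for ba in ba_map.ba_ids:
                names.append(f"{kind}_ba{ba}_{band.name}")
    return names


def extract_eeg_features(rec: EegRecording,
                         ba_map: ChannelBaMap | None = None,
                         bands=BANDS,
                         n_consensus: int = 100,
                         seed=0,
                         window_s: float = 1.0,
                         resolution: float = 1.0,
                         squared: bool = False,
                         length_transform: str = "inverse") -> pd.Series:
    """The full EEG feature vector for one preprocessed recording.

    Per band: search information from the whole-recording adjacency and
    flexibility from per-window consensus partitions, both averaged within
    Brodmann areas. Consensus seeds derive from ``seed`` keyed by band and
    window so any single window can be re-run exactly.
    """
    ba_map = ba_map if ba_map is not None else default_ba_map()
    out = {}
    for bi, band in enumerate(bands):
        adj = full_record_adjacency(rec, band, squared=squared)
        si = ba_average(search_information(adj, length_transform),
                        rec.channel_labels, ba_map)
        stack = windowed_adjacency(rec, band, window_s, squared=squared)
        if len(stack) < 2:
            raise ValueError("flexibility needs at least 2 retained windows")
        parts = np.column_stack([
            consensus_partition(
                m, n_consensus,
                seed=np.random.SeedSequence([int(seed), bi, t]),
                resolution=resolution)
            for t, m in zip(stack.window_indices, stack)])
        flex = ba_average(flexibility(parts), rec.channel_labels, ba_map)
        for ba in ba_map.ba_ids:
            out[f"search_info_ba{ba}_{band.name}"] = si[ba]
            out[f"flexibility_ba{ba}_{band.name}"] = flex[ba]
    return pd.Series(out).reindex(eeg_feature_names(ba_map, bands))


class EegFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping preprocessed recordings to EEG feature rows."""

    def __init__(self, ba_map=None, bands=BANDS, n_consensus=100, seed=0,
                 window_s=1.0, resolution=1.0, squared=False,
                 length_transform="inverse"):
        self.ba_map = ba_map
        self.bands = bands
        self.n_consensus = n_consensus
        self.seed = seed
        self.window_s = window_s
        self.resolution = resolution
        self.squared = squared
        self.length_transform = length_transform

    def fit(self, X=None, y=None):
        return self

    def transform_one(self, rec: EegRecording) -> pd.Series:
        return extract_eeg_features(
            rec, self.ba_map, self.bands, self.n_consensus, self.seed,
            self.window_s, self.resolution, self.squared,
            self.length_transform)

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, EegRecording):
            X = [X]
        rows, keys = [], []
        for rec in X:
            rows.append(self.transform_one(rec))
            keys.append((rec.subject_id, rec.task_id, rec.attempt_index))
        return pd.DataFrame(
            rows, index=pd.MultiIndex.from_tuples(
                keys, names=["subject", "task", "attempt"]))
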