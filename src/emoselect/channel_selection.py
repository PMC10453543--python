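"""Differential-entropy channel scoring and threshold selection.

Each channel is scored per class by symbolizing its amplitudes into
equal-frequency bins and measuring, for every trial in the universe U, how
much of the trial's symbol distribution is shared with the pooled symbol
distribution of the class:

    E(channel | class C) = -(1/|U|) * sum_{z in U} log2( overlap(z, C) )

where ``overlap(z, C) = sum_b min(p_z(b), p_C(b))`` is the histogram
intersection between trial z's per-channel bin distribution p_z and the
class-conditional distribution p_C. A channel whose amplitude distribution
is the same in every trial regardless of class has overlap ~= 1 and score
~= 0; a channel whose distribution shifts with the class accumulates
log-penalties from the opposite-class trials and scores high. Channels whose
best (max-over-class) score reaches a threshold (1.5 by default) are kept,
and selections from several datasets can be intersected to find common
channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import EpochSet

__all__ = [
    "DiscretizedEpochs",
    "discretize",
    "channel_class_score",
    "score_table",
    "ChannelScoreTable",
    "select_channels",
    "common_channels",
    "DifferentialEntropyChannelSelector",
]


@dataclass
class DiscretizedEpochs:
    """Per-channel amplitude-bin symbols for a set of trials."""

    symbols: np.ndarray            # (n_trials, n_channels, n_samples) int
    bin_edges: list                # per channel, inner edges (strictly increasing)
    n_bins: int
    constant_channels: list = field(default_factory=list)


def _as_array(epochs) -> np.ndarray:
    if isinstance(epochs, EpochSet):
        return epochs.data
    x = np.asarray(epochs, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (n_trials, n_channels, n_samples)")
    return x


def discretize(epochs, n_bins: int = 8) -> DiscretizedEpochs:
    """Equal-frequency amplitude binning, per channel over all trials.

    Edges are the pooled per-channel quantiles; duplicate edges (from heavy
    ties or constant channels) are dropped, so a constant channel collapses
    to a single occupied bin and is flagged.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = _as_array(epochs)
    n_trials, n_channels, n_samples = x.shape
    symbols = np.empty(x.shape, dtype=np.int32)
    edges_per_channel, constant = [], []
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for c in range(n_channels):
        pooled = x[:, c, :].ravel()
        edges = np.unique(np.quantile(pooled, qs))
        if pooled.min() == pooled.max():
            constant.append(c)
            edges = np.array([])
        symbols[:, c, :] = np.searchsorted(edges, x[:, c, :], side="right")
        edges_per_channel.append(edges)
    return DiscretizedEpochs(symbols, edges_per_channel, n_bins, constant)


def _bin_distribution(sym: np.ndarray, n_bins: int) -> np.ndarray:
    counts = np.bincount(sym.ravel(), minlength=n_bins).astype(float)
    return counts / counts.sum()


def channel_class_score(disc: DiscretizedEpochs, labels, channel: int,
                        class_c) -> float:
    """Differential-entropy score of one channel with respect to one class.

    Mean over all trials z of ``-log2`` of the shared-symbol mass between
    trial z and class ``class_c`` on this channel. Zero overlap is floored at
    ``1 / (n_samples + 1)`` so the logarithm stays finite.
    """
    labels = np.asarray(labels)
    mask = labels == class_c
    if not mask.any():
        raise ValueError(f"class {class_c!r} not present in labels")
    sym = disc.symbols[:, channel, :]
    n_trials, n_samples = sym.shape
    p_class = _bin_distribution(sym[mask], disc.n_bins)
    floor = 1.0 / (n_samples + 1)
    total = 0.0
    for z in range(n_trials):
        p_z = _bin_distribution(sym[z], disc.n_bins)
        overlap = np.minimum(p_z, p_class).sum()
        total += -np.log2(max(overlap, floor))
    return total / n_trials


@dataclass
class ChannelScoreTable:
    """Per-channel, per-class scores plus the thresholded selection."""

    scores: pd.DataFrame           # index = channel names, columns = classes
    threshold: float
    selected: list                 # channel names, descending best score
    universe_size: int

    @property
    def best_score(self) -> pd.Series:
        return self.scores.max(axis=1)


def score_table(epochs: EpochSet, labels, n_bins: int = 8,
                threshold: float = 1.5) -> ChannelScoreTable:
    """Score every channel against every class and apply the threshold."""
    labels = np.asarray(labels)
    disc = discretize(epochs, n_bins=n_bins)
    if disc.constant_channels:
        warnings.warn(
            f"constant channels (single occupied bin): {disc.constant_channels}")
    classes = pd.unique(labels)
    names = (epochs.channel_names if isinstance(epochs, EpochSet)
             else [f"ch{c}" for c in range(disc.symbols.shape[1])])
    table = pd.DataFrame(
        {cls: [channel_class_score(disc, labels, c, cls)
               for c in range(len(names))] for cls in classes},
        index=names,
    )
    result = ChannelScoreTable(table, threshold, [], len(labels))
    result.selected = select_channels(result, threshold)
    return result


def select_channels(table: ChannelScoreTable, threshold: float = 1.5) -> list:
    """Channels whose max-over-class score reaches the threshold.

    Ordered by descending score; ties keep montage (input) order, which a
    stable sort provides. An empty result is allowed (warned): the caller may
    lower the threshold.
    """
    best = table.best_score
    keep = best[best >= threshold]
    if keep.empty:
        warnings.warn(
            f"no channel reaches threshold {threshold}; consider lowering it")
        return []
    return list(keep.sort_values(ascending=False, kind="stable").index)


def common_channels(selections, k: int = 10) -> list:
    """Intersect per-dataset channel selections, keeping at most ``k``.

    Each selection is an ordered (best-first) channel list. If the
    intersection exceeds ``k``, the ``k`` channels with the best (lowest)
    mean rank across selections are kept; if smaller, the intersection is
    returned as-is with a warning.
    """
    selections = [list(s) for s in selections]
    if not selections:
        raise ValueError("need at least one selection")
    sets = [set(s) for s in selections]
    if (len(sets) > 1 and all(sets)
            and not any(a & b for i, a in enumerate(sets)
                        for b in sets[i + 1:])):
        raise ValueError("selections share no channel names at all "
                         "(disjoint name spaces?)")
    common = set.intersection(*sets)
    mean_rank = {
        ch: float(np.mean([s.index(ch) for s in selections]))
        for ch in common
    }
    ordered = sorted(common, key=lambda ch: (mean_rank[ch], str(ch)))
    if len(ordered) < k:
        warnings.warn(
            f"intersection has {len(ordered)} channels, fewer than k={k}")
        return ordered
    return ordered[:k]


class DifferentialEntropyChannelSelector(BaseEstimator):
    """Scikit-learn style transformer selecting channels by DE score.

    Parameters
    ----------
    n_bins : int, default 8
        Equal-frequency amplitude bins per channel.
    threshold : float, default 1.5
        Minimum max-over-class score for a channel to be kept.
    top_k : int or None
        If set, keep exactly the ``top_k`` best-scoring channels instead of
        (or in addition to, whichever is smaller) the threshold rule. Useful
        when a fixed channel budget is wanted, mirroring the 10-channel
        operating point.

    Fitted attributes: ``scores_`` (DataFrame channels x classes),
    ``selected_channels_`` (names, best first), ``selected_idx_``.
    """

    def __init__(self, n_bins: int = 8, threshold: float = 1.5,
                 top_k: int | None = None):
        self.n_bins = n_bins
        self.threshold = threshold
        self.top_k = top_k

    def fit(self, X, y):
        epochs = X
        x = _as_array(epochs)
        y = np.asarray(y)
        if y.shape[0] != x.shape[0]:
            raise ValueError("y must have one label per trial")
        names = (epochs.channel_names if isinstance(epochs, EpochSet)
                 else [f"ch{c}" for c in range(x.shape[1])])
        with warnings.catch_warnings():
            if self.top_k is not None:
                # the fixed budget makes an empty threshold pass harmless
                warnings.simplefilter("ignore", UserWarning)
            table = score_table(epochs if isinstance(epochs, EpochSet) else x,
                                y, n_bins=self.n_bins,
                                threshold=self.threshold)
        selected = table.selected
        if self.top_k is not None:
            ranked = list(table.best_score.sort_values(
                ascending=False, kind="stable").index)
            budget = ranked[: self.top_k]
            selected = [c for c in budget if c in selected] or budget
            selected = selected[: self.top_k]
        self.score_table_ = table
        self.scores_ = table.scores
        self.selected_channels_ = selected
        self.selected_idx_ = np.array([names.index(c) for c in selected],
                                      dtype=int)
        self.channel_names_ = list(names)
        return self

    def transform(self, X):
        if not hasattr(self, "selected_idx_"):
            raise RuntimeError("selector is not fitted")
        if isinstance(X, EpochSet):
            return X.select_channels(self.selected_channels_)
        return _as_array(X)[:, self.selected_idx_, :]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
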