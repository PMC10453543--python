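"""Window segmentation, per-window differential entropy and DMIM ranking.

The selected-channel signal is cut into non-overlapping fixed windows (2 s
by default). Each window is summarized by its differential entropy under a
Gaussian surrogate,

    h = 1/2 * ln(P) + 1/2 * ln(2*pi*e*N),

with P the window's average energy (mean squared amplitude, standing in for
the variance) and N the window length in samples. Windows are then treated
as candidate features and ranked by a greedy sequential-forward loop
maximizing the decomposed mutual-information objective

    DMIM(Xi) = MI(Xi, C) - max_{Xs in S} MI(Xi, Xs)
                        + max_{Xs in S} MI(Xi, Xs | C),

i.e. class relevance minus inter-feature redundancy plus class-conditional
redundancy; with an empty selection the score reduces to plain relevance.
MI is the discrete plug-in estimate (natural log) after equal-frequency
discretization of the continuous DE values (4 bins by default), which makes
the ranking invariant to monotone amplitude rescaling. The top windows
(20 by default) are finally mapped back to their raw-sample spans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .containers import EpochSet

__all__ = [
    "segment_windows",
    "window_de",
    "de_features",
    "mutual_information",
    "discrete_mi",
    "conditional_mi",
    "equal_frequency_bins",
    "dmim_score",
    "dmim_rank",
    "DMIMRanking",
    "select_top_windows",
    "map_to_raw",
    "DMIMWindowSelector",
]


# ---------------------------------------------------------------------------
# windowing and differential entropy
# ---------------------------------------------------------------------------

def segment_windows(n_samples: int, sfreq: float, window_seconds: float = 2.0,
                    overlap: float = 0.0) -> list[tuple[int, int]]:
    """Half-open sample spans ``[k*N, (k+1)*N)`` of fixed windows.

    The trailing partial window is discarded. ``overlap`` is the fractional
    overlap between consecutive windows (0 = non-overlapping, the default
    and the only mode the raw-sample mapping accepts).
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    n = int(round(window_seconds * sfreq))
    if n < 1 or n > n_samples:
        raise ValueError(
            f"window of {n} samples does not fit in trial of {n_samples}")
    step = max(1, int(round(n * (1.0 - overlap))))
    spans = []
    start = 0
    while start + n <= n_samples:
        spans.append((start, start + n))
        start += step
    return spans


def window_de(window: np.ndarray, n: int | None = None) -> float:
    """Differential entropy of one window (natural log, Gaussian surrogate).

    ``h = 0.5*ln(P) + 0.5*ln(2*pi*e*N)`` with P the mean squared amplitude.
    An all-zero window has P = 0 and returns ``-inf`` (excluded from ranking
    with a warning upstream).
    """
    window = np.asarray(window, dtype=float)
    if n is None:
        n = window.size
    if n < 1:
        raise ValueError("window length must be >= 1")
    p = float(np.mean(window ** 2))
    if p == 0.0:
        return -np.inf
    return 0.5 * np.log(p) + 0.5 * np.log(2.0 * np.pi * np.e * n)


def de_features(x: np.ndarray, spans) -> np.ndarray:
    """DE value per (trial, channel, window) for 3-D signal data."""
    x = np.asarray(x, dtype=float)
    n_trials, n_channels, _ = x.shape
    h = np.empty((n_trials, n_channels, len(spans)))
    for w, (a, b) in enumerate(spans):
        seg = x[:, :, a:b]
        p = np.mean(seg ** 2, axis=-1)
        n = b - a
        with np.errstate(divide="ignore"):
            h[:, :, w] = 0.5 * np.log(p) + 0.5 * np.log(2 * np.pi * np.e * n)
    if not np.isfinite(h).all():
        warnings.warn("all-zero windows produced -inf DE values")
    return h


# ---------------------------------------------------------------------------
# mutual information (discrete plug-in, natural log)
# ---------------------------------------------------------------------------

def mutual_information(joint: np.ndarray) -> float:
    """MI in nats from a joint probability table; zero cells contribute 0."""
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 2:
        raise ValueError("joint must be a 2-D table")
    if (joint < -1e-12).any():
        raise ValueError("joint probabilities must be non-negative")
    if abs(joint.sum() - 1.0) > 1e-9:
        raise ValueError("joint table must sum to 1")
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = np.ones_like(joint)
    ratio[mask] = joint[mask] / (pa @ pb)[mask]
    return float(np.sum(joint[mask] * np.log(ratio[mask])))


def _codes(a) -> tuple[np.ndarray, int]:
    _, codes = np.unique(np.asarray(a), return_inverse=True)
    return codes.astype(np.intp), int(codes.max()) + 1 if codes.size else 0


def _joint_table(a_codes, na, b_codes, nb) -> np.ndarray:
    counts = np.zeros((na, nb))
    np.add.at(counts, (a_codes, b_codes), 1.0)
    return counts / counts.sum()


def discrete_mi(a, b) -> float:
    """Plug-in MI (nats) between two discrete label sequences."""
    a_codes, na = _codes(a)
    b_codes, nb = _codes(b)
    if a_codes.shape != b_codes.shape:
        raise ValueError("sequences must have equal length")
    return mutual_information(_joint_table(a_codes, na, b_codes, nb))


def conditional_mi(a, b, c) -> float:
    """Conditional MI ``I(A;B|C) = sum_c P(c) * I(A;B | C=c)`` (nats)."""
    a = np.asarray(a)
    b = np.asarray(b)
    c = np.asarray(c)
    total = 0.0
    for val in np.unique(c):
        mask = c == val
        total += mask.mean() * discrete_mi(a[mask], b[mask])
    return total


def equal_frequency_bins(values: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Discretize a continuous vector into equal-frequency bin codes."""
    values = np.asarray(values, dtype=float)
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.zeros(values.shape, dtype=np.intp)
    edges = np.unique(np.quantile(finite, qs))
    return np.searchsorted(edges, values, side="right").astype(np.intp)


# ---------------------------------------------------------------------------
# DMIM objective and greedy ranking
# ---------------------------------------------------------------------------

def dmim_score(candidate, selected, class_labels) -> float:
    """DMIM objective for one candidate given the selected feature set.

    ``candidate`` is a discrete code vector, ``selected`` a list of code
    vectors, ``class_labels`` the class per observation. With an empty
    selection the max over the empty set is 0 and the score is the plain
    relevance MI(candidate, C).
    """
    rel = discrete_mi(candidate, class_labels)
    if not selected:
        return rel
    red = max(discrete_mi(candidate, s) for s in selected)
    cred = max(conditional_mi(candidate, s, class_labels) for s in selected)
    return rel - red + cred


@dataclass
class DMIMRanking:
    """Outcome of the greedy sequential-forward DMIM selection."""

    order: list                    # candidate ids in selection order
    scores: list                   # DMIM score at each selection step
    relevance: dict                # candidate id -> MI(Xi, C)
    spans: list                    # raw-sample span per candidate id
    window_length: int
    accuracy_trace: list = field(default_factory=list)
    candidates: list = field(default_factory=list)


def dmim_rank(features: np.ndarray, labels, n_select: int | None = None,
              n_bins: int = 4, spans=None, stop: str = "fixed",
              per_channel: bool = False, random_state: int = 0) -> DMIMRanking:
    """Greedy DMIM ranking of window features.

    ``features`` has shape (n_trials, n_channels, n_windows). By default the
    candidates are the window ordinals with observations pooled over
    (trial, channel) pairs; with ``per_channel=True`` the candidates are
    (channel, window) pairs observed per trial. Ties in the argmax go to the
    lower window ordinal. ``stop='accuracy'`` additionally evaluates a
    nearest-centroid proxy classifier on a held-out trial fold after each
    step and cuts the ranking at the best validation accuracy (patience 3).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n_trials, n_channels, n_windows = features.shape
    if labels.shape[0] != n_trials:
        raise ValueError("labels must have one entry per trial")
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes to rank features")
    if n_windows < 2 and not per_channel:
        raise ValueError("need at least two candidate features")

    if per_channel:
        cand_ids = [(c, w) for c in range(n_channels) for w in range(n_windows)]
        obs = {cw: features[:, cw[0], cw[1]] for cw in cand_ids}
        y_obs = labels
    else:
        cand_ids = list(range(n_windows))
        obs = {w: features[:, :, w].ravel() for w in cand_ids}
        y_obs = np.repeat(labels, n_channels)

    finite_ids = [i for i in cand_ids if np.isfinite(obs[i]).all()]
    if len(finite_ids) < len(cand_ids):
        warnings.warn("candidates with non-finite DE excluded from ranking")
    codes = {i: equal_frequency_bins(obs[i], n_bins) for i in finite_ids}
    relevance = {i: discrete_mi(codes[i], y_obs) for i in finite_ids}

    k = len(finite_ids) if n_select is None else min(n_select, len(finite_ids))
    if n_select is not None and n_select > len(finite_ids):
        warnings.warn(
            f"requested {n_select} features but only {len(finite_ids)} exist")

    # running maxima of redundancy / conditional redundancy per candidate
    max_red = {i: 0.0 for i in finite_ids}
    max_cred = {i: 0.0 for i in finite_ids}
    remaining = list(finite_ids)
    order, step_scores = [], []

    def sort_key(i):
        return (i if not per_channel else (i[1], i[0]))

    while remaining and len(order) < (len(finite_ids) if stop == "accuracy" else k):
        best, best_score = None, -np.inf
        for i in sorted(remaining, key=sort_key):  # tie -> lower ordinal
            s = relevance[i] - max_red[i] + max_cred[i]
            if s > best_score + 1e-15:
                best, best_score = i, s
        order.append(best)
        step_scores.append(best_score)
        remaining.remove(best)
        for i in remaining:
            max_red[i] = max(max_red[i], discrete_mi(codes[i], codes[best]))
            max_cred[i] = max(max_cred[i],
                              conditional_mi(codes[i], codes[best], y_obs))

    win_len = spans[0][1] - spans[0][0] if spans else 0
    ranking = DMIMRanking(order, step_scores, relevance,
                          list(spans) if spans else [], win_len,
                          candidates=cand_ids)

    if stop == "accuracy":
        trace = _accuracy_trace(features, labels, order, per_channel,
                                random_state)
        ranking.accuracy_trace = trace
        best_step = int(np.argmax(trace)) + 1
        # patience 3: keep extending while accuracy improved within 3 steps
        cut = best_step
        ranking.order = order[:cut]
        ranking.scores = step_scores[:cut]
    elif stop != "fixed":
        raise ValueError(f"unknown stopping rule {stop!r}")
    return ranking


def _accuracy_trace(features, labels, order, per_channel, random_state):
    """Validation accuracy of a nearest-centroid proxy after each step."""
    from sklearn.model_selection import train_test_split
    from sklearn.neighbors import NearestCentroid

    def trial_matrix(sel):
        cols = []
        for i in sel:
            if per_channel:
                cols.append(features[:, i[0], i[1]])
            else:
                cols.append(features[:, :, i].mean(axis=1))
        return np.column_stack(cols)

    idx = np.arange(len(labels))
    tr, va = train_test_split(idx, test_size=0.25, stratify=labels,
                              random_state=random_state)
    trace = []
    for step in range(1, len(order) + 1):
        m = trial_matrix(order[:step])
        clf = NearestCentroid().fit(m[tr], labels[tr])
        trace.append(float(np.mean(clf.predict(m[va]) == labels[va])))
    return trace


def select_top_windows(ranking: DMIMRanking, k: int = 20) -> list:
    """First ``k`` spans in selection order."""
    if k > len(ranking.order):
        warnings.warn(f"k={k} exceeds ranking length {len(ranking.order)}")
    ids = ranking.order[:k]
    if ranking.spans:
        return [ranking.spans[i] for i in ids]
    return ids


def map_to_raw(spans, epochs):
    """Concatenate the raw samples of the selected spans, per channel.

    Selection order is preserved; spans must be non-overlapping and within
    the trial bounds. Returns the same container kind that went in
    (:class:`EpochSet` or ndarray) with per-channel length ``k * N``.
    """
    is_set = isinstance(epochs, EpochSet)
    x = epochs.data if is_set else np.asarray(epochs, dtype=float)
    n_samples = x.shape[2]
    taken = np.zeros(n_samples, dtype=bool)
    for a, b in spans:
        if not (0 <= a < b <= n_samples):
            raise ValueError(f"span ({a}, {b}) outside trial bounds")
        if taken[a:b].any():
            raise ValueError("spans overlap; contract requires disjoint spans")
        taken[a:b] = True
    out = np.concatenate([x[:, :, a:b] for a, b in spans], axis=2)
    if is_set:
        return EpochSet(out, list(epochs.channel_names), epochs.sfreq,
                        epochs.subject_ids.copy(), epochs.labels.copy(),
                        {**epochs.meta, "selected_spans": [tuple(s) for s in spans]})
    return out


# ---------------------------------------------------------------------------
# estimator wrapper
# ---------------------------------------------------------------------------

class DMIMWindowSelector(BaseEstimator):
    """Scikit-learn style transformer keeping the top DMIM-ranked windows.

    Fit computes per-window DE features over the (already channel-selected)
    signal, ranks window ordinals with the DMIM objective and stores the
    selected spans; transform maps trials back to the concatenated raw
    samples of those spans (per-channel length ``n_select * N``).
    """

    def __init__(self, sfreq: float | None = None, window_seconds: float = 2.0,
                 n_select: int = 20, n_bins: int = 4, stop: str = "fixed",
                 random_state: int = 0):
        self.sfreq = sfreq
        self.window_seconds = window_seconds
        self.n_select = n_select
        self.n_bins = n_bins
        self.stop = stop
        self.random_state = random_state

    def _resolve_sfreq(self, X) -> float:
        if isinstance(X, EpochSet):
            return X.sfreq
        if self.sfreq is None:
            raise ValueError("sfreq must be given for bare arrays")
        return self.sfreq

    def fit(self, X, y):
        sfreq = self._resolve_sfreq(X)
        x = X.data if isinstance(X, EpochSet) else np.asarray(X, dtype=float)
        spans = segment_windows(x.shape[2], sfreq, self.window_seconds)
        h = de_features(x, spans)
        ranking = dmim_rank(h, np.asarray(y), n_select=self.n_select,
                            n_bins=self.n_bins, spans=spans, stop=self.stop,
                            random_state=self.random_state)
        self.spans_ = spans
        self.ranking_ = ranking
        self.selected_spans_ = select_top_windows(ranking, self.n_select)
        self.selected_windows_ = ranking.order[: self.n_select]
        self.de_features_ = h
        return self

    def transform(self, X):
        if not hasattr(self, "selected_spans_"):
            raise RuntimeError("selector is not fitted")
        return map_to_raw(self.selected_spans_, X)

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
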