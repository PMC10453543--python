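"""Graph empirical mode decomposition and class-conditional augmentation.

An EEG epoch is viewed as a signal on a graph and decomposed into graph
intrinsic mode functions (IMFs) by sifting: strict local extrema against the
graph neighborhood are detected, upper and lower envelopes are estimated by
harmonic (Laplacian-regularized) interpolation through the extrema, and the
mean envelope is subtracted until a standard-deviation stop criterion is
met. The procedure repeats on the residue until a maximum of five IMFs is
reached or the residue has fewer than two maxima or two minima. The sum of
IMFs plus the residual reconstructs the input exactly (up to floating-point
rounding), because every IMF is literally subtracted from the running
residue.

Artificial epochs are synthesized per class by mixing IMFs across epochs:
the j-th IMF of the j-th contributing epoch is taken (a missing IMF counts
as the zero graph signal), so each artificial epoch is a sum of
mono-component pieces from five same-class contributors and inherits that
class label.

Two graph constructions are provided: a per-channel path graph over time
("temporal" mode; on a path, harmonic interpolation reduces to linear
interpolation with constant extension, so this mode is a classical-EMD
variant and doubles as a cross-check), and the Cartesian product of a k-NN
Gaussian-kernel electrode graph (10-20 coordinates) with that path graph
("product" mode).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from sklearn.base import BaseEstimator

from .containers import EpochSet
from .io import Montage, standard_1020_montage

__all__ = [
    "SignalGraph",
    "build_signal_graph",
    "GraphIMFDecomposition",
    "decompose",
    "synthesize_epoch",
    "augment_dataset",
    "GraphEMDAugmenter",
]

#: sifting SD stop criterion and iteration cap
SIFT_SD = 0.2
MAX_SIFT_ITER = 10

_logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

@dataclass
class SignalGraph:
    """Weighted graph carrying one epoch's samples on its vertices."""

    adjacency: sp.csr_matrix
    mode: str                      # "temporal" (path over time) or "product"
    shape: tuple                   # (n_channels, n_samples) mapped onto vertices
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.adjacency
        if (abs(a - a.T) > 1e-12 * (abs(a) + abs(a.T))).nnz:
            raise ValueError("adjacency must be symmetric")
        if a.data.size and a.data.min() < 0:
            raise ValueError("edge weights must be non-negative")

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]

    @property
    def laplacian(self) -> sp.csr_matrix:
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        return (sp.diags(deg) - self.adjacency).tocsr()


def _path_adjacency(n: int) -> sp.csr_matrix:
    if n < 2:
        return sp.csr_matrix((n, n))
    ones = np.ones(n - 1)
    return sp.diags([ones, ones], [-1, 1]).tocsr()


def _spatial_adjacency(coords: np.ndarray, knn: int) -> sp.csr_matrix:
    """Symmetrized k-NN graph with a Gaussian kernel on electrode distances."""
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    k = min(knn, n - 1)
    a = np.zeros((n, n))
    neigh_d = []
    for i in range(n):
        nbrs = np.argpartition(d[i], k - 1)[:k]
        neigh_d.extend(d[i, nbrs])
        a[i, nbrs] = 1.0
    sigma = float(np.median(neigh_d)) or 1.0
    w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    w[~((a > 0) | (a.T > 0))] = 0.0
    np.fill_diagonal(w, 0.0)
    return sp.csr_matrix(np.maximum(w, w.T))


def build_signal_graph(montage: Montage | None, n_samples: int,
                       mode: str = "temporal", channel_names=None,
                       knn: int = 4) -> SignalGraph:
    """Build the graph an epoch lives on.

    ``temporal``: a path graph over the time samples, applied per channel.
    ``product``: Cartesian product of the k-NN electrode graph (from the
    montage coordinates of ``channel_names``) and the path graph; vertex
    ``ch * n_samples + t`` carries channel ch at sample t.
    """
    a_t = _path_adjacency(n_samples)
    if mode == "temporal":
        return SignalGraph(a_t, "temporal", (1, n_samples),
                           {"n_samples": n_samples})
    if mode != "product":
        raise ValueError(f"unknown graph mode {mode!r}")
    if channel_names is None:
        raise ValueError("product mode needs channel_names")
    if montage is None:
        montage = standard_1020_montage(channel_names)
    missing = [c for c in channel_names if c in montage.unresolved
               or c not in montage.positions]
    if missing:
        raise ValueError(f"unresolvable electrodes for product graph: {missing}")
    coords = np.array([montage.positions[c] for c in channel_names])
    a_s = _spatial_adjacency(coords, knn)
    n_ch = len(channel_names)
    adj = (sp.kron(sp.identity(n_ch), a_t) +
           sp.kron(a_s, sp.identity(n_samples))).tocsr()
    return SignalGraph(adj, "product", (n_ch, n_samples),
                       {"knn": knn, "n_channels": n_ch,
                        "n_samples": n_samples})


# ---------------------------------------------------------------------------
# sifting machinery
# ---------------------------------------------------------------------------

def _neighbor_extrema(values: np.ndarray, adj: sp.csr_matrix):
    """Strict local maxima / minima against graph neighbors (plateaus are
    not extrema)."""
    coo = adj.tocoo()
    nmax = np.full(values.shape, -np.inf)
    nmin = np.full(values.shape, np.inf)
    np.maximum.at(nmax, coo.row, values[coo.col])
    np.minimum.at(nmin, coo.row, values[coo.col])
    return np.flatnonzero(values > nmax), np.flatnonzero(values < nmin)


def _harmonic_envelope(values: np.ndarray, knots: np.ndarray,
                       graph: SignalGraph) -> np.ndarray:
    """Interpolate through the knot values by minimizing the Laplacian
    quadratic form (discrete harmonic interpolation)."""
    n = values.shape[0]
    if knots.size == n:
        return values.copy()
    if graph.mode == "temporal":
        # harmonic interpolation on a path == linear interpolation with
        # constant extension beyond the extreme knots
        return np.interp(np.arange(n), knots, values[knots])
    lap = graph.laplacian.tocsc()
    free = np.setdiff1d(np.arange(n), knots)
    out = np.empty(n)
    out[knots] = values[knots]
    l_uu = lap[np.ix_(free, free)]
    l_uk = lap[np.ix_(free, knots)]
    out[free] = splu(l_uu.tocsc()).solve(-l_uk @ values[knots])
    return out


def _sift(residue: np.ndarray, graph: SignalGraph) -> np.ndarray | None:
    """Extract one IMF from the residue, or None if too few extrema."""
    adj = graph.adjacency
    h = residue
    maxima, minima = _neighbor_extrema(h, adj)
    if maxima.size < 2 or minima.size < 2:
        return None
    for _ in range(MAX_SIFT_ITER):
        upper = _harmonic_envelope(h, maxima, graph)
        lower = _harmonic_envelope(h, minima, graph)
        mean = 0.5 * (upper + lower)
        h_new = h - mean
        denom = float(np.sum(h ** 2))
        sd = float(np.sum(mean ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < SIFT_SD:
            break
        maxima, minima = _neighbor_extrema(h, adj)
        if maxima.size < 2 or minima.size < 2:
            break
    return h


@dataclass
class GraphIMFDecomposition:
    """Ordered graph IMFs plus residual for one epoch."""

    imfs: list                     # each (n_channels, n_samples)
    residual: np.ndarray
    epoch_id: int | None = None
    class_label: object = None
    mode: str = "temporal"

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


def decompose(epoch: np.ndarray, graph: SignalGraph, max_imfs: int = 5,
              epoch_id: int | None = None,
              class_label=None) -> GraphIMFDecomposition:
    """Decompose one channels x samples epoch on the given graph.

    A constant signal has no strict extrema and yields zero IMFs with the
    residual equal to the signal.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_ch, n_samp = epoch.shape
    if graph.mode == "product":
        if graph.shape != (n_ch, n_samp):
            raise ValueError(
                f"graph carries shape {graph.shape}, epoch is {(n_ch, n_samp)}")
        flat_imfs, residual = _decompose_vector(epoch.ravel(), graph, max_imfs)
        imfs = [f.reshape(n_ch, n_samp) for f in flat_imfs]
        residual = residual.reshape(n_ch, n_samp)
    else:
        if graph.shape[1] != n_samp:
            raise ValueError("temporal graph length mismatches the epoch")
        per_ch = [_decompose_vector(epoch[c], graph, max_imfs)
                  for c in range(n_ch)]
        n_imfs = max((len(f) for f, _ in per_ch), default=0)
        imfs = []
        for j in range(n_imfs):
            layer = np.zeros((n_ch, n_samp))
            for c, (f, _) in enumerate(per_ch):
                if j < len(f):
                    layer[c] = f[j]
            imfs.append(layer)
        residual = np.stack([r for _, r in per_ch]) if per_ch else epoch.copy()
    return GraphIMFDecomposition(imfs, residual, epoch_id, class_label,
                                 graph.mode)


def _decompose_vector(x: np.ndarray, graph: SignalGraph, max_imfs: int):
    residue = x.astype(float).copy()
    imfs = []
    while len(imfs) < max_imfs:
        imf = _sift(residue, graph)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    return imfs, residue


# ---------------------------------------------------------------------------
# class-conditional synthesis
# ---------------------------------------------------------------------------

def synthesize_epoch(contributors, class_c, max_imfs: int = 5) -> np.ndarray:
    """Artificial epoch from an ordered contributor list of decompositions.

    The j-th IMF is taken from the j-th contributor; a contributor lacking
    that IMF contributes the zero graph signal. All contributors must carry
    ``class_c`` (single-class mixing).
    """
    contributors = list(contributors)
    if len(contributors) != max_imfs:
        raise ValueError(f"need exactly {max_imfs} contributors")
    for d in contributors:
        if d.class_label != class_c:
            raise ValueError(
                f"contributor of class {d.class_label!r} mixed into {class_c!r}")
    shape = contributors[0].residual.shape
    out = np.zeros(shape)
    for j, d in enumerate(contributors):
        if j < d.n_imfs:
            out += d.imfs[j]
    return out


def _default_class_labels(epochs: EpochSet) -> np.ndarray:
    if "emotion" in epochs.labels.columns:
        return epochs.labels["emotion"].to_numpy(dtype=object)
    from .containers import class_vector
    return class_vector(epochs, "binary_valence")


def augment_dataset(epochs: EpochSet, ratio: float = 1.0, seed: int = 0,
                    mode: str = "temporal", max_imfs: int = 5,
                    labels=None, montage: Montage | None = None) -> EpochSet:
    """Append class-conditional artificial epochs to an epoch set.

    Generates ``round(ratio * class_count)`` artificial epochs per class
    (class proportions preserved); for each synthesis, ``max_imfs`` distinct
    contributor epochs of that class are drawn uniformly without
    replacement. Artificial epochs carry ``augmented=True`` in the label
    table and provenance records in ``meta``; a class with fewer than
    ``max_imfs`` epochs is skipped with a warning. Deterministic under
    ``seed``.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    y = np.asarray(labels if labels is not None
                   else _default_class_labels(epochs))
    if ratio == 0:
        return epochs
    rng = np.random.default_rng(seed)
    if mode == "product":
        graph = build_signal_graph(montage, epochs.n_samples, "product",
                                   channel_names=epochs.channel_names)
    else:
        graph = build_signal_graph(None, epochs.n_samples, "temporal")

    decos: dict[int, GraphIMFDecomposition] = {}
    new_data, new_rows, new_subjects, provenance = [], [], [], []
    for cls in pd.unique(y):
        members = np.flatnonzero(y == cls)
        n_new = int(round(ratio * members.size))
        if members.size < max_imfs:
            warnings.warn(
                f"class {cls!r} has {members.size} epochs < {max_imfs}; skipped")
            continue
        for _ in range(n_new):
            chosen = members[rng.choice(members.size, size=max_imfs,
                                        replace=False)]
            for idx in chosen:
                if idx not in decos:
                    decos[idx] = decompose(epochs.data[idx], graph, max_imfs,
                                           epoch_id=int(idx), class_label=cls)
            art = synthesize_epoch([decos[i] for i in chosen], cls, max_imfs)
            _variance_guard(art, [epochs.data[i] for i in chosen], cls)
            new_data.append(art)
            row = epochs.labels.iloc[chosen[0]].to_dict()
            row["augmented"] = True
            new_rows.append(row)
            new_subjects.append(epochs.subject_ids[chosen[0]])
            provenance.append({"class": cls,
                               "contributors": [int(i) for i in chosen]})

    labels_orig = epochs.labels.copy()
    if "augmented" not in labels_orig.columns:
        labels_orig["augmented"] = False
    if not new_data:
        return EpochSet(epochs.data.copy(), list(epochs.channel_names),
                        epochs.sfreq, epochs.subject_ids.copy(), labels_orig,
                        dict(epochs.meta))
    all_labels = pd.concat([labels_orig, pd.DataFrame(new_rows)],
                           ignore_index=True)
    return EpochSet(
        data=np.concatenate([epochs.data, np.stack(new_data)]),
        channel_names=list(epochs.channel_names),
        sfreq=epochs.sfreq,
        subject_ids=np.concatenate([epochs.subject_ids,
                                    np.asarray(new_subjects, dtype=int)]),
        labels=all_labels,
        meta={**epochs.meta, "augmentation": {"ratio": ratio, "seed": seed,
                                              "mode": mode,
                                              "provenance": provenance}},
    )


def _variance_guard(artificial: np.ndarray, contributors, cls) -> None:
    """Heuristic blow-up guard: per-channel variance of the artificial epoch
    should stay within 1.5x the contributor variance range (logged only)."""
    var = artificial.var(axis=1)
    cvars = np.stack([c.var(axis=1) for c in contributors])
    lo, hi = cvars.min(axis=0) / 1.5, cvars.max(axis=0) * 1.5
    bad = np.flatnonzero((var < lo) | (var > hi))
    if bad.size:
        _logger.info(
            "artificial epoch for class %r: channel variance outside "
            "contributor range x1.5 on channels %s", cls, bad.tolist())


class GraphEMDAugmenter(BaseEstimator):
    """Scikit-learn style resampler wrapping :func:`augment_dataset`.

    ``fit_resample(X, y)`` accepts a (n_trials, n_channels, n_samples) array
    with per-trial class labels and returns the augmented pair plus a
    provenance mask (original=False / artificial=True) in
    ``self.augmented_mask_``; an :class:`EpochSet` is returned as such.
    """

    def __init__(self, ratio: float = 1.0, mode: str = "temporal",
                 max_imfs: int = 5, random_state: int = 0):
        self.ratio = ratio
        self.mode = mode
        self.max_imfs = max_imfs
        self.random_state = random_state

    def fit_resample(self, X, y=None):
        if isinstance(X, EpochSet):
            out = augment_dataset(X, ratio=self.ratio, seed=self.random_state,
                                  mode=self.mode, max_imfs=self.max_imfs,
                                  labels=y)
            self.augmented_mask_ = out.is_augmented
            return out
        x = np.asarray(X, dtype=float)
        if y is None:
            raise ValueError("y is required for bare arrays")
        y = np.asarray(y)
        labels = pd.DataFrame({"cls": y})
        epochs = EpochSet(x, [f"ch{i}" for i in range(x.shape[1])], 1.0,
                          np.zeros(x.shape[0], dtype=int), labels)
        out = augment_dataset(epochs, ratio=self.ratio,
                              seed=self.random_state, mode=self.mode,
                              max_imfs=self.max_imfs, labels=y)
        self.augmented_mask_ = out.is_augmented
        return out.data, out.labels["cls"].to_numpy()
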