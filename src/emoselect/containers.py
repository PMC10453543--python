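"""In-memory containers shared across the pipeline.

The central object is :class:`EpochSet`: a stack of fixed-length multichannel
EEG trials (epochs) with sampling metadata, per-trial subject identifiers and
a label table. All signal arrays are oriented channels x samples and expressed
in microvolts; sample indices are 0-based and window spans are half-open
``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "class_vector"]

#: Tasks understood by :func:`class_vector`.
TASKS = ("binary_valence", "binary_arousal", "three_class")


@dataclass
class EpochSet:
    """Labelled collection of fixed-length multichannel EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    channel_names : list of str
        Unique channel names, 10-20 nomenclature where applicable.
    sfreq : float
        Sampling rate in Hz.
    subject_ids : ndarray, shape (n_trials,)
        Integer subject identifier per trial.
    labels : DataFrame with one row per trial. Rating-scheme datasets carry
        ``valence`` / ``arousal`` columns (1-9 floats); categorical datasets a
        ``emotion`` column. An optional boolean ``augmented`` column flags
        artificial epochs.
    """

    data: np.ndarray
    channel_names: list[str]
    sfreq: float
    subject_ids: np.ndarray
    labels: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_trials, n_channels, n_samples), got shape {self.data.shape}"
            )
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        if self.subject_ids.shape != (self.data.shape[0],):
            raise ValueError("subject_ids must have one entry per trial")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel axis")
        if len(set(n.upper() for n in self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique (case-insensitive)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per trial")
        self.labels = self.labels.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def is_augmented(self) -> np.ndarray:
        """Boolean mask of artificial (augmented) trials."""
        if "augmented" in self.labels.columns:
            return self.labels["augmented"].to_numpy(dtype=bool)
        return np.zeros(self.n_trials, dtype=bool)

    # -- subsetting ------------------------------------------------------
    def select_trials(self, index) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            channel_names=list(self.channel_names),
            sfreq=self.sfreq,
            subject_ids=self.subject_ids[index],
            labels=self.labels.iloc[index].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def select_channels(self, names) -> "EpochSet":
        lookup = {n.upper(): i for i, n in enumerate(self.channel_names)}
        try:
            idx = [lookup[str(n).upper()] for n in names]
        except KeyError as err:
            raise KeyError(f"unknown channel {err.args[0]!r}") from None
        return EpochSet(
            data=self.data[:, idx, :],
            channel_names=[self.channel_names[i] for i in idx],
            sfreq=self.sfreq,
            subject_ids=self.subject_ids.copy(),
            labels=self.labels.copy(),
            meta=dict(self.meta),
        )

    def __eq__(self, other) -> bool:  # bit-identity, used by determinism tests
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and self.channel_names == other.channel_names
            and self.sfreq == other.sfreq
            and np.array_equal(self.subject_ids, other.subject_ids)
            and self.labels.equals(other.labels)
        )


def class_vector(epochs: EpochSet, task: str) -> np.ndarray:
    """Per-trial class labels for a classification task.

    ``binary_valence`` / ``binary_arousal`` binarize the 1-9 SAM rating at 5
    (> 5 high, <= 5 low); ``three_class`` passes the categorical ``emotion``
    column through.
    """
    from .synthetic import binarize_sam  # local import avoids a cycle

    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if task == "three_class":
        if "emotion" not in epochs.labels.columns:
            raise ValueError("three_class task needs an 'emotion' label column")
        return epochs.labels["emotion"].to_numpy(dtype=object)
    axis = "valence" if task == "binary_valence" else "arousal"
    if axis not in epochs.labels.columns:
        raise ValueError(f"{task} task needs a {axis!r} label column")
    ratings = epochs.labels[axis].to_numpy(dtype=float)
    return np.array([binarize_sam(r) for r in ratings], dtype=object)
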