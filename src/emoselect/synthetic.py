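"""Synthetic EEG epoch sets with controllable class-discriminative structure.

Real emotion-recognition corpora (DEAP, MAHNOB-HCI, SEED) are licensed and
cannot ship with a toolkit, so every downstream stage is exercised on
synthetic epochs that reproduce those recording geometries: subject / trial
counts, channel counts, sampling rates and trial durations.

Each synthetic trial is 1/f (pink) background noise; class-discriminative
structure is planted as band-limited sinusoidal bursts whose amplitude is
scaled per class, injected only into a declared set of informative channels
and only inside a declared set of 2-s windows. This gives the
differential-entropy-based selectors downstream a variance contrast to find,
without modelling artifacts (blinks, EMG, drift) that the pipeline never
exploits.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; identical specs produce bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "DatasetProfile",
    "SyntheticSpec",
    "builtin_profile",
    "generate_epoch_set",
    "binarize_sam",
    "BAND_FREQS",
    "benchmark_spec",
    "null_spec",
    "planted_recovery_spec",
    "trend_benchmark_spec",
]

#: Centre frequencies (Hz) of the classical EEG bands used for planted bursts.
BAND_FREQS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 22.0, "gamma": 40.0}

#: Ordered pool of 10-20 electrode names used to label synthetic channels.
#: All names resolve against the standard 10-20 montage.
CHANNEL_NAME_POOL = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "Oz",
    "AF3", "AF4", "FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "CP5", "CP6",
    "PO3", "PO4", "AF7", "AF8", "F1", "F2", "F5", "F6", "FC3", "FC4",
    "C1", "C2", "C5", "C6", "CP3", "CP4", "P1", "P2", "P5", "P6",
    "PO7", "PO8", "FT7", "FT8", "TP7", "TP8", "AFz", "FCz", "CPz", "POz",
    "Iz", "FT9", "FT10", "TP9",
]

LABEL_SCHEMES = ("valence_arousal_1to9", "categorical_3class")
_THREE_CLASSES = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class DatasetProfile:
    """Recording geometry of one dataset (subjects, trials, channels, rate)."""

    name: str
    n_subjects: int
    n_trials_per_subject: int
    n_channels: int
    sampling_rate: float
    trial_duration: float
    label_scheme: str

    def __post_init__(self) -> None:
        for f in ("n_subjects", "n_trials_per_subject", "n_channels"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.label_scheme not in LABEL_SCHEMES:
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")
        n = self.trial_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration x sampling_rate must be an integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    def replace(self, **kw) -> "DatasetProfile":
        return dataclasses.replace(self, **kw)


_BUILTIN = {
    # DEAP: 32 subjects x 40 trials, 32 EEG channels at 128 Hz, one-minute
    # musical video clips.
    "deap_like": DatasetProfile("deap_like", 32, 40, 32, 128.0, 60.0,
                                "valence_arousal_1to9"),
    # MAHNOB-HCI: 27 usable subjects x 20 trials, 32 channels at 256 Hz.
    # Clips range 34-117 s; the default 60 s keeps the canonical per-trial
    # shape (15,360 samples); override trial_duration for other lengths.
    "mahnob_like": DatasetProfile("mahnob_like", 27, 20, 32, 256.0, 60.0,
                                  "valence_arousal_1to9"),
    # SEED: 15 subjects x 15 trials, 62 channels at 128 Hz, four-minute film
    # excerpts, categorical positive/neutral/negative labels.
    "seed_like": DatasetProfile("seed_like", 15, 15, 62, 128.0, 240.0,
                                "categorical_3class"),
}


def builtin_profile(name: str) -> DatasetProfile:
    """Return one of the built-in dataset geometries.

    ``name`` must be one of ``deap_like``, ``mahnob_like``, ``seed_like``.
    """
    try:
        return _BUILTIN[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; available: {sorted(_BUILTIN)}"
        ) from None


def binarize_sam(rating: float) -> str:
    """Binarize a 1-9 SAM rating: > 5 -> ``'high'``, <= 5 -> ``'low'``."""
    rating = float(rating)
    if not (1.0 <= rating <= 9.0):
        raise ValueError(f"SAM rating must be in [1, 9], got {rating}")
    return "high" if rating > 5.0 else "low"


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for one synthetic epoch set.

    ``class_band_power`` maps class name -> {band: amplitude multiplier}.
    For rating-scheme profiles the classes are ``'low'`` / ``'high'``
    (driving both valence and arousal ratings); for categorical profiles
    ``'negative'`` / ``'neutral'`` / ``'positive'``. An empty map plants no
    signal at all (pure-noise null dataset, flagged in metadata).
    Multipliers scale a burst whose base amplitude equals ``noise_scale``.
    """

    profile: DatasetProfile
    informative_channels: frozenset = frozenset()
    informative_window_indices: frozenset = frozenset()
    class_band_power: dict = field(default_factory=dict)
    noise_scale: float = 10.0  # microvolts (std of the pink background)
    window_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "informative_channels",
                           frozenset(int(c) for c in self.informative_channels))
        object.__setattr__(self, "informative_window_indices",
                           frozenset(int(w) for w in self.informative_window_indices))
        nc = self.profile.n_channels
        if any(not (0 <= c < nc) for c in self.informative_channels):
            raise ValueError("informative_channels outside [0, n_channels)")
        for cls, bands in self.class_band_power.items():
            for band, mult in bands.items():
                if band not in BAND_FREQS:
                    raise ValueError(f"unknown band {band!r}")
                if mult <= 0:
                    raise ValueError("band-power multipliers must be > 0")

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)


def _classes_for(profile: DatasetProfile) -> tuple:
    if profile.label_scheme == "categorical_3class":
        return _THREE_CLASSES
    return ("low", "high")


def _pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit variance per channel, via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    # flatten below 1 Hz so the DC/infra-slow part does not dominate
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_epoch_set(spec: SyntheticSpec) -> EpochSet:
    """Generate a labelled synthetic :class:`~emoselect.containers.EpochSet`.

    Per trial: pink background noise scaled to ``noise_scale`` plus, for the
    trial's class, one random-phase sinusoid per configured band, with
    amplitude ``noise_scale * multiplier``, present only in the informative
    channels and only inside the informative windows. Class labels are drawn
    balanced per subject; rating-scheme profiles receive integer SAM ratings
    consistent with the class on both valence and arousal axes.
    """
    prof = spec.profile
    if prof.n_channels > len(CHANNEL_NAME_POOL):
        raise ValueError(
            f"at most {len(CHANNEL_NAME_POOL)} synthetic channels supported"
        )
    rng = np.random.default_rng(spec.seed)
    classes = _classes_for(prof)
    n_samples = prof.n_samples
    win_len = int(round(spec.window_seconds * prof.sampling_rate))
    t = np.arange(n_samples) / prof.sampling_rate

    # sample mask of informative windows
    win_mask = np.zeros(n_samples)
    for w in sorted(spec.informative_window_indices):
        start = w * win_len
        if start >= n_samples:
            raise ValueError(f"informative window {w} outside the trial")
        win_mask[start:min(start + win_len, n_samples)] = 1.0

    ch_idx = sorted(spec.informative_channels)

    # ---- labels: balanced class sequence per subject --------------------
    rows = []
    trial_classes = []
    for subj in range(prof.n_subjects):
        seq = [classes[i % len(classes)] for i in range(prof.n_trials_per_subject)]
        seq = [seq[i] for i in rng.permutation(len(seq))]
        for trial, cls in enumerate(seq):
            trial_classes.append(cls)
            if prof.label_scheme == "categorical_3class":
                rows.append({"subject": subj, "trial": trial, "emotion": cls})
            else:
                lo, hi = (6, 9) if cls == "high" else (1, 5)
                rows.append({
                    "subject": subj, "trial": trial,
                    "valence": float(rng.integers(lo, hi + 1)),
                    "arousal": float(rng.integers(lo, hi + 1)),
                })
    labels = pd.DataFrame(rows)
    n_trials = len(labels)

    # ---- signals --------------------------------------------------------
    data = np.empty((n_trials, prof.n_channels, n_samples))
    for i in range(n_trials):
        trial = spec.noise_scale * _pink_noise(
            rng, (prof.n_channels, n_samples), prof.sampling_rate)
        bands = spec.class_band_power.get(trial_classes[i], {})
        if ch_idx and bands and win_mask.any():
            for band, mult in sorted(bands.items()):
                phases = rng.uniform(0.0, 2 * np.pi, size=len(ch_idx))
                burst = np.sin(2 * np.pi * BAND_FREQS[band] * t[None, :]
                               + phases[:, None])
                trial[ch_idx, :] += spec.noise_scale * mult * burst * win_mask
        data[i] = trial

    meta = {
        "profile": prof.name,
        "seed": spec.seed,
        "null_dataset": not (ch_idx and spec.class_band_power
                             and spec.informative_window_indices),
        "informative_channels": ch_idx,
        "informative_windows": sorted(spec.informative_window_indices),
    }
    return EpochSet(
        data=data,
        channel_names=CHANNEL_NAME_POOL[:prof.n_channels],
        sfreq=prof.sampling_rate,
        subject_ids=labels["subject"].to_numpy(),
        labels=labels.drop(columns=["subject"]),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Canonical study conditions used by the test-bench and reproduction script.
# Sizes are fixed package-level choices (see docs/methods.md) so that results
# are comparable across runs.
# ---------------------------------------------------------------------------

def benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """Strongly separable 2-class benchmark: 8 subjects x 20 trials.

    8 channels at 128 Hz, 6-s trials (3 windows); 4 informative channels and
    2 informative windows. The classes are band-separated (low: theta burst,
    high: alpha + beta bursts), i.e. they differ in both spectral content
    and band power, which is the kind of contrast the differential-entropy
    selectors and the CNN are built for.
    """
    prof = DatasetProfile("benchmark", 8, 20, 8, 128.0, 6.0,
                          "valence_arousal_1to9")
    return SyntheticSpec(
        profile=prof,
        informative_channels=frozenset({0, 2, 4, 6}),
        informative_window_indices=frozenset({0, 2}),
        class_band_power={
            "low": {"theta": 2.0},
            "high": {"alpha": 2.5, "beta": 2.0},
        },
        seed=seed,
    )


def null_spec(seed: int = 0) -> SyntheticSpec:
    """Pure-noise control with the benchmark geometry scaled down (4 x 8)."""
    prof = DatasetProfile("null", 4, 8, 6, 128.0, 6.0, "valence_arousal_1to9")
    return SyntheticSpec(profile=prof, seed=seed)


def planted_recovery_spec(seed: int = 0) -> SyntheticSpec:
    """Planted-signal recovery conditions: 10 informative channels out of 16
    and 20 informative windows out of 30 (60-s trials at 128 Hz), strong
    contrast; 6 subjects x 12 trials."""
    prof = DatasetProfile("planted", 6, 12, 16, 128.0, 60.0,
                          "valence_arousal_1to9")
    return SyntheticSpec(
        profile=prof,
        informative_channels=frozenset(range(10)),
        informative_window_indices=frozenset(range(20)),
        class_band_power={
            "low": {"alpha": 0.3},
            "high": {"alpha": 3.0, "beta": 2.0},
        },
        seed=seed,
    )


def trend_benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """Smaller benchmark used for the augmentation-trend study (5 x 16)."""
    prof = DatasetProfile("trend", 5, 16, 6, 128.0, 6.0,
                          "valence_arousal_1to9")
    return SyntheticSpec(
        profile=prof,
        informative_channels=frozenset({0, 2, 4}),
        informative_window_indices=frozenset({0, 2}),
        class_band_power={
            "low": {"theta": 2.0},
            "high": {"alpha": 2.5, "beta": 2.0},
        },
        seed=seed,
    )
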