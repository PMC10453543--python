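"""Reading and writing EEG epochs, labels and montage geometry.

Two on-disk layouts are supported, both one directory per dataset:

* fixture CSV: ``epochs/<subject>_<trial>.csv`` holding the channels x
  samples matrix (stored with samples as rows and a header row of channel
  names), ``labels.tsv`` (subject, trial, valence/arousal or emotion,
  optional ``augmented`` flag) and ``profile.yaml`` (sampling rate etc.);
* EDF: ``epochs/<subject>_<trial>.edf`` plus the same ``labels.tsv``.

The internal unit is microvolts everywhere. EDF files are written with
16-bit samples, so an EDF round trip is exact only up to the quantization
step ``(phys_max - phys_min) / 65535`` per channel; the CSV round trip is
bit-exact. EDF reading goes through :mod:`mne`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet

__all__ = [
    "read_epochs",
    "write_epochs",
    "write_edf",
    "Montage",
    "standard_1020_montage",
]

_LABEL_COLUMNS = ("valence", "arousal", "emotion", "augmented")


# ---------------------------------------------------------------------------
# fixture CSV layout
# ---------------------------------------------------------------------------

def write_epochs(epochs: EpochSet, path, format: str = "csv_dir") -> Path:
    """Write an :class:`EpochSet` as a fixture directory (CSV or EDF)."""
    if format not in ("csv_dir", "edf"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    (path / "epochs").mkdir(parents=True, exist_ok=True)

    labels = epochs.labels.copy()
    labels.insert(0, "subject", epochs.subject_ids)
    if "trial" not in labels.columns:
        labels.insert(1, "trial", np.arange(epochs.n_trials))
    if labels.duplicated(["subject", "trial"]).any():
        # augmented epochs inherit their contributor's trial id; renumber
        # per subject so every epoch file name is unique
        labels["trial"] = labels.groupby("subject").cumcount()
    labels.to_csv(path / "labels.tsv", sep="\t", index=False)

    profile = {
        "sampling_rate": float(epochs.sfreq),
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "channel_names": list(epochs.channel_names),
        **{k: v for k, v in epochs.meta.items()
           if isinstance(v, (str, int, float, bool, list))},
    }
    with open(path / "profile.yaml", "w") as fh:
        yaml.safe_dump(profile, fh)

    for i in range(epochs.n_trials):
        subj = int(epochs.subject_ids[i])
        trial = int(labels["trial"].iloc[i])
        stem = path / "epochs" / f"{subj}_{trial}"
        if format == "csv_dir":
            # %.17g guarantees a bit-exact float64 round trip
            pd.DataFrame(epochs.data[i].T, columns=epochs.channel_names).to_csv(
                f"{stem}.csv", index=False, float_format="%.17g")
        else:
            write_edf(f"{stem}.edf", epochs.data[i], epochs.channel_names,
                      epochs.sfreq)
    return path


def _parse_stem(stem: str) -> tuple[int, int]:
    m = re.fullmatch(r"(\d+)_(\d+)", stem)
    if not m:
        raise ValueError(f"epoch file name {stem!r} is not <subject>_<trial>")
    return int(m.group(1)), int(m.group(2))


def read_epochs(path, format: str = "csv_dir") -> EpochSet:
    """Read a fixture directory (``csv_dir`` or ``edf``) into an EpochSet.

    Trials are ordered by (subject, trial). A sampling-rate mismatch across
    EDF files, or a channel-set mismatch across trials, is an error.
    """
    if format not in ("csv_dir", "edf"):
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    label_path = path / "labels.tsv"
    if not label_path.exists():
        raise FileNotFoundError(f"missing label table {label_path}")
    labels = pd.read_csv(label_path, sep="\t")
    if not {"subject", "trial"} <= set(labels.columns):
        raise ValueError("labels.tsv needs 'subject' and 'trial' columns")
    labels = labels.sort_values(["subject", "trial"]).reset_index(drop=True)

    profile = {}
    if (path / "profile.yaml").exists():
        with open(path / "profile.yaml") as fh:
            profile = yaml.safe_load(fh) or {}

    ext = "csv" if format == "csv_dir" else "edf"
    data, ch_names, sfreq = [], None, profile.get("sampling_rate")
    for _, row in labels.iterrows():
        f = path / "epochs" / f"{int(row.subject)}_{int(row.trial)}.{ext}"
        if not f.exists():
            raise FileNotFoundError(f"missing epoch file {f}")
        if format == "csv_dir":
            frame = pd.read_csv(f, float_precision="round_trip")
            names, x = list(frame.columns), frame.to_numpy(dtype=float).T
            rate = sfreq
        else:
            names, x, rate = _read_edf(f)
        if ch_names is None:
            ch_names = names
        elif names != ch_names:
            raise ValueError(f"channel set of {f} differs from first epoch")
        if rate is not None:
            if sfreq is not None and abs(rate - sfreq) > 1e-9:
                raise ValueError(
                    f"sampling rate {rate} of {f} mismatches {sfreq}")
            sfreq = rate
        if data and x.shape != data[0].shape:
            raise ValueError(f"epoch {f} has inconsistent shape {x.shape}")
        data.append(x)
    if sfreq is None:
        raise ValueError("sampling rate not found (no profile.yaml)")

    meta = {k: v for k, v in profile.items()
            if k not in ("sampling_rate", "n_channels", "n_samples",
                         "channel_names")}
    return EpochSet(
        data=np.stack(data),
        channel_names=ch_names,
        sfreq=float(sfreq),
        subject_ids=labels["subject"].to_numpy(),
        labels=labels.drop(columns=["subject"]).reset_index(drop=True),
        meta=meta,
    )


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit
# ---------------------------------------------------------------------------

def _read_edf(f) -> tuple[list[str], np.ndarray, float]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(f), preload=True, verbose="error")
    # mne returns Volts for channels whose physical dimension is uV
    return list(raw.ch_names), raw.get_data() * 1e6, float(raw.info["sfreq"])


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(filename, data: np.ndarray, channel_names, sfreq: float) -> None:
    """Write one channels x samples epoch as a 16-bit EDF file.

    Physical range is taken per channel from the data, so the quantization
    error is bounded by ``(max - min) / 65535`` per channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names must match the channel axis")
    if sfreq <= 0:
        raise ValueError("sampling rate must be positive")

    sfreq_i = int(round(sfreq))
    if abs(sfreq - sfreq_i) < 1e-9 and n_samp % sfreq_i == 0:
        n_records, rec_dur, spr = n_samp // sfreq_i, 1.0, sfreq_i
    else:  # single record holding the whole epoch
        n_records, rec_dur, spr = 1, n_samp / sfreq, n_samp

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    header_bytes = 256 * (1 + n_ch)
    head = b"".join([
        _pad("0", 8), _pad("X", 80), _pad("X", 80),
        _pad("01.01.2000", 8), _pad("00.00.00", 8),
        _pad(str(header_bytes), 8), _pad("", 44),
        _pad(str(n_records), 8), _pad(f"{rec_dur:g}", 8), _pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_pad(str(name), 16) for name in channel_names),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad("uV", 8) for _ in range(n_ch)),
        b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmin),
        b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmax),
        b"".join(_pad(str(dmin), 8) for _ in range(n_ch)),
        b"".join(_pad(str(dmax), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ])

    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(filename, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within each record


# ---------------------------------------------------------------------------
# 10-20 montage
# ---------------------------------------------------------------------------

@dataclass
class Montage:
    """Resolved scalp coordinates (meters, head frame) for a channel list."""

    channel_names: list[str]
    positions: dict = field(default_factory=dict)  # name -> (x, y, z)
    unresolved: set = field(default_factory=set)

    def position(self, name: str):
        return self.positions[name]


_STANDARD_1020 = None


def _standard_positions() -> dict:
    """Case-folded name -> (x, y, z) table of the standard 10-20 montage."""
    global _STANDARD_1020
    if _STANDARD_1020 is None:
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = mne.channels.make_standard_montage("standard_1020")
        _STANDARD_1020 = {
            name.upper(): tuple(float(v) for v in pos)
            for name, pos in m.get_positions()["ch_pos"].items()
        }
    return _STANDARD_1020


def standard_1020_montage(channel_names) -> Montage:
    """Resolve channel names against the international 10-20 system.

    Matching is case-insensitive. Unknown electrodes land in
    ``Montage.unresolved`` rather than raising: downstream stages that need
    geometry (spatial graph construction) refuse unresolved channels
    themselves.
    """
    table = _standard_positions()
    positions, unresolved = {}, set()
    for name in channel_names:
        pos = table.get(str(name).upper())
        if pos is None:
            unresolved.add(name)
        else:
            positions[name] = pos
    return Montage(list(channel_names), positions, unresolved)
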