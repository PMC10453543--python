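"""Leave-one-subject-out evaluation with the full metric bundle.

Each subject serves once as the test fold; channels are scored, windows
ranked and the network trained on the remaining subjects only, so no
subject (and no augmented epoch) ever leaks into its own test fold. Fold
metrics are accuracy, precision, specificity, recall, F1 (macro one-vs-rest
for the 3-class task), a paired t-test p-score comparing the selected
window features against the full window set, Cohen's kappa over the pooled
confusion matrix, and a dimensionless selection-cost index

    CT = (1/F_T) * sum_{classes} [ C_P * ln(f_v) + (1 - C_P) * ln(1 - f_v) ]

with f_v the selected feature value (a fraction in (0, 1)), F_T the
training-feature count and C_P the class-specific feature proportion.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .channel_selection import DifferentialEntropyChannelSelector
from .containers import EpochSet, class_vector
from .feature_selection import DMIMWindowSelector, de_features, segment_windows
from .graph_emd import GraphEMDAugmenter
from .nn import Cnn1DClassifier

__all__ = [
    "loso_splits",
    "confusion_matrix",
    "confusion_metrics",
    "kappa",
    "p_score",
    "selection_cost",
    "EvalReport",
    "evaluate_loso",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# splits and metrics
# ---------------------------------------------------------------------------

def loso_splits(subject_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_idx, test_idx) pair per subject; folds partition the data."""
    from sklearn.model_selection import LeaveOneGroupOut

    subject_ids = np.asarray(subject_ids)
    if np.unique(subject_ids).size < 2:
        raise ValueError("leave-one-subject-out needs at least two subjects")
    x_dummy = np.zeros((subject_ids.size, 1))
    return [(tr, te) for tr, te
            in LeaveOneGroupOut().split(x_dummy, groups=subject_ids)]


def confusion_matrix(y_true, y_pred, labels) -> np.ndarray:
    """K x K integer count table indexed [true, predicted] by ``labels``."""
    lookup = {c: i for i, c in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[lookup[t], lookup[p]] += 1
    return cm


def _safe_div(num, den, flags, name):
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(cm: np.ndarray) -> dict:
    """Accuracy / precision / specificity / recall / F1 from a count table.

    Binary tables treat index 1 as the positive class; larger tables are
    macro-averaged one-vs-rest. Undefined ratios (zero denominator) are
    reported as 0 with the metric name listed under ``flags``.
    """
    cm = np.asarray(cm)
    if (cm < 0).any():
        raise ValueError("confusion counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    accuracy = np.trace(cm) / total
    per_class = []
    classes = range(cm.shape[0]) if cm.shape[0] > 2 else [1]
    for k in classes:
        tp = cm[k, k]
        fn = cm[k, :].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        precision = _safe_div(tp, tp + fp, flags, f"precision[{k}]")
        recall = _safe_div(tp, tp + fn, flags, f"recall[{k}]")
        specificity = _safe_div(tn, tn + fp, flags, f"specificity[{k}]")
        f1 = _safe_div(2 * precision * recall, precision + recall, flags,
                       f"f1[{k}]")
        per_class.append((precision, specificity, recall, f1))
    precision, specificity, recall, f1 = np.mean(per_class, axis=0)
    return {"accuracy": float(accuracy), "precision": float(precision),
            "specificity": float(specificity), "recall": float(recall),
            "f1": float(f1), "flags": flags}


def kappa(cm: np.ndarray) -> float:
    """Cohen's kappa with chance agreement from the marginals.

    Degenerate tables with chance agreement 1 return 0 (with a warning).
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / total ** 2)
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("chance agreement is 1; kappa undefined, returning 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def p_score(selected_features, original_features) -> float:
    """Two-sided paired t-test between per-trial summary vectors.

    ``selected_features`` and ``original_features`` are equal-length vectors
    (one summary value per trial, e.g. mean DE of the selected windows vs
    of all windows). Identical vectors give p = 1 (zero differences; the
    defined limit, with a warning).
    """
    a = np.asarray(selected_features, dtype=float)
    b = np.asarray(original_features, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expected two equal-length 1-D summary vectors")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.allclose(diff, 0.0):
        warnings.warn("selected == original; p-score defined as 1")
        return 1.0
    return float(stats.ttest_rel(a, b).pvalue)


def selection_cost(f_v: float, f_t: float, class_proportions) -> float:
    """Literal evaluation of the selection-cost index (always <= 0)."""
    if not (0.0 < f_v < 1.0):
        raise ValueError("f_v must lie strictly inside (0, 1)")
    if f_t <= 0:
        raise ValueError("training-feature count must be positive")
    cp = np.asarray(class_proportions, dtype=float)
    terms = cp * np.log(f_v) + (1.0 - cp) * np.log(1.0 - f_v)
    return float(terms.sum() / f_t)


# ---------------------------------------------------------------------------
# the LOSO pipeline
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-fold metric table plus pooled summaries."""

    per_fold: pd.DataFrame
    mean: dict
    kappa: float
    confusion: np.ndarray
    classes: list
    config_fingerprint: str
    selection_cost: float | None = None
    extras: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        row = {**self.mean, "kappa": self.kappa}
        return pd.DataFrame([row])


def _fingerprint(params: dict) -> str:
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _ordered_classes(y) -> list:
    classes = sorted(set(np.asarray(y).tolist()))
    if set(classes) == {"low", "high"}:
        return ["low", "high"]          # positive class = high
    return classes


def _window_samples(x: np.ndarray, n_windows: int):
    """Cut reduced (trials, channels, k*N) signal into per-window vectors."""
    n_trials, n_ch, length = x.shape
    n = length // n_windows
    wins = x.reshape(n_trials, n_ch, n_windows, n)
    # one sample per (trial, window): channels concatenated
    return wins.transpose(0, 2, 1, 3).reshape(n_trials * n_windows,
                                              n_ch * n)


def evaluate_loso(epochs: EpochSet, task: str = "binary_valence",
                  n_channels: int = 10, channel_bins: int = 8,
                  channel_threshold: float = 1.5,
                  window_seconds: float = 2.0, top_windows: int = 20,
                  augment_ratio: float = 0.0, augment_mode: str = "temporal",
                  model_params: dict | None = None, seed: int = 0,
                  shuffle_labels: bool = False,
                  max_folds: int | None = None) -> EvalReport:
    """Run the full channels -> windows -> (augment) -> CNN pipeline under
    leave-one-subject-out cross-validation.

    Augmentation, when enabled, touches training folds only; trial-level
    predictions are obtained by averaging window probabilities. With
    ``shuffle_labels=True`` the class labels are permuted across trials
    before splitting (permutation control; accuracy should be at chance).
    """
    model_params = dict(model_params or {})
    y = class_vector(epochs, task)
    rng = np.random.default_rng(seed)
    if shuffle_labels:
        y = y[rng.permutation(len(y))]
    classes = _ordered_classes(y)
    augmented_mask = epochs.is_augmented

    folds = loso_splits(epochs.subject_ids)
    if max_folds is not None:
        folds = folds[:max_folds]
    rows, pooled_true, pooled_pred = [], [], []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        test_idx = test_idx[~augmented_mask[test_idx]]  # leakage guard
        assert not set(epochs.subject_ids[train_idx]) & \
            set(epochs.subject_ids[test_idx])
        x_train, y_train = epochs.data[train_idx], y[train_idx]
        x_test, y_test = epochs.data[test_idx], y[test_idx]
        subject = int(epochs.subject_ids[test_idx[0]])

        chan = DifferentialEntropyChannelSelector(
            n_bins=channel_bins, threshold=channel_threshold,
            top_k=n_channels).fit(x_train, y_train)
        x_train_c = chan.transform(x_train)
        x_test_c = chan.transform(x_test)

        sel = DMIMWindowSelector(
            sfreq=epochs.sfreq, window_seconds=window_seconds,
            n_select=top_windows).fit(x_train_c, y_train)
        x_train_r = sel.transform(x_train_c)
        x_test_r = sel.transform(x_test_c)
        k = len(sel.selected_spans_)

        if augment_ratio > 0:
            aug = GraphEMDAugmenter(ratio=augment_ratio, mode=augment_mode,
                                    random_state=seed + 1000 + fold_id)
            x_train_r, y_train = aug.fit_resample(x_train_r, y_train)
            assert not aug.augmented_mask_[:len(train_idx)].any()

        # standardize per channel on training statistics only
        mean = x_train_r.mean(axis=(0, 2), keepdims=True)
        std = x_train_r.std(axis=(0, 2), keepdims=True)
        std[std == 0] = 1.0
        x_train_r = (x_train_r - mean) / std
        x_test_r = (x_test_r - mean) / std

        xw_train = _window_samples(x_train_r, k)
        yw_train = np.repeat(y_train, k)
        xw_test = _window_samples(x_test_r, k)

        clf = Cnn1DClassifier(random_state=seed + fold_id,
                              **model_params).fit(xw_train, yw_train)
        probs = clf.predict_proba(xw_test)
        trial_probs = probs.reshape(len(test_idx), k, -1).mean(axis=1)
        y_pred = clf.classes_[np.argmax(trial_probs, axis=1)]

        cm = confusion_matrix(y_test, y_pred, classes)
        metrics = confusion_metrics(cm)
        rows.append({
            "fold": fold_id, "subject": subject, "n_test": len(test_idx),
            "accuracy": metrics["accuracy"], "precision": metrics["precision"],
            "specificity": metrics["specificity"], "recall": metrics["recall"],
            "f1": metrics["f1"],
            "p_score": _fold_p_score(x_test_c, sel, epochs.sfreq,
                                     window_seconds),
        })
        pooled_true.extend(y_test)
        pooled_pred.extend(y_pred)

    per_fold = pd.DataFrame(rows)
    metric_cols = ["accuracy", "precision", "specificity", "recall", "f1",
                   "p_score"]
    mean = {c: float(per_fold[c].mean()) for c in metric_cols}
    pooled_cm = confusion_matrix(pooled_true, pooled_pred, classes)
    n_windows_total = len(segment_windows(epochs.n_samples, epochs.sfreq,
                                          window_seconds))
    cost = selection_cost(
        f_v=min(top_windows, n_windows_total) / (n_windows_total + 1),
        f_t=n_windows_total * n_channels,
        class_proportions=[1.0 / len(classes)] * len(classes))
    params = dict(task=task, n_channels=n_channels, channel_bins=channel_bins,
                  channel_threshold=channel_threshold,
                  window_seconds=window_seconds, top_windows=top_windows,
                  augment_ratio=augment_ratio, augment_mode=augment_mode,
                  model_params=model_params, seed=seed,
                  shuffle_labels=shuffle_labels)
    return EvalReport(per_fold=per_fold, mean=mean, kappa=kappa(pooled_cm),
                      confusion=pooled_cm, classes=classes,
                      config_fingerprint=_fingerprint(params),
                      selection_cost=cost,
                      extras={"n_windows_total": n_windows_total})


def _fold_p_score(x_test_channels, selector, sfreq, window_seconds) -> float:
    """Paired t-test of mean selected-window DE vs mean all-window DE per
    test trial."""
    spans_all = segment_windows(x_test_channels.shape[2], sfreq,
                                window_seconds)
    h = de_features(x_test_channels, spans_all)     # (trials, ch, windows)
    trial_all = h.mean(axis=(1, 2))
    sel_idx = selector.selected_windows_
    trial_sel = h[:, :, sel_idx].mean(axis=(1, 2))
    if trial_all.size < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return p_score(trial_sel, trial_all)


# ---------------------------------------------------------------------------
# config-file entry point
# ---------------------------------------------------------------------------

def run_pipeline(config, out_dir=None) -> EvalReport:
    """Run the full pipeline from a config mapping (or YAML file path).

    Config keys: ``data`` (either ``fixture_dir``+``format`` or
    ``synthetic`` with ``profile``/generator fields), ``task``, ``channels``
    (``top_k``, ``n_bins``, ``threshold``), ``windows`` (``seconds``,
    ``top_k``), ``augment`` (``ratio``, ``mode``), ``model`` (classifier
    overrides), ``seed``, ``shuffle_labels``. When ``out_dir`` is given the
    per-fold report and the summary are written as TSV.
    """
    import pathlib

    import yaml

    if isinstance(config, (str, pathlib.Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    seed = int(config.get("seed", 0))

    data_cfg = dict(config.get("data", {}))
    if "fixture_dir" in data_cfg:
        from .io import read_epochs
        epochs = read_epochs(data_cfg["fixture_dir"],
                             format=data_cfg.get("format", "csv_dir"))
    elif "synthetic" in data_cfg:
        epochs = _synthetic_from_config(dict(data_cfg["synthetic"]), seed)
    else:
        raise ValueError("config.data needs 'fixture_dir' or 'synthetic'")

    channels = dict(config.get("channels", {}))
    windows = dict(config.get("windows", {}))
    augment = dict(config.get("augment", {}))
    report = evaluate_loso(
        epochs,
        task=config.get("task", "binary_valence"),
        n_channels=int(channels.get("top_k", 10)),
        channel_bins=int(channels.get("n_bins", 8)),
        channel_threshold=float(channels.get("threshold", 1.5)),
        window_seconds=float(windows.get("seconds", 2.0)),
        top_windows=int(windows.get("top_k", 20)),
        augment_ratio=float(augment.get("ratio", 0.0)),
        augment_mode=augment.get("mode", "temporal"),
        model_params=dict(config.get("model", {})),
        seed=seed,
        shuffle_labels=bool(config.get("shuffle_labels", False)),
    )
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.per_fold.to_csv(out / "report.tsv", sep="\t", index=False)
        report.summary_frame().to_csv(out / "summary.tsv", sep="\t",
                                      index=False)
    return report


def _synthetic_from_config(cfg: dict, seed: int):
    from . import synthetic

    name = cfg.pop("profile", "benchmark")
    cfg.setdefault("seed", seed)
    factories = {
        "benchmark": synthetic.benchmark_spec,
        "null": synthetic.null_spec,
        "planted": synthetic.planted_recovery_spec,
        "trend": synthetic.trend_benchmark_spec,
    }
    if name in factories:
        spec = factories[name](seed=int(cfg["seed"]))
    else:
        profile = synthetic.builtin_profile(name)
        spec = synthetic.SyntheticSpec(
            profile=profile,
            informative_channels=frozenset(cfg.get("informative_channels", ())),
            informative_window_indices=frozenset(
                cfg.get("informative_windows", ())),
            class_band_power=cfg.get("class_band_power", {}),
            noise_scale=float(cfg.get("noise_scale", 10.0)),
            seed=int(cfg["seed"]),
        )
    return synthetic.generate_epoch_set(spec)
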