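"""Canonical synthetic benchmark runs shared by the test-bench and the
reproduction script.

These functions pin the study conditions (data geometry, selection budgets,
training lengths) so that every caller measures the same quantities. Sizes
are chosen once as a package-level compromise between statistical
resolution and desk-scale runtimes; see docs/methods.md.
"""

from __future__ import annotations

import warnings

import numpy as np

from .evaluation import evaluate_loso
from .synthetic import (
    benchmark_spec,
    generate_epoch_set,
    null_spec,
    trend_benchmark_spec,
)

__all__ = [
    "learnability_benchmark",
    "shuffled_control",
    "augmentation_trend",
    "chance_bounds",
]

#: selection budgets on the 8-channel learnability benchmark
BENCH_CHANNELS = 3
BENCH_WINDOWS = 2
#: training length for benchmark runs (the separable benchmark converges
#: well before the production default; early stopping may cut further)
BENCH_EPOCHS = 18
#: shuffled-label control: all folds, short training (the chance check
#: needs calibration, not convergence)
CONTROL_FOLDS = 8
CONTROL_EPOCHS = 10
#: reduced classifier for the augmentation-trend study (same architecture
#: family, fewer filters; identical in both arms of the comparison)
TREND_MODEL = {"filters": (16, 8, 8, 8), "epochs": 25}
TREND_CHANNELS = 3
TREND_WINDOWS = 2


def chance_bounds(n_trials: int, n_classes: int = 2,
                  level: float = 0.99) -> tuple[float, float]:
    """Two-sided binomial bounds around chance accuracy for n trials."""
    from scipy import stats

    p = 1.0 / n_classes
    lo, hi = stats.binom.interval(level, n_trials, p)
    return lo / n_trials, hi / n_trials


def learnability_benchmark(seed: int = 0, augment_ratio: float = 0.0):
    """Full LOSO run of the default CNN on the separable 8 x 20 benchmark."""
    epochs = generate_epoch_set(benchmark_spec(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_loso(
            epochs, n_channels=BENCH_CHANNELS, top_windows=BENCH_WINDOWS,
            augment_ratio=augment_ratio,
            model_params={"epochs": BENCH_EPOCHS}, seed=seed)


def shuffled_control(seed: int = 0):
    """Label-shuffled LOSO control on the same benchmark (chance check)."""
    epochs = generate_epoch_set(benchmark_spec(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_loso(
            epochs, n_channels=BENCH_CHANNELS, top_windows=BENCH_WINDOWS,
            model_params={"epochs": CONTROL_EPOCHS}, seed=seed,
            shuffle_labels=True, max_folds=CONTROL_FOLDS)


def null_calibration(seed: int = 0):
    """LOSO on the pure-noise null dataset; accuracy should be at chance."""
    epochs = generate_epoch_set(null_spec(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return evaluate_loso(
            epochs, n_channels=3, top_windows=2,
            model_params=dict(TREND_MODEL), seed=seed)


def augmentation_trend(seeds=(0, 1, 2, 3, 4)) -> dict:
    """Mean LOSO accuracy with and without ratio-1.0 graph-EMD augmentation.

    Both arms use the identical reduced classifier so the comparison
    isolates the augmentation effect. Returns per-seed accuracies and the
    mean difference in percentage points.
    """
    plain, augmented = [], []
    for seed in seeds:
        epochs = generate_epoch_set(trend_benchmark_spec(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep0 = evaluate_loso(
                epochs, n_channels=TREND_CHANNELS, top_windows=TREND_WINDOWS,
                model_params=dict(TREND_MODEL), seed=seed)
            rep1 = evaluate_loso(
                epochs, n_channels=TREND_CHANNELS, top_windows=TREND_WINDOWS,
                augment_ratio=1.0, model_params=dict(TREND_MODEL), seed=seed)
        plain.append(rep0.mean["accuracy"])
        augmented.append(rep1.mean["accuracy"])
    plain, augmented = np.asarray(plain), np.asarray(augmented)
    return {
        "seeds": list(seeds),
        "accuracy_plain": plain.tolist(),
        "accuracy_augmented": augmented.tolist(),
        "mean_delta_points": float(100.0 * (augmented.mean() - plain.mean())),
    }
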