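"""Uncertainty quantification and concept-drift detection.

Predictive uncertainty comes from Monte Carlo dropout: repeated stochastic
forward passes approximate the predictive distribution, whose variance
splits into an aleatoric part (mean per-pass Bernoulli variance — the model
has no separate aleatoric output head) and an epistemic part (variance of
the per-pass means). Drift detection compares standardized input mean
vectors between training data and a deployment batch against a threshold
calibrated from bootstrap resampling of the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UncertaintyReport",
    "DriftBaseline",
    "DriftReport",
    "mc_dropout",
    "decompose",
    "percentile_intervals",
    "fit_drift_baseline",
    "detect_drift",
]


@dataclass
class UncertaintyReport:
    mean: np.ndarray
    total: np.ndarray
    aleatoric: np.ndarray
    epistemic: np.ndarray
    n_passes: int
    lower: np.ndarray    # per-unit 95% percentile interval bounds
    upper: np.ndarray
    samples: np.ndarray  # (T, n)


def mc_dropout(model, X: np.ndarray, n_passes: int = 50, seed: int = 0,
               arm=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dropout-active forward passes -> (samples, mean, total variance).

    ``model`` must expose ``predict_stochastic(X, rng)`` (and
    ``counterfactual_predict(X, arm, rng)`` when ``arm`` is given). The
    variance is the population second moment minus the squared mean.
    """
    if n_passes < 2:
        raise ValueError("need at least two stochastic passes")
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_passes):
        if arm is None:
            samples.append(model.predict_stochastic(X, rng))
        else:
            samples.append(model.counterfactual_predict(X, arm, rng=rng))
    samples = np.stack(samples)
    mean = samples.mean(axis=0)
    var = (samples**2).mean(axis=0) - mean**2
    return samples, mean, np.maximum(var, 0.0)


def decompose(mu_samples: np.ndarray,
              sigma2_samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split predictive variance: aleatoric = mean per-pass variance,
    epistemic = variance of per-pass means, total = their sum."""
    mu = np.asarray(mu_samples, float)
    s2 = np.asarray(sigma2_samples, float)
    if mu.shape != s2.shape:
        raise ValueError("sample vectors must be aligned")
    aleatoric = s2.mean(axis=0)
    epistemic = (mu**2).mean(axis=0) - mu.mean(axis=0) ** 2
    epistemic = np.maximum(epistemic, 0.0)
    return aleatoric, epistemic, aleatoric + epistemic


def percentile_intervals(samples: np.ndarray,
                         level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit percentile interval bounds from (T, n) Monte Carlo samples."""
    tail = 100.0 * (1.0 - level) / 2.0
    lower = np.percentile(samples, tail, axis=0)
    upper = np.percentile(samples, 100.0 - tail, axis=0)
    return lower, upper


@dataclass
class DriftBaseline:
    """Standardization statistics and calibrated threshold of the training data."""

    feature_names: tuple
    center: np.ndarray   # training means (raw scale)
    scale: np.ndarray    # training SDs (raw scale), zeros mapped to 1
    mu_train: np.ndarray  # standardized training mean vector (zeros)
    delta: float


@dataclass
class DriftReport:
    mu_train: np.ndarray
    mu_test: np.ndarray
    distance: float
    delta: float
    drift: bool
    feature_names: tuple


def fit_drift_baseline(X_train: np.ndarray, feature_names=None,
                       delta: float | None = None, n_boot: int = 500,
                       quantile: float = 0.99, batch_size: int | None = None,
                       seed: int = 0) -> DriftBaseline:
    """Fit standardization stats; calibrate the threshold unless given.

    The default threshold is the ``quantile`` of the distance between the
    training mean and bootstrap-resample means on standardized features, so
    sampling noise alone rarely flags drift. Resamples are drawn at
    ``batch_size`` (default: the expected deployment batch size = training
    size) because mean-vector noise scales with the batch size.
    """
    X_train = np.atleast_2d(np.asarray(X_train, float))
    n, p = X_train.shape
    center = X_train.mean(axis=0)
    scale = X_train.std(axis=0)
    scale[scale == 0] = 1.0
    if feature_names is None:
        feature_names = tuple(f"f{i}" for i in range(p))
    if delta is None:
        rng = np.random.default_rng(seed)
        Z = (X_train - center) / scale
        m = n if batch_size is None else int(batch_size)
        dists = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, m)
            dists[b] = np.linalg.norm(Z[idx].mean(axis=0))
        delta = float(np.quantile(dists, quantile))
    return DriftBaseline(feature_names=tuple(feature_names), center=center,
                         scale=scale, mu_train=np.zeros(p), delta=float(delta))


def detect_drift(baseline: DriftBaseline, batch: np.ndarray,
                 delta: float | None = None) -> DriftReport:
    """Flag drift when the standardized mean-vector distance exceeds delta."""
    batch = np.atleast_2d(np.asarray(batch, float))
    if batch.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    if batch.shape[1] != len(baseline.center):
        raise ValueError("feature mismatch between baseline and batch")
    delta = baseline.delta if delta is None else float(delta)
    mu_test = ((batch - baseline.center) / baseline.scale).mean(axis=0)
    distance = float(np.linalg.norm(baseline.mu_train - mu_test))
    return DriftReport(mu_train=baseline.mu_train, mu_test=mu_test,
                       distance=distance, delta=delta,
                       drift=distance > delta,
                       feature_names=baseline.feature_names)
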