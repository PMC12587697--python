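"""Causal-validity, interval and classification metrics.

PEHE is the root-mean-squared error between estimated and true individual
effects; ATE error/bias compare mean effects; ITE R-squared, MAE and the
effect SD summarize heterogeneity recovery. Interval metrics report the
coverage of nominal predictive intervals and its deviation from the nominal
level. Classification metrics are computed from the confusion counts at a
fixed threshold plus a midrank-tie-handled ROC AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CausalMetricsReport",
    "IntervalMetricsReport",
    "ClassificationReport",
    "causal_metrics",
    "interval_metrics",
    "classification_metrics",
    "write_reports",
]


@dataclass
class CausalMetricsReport:
    pehe: float
    ate_error: float
    ate_bias: float
    estimated_ate: float
    ite_r2: float | None
    ite_mae: float
    ite_std: float


@dataclass
class IntervalMetricsReport:
    coverage: float
    nominal: float
    calibration_error: float


@dataclass
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int


def causal_metrics(tau_hat: np.ndarray, tau_true: np.ndarray) -> CausalMetricsReport:
    """Compare estimated against true individual effects."""
    tau_hat = np.asarray(tau_hat, float).ravel()
    tau_true = np.asarray(tau_true, float).ravel()
    if tau_hat.shape != tau_true.shape or len(tau_hat) < 2:
        raise ValueError("need two aligned vectors with n >= 2")
    err = tau_hat - tau_true
    sst = float(((tau_true - tau_true.mean()) ** 2).sum())
    r2 = None if sst == 0 else float(1.0 - (err**2).sum() / sst)
    bias = float(err.mean())
    return CausalMetricsReport(
        pehe=float(np.sqrt((err**2).mean())),
        ate_error=abs(bias),
        ate_bias=bias,
        estimated_ate=float(tau_hat.mean()),
        ite_r2=r2,
        ite_mae=float(np.abs(err).mean()),
        ite_std=float(tau_hat.std(ddof=1)),
    )


def interval_metrics(lower: np.ndarray, upper: np.ndarray, tau_true: np.ndarray,
                     nominal: float = 0.95) -> IntervalMetricsReport:
    """Coverage of true effects by the intervals and its calibration error."""
    lower = np.asarray(lower, float).ravel()
    upper = np.asarray(upper, float).ravel()
    tau_true = np.asarray(tau_true, float).ravel()
    if np.any(lower > upper):
        raise ValueError("crossed interval bounds")
    coverage = float(((tau_true >= lower) & (tau_true <= upper)).mean())
    return IntervalMetricsReport(coverage=coverage, nominal=nominal,
                                 calibration_error=abs(coverage - nominal))


def _auc_midrank(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation with midrank ties."""
    ranks = rankdata(y_prob)  # midranks
    n_pos = int(y_true.sum())
    n_neg = len(y_true) - n_pos
    rank_sum = ranks[y_true == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def classification_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                           threshold: float = 0.5) -> ClassificationReport:
    """Confusion-count metrics at a threshold plus ROC AUC.

    AUC is undefined (None) when only one class is present.
    """
    y_true = np.asarray(y_true).ravel().astype(int)
    y_prob = np.asarray(y_prob, float).ravel()
    if set(np.unique(y_true)) - {0, 1}:
        raise ValueError("y_true must be binary")
    pred = (y_prob >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    n = len(y_true)
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    auc = None if len(np.unique(y_true)) < 2 else _auc_midrank(y_true, y_prob)
    return ClassificationReport(accuracy=accuracy, precision=precision,
                                recall=recall, f1=f1, auc=auc,
                                threshold=threshold, tp=tp, tn=tn, fp=fp, fn=fn)


def write_reports(outdir, reports: dict, row_key: dict | None = None) -> None:
    """Write metric dataclasses as JSON plus one flat CSV row for tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flat = dict(row_key or {})
    payload = {}
    for name, report in reports.items():
        d = asdict(report) if hasattr(report, "__dataclass_fields__") else dict(report)
        payload[name] = d
        flat.update({f"{name}.{k}": v for k, v in d.items()})
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame([flat]).to_csv(outdir / "metrics.csv", index=False)
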