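"""Power and accuracy statistics against simulator truth.

Scores are -log10(p) per marker; truth is the binary causal labelling of
the relevant effect class (beta1 != 0 for self, beta2 != 0 for neighbor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["EvalMetrics", "roc_auc", "sensitivity_at_fpr", "mae_effects",
           "pve_accuracy", "neglog10"]


@dataclass
class EvalMetrics:
    auc_self: float
    auc_nei: float
    sens_self: float
    sens_nei: float
    mae_self: float | None = None
    mae_nei: float | None = None
    pve_accuracy: float | None = None


def neglog10(p: np.ndarray) -> np.ndarray:
    """-log10(p), with p floored at the smallest positive float."""
    p = np.asarray(p, dtype=float)
    return -np.log10(np.clip(p, np.finfo(float).tiny, None))


def _check_labels(truth: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("need both causal and non-causal markers")
    return truth


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve (Mann–Whitney statistic, midrank ties).

    0.5 means no power to rank causal markers above non-causal ones; 1.0
    means every causal marker outranks every non-causal one.
    """
    truth = _check_labels(truth)
    return float(roc_auc_score(truth, np.asarray(scores, float)))


def sensitivity_at_fpr(scores: np.ndarray, truth: np.ndarray,
                       fpr: float = 0.05) -> float:
    """True-positive rate at the largest threshold with empirical FPR <= fpr.

    Step-function convention on the empirical ROC (no interpolation).
    """
    truth = _check_labels(truth)
    f, t, _ = roc_curve(truth, np.asarray(scores, float))
    ok = f <= fpr
    return float(t[ok].max()) if ok.any() else 0.0


def mae_effects(beta_true: np.ndarray, beta_hat: np.ndarray,
                sd_raw_y: float = 1.0) -> float | None:
    """Mean |beta_true - beta_hat * sd_raw_y| over causal markers.

    Estimates come from the standardized phenotype, so multiplying by the
    raw-phenotype standard deviation puts them back on the true-beta scale.
    Returns None for an empty causal class.
    """
    beta_true = np.asarray(beta_true, float)
    beta_hat = np.asarray(beta_hat, float)
    if beta_true.size != beta_hat.size:
        raise ValueError("beta vectors must align on the causal markers")
    if beta_true.size == 0:
        return None
    return float(np.mean(np.abs(beta_true - beta_hat * sd_raw_y)))


def pve_accuracy(est_total: float, true_total: float) -> float:
    """Signed relative error (estimated - true) / true of the total PVE."""
    if true_total <= 0:
        raise ValueError("true total PVE must be positive")
    return (est_total - true_total) / true_total
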