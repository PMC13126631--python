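"""Accuracy, error and uncertainty metrics for state classification and
denoising.

State labels are assumed 1..K and *ordered along the conformational
transition* (guaranteed by the PC1 ordering of the state model), so
absolute label differences are meaningful distances.
"""

from __future__ import annotations

import csv
import json

import numpy as np

__all__ = [
    "shannon_entropy",
    "tolerance_accuracy",
    "deviation_histogram",
    "image_errors",
    "mean_probs",
    "write_metrics",
]


def _check_simplex(p, tol: float = 1e-6) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise ValueError("probabilities must be a simplex vector")
    return np.clip(p, 0.0, None)


def shannon_entropy(p, base: float | None = None) -> float:
    """Shannon entropy H(P) = -sum p_i ln p_i (nats by default).

    0 * ln 0 is treated as 0; with ``base`` the logarithm base changes
    for reporting (e.g. 2 for bits).
    """
    p = _check_simplex(p)
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def tolerance_accuracy(y_true, y_hat, k: int = 0) -> float:
    """Fraction of predictions within ``k`` ordered states of the truth;
    ``k = 0`` is exact-match accuracy."""
    y_true = np.asarray(y_true, dtype=int)
    y_hat = np.asarray(y_hat, dtype=int)
    if y_true.shape != y_hat.shape or y_true.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    return float((np.abs(y_hat - y_true) <= k).mean())


def deviation_histogram(y_true, y_hat, K: int | None = None):
    """Histogram of absolute state deviations |y_hat - y_true|.

    Returns ``(counts, tail_ge4)``: integer counts over deviations
    0..K-1 and the number of predictions off by four or more states.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_hat = np.asarray(y_hat, dtype=int)
    if y_true.shape != y_hat.shape:
        raise ValueError("label vectors must have equal length")
    dev = np.abs(y_hat - y_true)
    K = K or int(max(y_true.max(), y_hat.max()))
    counts = np.bincount(dev, minlength=K)[:K]
    tail = int((dev >= 4).sum())
    return counts, tail


def image_errors(a, b):
    """Pixelwise mean absolute error (nm) and mean squared error (nm^2)."""
    va = a.values if hasattr(a, "values") else np.asarray(a)
    vb = b.values if hasattr(b, "values") else np.asarray(b)
    if va.shape != vb.shape:
        raise ValueError("images must share one grid")
    diff = va - vb
    return float(np.abs(diff).mean()), float((diff * diff).mean())


def mean_probs(preds) -> np.ndarray:
    """Elementwise mean of a list of class-probability vectors (remains a
    simplex)."""
    preds = [_check_simplex(p) for p in preds]
    if not preds:
        raise ValueError("need at least one probability vector")
    return np.mean(preds, axis=0)


def write_metrics(csv_path, rows, summary_path=None, summary=None) -> None:
    """Emit per-image metric rows as tidy CSV and an optional JSON summary."""
    rows = list(rows)
    if rows:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(summary or {}, fh, indent=2)
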