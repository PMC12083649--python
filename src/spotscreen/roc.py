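"""Spatial-vs-pooled recapitulation benchmark.

A spatial screen should re-detect the sgRNAs that an orthogonal pooled
readout of the same model detects.  The benchmark treats the pooled
per-sgRNA detection fraction (fraction of tumor sample lobes in which the
sgRNA was seen) as a continuous predictor of the binary spatial response
"sgRNA area > 2 spots", and summarises agreement by the ROC curve and its
area.  AUC uses the trapezoidal rule, which with the half-credit tie
convention equals the Mann-Whitney U statistic divided by n_pos * n_neg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn import metrics

__all__ = ["build_benchmark", "roc_auc"]


def build_benchmark(table: pd.DataFrame, area_cutoff: int = 2,
                    pooled_cutoff: float = 0.25) -> dict:
    """Predictor/response construction from a detection table.

    ``table`` needs columns ``sgrna``, ``pooled_fraction`` (in [0, 1]) and
    ``spatial_area`` (spots).  Response label = spatial_area > area_cutoff;
    score = pooled_fraction.  A confusion matrix at the binarised predictor
    (pooled_fraction > pooled_cutoff) is reported alongside.
    """
    need = {"sgrna", "pooled_fraction", "spatial_area"}
    if not need.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    if table.empty:
        raise ValueError("empty detection table")
    t = table.dropna(subset=["pooled_fraction", "spatial_area"])
    if len(t) < len(table):
        warnings.warn(f"dropped {len(table) - len(t)} rows with missing values")
    labels = (t["spatial_area"].to_numpy() > area_cutoff).astype(int)
    scores = t["pooled_fraction"].to_numpy(dtype=float)
    if labels.min() == labels.max():
        raise ValueError("degenerate ROC: only one response class present")
    pred = (scores > pooled_cutoff).astype(int)
    confusion = {
        "tp": int(((pred == 1) & (labels == 1)).sum()),
        "fp": int(((pred == 1) & (labels == 0)).sum()),
        "fn": int(((pred == 0) & (labels == 1)).sum()),
        "tn": int(((pred == 0) & (labels == 0)).sum()),
    }
    return {"scores": scores, "labels": labels, "confusion": confusion,
            "sgrnas": list(t["sgrna"])}


def roc_auc(scores, labels) -> dict:
    """ROC curve (all distinct thresholds) and trapezoidal AUC.

    Rows with NaN scores are dropped with a warning.  Returns ``{"fpr",
    "tpr", "thresholds", "auc", "n_pos", "n_neg"}``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    ok = ~np.isnan(scores)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} NaN scores")
        scores, labels = scores[ok], labels[ok]
    if labels.min() == labels.max():
        raise ValueError("degenerate ROC: only one class present")
    fpr, tpr, thr = metrics.roc_curve(labels, scores, drop_intermediate=False)
    return {
        "fpr": fpr, "tpr": tpr, "thresholds": thr,
        "auc": float(metrics.auc(fpr, tpr)),
        "n_pos": int(labels.sum()), "n_neg": int((1 - labels).sum()),
    }
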