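"""Thin plotting conveniences (ROC curve, stability barplot).

Requires matplotlib (optional extra); everything here is presentation only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .nested_eval import FoldRecord
from .probe_select import StabilityTable


def roc_points(fold_records: Sequence[FoldRecord]) -> tuple[np.ndarray, np.ndarray]:
    """FPR/TPR staircase from outer-fold scores (pooled, ties grouped)."""
    y = np.array([r.true_label for r in fold_records])
    s = np.array([r.score for r in fold_records])
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y)[idx]
    fps = (idx + 1) - tps
    tpr = np.r_[0, tps] / max(y.sum(), 1)
    fpr = np.r_[0, fps] / max((1 - y).sum(), 1)
    return fpr, tpr


def plot_roc(fold_records: Sequence[FoldRecord], label: str = "", ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    fpr, tpr = roc_points(fold_records)
    ax.plot(fpr, tpr, label=label or None, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    if label:
        ax.legend()
    return ax


def plot_stability(table: StabilityTable, top: int = 25, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, top * 0.25)))
    frame = table.to_frame().head(top).iloc[::-1]
    ax.barh(frame["mirna"], frame["frequency"])
    ax.axvline(table.stability_threshold, color="orange", lw=1, label="retention")
    ax.axvline(table.high_stability_threshold, color="red", lw=1, label="high tier")
    ax.set_xlabel("selection frequency")
    ax.legend(loc="lower right")
    return ax
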