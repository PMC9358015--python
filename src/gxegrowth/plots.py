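"""Basic diagnostic plots: Manhattan, factor-count scan, observed-vs-model."""
from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def manhattan(result: pd.DataFrame, ax=None, significance: float | None = None):
    """-log10(p) along the chromosomes for one scan result frame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(result.dropna(subset=["p"]).groupby("chrom", sort=True)):
        x = sub["pos"].to_numpy(dtype=float) + offset
        ax.scatter(x, -np.log10(sub["p"]), s=6, color=f"C{i % 2}")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max()
    if significance is not None:
        ax.axhline(-np.log10(significance), ls="--", color="red", lw=0.8)
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10}(P)$")
    return ax


def scan_curves(scan: pd.DataFrame, metric: str = "pearson_r", split: str = "test", ax=None):
    """Prediction ability vs number of genetic factors, one line per pattern."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = scan[scan["split"] == split]
    for pattern, grp in sub.groupby("pattern"):
        ax.plot(grp["n_g"], grp[metric], label=pattern)
    ax.set_xlabel("number of genetic factors")
    ax.set_ylabel(f"{split} {metric}")
    ax.legend()
    return ax


def observed_vs_model(observed, predicted, ax=None, label: str = ""):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(observed, predicted, s=10, alpha=0.6)
    lo = min(np.min(observed), np.min(predicted))
    hi = max(np.max(observed), np.max(predicted))
    ax.plot([lo, hi], [lo, hi], color="grey", lw=0.8)
    ax.set_xlabel("observed")
    ax.set_ylabel("model value")
    if label:
        ax.set_title(label)
    return ax
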