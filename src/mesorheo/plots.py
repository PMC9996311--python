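"""Optional figure helpers: ensemble MSD curves, fold-change bars, intensity histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import ComparisonResult, IntensityDistribution
from .msd import MSDCurve


def plot_ensemble_msd(curves: dict[str, MSDCurve], path=None, ax=None):
    """Log-log ensemble MSD per condition (one line each)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.2))
    for label, curve in curves.items():
        ax.loglog(curve.tau_s, curve.msd_um2, marker="o", ms=3, label=label)
    ax.set_xlabel("time delay τ (s)")
    ax.set_ylabel("MSD (μm²)")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def plot_fold_changes(results: dict[str, ComparisonResult], path=None, ax=None):
    """Mean ± SD fold change of median D_eff per condition vs the reference."""
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    labels = list(results)
    means = [results[k].mean_fold for k in labels]
    sds = [results[k].sd_fold for k in labels]
    x = np.arange(len(labels))
    ax.bar(x, means, yerr=sds, capsize=4, color="0.7", edgecolor="k")
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xticks(x, labels, rotation=20, ha="right")
    ax.set_ylabel("fold change of median $D_{eff}$")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


def plot_intensity_distribution(
    dists: dict[str, IntensityDistribution], path=None, ax=None
):
    """Overlaid normalized brightness histograms per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.2))
    for label, d in dists.items():
        centers = 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])
        ax.step(centers, d.mass, where="mid", label=label)
    ax.set_xlabel("average mean intensity (counts)")
    ax.set_ylabel("fraction of particles")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
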