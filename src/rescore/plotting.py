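"""Small plotting helpers for the evaluation outputs."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .benchmark import ExperimentGrid, PairedQValues, accepted_count_summary


def plot_qvalue_scatter(paired: PairedQValues, threshold: float = 0.01, ax=None):
    """Scatter of paired test-set q-values (log-log) with the acceptance
    threshold marked; one point per shared PSM."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(paired.frame["q_a"], paired.frame["q_b"], s=4, alpha=0.4, lw=0)
    ax.axhline(threshold, ls="--", c="gray")
    ax.axvline(threshold, ls="--", c="gray")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("q-value (A)")
    ax.set_ylabel("q-value (B)")
    return ax


def plot_downsampling_curve(grid: ExperimentGrid, threshold: float = 0.01, ax=None):
    """Mean accepted test PSMs vs training size with the 95% CI band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    summary = accepted_count_summary(grid, threshold).sort_values("size")
    ax.plot(summary["size"], summary["mean"], marker="o")
    if summary["ci_defined"].all():
        ax.fill_between(summary["size"], summary["ci_low"], summary["ci_high"], alpha=0.3)
    ax.set_xscale("log")
    ax.set_xlabel("training PSMs" if grid.spec.mode == "total" else "confident training PSMs")
    ax.set_ylabel(f"test PSMs accepted at {threshold:g} FDR")
    return ax


def plot_shared_peptide_curves(curves: dict, ax=None):
    """Overlay shared-peptide curves (peptides in >= k experiments) for
    one or more labelled methods."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for label, curve in curves.items():
        ks = np.arange(1, len(curve) + 1)
        ax.step(ks, curve, where="mid", label=label)
    ax.set_xlabel("detected in >= k experiments")
    ax.set_ylabel("peptides")
    ax.legend()
    return ax
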