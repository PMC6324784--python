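"""Dot-and-whisker and bar figures for AMCE and WTP results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .wtp import INTERVAL_LABELS, ApprovalComparison, WtpDistribution


def plot_amce(summary: pd.DataFrame, ax=None):
    """Dot-and-whisker plot of AMCE estimates with 95% CIs; reference levels
    are drawn as solid dots at zero."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 8))
    labels, y = [], 0
    for attr, grp in summary.groupby("attribute", sort=False):
        for row in grp.itertuples(index=False):
            if row.is_reference:
                ax.plot([0], [y], "o", color="black")
            else:
                ax.plot([row.estimate], [y], "o", color="tab:blue")
                ax.hlines(y, row.ci_lo, row.ci_hi, color="tab:blue")
            labels.append(f"{attr}: {row.level}")
            y += 1
        y += 1  # gap between attributes
        labels.append("")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(range(len(labels)), labels)
    ax.invert_yaxis()
    outcome = summary["outcome"].iloc[0]
    ax.set_xlabel(f"AMCE on {outcome} choice probability")
    ax.figure.tight_layout()
    return ax


def plot_wtp_masses(dist: WtpDistribution, ax=None):
    """Bar plot of the five WTP interval masses with 95% CIs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(INTERVAL_LABELS))
    ax.bar(x, dist.interval_masses, yerr=1.96 * dist.interval_se, capsize=3)
    ax.set_xticks(x, INTERVAL_LABELS)
    ax.set_ylabel("marginal share of WTP")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.figure.tight_layout()
    return ax


def plot_approval(dist: WtpDistribution, ax=None):
    """Bar plot of approval rates at the four premium thresholds."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(4)
    ax.bar(x, dist.approval_rates, yerr=1.96 * dist.approval_se, capsize=3)
    ax.set_xticks(x, [f"p{k}" for k in (1, 2, 3, 4)])
    ax.set_ylabel("approval rate")
    ax.set_ylim(0, 1.05)
    ax.figure.tight_layout()
    return ax


def plot_approval_comparison(cmp: ApprovalComparison, ax=None):
    """Grouped bars: approval rates under the baseline and new level."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(4)
    w = 0.38
    ax.bar(x - w / 2, cmp.dist_a0.approval_rates, w,
           yerr=1.96 * cmp.dist_a0.approval_se, capsize=2, label=f"{cmp.level_a0} (baseline)")
    ax.bar(x + w / 2, cmp.dist_a1.approval_rates, w,
           yerr=1.96 * cmp.dist_a1.approval_se, capsize=2, label=cmp.level_a1)
    ax.set_xticks(x, [f"p{k}" for k in (1, 2, 3, 4)])
    ax.set_ylabel("approval rate")
    ax.set_title(cmp.attribute)
    ax.legend()
    ax.figure.tight_layout()
    return ax
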