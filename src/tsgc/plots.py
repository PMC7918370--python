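"""Publication-style plots: ACF grids, residual grids, significance windows."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import WhitenessReport
from .inference import ComparisonReport


def _subject_title(subject: str) -> str:
    # simulated ids are "G1:r2:e3"; render as "Group: Replicate: Experiment"
    return subject.replace(":r", ": ").replace(":e", ": ")


def acf_grid(report: WhitenessReport, path, title: str | None = None) -> None:
    """One correlogram panel per subject with the 95% white-noise band."""
    subjects = sorted(report.acfs)
    ncol = math.ceil(math.sqrt(len(subjects)))
    nrow = math.ceil(len(subjects) / ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.4 * ncol, 1.9 * nrow), squeeze=False, sharey=True
    )
    for ax in axes.flat[len(subjects):]:
        ax.set_axis_off()
    for subj, ax in zip(subjects, axes.flat):
        res = report.acfs[subj]
        ax.vlines(res.lags, 0, res.values, color="black", lw=1)
        ax.axhline(0, color="black", lw=0.6)
        for s in (1, -1):
            ax.axhline(s * res.band, color="tab:blue", ls="--", lw=0.8)
        ax.set_title(_subject_title(subj), fontsize=7)
        ax.tick_params(labelsize=6)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def residual_grid(residuals_by_subject: dict[str, np.ndarray], path) -> None:
    """Per-subject residual traces against the time index."""
    subjects = sorted(residuals_by_subject)
    ncol = math.ceil(math.sqrt(len(subjects)))
    nrow = math.ceil(len(subjects) / ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.4 * ncol, 1.9 * nrow), squeeze=False
    )
    for ax in axes.flat[len(subjects):]:
        ax.set_axis_off()
    for subj, ax in zip(subjects, axes.flat):
        r = residuals_by_subject[subj]
        ax.plot(np.arange(1, len(r) + 1), r, lw=0.8, color="black")
        ax.axhline(0, color="grey", lw=0.6)
        ax.set_title(_subject_title(subj), fontsize=7)
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def window_plot(
    corrected: ComparisonReport,
    path,
    naive: ComparisonReport | None = None,
) -> None:
    """Group-mean curves per pair with significance windows as vertical lines.

    Corrected-mode windows are drawn solid black; naive-mode windows (when
    given) dashed red, for the false-positive/false-negative contrast.
    """
    pairs = sorted(
        set(map(tuple, corrected.results[["group_a", "group_b"]].to_numpy()))
    )
    fig, axes = plt.subplots(
        len(pairs), 1, figsize=(7, 2.6 * len(pairs)), squeeze=False
    )
    for (ga, gb), ax in zip(pairs, axes.flat):
        sub = corrected.results[
            (corrected.results["group_a"] == ga) & (corrected.results["group_b"] == gb)
        ]
        ax.plot(sub["minutes"], sub["mean_a"], label=ga, lw=1.2)
        ax.plot(sub["minutes"], sub["mean_b"], label=gb, lw=1.2)
        for w in corrected.windows_for((ga, gb)):
            ax.axvline(w.start_minutes, color="black", lw=1.2)
            ax.axvline(w.end_minutes, color="black", lw=1.2)
        if naive is not None:
            for w in naive.windows_for((ga, gb)):
                ax.axvline(w.start_minutes, color="tab:red", ls="--", lw=1.0)
                ax.axvline(w.end_minutes, color="tab:red", ls="--", lw=1.0)
        ax.set_title(f"{ga} vs {gb}", fontsize=9)
        ax.set_xlabel("minutes")
        ax.set_ylabel("mean fitted value")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
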