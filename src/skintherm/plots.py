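"""Diagnostic plots for cooling-study results."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats

__all__ = ["plot_melanin_relationship", "plot_phase_by_camera"]


def plot_melanin_relationship(measurements: pd.DataFrame, ax=None):
    """ROI-minus-control difference vs melanin, baseline and cooled.

    One point per subject x phase (within-subject averages), with ordinary
    least-squares trend lines per phase.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    diff = stats.differential_outcome(measurements)
    per_subject = (diff.groupby(["subject_id", "phase"])
                   .agg(diff_C=("diff_C", "mean"),
                        melanin=("melanin_converted", "first"))
                   .reset_index())
    colors = {"baseline": "#d4a017", "cooled": "#1f77b4"}
    for phase, sub in per_subject.groupby("phase"):
        ax.scatter(sub["melanin"], sub["diff_C"], s=18, alpha=0.8,
                   color=colors.get(phase), label=phase)
        slope, intercept = np.polyfit(sub["melanin"], sub["diff_C"], 1)
        xs = np.linspace(sub["melanin"].min(), sub["melanin"].max(), 50)
        ax.plot(xs, slope * xs + intercept, color=colors.get(phase), lw=1.5)
    ax.set_xlabel("melanin (converted scale)")
    ax.set_ylabel("ROI − control (°C)")
    ax.legend(title="phase")
    return ax


def plot_phase_by_camera(measurements: pd.DataFrame, outcome: str = "absolute", ax=None):
    """Subject-level phase-by-camera means for either outcome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if outcome == "absolute":
        data = measurements[measurements["region"] == "roi"]
        value = "median_temp_C"
    else:
        data = stats.differential_outcome(measurements)
        value = "diff_C"
    per_subject = (data.groupby(["subject_id", "camera", "phase"])[value]
                   .mean().reset_index())
    offsets = {"E8XT": -0.12, "ONEPro": 0.12}
    phase_x = {"baseline": 0, "cooled": 1}
    for camera, sub in per_subject.groupby("camera"):
        xs = sub["phase"].map(phase_x) + offsets[camera]
        ax.scatter(xs, sub[value], s=12, alpha=0.5, label=camera)
        means = sub.groupby("phase")[value].mean()
        ax.plot([phase_x[p] + offsets[camera] for p in means.index],
                means.to_numpy(), marker="_", ms=20, lw=1.2)
    ax.set_xticks([0, 1], ["baseline", "cooled"])
    ax.set_ylabel("°C" if outcome == "absolute" else "ROI − control (°C)")
    ax.legend(title="camera")
    return ax
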