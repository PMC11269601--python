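"""Diagnostic figures: error-by-position bars, data + model overlays with
the latent skill curve underneath, and cross-group skill curves."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fitting import FitResult
from .model_core import predict_rt, skill_rt
from .trial_design import DesignConstants

__all__ = ["plot_error_by_position", "plot_fit", "plot_skill_curves"]


def plot_error_by_position(summary: pd.DataFrame, ax=None):
    """Mean error presses before each within-trial sequence position."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for grp, chunk in summary.groupby("group"):
        ax.errorbar(chunk["seq_in_trial"], chunk["mean"],
                    yerr=chunk["sem"], marker="o", capsize=2, label=grp)
    ax.set_xlabel("sequence within trial")
    ax.set_ylabel("error keypresses before sequence")
    ax.legend()
    return ax


def plot_fit(series: pd.DataFrame, fit: FitResult, schedule: pd.DataFrame,
             consts: DesignConstants, ax=None):
    """Averaged RTs with the overall fit and the latent skill curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(1, len(series) + 1)
    ax.errorbar(x, series["rt_mean"], yerr=series.get("rt_sem"),
                fmt="k.", ms=3, elinewidth=0.5, label="data")
    pred = predict_rt(fit.model, fit.params, schedule, consts)
    skill = skill_rt(fit.model, fit.params, schedule, consts)
    ax.plot(x, pred, lw=1.5, label=f"{fit.model} fit")
    ax.plot(x, skill, lw=1.0, alpha=0.35, label="achieved skill")
    ax.set_xlabel("modeled sequence")
    ax.set_ylabel("sequence RT (ms)")
    ax.legend()
    return ax


def plot_skill_curves(fits: dict[str, FitResult],
                      schedules: dict[str, tuple[pd.DataFrame, DesignConstants]],
                      ax=None):
    """Achieved-skill curves of one model across groups (training phase)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for grp, fit in fits.items():
        schedule, consts = schedules[grp]
        train = schedule.loc[schedule["phase"] == "train"]
        skill = skill_rt(fit.model, fit.params, train, consts)
        ax.plot(train["s"], skill, label=grp)
    ax.set_xlabel("modeled sequence")
    ax.set_ylabel("achieved skill RT (ms)")
    ax.legend()
    return ax
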