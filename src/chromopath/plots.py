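"""Matplotlib renderings of the evaluation outputs and the nomogram.

Every number plotted comes from the tables/objects computed elsewhere; the
plots add no computation of their own.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import ROCResult
from .model import NomogramSpec

__all__ = ["plot_roc", "plot_calibration", "plot_dca", "plot_nomogram"]


def _save(fig, path: str | Path | None):
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_roc(curves: Mapping[str, ROCResult], path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in curves.items():
        lab = f"{name}: AUC={roc.auc:.3f}"
        if roc.ci is not None:
            lab += f" (95% CI {roc.ci[0]:.3f}-{roc.ci[1]:.3f})"
        ax.plot(roc.fpr, roc.tpr, label=lab)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return _save(fig, path)


def plot_calibration(
    curves: Mapping[str, pd.DataFrame], path: str | Path | None = None
):
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, df in curves.items():
        ax.plot(df["mean_pred"], df["frac_obs"], "o-", label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed malignant fraction")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_dca(dca: pd.DataFrame, path: str | Path | None = None):
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.plot(dca["threshold"], dca["nb_model"], label="model")
    if {"nb_model_lo", "nb_model_hi"} <= set(dca.columns):
        ax.plot(dca["threshold"], dca["nb_model_lo"], lw=0.7, ls=":",
                color="C0", label="95% band")
        ax.plot(dca["threshold"], dca["nb_model_hi"], lw=0.7, ls=":",
                color="C0")
    ax.plot(dca["threshold"], dca["nb_all"], label="treat all")
    ax.plot(dca["threshold"], dca["nb_none"], label="treat none")
    ax.set_ylim(bottom=max(-0.05, float(dca["nb_all"].min())))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(fontsize=8)
    return _save(fig, path)


def plot_nomogram(spec: NomogramSpec, path: str | Path | None = None):
    """Axis-per-variable nomogram: each predictor's value range on a points
    ruler, a total-points axis, and the probability axis below it."""
    n = len(spec.features) + 2
    fig, axes = plt.subplots(n, 1, figsize=(7, 1.1 * n), sharex=False)
    pts_max = max(spec.axis_maximum(f) for f in spec.features)

    for ax, f in zip(axes[:-2], spec.features):
        lo, hi = spec.ranges[f]
        vals = np.linspace(lo, hi, 6)
        pts = np.array([spec.points(f, v) for v in vals])
        ax.plot(pts, np.zeros_like(pts), "k-", lw=1)
        for v, p in zip(vals, pts):
            ax.plot([p, p], [-0.2, 0.2], "k-", lw=1)
            ax.text(p, 0.35, f"{v:.2f}", ha="center", fontsize=7)
        ax.set_xlim(-2, pts_max + 2)
        ax.set_ylim(-1, 1)
        ax.set_ylabel(f, rotation=0, ha="right", fontsize=8)
        ax.axis("off")
        ax.text(-4, 0, f, ha="right", va="center", fontsize=8)

    total_max = sum(spec.axis_maximum(f) for f in spec.features)
    ax = axes[-2]
    totals = np.linspace(0, total_max, 11)
    ax.plot(totals, np.zeros_like(totals), "k-", lw=1)
    for t in totals:
        ax.plot([t, t], [-0.2, 0.2], "k-", lw=1)
        ax.text(t, 0.35, f"{t:.0f}", ha="center", fontsize=7)
    ax.set_xlim(-2, max(pts_max, total_max) + 2)
    ax.set_ylim(-1, 1)
    ax.axis("off")
    ax.text(-4, 0, "total points", ha="right", va="center", fontsize=8)

    ax = axes[-1]
    probs = np.asarray(spec.probability(totals))
    ax.plot(totals, np.zeros_like(totals), "k-", lw=1)
    for t, pr in zip(totals, probs):
        ax.plot([t, t], [-0.2, 0.2], "k-", lw=1)
        ax.text(t, 0.35, f"{pr:.2f}", ha="center", fontsize=7)
    ax.set_xlim(-2, max(pts_max, total_max) + 2)
    ax.set_ylim(-1, 1)
    ax.axis("off")
    ax.text(-4, 0, "P(malignant)", ha="right", va="center", fontsize=8)
    return _save(fig, path)
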