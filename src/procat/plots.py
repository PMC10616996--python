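"""Evaluation figures: score distributions, regression, Bland-Altman."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_score_distributions(df: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 100, 26)
    ax.hist(df["full_score"], bins=bins, alpha=0.55, label="full-length")
    ax.hist(df["cat_score"], bins=bins, alpha=0.55, label="CAT")
    ax.axvline(df["full_score"].mean(), color="C0", ls="--", lw=1)
    ax.axvline(df["cat_score"].mean(), color="C1", ls="--", lw=1)
    ax.set_xlabel("score (0-100)")
    ax.set_ylabel("respondents")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_regression(df: pd.DataFrame, path) -> None:
    from scipy import stats

    full = df["full_score"].to_numpy(float)
    cat = df["cat_score"].to_numpy(float)
    reg = stats.linregress(full, cat)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(full, cat, s=8, alpha=0.4)
    xs = np.array([full.min(), full.max()])
    ax.plot(xs, reg.intercept + reg.slope * xs, color="C3",
            label=f"y = {reg.intercept:.2f} + {reg.slope:.2f} x (R²={reg.rvalue**2:.2f})")
    ax.plot(xs, xs, color="grey", ls=":", lw=1, label="identity")
    ax.set_xlabel("full-length score")
    ax.set_ylabel("CAT score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(df: pd.DataFrame, path) -> None:
    full = df["full_score"].to_numpy(float)
    cat = df["cat_score"].to_numpy(float)
    diff = cat - full
    mean_pair = (cat + full) / 2.0
    md = diff.mean()
    sd = diff.std(ddof=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean_pair, diff, s=8, alpha=0.4)
    ax.axhline(md, color="C3", label=f"mean difference {md:.2f}")
    for loa in (md - 1.96 * sd, md + 1.96 * sd):
        ax.axhline(loa, color="C3", ls="--", lw=1)
    ax.set_xlabel("mean of CAT and full-length score")
    ax.set_ylabel("CAT − full-length")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_score_trace(trace, full_score: Optional[float], path) -> None:
    """Per-step adaptive score trace with a ±1.96 SE band (one session)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.arange(1, len(trace) + 1)
    ys = np.array([s.estimate.score_0_100 for s in trace])
    ses = np.array([s.estimate.se_0_100 for s in trace])
    ax.errorbar(xs, ys, yerr=1.96 * ses, fmt="o-", capsize=3, label="CAT estimate")
    if full_score is not None:
        ax.axhline(full_score, color="C3", ls="--", label=f"full-length {full_score:.0f}")
    ax.set_xlabel("items answered")
    ax.set_ylabel("score (0-100)")
    ax.set_xticks(xs)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
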