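"""Diagnostic plots: per-SNP forest, effect–effect scatter, leave-one-out.

Best-effort analogues of the standard MR report figures; styling is
intentionally plain matplotlib.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimators import MrEstimate, RatioEstimate, Z_95
from .sensitivity import LeaveOneOutResult
from .summary_io import InstrumentSet


def forest_plot(
    ratios: Sequence[RatioEstimate],
    combined: Sequence[MrEstimate],
    path: str | Path,
    xlabel: str = "log odds ratio per 1-SD exposure",
) -> None:
    """Per-SNP Wald ratios with 95% CIs, with pooled estimates underneath."""
    n = len(ratios)
    fig, ax = plt.subplots(figsize=(7, 0.22 * (n + len(combined)) + 1.5))
    ys = np.arange(n)[::-1] + len(combined) + 1
    for y, r in zip(ys, ratios):
        ax.errorbar(r.theta, y, xerr=Z_95 * r.se_theta, fmt="o", color="black", ms=3, lw=1)
    for k, est in enumerate(combined):
        y = len(combined) - k - 1
        ax.errorbar(
            est.beta, y, xerr=[[est.beta - est.ci_low], [est.ci_high - est.beta]],
            fmt="D", color="crimson", ms=5, lw=1.5,
        )
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(ys) + list(range(len(combined) - 1, -1, -1)))
    ax.set_yticklabels([r.rsid for r in ratios] + [e.method for e in combined], fontsize=6)
    ax.set_xlabel(xlabel)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def scatter_plot(
    s: InstrumentSet,
    estimates: Sequence[MrEstimate],
    path: str | Path,
) -> None:
    """SNP-exposure vs SNP-outcome effects with each method's fitted slope.

    Instruments are oriented to a positive exposure effect so the fitted
    lines (through the origin for IVW and weighted median, free intercept
    for MR-Egger) are drawn in the convention the estimators use.
    """
    bx = np.array([i.beta_exp for i in s])
    by = np.array([i.beta_out for i in s])
    so = np.array([i.se_out for i in s])
    sx = np.array([i.se_exp for i in s])
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sign, by * sign

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(x, y, xerr=Z_95 * sx, yerr=Z_95 * so, fmt="o", ms=4,
                color="steelblue", ecolor="lightsteelblue", lw=0.8, zorder=2)
    grid = np.linspace(0.0, float(x.max()) * 1.05, 50)
    for est in estimates:
        icpt = est.intercept or 0.0
        ax.plot(grid, icpt + est.beta * grid, lw=1.5, label=est.method, zorder=3)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"SNP effect on {s.exposure_name} (SD)")
    ax.set_ylabel(f"SNP effect on {s.outcome_name} (log OR)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def leave_one_out_plot(loo: LeaveOneOutResult, path: str | Path) -> None:
    """IVW estimate after excluding each SNP, with the all-SNP estimate last."""
    labels = list(loo.rows) + ["all SNPs"]
    ests = list(loo.rows.values()) + [loo.full]
    fig, ax = plt.subplots(figsize=(7, 0.22 * len(ests) + 1.5))
    ys = np.arange(len(ests))[::-1]
    for y, est, lab in zip(ys, ests, labels):
        color = "crimson" if lab == "all SNPs" else "black"
        ax.errorbar(
            est.beta, y, xerr=[[est.beta - est.ci_low], [est.ci_high - est.beta]],
            fmt="o", color=color, ms=3.5, lw=1,
        )
    ax.axvline(loo.full.beta, color="crimson", lw=0.8, ls=":")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ys)
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xlabel("IVW log odds ratio (one SNP excluded)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
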