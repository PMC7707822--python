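"""Figure rendering: circular phase diagrams, phase histograms, correlograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .coupling_stats import CircularStats, Correlogram, R_THRESHOLD_DEFAULT


def plot_circular(
    phases,
    stats: CircularStats,
    path: str | Path,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    title: str = "",
) -> None:
    """Phases as marks on the unit circle, mean vector as a dot, inner circle
    at the orientation threshold."""
    phis = np.asarray(phases, dtype=float)
    theta = 2 * np.pi * phis
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.plot(theta, np.ones_like(theta), "kd", ms=4, alpha=0.6)
    circle = np.linspace(0, 2 * np.pi, 200)
    ax.plot(circle, np.full_like(circle, r_threshold), "k--", lw=0.8)
    if np.isfinite(stats.mean_phase):
        ax.plot([2 * np.pi * stats.mean_phase], [stats.R], "o", color="C3", ms=8)
    ax.set_rlim(0, 1.05)
    ax.set_rticks([])
    ax.set_xticks(np.linspace(0, 2 * np.pi, 4, endpoint=False))
    ax.set_xticklabels(["0/1", "0.25", "0.5", "0.75"])
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_phase_histogram(counts, path: str | Path, title: str = "") -> None:
    counts = np.asarray(counts)
    n_bins = counts.size
    edges = np.linspace(0, 1, n_bins + 1)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(edges[:-1], counts, width=1 / n_bins, align="edge",
           color="0.4", edgecolor="k")
    ax.set_xlabel("inspiration phase in stride cycle")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_correlogram(cg: Correlogram, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.fill_between(cg.lags, cg.band_lo, cg.band_hi, color="0.85",
                    label="surrogate band")
    ax.plot(cg.lags, cg.r, "k-", lw=1)
    ax.axhline(0, color="0.5", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("r")
    ax.set_title(title or ("flat" if cg.flat else "not flat"))
    ax.legend(loc="upper right", fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
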