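"""CE-plane and acceptability-curve figures (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_ce_plane(pairs, path, wtp: float | None = 20_000.0, title: str | None = None):
    """Scatter of bootstrapped (delta effect, delta cost) pairs.

    Quadrant axes through the origin; optionally a willingness-to-pay line of
    slope ``wtp`` euros per unit effect.
    """
    pairs = np.asarray(pairs, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(pairs[:, 1], pairs[:, 0], s=4, alpha=0.3, color="#1f6fb4", linewidths=0)
    ax.axhline(0, color="black", lw=0.8)
    ax.axvline(0, color="black", lw=0.8)
    if wtp is not None:
        xs = np.array(ax.get_xlim())
        ax.plot(xs, wtp * xs, color="#c44e52", lw=1.0, ls="--",
                label=f"WTP = {wtp:,.0f} €/unit")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("Incremental effect")
    ax.set_ylabel("Incremental cost (€)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac: dict, path, wtp: float | None = 20_000.0, title: str | None = None):
    """Cost-effectiveness acceptability curve: P(cost-effective) vs ceiling ratio."""
    lambdas = sorted(float(k) for k in ceac)
    probs = [ceac[k] for k in lambdas]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(lambdas, probs, color="#1f6fb4")
    if wtp is not None and min(lambdas) <= wtp <= max(lambdas):
        ax.axvline(wtp, color="#c44e52", lw=1.0, ls="--")
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (€ per unit effect)")
    ax.set_ylabel("Probability cost-effective")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
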