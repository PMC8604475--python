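"""Cost-effectiveness plane and acceptability-curve plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
from matplotlib.patches import Ellipse

from .params import STRATEGY_LABELS

__all__ = ["plot_ce_plane", "plot_ceac"]


def plot_ce_plane(plane, ax=None):
    """Scatter of (ΔQALY, Δcost) draws with the 95% confidence ellipse."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane.d_qaly, plane.d_cost, s=6, alpha=0.4, edgecolors="none")
    if plane.ellipse is not None:
        e = plane.ellipse
        ax.add_patch(
            Ellipse(
                e.center, e.width, e.height, angle=e.angle_deg,
                fill=False, color="crimson", lw=1.5,
            )
        )
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (2020 CAD)")
    ax.set_title(
        f"{STRATEGY_LABELS.get(plane.strategy, plane.strategy)} vs "
        f"{STRATEGY_LABELS.get(plane.reference, plane.reference)}"
    )
    return ax


def plot_ceac(curve, ax=None, exclude_comparator=True):
    """Probability cost-effective against willingness to pay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, probs in curve.probabilities.items():
        if exclude_comparator and name == curve.comparator:
            continue
        ax.plot(curve.wtp, probs, label=STRATEGY_LABELS.get(name, name))
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
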