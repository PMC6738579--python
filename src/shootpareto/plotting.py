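"""Minimal figures: the per-plant Pareto front with the plant marked."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .pareto import AnalysisResult

__all__ = ["plot_front"]


def plot_front(result: AnalysisResult, path, baselines: dict | None = None):
    """Length-vs-travel front curve, the plant as a red X, baselines as markers.

    ``baselines`` maps a name to an iterable of (length, travel) pairs.
    """
    front = result.front
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(front.lengths(), front.travels(), "k-", lw=1.5, label="Pareto front")
    plant = result.summary.plant_objectives
    ax.plot(
        plant.total_length,
        plant.travel_distance,
        "rx",
        ms=10,
        mew=2,
        label=f"plant (ε = {result.summary.epsilon:.3f})",
    )
    markers = {"stable": "g^", "pref_attach": "yo", "random": "bD"}
    for name, pairs in (baselines or {}).items():
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        ax.plot(xs, ys, markers.get(name, "s"), ms=4, alpha=0.5, label=name)
    ax.set_xlabel("total length (mm)")
    ax.set_ylabel("travel distance (mm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
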