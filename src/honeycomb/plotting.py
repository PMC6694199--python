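"""Field-map and gain plots."""

from __future__ import annotations

import numpy as np

from .design import Layout
from .gain import GainEstimate

__all__ = ["plot_layout", "plot_gain"]


def plot_layout(layout: Layout, values=None, annotate_codes: bool = False, ax=None):
    """Scatter the field positions, coloured by entry code or by a
    per-plant value; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7 * 0.9))
    x, y = layout.plants["x_m"], layout.plants["y_m"]
    c = layout.plants["code"] if values is None else np.asarray(values)
    sc = ax.scatter(x, y, c=c, cmap="viridis", s=40)
    if annotate_codes:
        for _, p in layout.plants.iterrows():
            ax.annotate(str(p.code), (p.x_m, p.y_m), fontsize=6, ha="center")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label="entry code" if values is None else "value")
    return ax


def plot_gain(records, estimate: GainEstimate | None = None, ax=None):
    """Scatter (year, yield) records with the fitted gain line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    arr = np.asarray(records, dtype=float) if not hasattr(records, "columns") else (
        records[["year", "pod_g"]].to_numpy(float)
    )
    ax.scatter(arr[:, 0], arr[:, 1], s=12, alpha=0.5)
    if estimate is not None:
        xs = np.linspace(arr[:, 0].min(), arr[:, 0].max(), 2)
        ax.plot(xs, estimate.intercept + estimate.slope * xs, "r-",
                label=f"slope {estimate.slope:.1f} g/plant/year")
        ax.legend()
    ax.set_xlabel("year")
    ax.set_ylabel("pod yield (g/plant)")
    return ax
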