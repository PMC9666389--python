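"""Error-grid plots.

Zones are rendered as severity-coloured regions (A green, B yellow,
C orange, D red, E dark red), paired values as dots, and false negatives at
the hypoglycaemia threshold as crosses so the clinically dangerous errors
stand out. Axes are SMBG (x) versus CGM (y) in mmol/L.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon as MplPolygon

from .grid import RiskGrid, false_negative_mask
from .zones import RiskZone

ZONE_COLOURS = {
    RiskZone.A: "#7fbf7f",   # green
    RiskZone.B: "#ffe066",   # yellow
    RiskZone.C: "#ffa94d",   # orange
    RiskZone.D: "#ff6b6b",   # red
    RiskZone.E: "#c92a2a",   # dark red
}


def plot_grid(pairs, grid: RiskGrid, out_path=None, hypo_threshold: float = 3.5, ax=None):
    """Render a grid with paired values; returns the matplotlib Axes.

    ``pairs`` may be a PairedSet, a pairs DataFrame, or None for the bare
    grid. If ``out_path`` is given the figure is written there.
    """
    if not grid.zones:
        raise ValueError("grid has no zones to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for zone, poly in sorted(grid.zones, key=lambda zp: int(zp[0])):
        ax.add_patch(
            MplPolygon(
                np.asarray(poly.exterior.coords),
                closed=True,
                facecolor=ZONE_COLOURS[zone],
                edgecolor="black",
                linewidth=0.6,
                zorder=1,
            )
        )
    if pairs is not None:
        df = pairs.pairs if hasattr(pairs, "pairs") else pairs
        if len(df):
            smbg = df["smbg_mmol"].to_numpy()
            cgm = df["cgm_mmol"].to_numpy()
            fn = false_negative_mask(smbg, cgm, hypo_threshold)
            (xlo, xhi), (ylo, yhi) = grid.domain
            s = np.clip(smbg, None, xhi)
            c = np.clip(cgm, None, yhi)
            ax.scatter(s[~fn], c[~fn], s=8, marker="o", color="#1c3d5a",
                       zorder=3, label="paired value")
            if fn.any():
                ax.scatter(s[fn], c[fn], s=26, marker="x", color="black",
                           zorder=4, label=f"false negative (<{hypo_threshold:g})")
            ax.legend(loc="upper left", fontsize=8)
    (xlo, xhi), (ylo, yhi) = grid.domain
    ax.set_xlim(xlo, xhi)
    ax.set_ylim(ylo, yhi)
    ax.set_xlabel("SMBG (mmol/L)")
    ax.set_ylabel("CGM (mmol/L)")
    ax.set_title(f"{grid.name} error grid")
    ax.set_aspect("equal")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
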