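"""Tissue rendering: auxin in green, endosomal PIN in red, differentiated
cells in blue, with the projected whorl circle.

Brightness scales with the quantity; the coloring mirrors the convention
used throughout the package's figures.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.collections import PolyCollection
from matplotlib.patches import Circle

from .geometry import TissueMesh

__all__ = ["render_mesh"]


def render_mesh(
    mesh: TissueMesh,
    path: str,
    A_threshold: float = 1.0,
    whorl_radius_fraction: Optional[float] = None,
    pin_scale: Optional[float] = None,
    title: Optional[str] = None,
) -> None:
    """Render the tissue to an SVG/PNG/PDF file (by extension).

    Green channel: auxin relative to ``2 * A_threshold``; red channel:
    endosomal PIN relative to ``pin_scale`` (max observed if omitted);
    differentiated cells are drawn blue.  If ``whorl_radius_fraction``
    is given, the circle separating the outer whorls from the
    reproductive center is overlaid.
    """
    ids = sorted(mesh.cells)
    polys, colors = [], []
    pin_max = pin_scale or max(
        (c.state.pin_endosome for c in mesh.cells.values() if c.state), default=1.0
    ) or 1.0
    for cid in ids:
        cell = mesh.cells[cid]
        polys.append(mesh.ring_points(cid))
        st = cell.state
        if st is None:
            colors.append((0.9, 0.9, 0.9))
        elif st.differentiated:
            b = min(1.0, 0.4 + 0.6 * st.auxin / (2.0 * A_threshold))
            colors.append((0.1, 0.1, b))
        else:
            g = min(1.0, st.auxin / (2.0 * A_threshold))
            r = min(1.0, st.pin_endosome / pin_max)
            colors.append((0.6 * r, g, 0.1))
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.add_collection(
        PolyCollection(polys, facecolors=colors, edgecolors="k", linewidths=0.3)
    )
    if whorl_radius_fraction is not None:
        cx, cy = mesh.tissue_centroid()
        r = mesh.tissue_radius() * whorl_radius_fraction
        ax.add_patch(
            Circle((cx, cy), r, fill=False, ls="--", ec="w", lw=1.2)
        )
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
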