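"""Programmatic test tissues and synthetic traces.

Small, hand-checkable inputs used by the test suite and the examples: a
rectangular grid tissue, a one-dimensional ring of cells (for peak
spacing experiments), and a synthetic trace with planted auxin-maximum
clusters whose ground truth is returned alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np

from .geometry import TissueMesh
from .simulation import Trace, TraceSample
from .transport import CellState

__all__ = ["grid_tissue", "ring_tissue", "PlantedCluster", "planted_cluster_trace"]


def grid_tissue(
    nx: int, ny: int, scale: float = 1.0, with_state: bool = True
) -> TissueMesh:
    """A ``nx`` x ``ny`` block of unit quadrilateral cells."""
    mesh = TissueMesh()
    vid = {}
    for r in range(ny + 1):
        for c in range(nx + 1):
            vid[(r, c)] = mesh.add_vertex(c * scale, r * scale)
    for r in range(ny):
        for c in range(nx):
            cid = mesh.add_cell(
                [vid[(r, c)], vid[(r, c + 1)], vid[(r + 1, c + 1)], vid[(r + 1, c)]]
            )
            if with_state:
                mesh.cells[cid].state = CellState()
    return mesh


def ring_tissue(
    n_cells: int, r_inner: float = 5.0, width: float = 1.0, with_state: bool = True
) -> TissueMesh:
    """A closed 1-D ring of ``n_cells`` quadrilateral cells.

    Every cell has exactly two neighbors; the ring is the standard
    periodic geometry for measuring auxin peak spacing.
    """
    if n_cells < 3:
        raise ValueError("a ring needs at least 3 cells")
    mesh = TissueMesh()
    inner, outer = [], []
    r_out = r_inner + width
    for k in range(n_cells):
        a = 2.0 * math.pi * k / n_cells
        inner.append(mesh.add_vertex(r_inner * math.cos(a), r_inner * math.sin(a)))
        outer.append(mesh.add_vertex(r_out * math.cos(a), r_out * math.sin(a)))
    for k in range(n_cells):
        k2 = (k + 1) % n_cells
        cid = mesh.add_cell([inner[k], inner[k2], outer[k2], outer[k]])
        if with_state:
            mesh.cells[cid].state = CellState()
    return mesh


@dataclass
class PlantedCluster:
    """Ground truth for one synthetic organ cluster."""

    members: Set[int]
    onset_time: float


def planted_cluster_trace(
    mesh: TissueMesh,
    planted: Sequence[PlantedCluster],
    threshold: float,
    t_end: float,
    dt: float = 1.0,
    base_level: float = 0.0,
    peak_level: float | None = None,
) -> Trace:
    """Build a synthetic trace on a static mesh with planted clusters.

    Every planted cluster's member cells jump from ``base_level`` (below
    threshold) to ``peak_level`` (above it) at the cluster's onset time
    and stay there.  Ground truth recovery is exact by construction.
    """
    if peak_level is None:
        peak_level = 2.0 * threshold + 1.0
    ids = sorted(mesh.cells)
    index = {cid: k for k, cid in enumerate(ids)}
    pairs = sorted(
        (i, j) for i, nbrs in mesh.adjacency.items() for j in nbrs if i < j
    )
    centroids = np.array([mesh.cell_centroid(c) for c in ids])
    areas = np.array([mesh.cell_area(c) for c in ids])
    trace = Trace()
    t = 0.0
    while t <= t_end + 1e-9:
        auxin = np.full(len(ids), base_level)
        for cl in planted:
            if t >= cl.onset_time:
                for c in cl.members:
                    auxin[index[c]] = peak_level
        trace.samples.append(
            TraceSample(
                time=t,
                ids=np.asarray(ids),
                auxin=auxin,
                pin_endosome=np.zeros(len(ids)),
                differentiated=auxin > threshold,
                areas=areas.copy(),
                centroids=centroids.copy(),
                adjacency=pairs,
                influx_on=False,
            )
        )
        t += dt
    return trace
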