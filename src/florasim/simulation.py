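"""Growth-transport simulation loop and the recorded trace.

One macro time step applies, in fixed order:

1. Monte Carlo mechanical relaxation (minimize the vertex-model energy),
2. subdivision of over-long boundary walls,
3. auxin-dependent growth of resting areas (while the tissue is growing),
4. integration of the transport/PIN ODE system over ``dt``,
5. differentiation update (threshold crossing),
6. division sweep with PIN replenishment.

Growth stops once the tissue reaches the stopping cell count (meristem
growth cessation); transport then continues for a settling period before
the run ends.  A fixed seed fully determines the trajectory.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import TissueMesh, build_initial_tissue
from .mechanics import (
    divide_if_ready,
    grow_targets,
    relax,
    replenish_pin,
    split_long_boundary_walls,
)
from .params import ModelParams
from .transport import (
    CellState,
    TransportSystem,
    influx_active,
    update_differentiation,
)

__all__ = ["TraceSample", "Trace", "run_simulation", "write_trace_csv"]


@dataclass
class TraceSample:
    """Per-cell observables at one sampled time."""

    time: float
    ids: np.ndarray  # cell ids, sorted
    auxin: np.ndarray
    pin_endosome: np.ndarray
    differentiated: np.ndarray  # bool
    areas: np.ndarray
    centroids: np.ndarray  # (n, 2)
    adjacency: List[Tuple[int, int]]  # undirected id pairs, i < j
    influx_on: bool

    @property
    def n_cells(self) -> int:
        return len(self.ids)


@dataclass
class Trace:
    """Time series of samples from one simulation run."""

    samples: List[TraceSample] = field(default_factory=list)
    seed: Optional[int] = None
    events: Dict[str, float] = field(default_factory=dict)

    @property
    def final(self) -> TraceSample:
        return self.samples[-1]

    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.samples])

    def cell_counts(self) -> np.ndarray:
        return np.array([s.n_cells for s in self.samples])

    def time_cell_count_reached(self, k: int) -> Optional[float]:
        """First sampled time at which the tissue held >= ``k`` cells."""
        for s in self.samples:
            if s.n_cells >= k:
                return s.time
        return None

    def tissue_center_radius(self) -> Tuple[Tuple[float, float], float]:
        """Area-weighted tissue center and area-equivalent radius at trace end.

        The radius is that of the disc with the tissue's total area,
        which is robust to boundary lobes of the stochastic outline.
        """
        s = self.final
        w = s.areas / s.areas.sum()
        cx = float(np.dot(w, s.centroids[:, 0]))
        cy = float(np.dot(w, s.centroids[:, 1]))
        r = float(math.sqrt(s.areas.sum() / math.pi))
        return (cx, cy), r


def _sample(mesh: TissueMesh, t: float, influx_on: bool) -> TraceSample:
    ids = sorted(mesh.cells)
    n = len(ids)
    auxin = np.empty(n)
    pe = np.empty(n)
    diff = np.zeros(n, dtype=bool)
    areas = np.empty(n)
    cents = np.empty((n, 2))
    for k, cid in enumerate(ids):
        st: CellState = mesh.cells[cid].state
        auxin[k] = st.auxin
        pe[k] = st.pin_endosome
        diff[k] = st.differentiated
        areas[k] = mesh.cell_area(cid)
        cents[k] = mesh.cell_centroid(cid)
    pairs = sorted(
        (i, j) for i, nbrs in mesh.adjacency.items() for j in nbrs if i < j
    )
    return TraceSample(
        time=t,
        ids=np.asarray(ids),
        auxin=auxin,
        pin_endosome=pe,
        differentiated=diff,
        areas=areas,
        centroids=cents,
        adjacency=pairs,
        influx_on=influx_on,
    )


def init_states(mesh: TissueMesh, params: ModelParams) -> None:
    """Attach fresh chemical states to every cell of a new tissue."""
    for cell in mesh.cells.values():
        cell.state = CellState(
            auxin=params.sim.initial_auxin,
            pin_endosome=params.transport.pin_total,
        )


def run_simulation(
    params: ModelParams,
    seed: int,
    stop_cell_count: Optional[int] = None,
    mesh: Optional[TissueMesh] = None,
) -> Tuple[Trace, TissueMesh]:
    """Run one seeded simulation from the initial callus to cessation.

    Returns the recorded trace and the final tissue.  ``stop_cell_count``
    overrides the value in ``params.sim``; an existing ``mesh`` (e.g. a
    loaded snapshot) may be supplied to resume instead of starting from
    the initial tissue.
    """
    params.validate()
    sim = params.sim
    stop = stop_cell_count if stop_cell_count is not None else sim.stop_cell_count
    if mesh is None:
        mesh = build_initial_tissue(sim.n_initial_cells, sim.cell_scale)
        init_states(mesh, params)
    if stop <= len(mesh.cells):
        raise ValueError("stop_cell_count must exceed the initial cell count")
    rng = np.random.default_rng(seed)
    trace = Trace(seed=seed)

    t = 0.0
    growing = True
    settle_end = math.inf
    trace.samples.append(
        _sample(mesh, t, influx_active(len(mesh.cells), params.transport))
    )
    for _ in range(sim.max_steps):
        relax(mesh, params.mechanics, rng, n_sweeps=sim.mc_sweeps)
        split_long_boundary_walls(mesh, sim.boundary_wall_cap * sim.cell_scale)
        if growing:
            grow_targets(mesh, params.mechanics, sim.dt)

        states = {cid: c.state for cid, c in mesh.cells.items()}
        system = TransportSystem(
            mesh, states, params.transport, n_cells=len(mesh.cells)
        )
        system.integrate(sim.dt, sim.ode_substep)
        system.writeback()
        t += sim.dt
        update_differentiation(states, params.transport, t)

        if growing:
            divided = False
            for cid in sorted(mesh.cells):
                if divide_if_ready(mesh, cid, rng, params.mechanics):
                    divided = True
            if divided:
                replenish_pin(
                    {cid: c.state for cid, c in mesh.cells.items()},
                    params.transport.pin_total,
                )

        influx_on = growing and influx_active(len(mesh.cells), params.transport)
        trace.samples.append(_sample(mesh, t, influx_on))

        if growing and len(mesh.cells) >= stop:
            growing = False
            settle_end = t + sim.settle_time
            trace.events["growth_stop"] = t
        if not growing and t >= settle_end - 1e-9:
            break
    else:
        raise RuntimeError("simulation did not finish within max_steps")
    mesh.epoch = t
    return trace, mesh


def write_trace_csv(trace: Trace, path: str) -> None:
    """Write the trace as long-format CSV (one row per cell per sample)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["time", "cell_id", "auxin", "pin_endosome", "differentiated", "area"]
        )
        for s in trace.samples:
            for k, cid in enumerate(s.ids):
                w.writerow(
                    [
                        f"{s.time:.6g}",
                        int(cid),
                        f"{s.auxin[k]:.9g}",
                        f"{s.pin_endosome[k]:.9g}",
                        int(s.differentiated[k]),
                        f"{s.areas[k]:.9g}",
                    ]
                )
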