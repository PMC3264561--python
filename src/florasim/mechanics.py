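"""Vertex-model cell mechanics: energy, Monte Carlo relaxation, growth,
and cell division.

The tissue's generalized potential energy is the standard vertex-model
form

    H = sum_cells  lambda_A (a - A_T)^2  +  sum_walls lambda_M (l - L_T)^2

with ``a``/``A_T`` actual and resting cell area (turgor pressure
resistance) and ``l``/``L_T`` actual and resting wall length (wall
springs).  Growth raises the resting areas as a saturating function of
the cell's auxin concentration; the Monte Carlo minimizer then lets the
actual shapes follow by random vertex displacements with Metropolis
acceptance.  A cell divides once its area has doubled since its last
division, splitting through the centroid perpendicular to its longest
principal axis; daughters inherit the parent's auxin concentration and
partition its PIN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import TissueMesh, polygon_area, polygon_is_simple
from .transport import CellState

__all__ = [
    "MechanicsParams",
    "hamiltonian",
    "relax",
    "grow_targets",
    "divide_if_ready",
    "replenish_pin",
    "split_long_boundary_walls",
]


@dataclass
class MechanicsParams:
    """Mechanical and growth parameters.

    Units are dimensionless model units: energy per length^4 for
    ``lambda_area``, energy per length^2 for ``lambda_wall``, area per
    time for the growth rates.  ``mc_temperature = 0`` gives strict
    energy descent.
    """

    lambda_area: float = 10.0  # turgor resistance coefficient
    lambda_wall: float = 1.0  # wall spring constant
    mc_step: float = 0.05  # max vertex displacement per trial
    mc_temperature: float = 0.0  # Boltzmann acceptance scale
    mc_trials_per_sweep: int = 0  # 0 -> one trial per vertex
    g0: float = 0.05  # baseline target-area growth rate
    gA: float = 0.01  # auxin-dependent growth amplitude
    hA: float = 1.0  # half-maximum auxin for growth
    division_factor: float = 2.0  # divide when area doubles
    max_division_retries: int = 10
    global_scaling: bool = True  # strict-descent uniform inflation move

    def validate(self) -> None:
        if self.hA <= 0:
            raise ValueError("hA must be positive")
        if self.division_factor <= 1:
            raise ValueError("division_factor must exceed 1")
        for name in ("lambda_area", "lambda_wall", "mc_step",
                     "mc_temperature", "g0", "gA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# energy


def hamiltonian(mesh: TissueMesh, params: MechanicsParams) -> float:
    """Total potential energy of the tissue (zero at rest)."""
    h = 0.0
    la, lm = params.lambda_area, params.lambda_wall
    for cid, cell in mesh.cells.items():
        da = mesh.cell_area(cid) - cell.rest_area
        h += la * da * da
    for wall in mesh.walls.values():
        dl = mesh.wall_length_of(wall) - wall.rest_length
        h += lm * dl * dl
    return h


def _local_energy(mesh: TissueMesh, params: MechanicsParams,
                  cids, wids) -> float:
    la, lm = params.lambda_area, params.lambda_wall
    h = 0.0
    for cid in cids:
        cell = mesh.cells[cid]
        pts = [mesh.vertices[v] for v in cell.ring]
        da = polygon_area(pts) - cell.rest_area
        h += la * da * da
    for wid in wids:
        wall = mesh.walls[wid]
        dl = mesh.wall_length_of(wall) - wall.rest_length
        h += lm * dl * dl
    return h


# ---------------------------------------------------------------------------
# Monte Carlo relaxation


def _try_global_scaling(mesh: TissueMesh, params: MechanicsParams) -> None:
    """Propose a uniform inflation of the tissue about its centroid.

    The trial factor matches total actual to total resting area; it is
    accepted only if it strictly lowers the energy, so the move is always
    admissible under zero-temperature descent.  It lets the mesh follow
    near-uniform growth in one step instead of one boundary vertex at a
    time.
    """
    total_a = sum(mesh.cell_area(c) for c in mesh.cells)
    total_t = sum(c.rest_area for c in mesh.cells.values())
    if total_a <= 0 or total_t <= 0:
        return
    s = math.sqrt(total_t / total_a)
    s = min(1.05, max(0.95, s))
    if abs(s - 1.0) < 1e-12:
        return
    cx, cy = mesh.tissue_centroid()
    h_old = hamiltonian(mesh, params)
    old = dict(mesh.vertices)
    for vid, (x, y) in old.items():
        mesh.vertices[vid] = (cx + s * (x - cx), cy + s * (y - cy))
    if hamiltonian(mesh, params) >= h_old:
        mesh.vertices.update(old)


def relax(
    mesh: TissueMesh,
    params: MechanicsParams,
    rng: np.random.Generator,
    n_sweeps: int = 1,
) -> TissueMesh:
    """Metropolis relaxation by random single-vertex displacements.

    Each trial displaces one vertex uniformly within a disc of radius
    ``mc_step``; the move is accepted if it lowers the energy, or with
    Boltzmann probability ``exp(-dH / mc_temperature)`` when the
    temperature is positive.  Moves that would invert or self-intersect
    any incident cell are rejected outright, so at zero temperature the
    energy never increases.
    """
    temp = params.mc_temperature
    step = params.mc_step
    for _ in range(n_sweeps):
        if params.global_scaling:
            _try_global_scaling(mesh, params)
        vids = sorted(mesh.vertices)
        n_trials = params.mc_trials_per_sweep or len(vids)
        order = rng.integers(0, len(vids), size=n_trials)
        radii = step * np.sqrt(rng.random(n_trials))
        angles = 2.0 * math.pi * rng.random(n_trials)
        for t in range(n_trials):
            vid = vids[order[t]]
            cids = mesh._vertex_cells[vid]
            wids = mesh._vertex_walls[vid]
            old_pos = mesh.vertices[vid]
            h_old = _local_energy(mesh, params, cids, wids)
            mesh.vertices[vid] = (
                old_pos[0] + radii[t] * math.cos(angles[t]),
                old_pos[1] + radii[t] * math.sin(angles[t]),
            )
            dh = _local_energy(mesh, params, cids, wids) - h_old
            accept = dh < 0 or (
                temp > 0 and rng.random() < math.exp(-dh / temp)
            )
            if accept:
                for cid in cids:
                    pts = [mesh.vertices[v] for v in mesh.cells[cid].ring]
                    if polygon_area(pts) <= 0 or not polygon_is_simple(pts):
                        accept = False
                        break
            if not accept:
                mesh.vertices[vid] = old_pos
    return mesh


# ---------------------------------------------------------------------------
# growth


def grow_targets(mesh: TissueMesh, params: MechanicsParams, dt: float) -> TissueMesh:
    """Increase resting areas by the auxin-dependent growth law.

    Each cell's resting area grows by ``dt * (g0 + gA * A / (hA + A))``
    — saturating in the cell's auxin concentration ``A`` — and wall
    resting lengths are rescaled by the square root of the incident
    cells' resting-area ratio so that shape targets stay consistent
    (geometric mean of the two factors for shared walls).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    factor: Dict[int, float] = {}
    for cid, cell in mesh.cells.items():
        a = cell.state.auxin if cell.state is not None else 0.0
        inc = dt * (params.g0 + params.gA * a / (params.hA + a))
        old = cell.rest_area
        cell.rest_area = old + inc
        factor[cid] = math.sqrt(cell.rest_area / old) if old > 0 else 1.0
    for wall in mesh.walls.values():
        fs = [factor[c] for c in wall.cells]
        wall.rest_length *= math.prod(fs) ** (1.0 / len(fs))
    return mesh


# ---------------------------------------------------------------------------
# division


def _principal_axis(pts: List[Tuple[float, float]]) -> Tuple[float, float]:
    """Unit vector of the polygon's longest principal axis (area moments)."""
    cx, cy = 0.0, 0.0
    a = 0.0
    n = len(pts)
    for k in range(n):
        x1, y1 = pts[k]
        x2, y2 = pts[(k + 1) % n]
        cross = x1 * y2 - x2 * y1
        a += cross
        cx += (x1 + x2) * cross
        cy += (y1 + y2) * cross
    a *= 0.5
    cx /= 6.0 * a
    cy /= 6.0 * a
    sxx = sxy = syy = 0.0
    for k in range(n):
        x1, y1 = pts[k][0] - cx, pts[k][1] - cy
        x2, y2 = pts[(k + 1) % n][0] - cx, pts[(k + 1) % n][1] - cy
        cross = x1 * y2 - x2 * y1
        sxx += (x1 * x1 + x1 * x2 + x2 * x2) * cross
        syy += (y1 * y1 + y1 * y2 + y2 * y2) * cross
        sxy += (x1 * y2 + 2 * x1 * y1 + 2 * x2 * y2 + x2 * y1) * cross
    cov = np.array([[sxx / 12.0, sxy / 24.0], [sxy / 24.0, syy / 12.0]])
    w, v = np.linalg.eigh(cov)
    major = v[:, int(np.argmax(w))]
    return float(major[0]), float(major[1])


def _line_ring_crossings(mesh, ring, origin, direction):
    """Intersections of the infinite line with the ring's edges.

    Returns a list of ``(t_line, edge_index, s_edge, point)`` sorted by
    the line parameter.
    """
    ox, oy = origin
    dx, dy = direction
    out = []
    n = len(ring)
    for k in range(n):
        x1, y1 = mesh.vertices[ring[k]]
        x2, y2 = mesh.vertices[ring[(k + 1) % n]]
        ex, ey = x2 - x1, y2 - y1
        denom = dx * ey - dy * ex
        if abs(denom) < 1e-14:
            continue
        # origin + t*dir == p1 + s*e  (2-D cross-product solve)
        s = ((x1 - ox) * dy - (y1 - oy) * dx) / denom
        t = ((x1 - ox) * ey - (y1 - oy) * ex) / denom
        if 1e-6 < s < 1.0 - 1e-6:
            out.append((t, k, s, (x1 + s * ex, y1 + s * ey)))
    out.sort()
    return out


def divide_if_ready(
    mesh: TissueMesh,
    cid: int,
    rng: np.random.Generator,
    params: MechanicsParams,
) -> Optional[Tuple[int, int]]:
    """Divide a cell if its area has grown past the doubling threshold.

    The division plane passes through the centroid perpendicular to the
    longest principal axis (shortest-axis split).  Both daughters inherit
    the parent's auxin concentration unchanged; endosomal PIN is split in
    proportion to daughter area; wall PIN follows the walls (split by the
    shared-wall length each daughter keeps when a neighbor touches both),
    and the new daughter-daughter wall starts with zero PIN.  Resting
    areas are reset to the daughters' current areas.  Returns the
    daughter id pair, or None if the cell did not divide (or the split
    stayed degenerate after bounded plane-angle retries).
    """
    cell = mesh.cells[cid]
    area = mesh.cell_area(cid)
    if area < params.division_factor * cell.area_at_last_division:
        return None

    ring0 = list(cell.ring)
    pts = [mesh.vertices[v] for v in ring0]
    centroid = mesh.cell_centroid(cid)
    mx, my = _principal_axis(pts)
    # division line direction: perpendicular to the major axis
    base_dir = (-my, mx)

    parent_state: CellState = cell.state
    neighbors = sorted(mesh.adjacency[cid])

    for attempt in range(params.max_division_retries):
        if attempt == 0:
            direction = base_dir
        else:
            ang = rng.uniform(-0.5, 0.5)
            ca, sa = math.cos(ang), math.sin(ang)
            direction = (
                base_dir[0] * ca - base_dir[1] * sa,
                base_dir[0] * sa + base_dir[1] * ca,
            )
        crossings = _line_ring_crossings(mesh, cell.ring, centroid, direction)
        if len(crossings) < 2:
            continue
        # pick the two crossings straddling the centroid (t=0)
        below = [c for c in crossings if c[0] < 0]
        above = [c for c in crossings if c[0] > 0]
        if not below or not above:
            continue
        c1 = max(below)
        c2 = min(above)
        if c1[1] == c2[1]:
            continue
        wall_ids = mesh.cell_walls(cid)
        w1, w2 = wall_ids[c1[1]], wall_ids[c2[1]]
        va = mesh.split_wall(w1, c1[3])
        vb = mesh.split_wall(w2, c2[3])
        try:
            kept, new = mesh.split_cell(cid, va, vb)
        except ValueError:
            # degenerate ring; the inserted vertices stay (harmless) and
            # we retry with a jittered plane next attempt
            continue
        break
    else:
        return None

    a_kept = mesh.cell_area(kept)
    a_new = mesh.cell_area(new)
    frac = a_kept / (a_kept + a_new)

    for did, a in ((kept, a_kept), (new, a_new)):
        d = mesh.cells[did]
        d.rest_area = a
        d.area_at_last_division = a

    st_kept = CellState(
        auxin=parent_state.auxin,
        pin_endosome=parent_state.pin_endosome * frac,
        differentiated=parent_state.differentiated,
        differentiation_time=parent_state.differentiation_time,
    )
    st_new = CellState(
        auxin=parent_state.auxin,
        pin_endosome=parent_state.pin_endosome * (1.0 - frac),
        differentiated=parent_state.differentiated,
        differentiation_time=parent_state.differentiation_time,
    )
    adj = mesh.adjacency
    for j in neighbors:
        pij = parent_state.pin_wall.get(j, 0.0)
        sk = mesh.shared_wall_length(kept, j) if j in adj[kept] else 0.0
        sn = mesh.shared_wall_length(new, j) if j in adj[new] else 0.0
        tot = sk + sn
        if tot <= 0:
            # neighbor lost contact in the split (should not happen);
            # push the PIN back to the endosome to conserve it
            st_kept.pin_endosome += pij
            wk = wn = 0.0
        else:
            wk, wn = pij * sk / tot, pij * sn / tot
        if sk > 0:
            st_kept.pin_wall[j] = wk
        if sn > 0:
            st_new.pin_wall[j] = wn
        # the neighbor's own PIN facing the parent splits the same way
        jstate: CellState = mesh.cells[j].state
        pji = jstate.pin_wall.pop(cid, 0.0)
        if tot > 0:
            if sk > 0:
                jstate.pin_wall[kept] = pji * sk / tot
            if sn > 0:
                jstate.pin_wall[new] = pji * sn / tot
        else:
            jstate.pin_endosome += pji
    # new shared wall starts PIN-free
    st_kept.pin_wall[new] = 0.0
    st_new.pin_wall[kept] = 0.0

    mesh.cells[kept].state = st_kept
    mesh.cells[new].state = st_new
    return kept, new


def replenish_pin(states: Dict[int, CellState], pin_total: float) -> None:
    """Top each cell's PIN pool back up to the fixed per-cell amount.

    Models de-novo PIN synthesis after division: the endosomal pool is
    raised (or lowered) so that endosome + wall PIN equals ``pin_total``;
    if wall PIN alone exceeds the total, walls are scaled down instead.
    """
    for st in states.values():
        wall_sum = sum(st.pin_wall.values())
        if wall_sum > pin_total:
            scale = pin_total / wall_sum
            for j in st.pin_wall:
                st.pin_wall[j] *= scale
            st.pin_endosome = 0.0
        else:
            st.pin_endosome = pin_total - wall_sum


def split_long_boundary_walls(mesh: TissueMesh, max_length: float) -> int:
    """Subdivide boundary walls longer than ``max_length`` at the midpoint.

    Gives the Monte Carlo minimizer enough boundary vertices to express
    the curvature of the expanding outline.  Returns the number of splits.
    """
    n = 0
    for wid in [w for w, wall in mesh.walls.items() if wall.is_boundary]:
        wall = mesh.walls.get(wid)
        if wall is None:
            continue
        if mesh.wall_length_of(wall) > max_length:
            a, b = wall.vertices
            (x1, y1), (x2, y2) = mesh.vertices[a], mesh.vertices[b]
            mesh.split_wall(wid, (0.5 * (x1 + x2), 0.5 * (y1 + y2)))
            n += 1
    return n
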