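"""Polar auxin transport with up-the-gradient PIN polarization.

Each cell ``i`` carries an auxin concentration ``A_i``, an endosomal PIN
pool ``P_i`` and a membrane PIN amount ``P_ij`` for every wall facing a
neighbor ``j``.  The dynamics on the cell adjacency graph are

    dA_i/dt = sum_j [ T (P_ji g(A_j) - P_ij g(A_i)) + D S_ij (A_j - A_i) ]
              + p - d_eff(i) A_i + f * [i on boundary and influx active]

    dP_ij/dt = k1 P_i h(A_j) - k2 P_ij
    dP_i/dt  = sum_j [ k2 P_ij - k1 P_i h(A_j) ]

with ``h(x) = x / (K_mm + x)`` and ``g(x) = x / (K_transport + x)``
Michaelis-Menten saturation functions, ``S_ij`` the shared wall length,
``T``/``D`` the active/passive transport coefficients, and ``d_eff`` a
decay rate that switches from ``d1`` to ``d1 + d2`` once a cell
differentiates (its pro-vasculature starts to act as an auxin sink).

Two saturations play distinct roles.  ``h`` polarizes: PIN recruitment
to a wall is driven by the *neighbor's* auxin (auxin inhibits PIN
endocytosis across the wall), so membrane PIN — and with it active
efflux — concentrates on walls facing auxin-rich neighbors.  ``g``
saturates the efflux carrier in its cargo; without it (the switchable
linear-cargo variant, ``export_saturation=False``) the donor-
concentration factor always outweighs the PIN asymmetry and net active
transport runs *down* the gradient, so no patterning instability
exists.  With carriers near saturation, flux follows PIN placement and
concentration differences are amplified up the gradient, while passive
diffusion levels them out.  PIN is conserved per cell by construction;
transport is pairwise antisymmetric, so total auxin is conserved on a
closed tissue.

Integration uses the explicit fifth-order Dormand-Prince scheme; the
embedded fourth-order solution provides an error estimate for the
optional adaptive mode.  Negative states are never clipped: a step that
goes negative is rejected and retried at half the step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import TissueMesh

__all__ = [
    "CellState",
    "TransportParams",
    "saturation",
    "influx_active",
    "TransportSystem",
    "derivatives",
    "rk5_step",
    "integrate",
    "update_differentiation",
]


@dataclass
class CellState:
    """Per-cell chemical state."""

    auxin: float = 0.0
    pin_endosome: float = 0.0
    pin_wall: Dict[int, float] = field(default_factory=dict)
    differentiated: bool = False
    differentiation_time: Optional[float] = None

    @property
    def pin_total(self) -> float:
        return self.pin_endosome + sum(self.pin_wall.values())


@dataclass
class TransportParams:
    """Rate constants of the transport/PIN-cycling system.

    Time and length are dimensionless model units.  ``d_depletion`` is the
    extra decay switched on after differentiation; nominally ten times the
    baseline decay.  ``influx_cell_window`` gates the boundary influx by
    tissue cell count.
    """

    T_active: float = 0.0  # active transport, per PIN amount per time
    D_passive: float = 0.0  # passive transport, per length per time
    p_production: float = 0.0  # local production, conc / time
    production_cell_onset: int = 0  # cells; production inhibited below this
    d_decay: float = 0.0  # baseline decay d1, 1 / time
    d_depletion: float = 0.0  # extra depletion d2 after differentiation
    A_threshold: float = 1.0  # differentiation threshold concentration
    k1: float = 0.0  # endosome -> membrane PIN rate
    k2: float = 0.0  # membrane -> endosome PIN rate
    K_mm: float = 1.0  # Michaelis constant of PIN recruitment h
    K_transport: float = 0.2  # Michaelis constant of the efflux cargo g
    pin_total: float = 0.0  # fixed PIN amount per cell
    f_influx: float = 0.0  # boundary influx, conc / time per boundary cell
    influx_cell_window: Tuple[int, int] = (50, 100)
    influx_mode: str = "per_cell"  # or "per_length"
    export_saturation: bool = True  # False -> linear cargo (no patterning)

    def validate(self) -> None:
        if self.K_mm <= 0 or self.K_transport <= 0:
            raise ValueError("Michaelis constants must be positive")
        lo, hi = self.influx_cell_window
        if lo > hi:
            raise ValueError("influx window must satisfy N_lo <= N_hi")
        for name in (
            "T_active", "D_passive", "p_production", "d_decay",
            "d_depletion", "k1", "k2", "pin_total", "f_influx",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def saturation(x: float, K: float) -> float:
    """Michaelis-Menten saturation x / (K + x), in [0, 1)."""
    if K <= 0:
        raise ValueError("K must be positive")
    x = np.asarray(x, dtype=float) if not np.isscalar(x) else x
    if np.any(np.asarray(x) < 0):
        raise ValueError("saturation argument must be non-negative")
    return x / (K + x)


def influx_active(n_cells: int, params: TransportParams) -> bool:
    """True while the tissue cell count lies inside the influx window."""
    lo, hi = params.influx_cell_window
    return lo <= n_cells <= hi


# ---------------------------------------------------------------------------
# compiled system


class TransportSystem:
    """Mesh + states compiled to flat arrays for vectorized integration.

    The state vector is ``y = [A (n), P_endo (n), P_dir (m)]`` where the
    directed-edge block holds ``P_ij`` for every ordered adjacent pair.
    Compile once per topology change; :meth:`writeback` restores the
    results into the per-cell :class:`CellState` records.
    """

    def __init__(
        self,
        mesh: TissueMesh,
        states: Dict[int, CellState],
        params: TransportParams,
        n_cells: Optional[int] = None,
    ) -> None:
        self.params = params
        self.cell_ids: List[int] = sorted(mesh.cells)
        self.n = len(self.cell_ids)
        self.n_cells = self.n if n_cells is None else n_cells
        idx = {cid: k for k, cid in enumerate(self.cell_ids)}

        # shared wall lengths in one pass over the walls
        pair_len: Dict[Tuple[int, int], float] = {}
        for wall in mesh.walls.values():
            if len(wall.cells) == 2:
                i, j = sorted(wall.cells)
                pair_len[(i, j)] = pair_len.get((i, j), 0.0) + mesh.wall_length_of(
                    wall
                )
        src, dst, shared = [], [], []
        for (i, j), length in sorted(pair_len.items()):
            src.append(idx[i])
            dst.append(idx[j])
            shared.append(length)
            src.append(idx[j])
            dst.append(idx[i])
            shared.append(length)
        self.src = np.asarray(src, dtype=np.intp)
        self.dst = np.asarray(dst, dtype=np.intp)
        self.S = np.asarray(shared, dtype=float)
        self.m = len(src)

        bcells = mesh.boundary_cells()
        self.boundary = np.array([c in bcells for c in self.cell_ids])
        if params.influx_mode == "per_length":
            blen = np.zeros(self.n)
            for k, cid in enumerate(self.cell_ids):
                blen[k] = sum(
                    mesh.wall_length(w)
                    for w in mesh.cell_walls(cid)
                    if mesh.walls[w].is_boundary
                )
            self.boundary_weight = blen
        else:
            self.boundary_weight = self.boundary.astype(float)

        self.differentiated = np.array(
            [states[c].differentiated for c in self.cell_ids]
        )

        y = np.empty(2 * self.n + self.m)
        for k, cid in enumerate(self.cell_ids):
            y[k] = states[cid].auxin
            y[self.n + k] = states[cid].pin_endosome
        for e in range(self.m):
            i = self.cell_ids[self.src[e]]
            j = self.cell_ids[self.dst[e]]
            y[2 * self.n + e] = states[i].pin_wall.get(j, 0.0)
        self.y = y
        self._states = states

    # -- right-hand side ---------------------------------------------------

    def rhs(self, y: np.ndarray) -> np.ndarray:
        p = self.params
        n, m = self.n, self.m
        A = y[:n]
        Pe = y[n : 2 * n]
        P = y[2 * n :]
        src, dst = self.src, self.dst

        out = np.empty_like(y)
        dA = out[:n]
        d_eff = p.d_decay + p.d_depletion * self.differentiated
        np.multiply(A, -d_eff, out=dA)
        if self.n_cells >= p.production_cell_onset:
            dA += p.p_production
        if p.f_influx and influx_active(self.n_cells, p):
            dA += p.f_influx * self.boundary_weight

        if m:
            A_src = A[src]
            A_dst = A[dst]
            if p.export_saturation:
                cargo = A_src / (p.K_transport + A_src)
            else:
                cargo = A_src
            act = p.T_active * P * cargo  # efflux carried by P_ij, from i to j
            flux = p.D_passive * self.S * (A_dst - A_src) - act
            dA += np.bincount(src, weights=flux, minlength=n)
            dA += np.bincount(dst, weights=act, minlength=n)

            h = A_dst / (p.K_mm + A_dst)
            recruit = p.k1 * Pe[src] * h
            ret = p.k2 * P
            out[2 * n :] = recruit - ret
            out[n : 2 * n] = np.bincount(src, weights=ret - recruit, minlength=n)
        else:
            out[n:] = 0.0
        return out

    # -- stepping ----------------------------------------------------------

    # Dormand-Prince 5(4) tableau
    _A = (
        (),
        (1 / 5,),
        (3 / 40, 9 / 40),
        (44 / 45, -56 / 15, 32 / 9),
        (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729),
        (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656),
        (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84),
    )
    _B5 = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0)
    _B4 = (
        5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
        -92097 / 339200, 187 / 2100, 1 / 40,
    )

    def _dp_step(self, y: np.ndarray, h: float) -> Tuple[np.ndarray, float]:
        """One Dormand-Prince step; returns (y5, error norm estimate)."""
        k = [self.rhs(y)]
        for row in self._A[1:]:
            yk = y + h * sum(a * ki for a, ki in zip(row, k) if a != 0.0)
            k.append(self.rhs(yk))
        y5 = y + h * sum(b * ki for b, ki in zip(self._B5, k) if b != 0.0)
        y4 = y + h * sum(b * ki for b, ki in zip(self._B4, k) if b != 0.0)
        err = float(np.max(np.abs(y5 - y4)))
        return y5, err

    def step(self, h: float, max_halvings: int = 20) -> None:
        """Advance the state by ``h``, halving on negativity."""
        self.y = self._advance(self.y, h, max_halvings)

    def _advance(self, y: np.ndarray, h: float, budget: int) -> np.ndarray:
        y5, _ = self._dp_step(y, h)
        if y5.min() >= 0.0:
            return y5
        if budget <= 0:
            raise RuntimeError(
                "transport step kept producing negative state at the step floor"
            )
        half = 0.5 * h
        y_mid = self._advance(y, half, budget - 1)
        return self._advance(y_mid, half, budget - 1)

    def integrate(
        self,
        t_span: float,
        h: float,
        adaptive: bool = False,
        rtol: float = 1e-7,
        atol: float = 1e-10,
    ) -> None:
        """Integrate over ``t_span`` with fixed substeps of at most ``h``.

        With ``adaptive=True`` the embedded 4th-order error estimate
        controls the step size instead (deterministic given the state).
        """
        if t_span <= 0:
            raise ValueError("t_span must be positive")
        if not adaptive:
            nsub = max(1, int(math.ceil(t_span / h - 1e-12)))
            hs = t_span / nsub
            for _ in range(nsub):
                self.step(hs)
            return
        t = 0.0
        while t < t_span - 1e-12:
            h = min(h, t_span - t)
            y5, err = self._dp_step(self.y, h)
            scale = atol + rtol * float(np.max(np.abs(self.y)))
            if err <= scale and y5.min() >= 0.0:
                self.y = y5
                t += h
                h *= min(5.0, 0.9 * (scale / max(err, 1e-300)) ** 0.2)
            else:
                h *= 0.5
                if h < 1e-12:
                    raise RuntimeError("adaptive step underflow")

    # -- writeback ---------------------------------------------------------

    def writeback(self) -> Dict[int, CellState]:
        y = self.y
        n = self.n
        for k, cid in enumerate(self.cell_ids):
            st = self._states[cid]
            st.auxin = float(y[k])
            st.pin_endosome = float(y[n + k])
        for e in range(self.m):
            i = self.cell_ids[self.src[e]]
            j = self.cell_ids[self.dst[e]]
            self._states[i].pin_wall[j] = float(y[2 * n + e])
        return self._states

    def auxin(self) -> np.ndarray:
        return self.y[: self.n].copy()


# ---------------------------------------------------------------------------
# spec-surface wrappers


def derivatives(
    mesh: TissueMesh,
    states: Dict[int, CellState],
    params: TransportParams,
    n_cells: Optional[int] = None,
) -> Dict[int, Tuple[float, float, Dict[int, float]]]:
    """Per-cell time derivatives ``cid -> (dA, dP_endosome, {j: dP_ij})``."""
    sys = TransportSystem(mesh, states, params, n_cells)
    dy = sys.rhs(sys.y)
    n = sys.n
    out: Dict[int, Tuple[float, float, Dict[int, float]]] = {}
    per_wall: Dict[int, Dict[int, float]] = {cid: {} for cid in sys.cell_ids}
    for e in range(sys.m):
        i = sys.cell_ids[sys.src[e]]
        j = sys.cell_ids[sys.dst[e]]
        per_wall[i][j] = float(dy[2 * n + e])
    for k, cid in enumerate(sys.cell_ids):
        out[cid] = (float(dy[k]), float(dy[n + k]), per_wall[cid])
    return out


def rk5_step(
    mesh: TissueMesh,
    states: Dict[int, CellState],
    params: TransportParams,
    dt: float,
    n_cells: Optional[int] = None,
) -> Dict[int, CellState]:
    """Advance all cell states by one fifth-order Runge-Kutta step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    sys = TransportSystem(mesh, states, params, n_cells)
    sys.step(dt)
    return sys.writeback()


def integrate(
    mesh: TissueMesh,
    states: Dict[int, CellState],
    params: TransportParams,
    t_span: float,
    h: float,
    n_cells: Optional[int] = None,
    adaptive: bool = False,
) -> Dict[int, CellState]:
    """Integrate the transport system over ``t_span`` on a fixed mesh."""
    sys = TransportSystem(mesh, states, params, n_cells)
    sys.integrate(t_span, h, adaptive=adaptive)
    return sys.writeback()


def update_differentiation(
    states: Dict[int, CellState], params: TransportParams, t: float
) -> Dict[int, CellState]:
    """Differentiate cells whose auxin strictly exceeds the threshold.

    Differentiation is irreversible; the cell's decay permanently gains
    the depletion term (handled by the differentiated flag in the RHS).
    """
    for st in states.values():
        if not st.differentiated and st.auxin > params.A_threshold:
            st.differentiated = True
            st.differentiation_time = t
    return states
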