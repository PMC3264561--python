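"""Parameter bundles, nominal values, and config-file serialization.

Provenance of the defaults
--------------------------
Constraint-fixed values (stated properties of the model):
  * ``influx_cell_window = (50, 100)`` — boundary auxin influx is active
    while the tissue holds between 50 and 100 cells.
  * ``d_depletion = 10 * d_decay`` — the post-differentiation sink drains
    auxin ten times faster than ordinary decay.
  * ``gA`` small relative to ``g0`` — growth is nearly uniform, with a
    weak auxin dependence.
  * simulations start from 4 cells and stop growing at 700.
Calibrated values (chosen here, in dimensionless model units, so that the
wild-type run develops four outer auxin maxima during the influx window
followed by later inner maxima): all transport rate constants, the
mechanical stiffnesses and Monte Carlo settings, and the analysis
defaults.  They are a re-calibration, not transcribed literature values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict

import yaml

from .mechanics import MechanicsParams
from .transport import TransportParams

__all__ = [
    "SimParams",
    "AnalysisParams",
    "ModelParams",
    "nominal_params",
    "params_to_yaml",
    "params_from_yaml",
]


@dataclass
class SimParams:
    """Operator-splitting loop settings.

    One macro step of length ``dt`` performs, in fixed order: Monte Carlo
    relaxation, boundary-wall subdivision, target growth, transport ODE
    integration over ``dt`` (fifth-order Runge-Kutta substeps of at most
    ``ode_substep``), differentiation update, then a division sweep.
    """

    dt: float = 1.0
    ode_substep: float = 0.2
    mc_sweeps: int = 2
    n_initial_cells: int = 4
    cell_scale: float = 1.0
    stop_cell_count: int = 700
    settle_time: float = 40.0
    boundary_wall_cap: float = 1.6
    initial_auxin: float = 0.0
    max_steps: int = 5000


@dataclass
class AnalysisParams:
    """Cluster detection and organ classification settings.

    ``whorl_radius_fraction`` is the projected circle separating the outer
    two whorls (sepals/petals) from the reproductive center, as a fraction
    of the tissue radius at trace end.  Stage boundaries are mapped to
    cell-count milestones: stage 2 begins when the tissue first reaches
    ``stage2_cells`` cells (a modeling convention of this package).
    ``t_gap`` is the onset-time separation beyond which two contiguous
    super-threshold groups count as distinct organs.
    """

    whorl_radius_fraction: float = 0.5
    stage2_cells: int = 200
    t_gap: float = 10.0


@dataclass
class ModelParams:
    """Full model configuration: mechanics + transport + loop + analysis."""

    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    transport: TransportParams = field(default_factory=TransportParams)
    sim: SimParams = field(default_factory=SimParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def copy(self) -> "ModelParams":
        return dataclasses.replace(
            self,
            mechanics=dataclasses.replace(self.mechanics),
            transport=dataclasses.replace(self.transport),
            sim=dataclasses.replace(self.sim),
            analysis=dataclasses.replace(self.analysis),
        )

    def validate(self) -> None:
        self.mechanics.validate()
        self.transport.validate()

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["transport"]["influx_cell_window"] = list(
            d["transport"]["influx_cell_window"]
        )
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "ModelParams":
        t = dict(d.get("transport", {}))
        if "influx_cell_window" in t:
            t["influx_cell_window"] = tuple(t["influx_cell_window"])
        return cls(
            mechanics=MechanicsParams(**d.get("mechanics", {})),
            transport=TransportParams(**t),
            sim=SimParams(**d.get("sim", {})),
            analysis=AnalysisParams(**d.get("analysis", {})),
        )


def nominal_params() -> ModelParams:
    """The calibrated wild-type parameter set (dimensionless units)."""
    return ModelParams(
        mechanics=MechanicsParams(
            lambda_area=5.0,
            lambda_wall=0.5,
            mc_step=0.08,
            mc_temperature=0.02,
            mc_trials_per_sweep=0,
            g0=0.08,
            gA=0.012,
            hA=1.0,
            division_factor=2.0,
        ),
        transport=TransportParams(
            T_active=0.26,
            D_passive=0.25,
            p_production=0.002,
            production_cell_onset=50,
            d_decay=0.008,
            d_depletion=0.08,
            A_threshold=1.3,
            k1=12.0,
            k2=3.6,
            K_mm=2.0,
            K_transport=0.1,
            pin_total=5.0,
            f_influx=0.12,
            influx_cell_window=(50, 100),
        ),
        sim=SimParams(
            dt=1.0,
            ode_substep=0.08,
            mc_sweeps=2,
            stop_cell_count=700,
            settle_time=70.0,
        ),
        analysis=AnalysisParams(
            whorl_radius_fraction=0.55,
            stage2_cells=100,
            t_gap=60.0,
        ),
    )


def params_to_yaml(params: ModelParams, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def params_from_yaml(path: str) -> ModelParams:
    with open(path) as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))
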