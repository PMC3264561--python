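"""Experiment orchestration: presets, single runs, batches, sweeps.

The presets mirror the genetic perturbations studied with the model:

* ``wildtype`` — the nominal calibrated bundle;
* ``yuc``  — altered auxin biosynthesis (*yucca*): scales the local
  production rate ``p`` and the boundary inflow ``f`` together;
* ``pid``  — altered PIN polarization capacity (*pinoid*): scales the
  endosome-to-membrane cycling rate ``k1``;
* ``pin``  — defective PIN1 (*pin-formed*): scales the fixed amount of
  PIN per cell (20% of nominal for the strong mutant).

Every run is fully determined by its (spec, seed) pair.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .analysis import (
    ORGAN_CLASSES,
    BatchSummary,
    OrganReport,
    analyze_trace,
    summarize_batch,
)
from .params import ModelParams, nominal_params
from .simulation import Trace, run_simulation

__all__ = [
    "ExperimentSpec",
    "preset_params",
    "run_single",
    "run_batch",
    "sensitivity_sweep",
    "SWEEP_PARAMS",
    "PRESETS",
]

PRESETS = ("wildtype", "yuc", "pid", "pin")


@dataclass
class ExperimentSpec:
    """A reproducible experiment definition."""

    preset: str = "wildtype"
    scale: float = 1.0
    n_runs: int = 1
    base_seed: int = 0
    seeds: Optional[Sequence[int]] = None
    stop_cell_count: Optional[int] = None
    output_dir: Optional[str] = None
    params: Optional[ModelParams] = None  # overrides the preset base

    def validate(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def seed_list(self) -> List[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return [self.base_seed + k for k in range(self.n_runs)]


def preset_params(
    preset: str, scale: float = 1.0, base: Optional[ModelParams] = None
) -> ModelParams:
    """The parameter bundle of a preset, with its mutant scaling applied."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    params = (base or nominal_params()).copy()
    if preset == "yuc":
        params.transport.p_production *= scale
        params.transport.f_influx *= scale
    elif preset == "pid":
        params.transport.k1 *= scale
    elif preset == "pin":
        params.transport.pin_total *= scale
    return params


def run_single(
    spec: ExperimentSpec, seed: int
) -> Tuple[Trace, OrganReport]:
    """One seeded simulation plus the organ-pattern analysis."""
    spec.validate()
    params = preset_params(spec.preset, spec.scale, base=spec.params)
    trace, _mesh = run_simulation(
        params, seed, stop_cell_count=spec.stop_cell_count
    )
    stage2 = trace.time_cell_count_reached(params.analysis.stage2_cells)
    _clusters, report = analyze_trace(
        trace,
        A_threshold=params.transport.A_threshold,
        t_gap=params.analysis.t_gap,
        whorl_radius_fraction=params.analysis.whorl_radius_fraction,
        stage2_time=stage2,
        seed=seed,
    )
    return trace, report


def _write_reports_csv(reports: Sequence[OrganReport], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["seed"] + [f"n_{c}" for c in ORGAN_CLASSES])
        for r in reports:
            w.writerow([r.run_seed] + list(r.pattern))


def run_batch(
    spec: ExperimentSpec,
) -> Tuple[BatchSummary, List[OrganReport], List[Tuple[int, str]]]:
    """Run ``n_runs`` seeded simulations and aggregate the patterns.

    Returns the batch summary, the per-run reports, and a list of
    (seed, error message) for runs that failed (excluded from the
    summary).
    """
    spec.validate()
    reports: List[OrganReport] = []
    failures: List[Tuple[int, str]] = []
    for seed in spec.seed_list():
        try:
            _trace, report = run_single(spec, seed)
            reports.append(report)
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            failures.append((seed, f"{type(exc).__name__}: {exc}"))
    if not reports:
        raise RuntimeError(f"all {spec.n_runs} runs failed: {failures}")
    summary = summarize_batch(reports)
    if spec.output_dir:
        os.makedirs(spec.output_dir, exist_ok=True)
        _write_reports_csv(
            reports, os.path.join(spec.output_dir, "organ_reports.csv")
        )
        summary.to_json(os.path.join(spec.output_dir, "batch_summary.json"))
    return summary, reports, failures


# ---------------------------------------------------------------------------
# sensitivity sweep

# the six swept parameters and how a level multiplier is applied
SWEEP_PARAMS = (
    "D_passive",      # passive transport (diffusion)
    "expansion_rate", # baseline target-area growth rate g0
    "influx_timing",  # scales both edges of the influx cell-count window
    "k1",             # endosome -> membrane PIN transport
    "gA",             # auxin-dependent growth amplitude
    "d_depletion",    # post-differentiation depletion rate
)


def _apply_sweep(params: ModelParams, name: str, level: float) -> None:
    if name == "D_passive":
        params.transport.D_passive *= level
    elif name == "expansion_rate":
        params.mechanics.g0 *= level
    elif name == "influx_timing":
        lo, hi = params.transport.influx_cell_window
        params.transport.influx_cell_window = (
            int(round(lo * level)),
            int(round(hi * level)),
        )
    elif name == "k1":
        params.transport.k1 *= level
    elif name == "gA":
        params.mechanics.gA *= level
    elif name == "d_depletion":
        params.transport.d_depletion *= level
    else:
        raise ValueError(f"unknown sweep parameter {name!r}")


def sweep_params_bundle(
    name: str, level: float, base: Optional[ModelParams] = None
) -> ModelParams:
    """Nominal bundle with one swept parameter set to ``level`` x nominal."""
    params = (base or nominal_params()).copy()
    _apply_sweep(params, name, level)
    return params


def sensitivity_sweep(
    params_to_vary: Sequence[str] = SWEEP_PARAMS,
    levels: Sequence[float] = (0.5, 1.0, 1.5),
    n_per_level: int = 30,
    base_seed: int = 0,
    base: Optional[ModelParams] = None,
    stop_cell_count: Optional[int] = None,
) -> pd.DataFrame:
    """Mean and sd of each organ-class count per (parameter, level).

    Each row of the returned table holds one parameter at one multiplier
    of its nominal value, averaged over ``n_per_level`` seeded runs.
    """
    rows = []
    for name in params_to_vary:
        if name not in SWEEP_PARAMS:
            raise ValueError(f"unknown sweep parameter {name!r}")
        for level in levels:
            spec = ExperimentSpec(
                preset="wildtype",
                n_runs=n_per_level,
                base_seed=base_seed,
                stop_cell_count=stop_cell_count,
                params=sweep_params_bundle(name, level, base=base),
            )
            summary, _reports, _failures = run_batch(spec)
            row = {"parameter": name, "level": level, "n_runs": summary.n_runs}
            for cls in ORGAN_CLASSES:
                row[f"mean_{cls}"] = summary.per_class_mean[cls]
                row[f"sd_{cls}"] = summary.per_class_sd[cls]
            rows.append(row)
    return pd.DataFrame(rows)
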