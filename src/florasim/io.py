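"""Lossless JSON tissue snapshots.

The snapshot stores the full simulation state of a tissue — vertices,
walls (with resting lengths), cells (rings, resting areas, division
bookkeeping) and per-cell chemical states — so a run can be resumed or
re-analyzed.  Floats survive the round trip exactly (JSON uses shortest
round-trippable decimal representation).
"""

from __future__ import annotations

import json
from typing import Any, Dict

import numpy as np

from .geometry import Cell, TissueMesh, Wall
from .simulation import Trace, TraceSample
from .transport import CellState

__all__ = [
    "mesh_to_dict",
    "mesh_from_dict",
    "save_mesh",
    "load_mesh",
    "save_trace",
    "load_trace",
]

FORMAT_VERSION = 1


def mesh_to_dict(mesh: TissueMesh) -> Dict[str, Any]:
    return {
        "format": "florasim-tissue",
        "version": FORMAT_VERSION,
        "epoch": mesh.epoch,
        "vertices": {str(v): list(p) for v, p in mesh.vertices.items()},
        "walls": [
            {
                "id": w.id,
                "vertices": list(w.vertices),
                "cells": sorted(w.cells),
                "rest_length": w.rest_length,
            }
            for w in mesh.walls.values()
        ],
        "cells": [
            {
                "id": c.id,
                "ring": list(c.ring),
                "rest_area": c.rest_area,
                "area_at_last_division": c.area_at_last_division,
                "state": None
                if c.state is None
                else {
                    "auxin": c.state.auxin,
                    "pin_endosome": c.state.pin_endosome,
                    "pin_wall": {str(j): v for j, v in c.state.pin_wall.items()},
                    "differentiated": c.state.differentiated,
                    "differentiation_time": c.state.differentiation_time,
                },
            }
            for c in mesh.cells.values()
        ],
    }


def mesh_from_dict(d: Dict[str, Any]) -> TissueMesh:
    if d.get("format") != "florasim-tissue":
        raise ValueError("not a florasim tissue snapshot")
    mesh = TissueMesh()
    mesh.epoch = float(d.get("epoch", 0.0))
    for v, (x, y) in d["vertices"].items():
        vid = int(v)
        mesh.vertices[vid] = (float(x), float(y))
        mesh._vertex_cells[vid] = set()
        mesh._vertex_walls[vid] = set()
    for wd in d["walls"]:
        wall = Wall(
            id=int(wd["id"]),
            vertices=tuple(int(v) for v in wd["vertices"]),
            cells=set(int(c) for c in wd["cells"]),
            rest_length=float(wd["rest_length"]),
        )
        mesh.walls[wall.id] = wall
        a, b = wall.vertices
        mesh._wall_by_pair[(a, b) if a < b else (b, a)] = wall.id
        mesh._vertex_walls[a].add(wall.id)
        mesh._vertex_walls[b].add(wall.id)
    for cd in d["cells"]:
        state = None
        if cd.get("state") is not None:
            sd = cd["state"]
            state = CellState(
                auxin=float(sd["auxin"]),
                pin_endosome=float(sd["pin_endosome"]),
                pin_wall={int(j): float(v) for j, v in sd["pin_wall"].items()},
                differentiated=bool(sd["differentiated"]),
                differentiation_time=sd["differentiation_time"],
            )
        cell = Cell(
            id=int(cd["id"]),
            ring=[int(v) for v in cd["ring"]],
            rest_area=float(cd["rest_area"]),
            area_at_last_division=float(cd["area_at_last_division"]),
            state=state,
        )
        mesh.cells[cell.id] = cell
        for v in cell.ring:
            mesh._vertex_cells[v].add(cell.id)
    mesh._next_vertex = max(mesh.vertices, default=-1) + 1
    mesh._next_wall = max(mesh.walls, default=-1) + 1
    mesh._next_cell = max(mesh.cells, default=-1) + 1
    return mesh


def save_mesh(mesh: TissueMesh, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(mesh_to_dict(mesh), fh)


def load_mesh(path: str) -> TissueMesh:
    with open(path) as fh:
        return mesh_from_dict(json.load(fh))


def save_trace(trace: Trace, path: str) -> None:
    """Serialize a full trace (all samples) to JSON for later analysis."""
    d = {
        "format": "florasim-trace",
        "version": FORMAT_VERSION,
        "seed": trace.seed,
        "events": trace.events,
        "samples": [
            {
                "time": s.time,
                "ids": s.ids.tolist(),
                "auxin": s.auxin.tolist(),
                "pin_endosome": s.pin_endosome.tolist(),
                "differentiated": s.differentiated.astype(int).tolist(),
                "areas": s.areas.tolist(),
                "centroids": s.centroids.tolist(),
                "adjacency": [list(p) for p in s.adjacency],
                "influx_on": s.influx_on,
            }
            for s in trace.samples
        ],
    }
    with open(path, "w") as fh:
        json.dump(d, fh)


def load_trace(path: str) -> Trace:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "florasim-trace":
        raise ValueError("not a florasim trace file")
    trace = Trace(seed=d.get("seed"), events=dict(d.get("events", {})))
    for sd in d["samples"]:
        trace.samples.append(
            TraceSample(
                time=float(sd["time"]),
                ids=np.asarray(sd["ids"], dtype=int),
                auxin=np.asarray(sd["auxin"], dtype=float),
                pin_endosome=np.asarray(sd["pin_endosome"], dtype=float),
                differentiated=np.asarray(sd["differentiated"], dtype=bool),
                areas=np.asarray(sd["areas"], dtype=float),
                centroids=np.asarray(sd["centroids"], dtype=float),
                adjacency=[tuple(p) for p in sd["adjacency"]],
                influx_on=bool(sd["influx_on"]),
            )
        )
    return trace
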