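"""Planar polygonal tissue representation.

A tissue is a planar complex of polygonal cells that share vertices and
walls, in the style of vertex models of plant tissue: every cell is a
simple, counter-clockwise polygon given by an ordered ring of vertex ids;
every wall (polygon edge) is shared by one cell (tissue boundary) or two
cells (interior).  All geometric quantities (areas, lengths, centroids)
are derived from vertex positions on demand and are therefore never stale
after a vertex move.

Coordinates are dimensionless model units; no physical calibration is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Set, Tuple

__all__ = [
    "Wall",
    "Cell",
    "TissueMesh",
    "build_initial_tissue",
    "cell_area",
    "cell_centroid",
    "shared_wall_length",
    "boundary_cells",
    "validate_mesh",
    "polygon_area",
    "polygon_centroid",
    "polygon_is_simple",
]


# ---------------------------------------------------------------------------
# free polygon helpers


def polygon_area(points: Sequence[Tuple[float, float]]) -> float:
    """Signed shoelace area of a polygon (positive for CCW orientation)."""
    s = 0.0
    n = len(points)
    for k in range(n):
        x1, y1 = points[k]
        x2, y2 = points[(k + 1) % n]
        s += x1 * y2 - x2 * y1
    return 0.5 * s


def polygon_centroid(points: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Area-weighted centroid of a simple polygon."""
    a = 0.0
    cx = 0.0
    cy = 0.0
    n = len(points)
    for k in range(n):
        x1, y1 = points[k]
        x2, y2 = points[(k + 1) % n]
        cross = x1 * y2 - x2 * y1
        a += cross
        cx += (x1 + x2) * cross
        cy += (y1 + y2) * cross
    if abs(a) < 1e-300:
        # degenerate: fall back to vertex mean
        return (
            sum(p[0] for p in points) / n,
            sum(p[1] for p in points) / n,
        )
    a *= 0.5
    return cx / (6.0 * a), cy / (6.0 * a)


def _segments_cross(p1, p2, p3, p4) -> bool:
    """True if open segments (p1,p2) and (p3,p4) properly intersect."""

    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != d2 and d3 != d4


def polygon_is_simple(points: Sequence[Tuple[float, float]]) -> bool:
    """O(n^2) check that no two non-adjacent edges cross (cells are small)."""
    n = len(points)
    for a in range(n):
        p1, p2 = points[a], points[(a + 1) % n]
        for b in range(a + 1, n):
            if b == a or (b + 1) % n == a or (a + 1) % n == b:
                continue
            if _segments_cross(p1, p2, points[b], points[(b + 1) % n]):
                return False
    return True


# ---------------------------------------------------------------------------
# entities


@dataclass
class Wall:
    """A straight wall segment between two vertices.

    ``cells`` holds the one (boundary) or two (interior) incident cell ids.
    ``rest_length`` is the resting length of the wall spring; the actual
    length is always recomputed from vertex positions.
    """

    id: int
    vertices: Tuple[int, int]
    cells: Set[int] = field(default_factory=set)
    rest_length: float = 0.0

    @property
    def is_boundary(self) -> bool:
        return len(self.cells) == 1


@dataclass
class Cell:
    """A polygonal cell: CCW ring of vertex ids plus mechanical targets.

    ``state`` is set by the transport layer (a :class:`CellState`); geometry
    does not interpret it.
    """

    id: int
    ring: List[int]
    rest_area: float = 0.0
    area_at_last_division: float = 0.0
    state: Any = None


class TissueMesh:
    """Mutable planar cell complex with incidence bookkeeping.

    Vertices are stored as ``(x, y)`` tuples; walls and cells as dataclass
    records.  Incidence maps (vertex -> cells, vertex -> walls, vertex-pair
    -> wall) are maintained incrementally through the topology-editing
    methods (:meth:`split_wall`, :meth:`split_cell`) so Monte Carlo moves
    and divisions stay cheap.
    """

    def __init__(self) -> None:
        self.vertices: Dict[int, Tuple[float, float]] = {}
        self.walls: Dict[int, Wall] = {}
        self.cells: Dict[int, Cell] = {}
        self.epoch: float = 0.0
        self._next_vertex = 0
        self._next_wall = 0
        self._next_cell = 0
        self._wall_by_pair: Dict[Tuple[int, int], int] = {}
        self._vertex_cells: Dict[int, Set[int]] = {}
        self._vertex_walls: Dict[int, Set[int]] = {}
        self._adjacency: Optional[Dict[int, Set[int]]] = None

    # -- construction -----------------------------------------------------

    def add_vertex(self, x: float, y: float, vid: Optional[int] = None) -> int:
        if vid is None:
            vid = self._next_vertex
        self._next_vertex = max(self._next_vertex, vid + 1)
        self.vertices[vid] = (float(x), float(y))
        self._vertex_cells.setdefault(vid, set())
        self._vertex_walls.setdefault(vid, set())
        return vid

    def _get_or_make_wall(self, a: int, b: int) -> Wall:
        key = (a, b) if a < b else (b, a)
        wid = self._wall_by_pair.get(key)
        if wid is not None:
            return self.walls[wid]
        wid = self._next_wall
        self._next_wall += 1
        wall = Wall(id=wid, vertices=(a, b))
        wall.rest_length = self.wall_length_of(wall)
        self.walls[wid] = wall
        self._wall_by_pair[key] = wid
        self._vertex_walls[a].add(wid)
        self._vertex_walls[b].add(wid)
        return wall

    def add_cell(self, ring: Sequence[int], cid: Optional[int] = None) -> int:
        """Add a cell from a vertex ring; clockwise input is auto-reversed."""
        ring = list(ring)
        if len(ring) < 3:
            raise ValueError("cell ring needs at least 3 vertices")
        pts = [self.vertices[v] for v in ring]
        if polygon_area(pts) < 0:
            ring.reverse()
        if cid is None:
            cid = self._next_cell
        self._next_cell = max(self._next_cell, cid + 1)
        cell = Cell(id=cid, ring=ring)
        self.cells[cid] = cell
        for k, v in enumerate(ring):
            self._vertex_cells[v].add(cid)
            wall = self._get_or_make_wall(v, ring[(k + 1) % len(ring)])
            wall.cells.add(cid)
        area = self.cell_area(cid)
        cell.rest_area = area
        cell.area_at_last_division = area
        self._adjacency = None
        return cid

    # -- geometric queries ------------------------------------------------

    def ring_points(self, cid: int) -> List[Tuple[float, float]]:
        return [self.vertices[v] for v in self.cells[cid].ring]

    def cell_area(self, cid: int) -> float:
        if cid not in self.cells:
            raise KeyError(f"unknown cell id {cid}")
        return polygon_area(self.ring_points(cid))

    def cell_centroid(self, cid: int) -> Tuple[float, float]:
        if cid not in self.cells:
            raise KeyError(f"unknown cell id {cid}")
        return polygon_centroid(self.ring_points(cid))

    def wall_length(self, wid: int) -> float:
        return self.wall_length_of(self.walls[wid])

    def wall_length_of(self, wall: Wall) -> float:
        (x1, y1) = self.vertices[wall.vertices[0]]
        (x2, y2) = self.vertices[wall.vertices[1]]
        return math.hypot(x2 - x1, y2 - y1)

    @property
    def adjacency(self) -> Dict[int, Set[int]]:
        """Map cell id -> set of neighboring cell ids (cached)."""
        if self._adjacency is None:
            adj: Dict[int, Set[int]] = {cid: set() for cid in self.cells}
            for wall in self.walls.values():
                if len(wall.cells) == 2:
                    i, j = tuple(wall.cells)
                    adj[i].add(j)
                    adj[j].add(i)
            self._adjacency = adj
        return self._adjacency

    def shared_walls(self, i: int, j: int) -> List[int]:
        out = []
        for wid in set().union(
            *(self._vertex_walls[v] for v in self.cells[i].ring)
        ):
            if self.walls[wid].cells == {i, j}:
                out.append(wid)
        return sorted(out)

    def shared_wall_length(self, i: int, j: int) -> float:
        if j not in self.adjacency.get(i, set()):
            raise ValueError(f"cells {i} and {j} are not adjacent")
        return sum(self.wall_length(w) for w in self.shared_walls(i, j))

    def cell_walls(self, cid: int) -> List[int]:
        """Wall ids along the cell's ring, in ring order."""
        ring = self.cells[cid].ring
        n = len(ring)
        return [
            self._wall_by_pair[
                (ring[k], ring[(k + 1) % n])
                if ring[k] < ring[(k + 1) % n]
                else (ring[(k + 1) % n], ring[k])
            ]
            for k in range(n)
        ]

    def is_boundary_cell(self, cid: int) -> bool:
        return any(self.walls[w].is_boundary for w in self.cell_walls(cid))

    def boundary_cells(self) -> Set[int]:
        return {cid for cid in self.cells if self.is_boundary_cell(cid)}

    def boundary_ring(self) -> List[int]:
        """Outer boundary as a CCW vertex ring.

        Boundary walls are traversed in the direction their owning cell's
        (CCW) ring uses, which yields a CCW outer polygon.  At a pinched
        vertex (two boundary cells meeting at a single vertex) the walk
        continues along the same cell, so the outline stays on the
        tissue's outside.
        """
        # directed boundary edges (a -> b in the owning cell's CCW ring)
        edges: Dict[int, List[Tuple[int, int]]] = {}  # tail -> [(head, cell)]
        n_edges = 0
        for wall in self.walls.values():
            if not wall.is_boundary:
                continue
            (cid,) = tuple(wall.cells)
            ring = self.cells[cid].ring
            a, b = wall.vertices
            ia = ring.index(a)
            if ring[(ia + 1) % len(ring)] != b:
                a, b = b, a
            edges.setdefault(a, []).append((b, cid))
            n_edges += 1
        if not edges:
            return []
        start = min(edges)
        out = [start]
        v, cell = edges[start][0]
        used = {(start, v)}
        while v != start:
            out.append(v)
            options = [e for e in edges.get(v, []) if (v, e[0]) not in used]
            if not options:
                raise RuntimeError("boundary walk did not close")
            # prefer continuing along the incoming cell's own ring
            same = [e for e in options if e[1] == cell]
            nxt, cell = (same or options)[0]
            used.add((v, nxt))
            v = nxt
            if len(out) > n_edges + 1:
                raise RuntimeError("boundary walk did not close")
        return out

    def boundary_area(self) -> float:
        ring = self.boundary_ring()
        return polygon_area([self.vertices[v] for v in ring])

    def tissue_centroid(self) -> Tuple[float, float]:
        """Area-weighted centroid of the whole tissue."""
        ax = ay = tot = 0.0
        for cid in self.cells:
            a = self.cell_area(cid)
            cx, cy = self.cell_centroid(cid)
            ax += a * cx
            ay += a * cy
            tot += a
        return ax / tot, ay / tot

    def tissue_radius(self) -> float:
        """Max distance from the tissue centroid to a boundary vertex."""
        cx, cy = self.tissue_centroid()
        bverts = {
            v for w in self.walls.values() if w.is_boundary for v in w.vertices
        }
        return max(
            math.hypot(x - cx, y - cy)
            for v in bverts
            for (x, y) in (self.vertices[v],)
        )

    # -- topology editing --------------------------------------------------

    def move_vertex(self, vid: int, x: float, y: float) -> None:
        self.vertices[vid] = (float(x), float(y))

    def split_wall(self, wid: int, pos: Tuple[float, float]) -> int:
        """Insert a vertex at ``pos`` on wall ``wid``; returns the vertex id.

        The wall is replaced by two sub-walls whose rest lengths split the
        original rest length proportionally to their actual lengths; the new
        vertex is inserted in the ring of every incident cell.
        """
        wall = self.walls.pop(wid)
        a, b = wall.vertices
        key = (a, b) if a < b else (b, a)
        del self._wall_by_pair[key]
        self._vertex_walls[a].discard(wid)
        self._vertex_walls[b].discard(wid)

        v = self.add_vertex(*pos)
        la = math.hypot(pos[0] - self.vertices[a][0], pos[1] - self.vertices[a][1])
        lb = math.hypot(pos[0] - self.vertices[b][0], pos[1] - self.vertices[b][1])
        tot = la + lb
        fa = la / tot if tot > 0 else 0.5
        for end, frac in ((a, fa), (b, 1.0 - fa)):
            w = self._get_or_make_wall(end, v)
            w.cells = set(wall.cells)
            w.rest_length = wall.rest_length * frac
        for cid in wall.cells:
            ring = self.cells[cid].ring
            n = len(ring)
            for k in range(n):
                if {ring[k], ring[(k + 1) % n]} == {a, b}:
                    ring.insert(k + 1, v)
                    break
            else:  # pragma: no cover - incidence kept consistent
                raise RuntimeError("wall not found in incident cell ring")
            self._vertex_cells[v].add(cid)
        return v

    def split_cell(self, cid: int, va: int, vb: int) -> Tuple[int, int]:
        """Split cell ``cid`` by a new wall between ring vertices va and vb.

        The parent id is kept by the daughter containing the ring segment
        va..vb; the other daughter gets a fresh id.  Wall incidences and
        rest quantities of the daughters are reset by the caller.
        Returns ``(kept_id, new_id)``.
        """
        cell = self.cells[cid]
        ring = cell.ring
        ia, ib = ring.index(va), ring.index(vb)
        if ia == ib:
            raise ValueError("split endpoints coincide")

        def seg(i, j):
            if i <= j:
                return ring[i : j + 1]
            return ring[i:] + ring[: j + 1]

        ring1 = seg(ia, ib)  # va .. vb
        ring2 = seg(ib, ia)  # vb .. va
        if len(ring1) < 3 or len(ring2) < 3:
            raise ValueError("degenerate split")

        # detach parent from all its walls/vertices
        for wid in self.cell_walls(cid):
            self.walls[wid].cells.discard(cid)
        for v in ring:
            self._vertex_cells[v].discard(cid)
        del self.cells[cid]

        kept = self.add_cell(ring1, cid=cid)
        new = self.add_cell(ring2)
        self._adjacency = None
        return kept, new

    # -- validation --------------------------------------------------------

    def validate(self) -> List[str]:
        """Return a list of human-readable invariant violations (empty = ok)."""
        issues: List[str] = []
        for vid, (x, y) in self.vertices.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                issues.append(f"vertex {vid}: non-finite position")
        for wid, wall in self.walls.items():
            a, b = wall.vertices
            if a == b:
                issues.append(f"wall {wid}: identical endpoints")
            if not 1 <= len(wall.cells) <= 2:
                issues.append(f"wall {wid}: incident to {len(wall.cells)} cells")
            if wall.rest_length < 0:
                issues.append(f"wall {wid}: negative rest length")
        for cid, cell in self.cells.items():
            if len(cell.ring) < 3:
                issues.append(f"cell {cid}: ring has fewer than 3 vertices")
                continue
            pts = self.ring_points(cid)
            if polygon_area(pts) <= 0:
                issues.append(f"cell {cid}: non-positive (non-CCW) area")
            if not polygon_is_simple(pts):
                issues.append(f"cell {cid}: self-intersecting polygon")
            if cell.area_at_last_division <= 0:
                issues.append(f"cell {cid}: non-positive area_at_last_division")
        adj = self.adjacency
        for i, nbrs in adj.items():
            for j in nbrs:
                if i not in adj.get(j, set()):
                    issues.append(f"adjacency not symmetric for pair ({i}, {j})")
                elif i < j and not self.shared_walls(i, j):
                    issues.append(f"adjacent pair ({i}, {j}) shares no wall")
        # tiling conservation: cell areas sum to the outer polygon area
        if self.cells and not issues:
            total = sum(self.cell_area(c) for c in self.cells)
            try:
                outer = self.boundary_area()
            except RuntimeError as exc:
                issues.append(f"boundary not traversable: {exc}")
            else:
                if outer > 0 and abs(total - outer) > 1e-9 * outer:
                    issues.append(
                        f"tiling violated: cell areas {total} vs boundary {outer}"
                    )
        return issues


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers, the public spec surface)


def build_initial_tissue(n_cells: int = 4, cell_scale: float = 1.0) -> TissueMesh:
    """Build the initial "callus": a compact block of quadrilateral cells.

    The starting tissue of a simulation is 4 roughly equal cells; this
    constructor lays out ``n_cells`` as the most square grid factorisation
    (2x2 for the default), each cell a square of side ``cell_scale``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if cell_scale <= 0:
        raise ValueError("cell_scale must be positive")
    rows = int(math.floor(math.sqrt(n_cells)))
    while n_cells % rows != 0:
        rows -= 1
    cols = n_cells // rows
    mesh = TissueMesh()
    vid = {}
    for r in range(rows + 1):
        for c in range(cols + 1):
            vid[(r, c)] = mesh.add_vertex(c * cell_scale, r * cell_scale)
    for r in range(rows):
        for c in range(cols):
            mesh.add_cell(
                [vid[(r, c)], vid[(r, c + 1)], vid[(r + 1, c + 1)], vid[(r + 1, c)]]
            )
    return mesh


def cell_area(mesh: TissueMesh, cid: int) -> float:
    """Shoelace area of cell ``cid`` (positive; rings are kept CCW)."""
    return mesh.cell_area(cid)


def cell_centroid(mesh: TissueMesh, cid: int) -> Tuple[float, float]:
    """Area-weighted polygon centroid of cell ``cid``."""
    return mesh.cell_centroid(cid)


def shared_wall_length(mesh: TissueMesh, i: int, j: int) -> float:
    """Total length of all walls shared by adjacent cells ``i`` and ``j``."""
    return mesh.shared_wall_length(i, j)


def boundary_cells(mesh: TissueMesh) -> Set[int]:
    """Cells owning at least one tissue-boundary wall."""
    return mesh.boundary_cells()


def validate_mesh(mesh: TissueMesh) -> List[str]:
    """Report all invariant violations; an empty list means a valid mesh."""
    return mesh.validate()
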