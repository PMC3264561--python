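"""Detection and classification of auxin-maximum clusters (presumed organs).

An organ anlage is a connected group of cells whose auxin concentration
exceeds the differentiation threshold.  Clusters are tracked through the
sampled time series:

* a super-threshold connected component that overlaps no currently
  active cluster founds a new cluster (its onset time is recorded) —
  unless a dormant cluster at the same place went quiet less than
  ``t_gap`` ago, in which case that cluster is simply reactivated;
* two contiguous super-threshold groups therefore count as different
  organs when they are separated by a sub-threshold cell, or when they
  come into existence more than ``t_gap`` apart in time;
* clusters that become one connected component and stay connected until
  the end of the trace are fused into a single presumed organ with the
  earlier onset time.

Classification projects a circle onto the tissue: clusters outside
``whorl_radius_fraction`` of the tissue radius belong to the outer two
whorls and are sepals if they emerged before stage 2 (petals otherwise);
clusters inside the circle are reproductive organs (stamens/carpels).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .simulation import Trace, TraceSample

__all__ = [
    "OrganCluster",
    "OrganReport",
    "BatchSummary",
    "detect_clusters",
    "merge_fused",
    "classify_organs",
    "summarize_batch",
    "analyze_trace",
]

ORGAN_CLASSES = ("sepal", "petal", "reproductive")


@dataclass
class OrganCluster:
    """A detected auxin-maximum cluster."""

    member_cells: Set[int]
    onset_time: float
    centroid: Tuple[float, float] = (0.0, 0.0)
    radial_fraction: float = 0.0
    organ_class: Optional[str] = None
    last_active_time: float = 0.0
    threshold: float = 0.0  # detection threshold, kept for fusion checks
    founding_cells: Set[int] = field(default_factory=set)  # initiation site


@dataclass
class OrganReport:
    """Per-run organ counts."""

    counts: Dict[str, int]
    run_seed: Optional[int] = None

    @property
    def pattern(self) -> Tuple[int, int, int]:
        return tuple(self.counts.get(c, 0) for c in ORGAN_CLASSES)


@dataclass
class BatchSummary:
    """Pattern frequencies and per-class variation over a batch of runs."""

    pattern_frequency: Dict[Tuple[int, int, int], int]
    per_class_mean: Dict[str, float]
    per_class_sd: Dict[str, float]
    per_class_cv_percent: Dict[str, float]
    n_runs: int
    single_run: bool = False  # sd reported as 0 for a single run

    @property
    def modal_pattern(self) -> Tuple[int, int, int]:
        return max(
            sorted(self.pattern_frequency), key=self.pattern_frequency.get
        )

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "pattern_frequency": {
                        "-".join(map(str, k)): v
                        for k, v in sorted(self.pattern_frequency.items())
                    },
                    "per_class_mean": self.per_class_mean,
                    "per_class_sd": self.per_class_sd,
                    "per_class_cv_percent": self.per_class_cv_percent,
                    "n_runs": self.n_runs,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# component helpers


def _components(cells: Set[int], pairs: Iterable[Tuple[int, int]]) -> List[Set[int]]:
    """Connected components of ``cells`` under the given adjacency pairs."""
    parent = {c: c for c in cells}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        if a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps: Dict[int, Set[int]] = {}
    for c in cells:
        comps.setdefault(find(c), set()).add(c)
    return list(comps.values())


def _super_threshold(sample: TraceSample, thr: float) -> Set[int]:
    mask = sample.auxin > thr
    return set(int(i) for i in sample.ids[mask])


# ---------------------------------------------------------------------------
# detection


def detect_clusters(
    trace: Trace, A_threshold: float, t_gap: float
) -> List[OrganCluster]:
    """Track connected super-threshold components into organ clusters.

    Components are matched to clusters by cell-id overlap from sample to
    sample; a component with no active predecessor founds a new cluster
    (onset = current time) unless it revives a cluster at the same place
    that fell silent less than ``t_gap`` ago.
    """
    if not trace.samples:
        raise ValueError("empty trace")
    clusters: List[OrganCluster] = []
    active_prev: Dict[int, Set[int]] = {}  # cluster index -> currently-over cells
    for sample in trace.samples:
        over = _super_threshold(sample, A_threshold)
        comps = _components(over, sample.adjacency)
        nbrs: Dict[int, Set[int]] = {}
        for a, b in sample.adjacency:
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        new_active: Dict[int, Set[int]] = {}
        for comp in comps:
            # the component plus its one-ring, for drift-tolerant matching
            halo = set(comp)
            for c in comp:
                halo |= nbrs.get(c, set())
            hits = [ci for ci, cells in active_prev.items() if cells & comp]
            if not hits:
                dormant = [
                    ci
                    for ci, cl in enumerate(clusters)
                    if ci not in active_prev
                    and cl.member_cells & halo
                    and sample.time - cl.last_active_time <= t_gap
                ]
                if dormant:
                    ci = max(dormant, key=lambda c: clusters[c].last_active_time)
                else:
                    clusters.append(
                        OrganCluster(
                            member_cells=set(),
                            onset_time=sample.time,
                            threshold=A_threshold,
                            founding_cells=set(comp),
                        )
                    )
                    ci = len(clusters) - 1
                clusters[ci].member_cells |= comp
                clusters[ci].last_active_time = sample.time
                new_active.setdefault(ci, set()).update(comp)
                continue
            # the component may span several active clusters (a fusion in
            # progress): each keeps its own continuing cells, so identities
            # survive a transient touch; merge_fused decides permanence
            claimed: Set[int] = set()
            for ci in hits:
                part = comp & (clusters[ci].member_cells | active_prev[ci])
                part -= claimed
                claimed |= part
                clusters[ci].member_cells |= part
                clusters[ci].last_active_time = sample.time
                new_active.setdefault(ci, set()).update(part)
            leftover = comp - claimed
            if leftover:
                ci = max(hits, key=lambda c: len(active_prev[c] & comp))
                clusters[ci].member_cells |= leftover
                new_active[ci].update(leftover)
        active_prev = new_active
    return clusters


def merge_fused(clusters: List[OrganCluster], trace: Trace) -> List[OrganCluster]:
    """Fuse clusters whose maxima become one persistent component.

    Two clusters are one presumed organ if, at every sampled time (from
    the first time they touch onward) at which both have super-threshold
    members, those members lie in a single connected component — and
    they are still together at the last such time.  Transient touches
    followed by re-separation keep the clusters distinct.  Fused clusters
    keep the earlier onset time.
    """
    n = len(clusters)
    if n <= 1:
        return list(clusters)
    thr = clusters[0].threshold
    # per pair: list of together/apart flags over samples where both active
    history: Dict[Tuple[int, int], List[bool]] = {}
    for sample in trace.samples:
        over = _super_threshold(sample, thr)
        comps = _components(over, sample.adjacency)
        label: Dict[int, int] = {}
        for k, comp in enumerate(comps):
            for c in comp:
                label[c] = k
        active_labels: List[Set[int]] = []
        for cl in clusters:
            active_labels.append(
                {label[c] for c in cl.member_cells if c in label}
            )
        for a in range(n):
            if not active_labels[a]:
                continue
            for b in range(a + 1, n):
                if not active_labels[b]:
                    continue
                together = bool(active_labels[a] & active_labels[b])
                history.setdefault((a, b), []).append(together)

    # union-find over pairs that fused persistently
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), flags in history.items():
        if not flags[-1]:
            continue
        first = flags.index(True)
        if all(flags[first:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    merged: Dict[int, OrganCluster] = {}
    for k, cl in enumerate(clusters):
        r = find(k)
        if r not in merged:
            merged[r] = OrganCluster(
                member_cells=set(cl.member_cells),
                onset_time=cl.onset_time,
                threshold=cl.threshold,
                last_active_time=cl.last_active_time,
                founding_cells=set(cl.founding_cells),
            )
        else:
            m = merged[r]
            m.member_cells |= cl.member_cells
            if cl.onset_time < m.onset_time:
                m.founding_cells = set(cl.founding_cells)
            m.onset_time = min(m.onset_time, cl.onset_time)
            m.last_active_time = max(m.last_active_time, cl.last_active_time)
    return sorted(merged.values(), key=lambda c: (c.onset_time, min(c.member_cells)))


def classify_organs(
    clusters: List[OrganCluster],
    tissue_center: Tuple[float, float],
    tissue_radius: float,
    whorl_radius_fraction: float,
    stage2_time: float,
) -> List[OrganCluster]:
    """Assign sepal / petal / reproductive labels by position and onset.

    Clusters outside the projected whorl circle belong to the outer two
    whorls: sepals if they emerged before stage 2, petals otherwise.
    Clusters inside the circle are reproductive organs.
    """
    if not 0 < whorl_radius_fraction < 1:
        raise ValueError("whorl_radius_fraction must lie in (0, 1)")
    for cl in clusters:
        dx = cl.centroid[0] - tissue_center[0]
        dy = cl.centroid[1] - tissue_center[1]
        cl.radial_fraction = min(1.0, math.hypot(dx, dy) / tissue_radius)
        if cl.radial_fraction >= whorl_radius_fraction:
            cl.organ_class = "sepal" if cl.onset_time < stage2_time else "petal"
        else:
            cl.organ_class = "reproductive"
    return clusters


def summarize_batch(reports: Sequence[OrganReport]) -> BatchSummary:
    """Pattern frequencies and per-class mean / sample sd / CV% over runs."""
    if not reports:
        raise ValueError("summarize_batch needs at least one report")
    freq = Counter(r.pattern for r in reports)
    mean: Dict[str, float] = {}
    sd: Dict[str, float] = {}
    cv: Dict[str, float] = {}
    single = len(reports) == 1
    for k, cls in enumerate(ORGAN_CLASSES):
        vals = np.array([r.pattern[k] for r in reports], dtype=float)
        mean[cls] = float(vals.mean())
        sd[cls] = 0.0 if single else float(vals.std(ddof=1))
        cv[cls] = 100.0 * sd[cls] / mean[cls] if mean[cls] > 0 else 0.0
    return BatchSummary(
        pattern_frequency=dict(freq),
        per_class_mean=mean,
        per_class_sd=sd,
        per_class_cv_percent=cv,
        n_runs=len(reports),
        single_run=single,
    )


def analyze_trace(
    trace: Trace,
    A_threshold: float,
    t_gap: float,
    whorl_radius_fraction: float,
    stage2_time: Optional[float],
    seed: Optional[int] = None,
) -> Tuple[List[OrganCluster], OrganReport]:
    """Full pipeline: detect, fuse, locate, classify, count."""
    clusters = detect_clusters(trace, A_threshold, t_gap)
    clusters = merge_fused(clusters, trace)
    final = trace.final
    pos = {int(i): final.centroids[k] for k, i in enumerate(final.ids)}
    for cl in clusters:
        # locate the cluster at its initiation site (founding cells, at
        # end-of-trace geometry); fall back to all members if necessary
        pts = [pos[c] for c in cl.founding_cells if c in pos]
        if not pts:
            pts = [pos[c] for c in cl.member_cells if c in pos]
        if pts:
            arr = np.asarray(pts)
            cl.centroid = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
    center, radius = trace.tissue_center_radius()
    if stage2_time is None:
        stage2_time = math.inf
    classify_organs(clusters, center, radius, whorl_radius_fraction, stage2_time)
    counts = Counter(cl.organ_class for cl in clusters)
    report = OrganReport(
        counts={c: counts.get(c, 0) for c in ORGAN_CLASSES}, run_seed=seed
    )
    return clusters, report
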