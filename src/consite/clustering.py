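"""Incremental energy-threshold clustering of low-energy probes.

Starting from the lowest probe energy, an energy threshold is raised in
0.1 kcal/mol steps; probes whose energy falls below the threshold become
active and join (or found, or merge) clusters with any active probe within
1 A.  Cluster-cluster distance is single linkage: the distance between the
two nearest member probes.  The procedure stops the moment any cluster
holds p_num probes (default 500); all clusters existing at that instant are
returned.  The cluster size cap plays the role that a fixed energy
threshold plays in other energy-based pocket finders: it adapts the final
threshold to each protein.

Because probes activate strictly in (energy, grid index) order, raising the
threshold in fixed steps is observationally identical to inserting probes
one at a time in that order, which is how both implementations below are
written; the optimized one finds linkage neighbors with a KD-tree, the
oracle with a literal O(n^2) scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .energy_grid import Probe


@dataclass
class ClusteringParams:
    p_num: int = 500
    threshold_step: float = 0.1
    linkage_radius: float = 1.0
    require_negative_start: bool = True

    def __post_init__(self) -> None:
        if self.p_num < 1 or self.threshold_step <= 0 or self.linkage_radius <= 0:
            raise ValueError("clustering parameters must be strictly positive")


@dataclass
class Cluster:
    """An ordered set of probes; the unit of prediction."""

    probe_indices: list[int]  # indices into the probe list, insertion order
    total_e_vdw: float
    total_e_weighted: float = 0.0
    min_grid_index: tuple[int, int, int] = (0, 0, 0)

    @property
    def member_count(self) -> int:
        return len(self.probe_indices)


def _insertion_order(probes: list[Probe]) -> list[int]:
    """Activation order: ascending energy, ties by grid index, then input order."""
    return sorted(range(len(probes)),
                  key=lambda i: (probes[i].e_vdw, probes[i].grid_index, i))


def _collect(probes: list[Probe], members_of: dict[int, list[int]]) -> list[Cluster]:
    out = []
    for members in members_of.values():
        tot = float(sum(probes[i].e_vdw for i in members))
        mgi = min(probes[i].grid_index for i in members)
        out.append(Cluster(probe_indices=list(members), total_e_vdw=tot,
                           min_grid_index=mgi))
    out.sort(key=lambda c: (c.total_e_vdw, c.min_grid_index))
    return out


def cluster_probes(probes: list[Probe], params: ClusteringParams | None = None) -> list[Cluster]:
    """Cluster probes by the incremental-threshold procedure (KD-tree linkage)."""
    params = params or ClusteringParams()
    if not probes:
        return []
    order = _insertion_order(probes)
    if params.require_negative_start and probes[order[0]].e_vdw >= 0:
        return []

    pos = np.array([p.position for p in probes])
    tree = cKDTree(pos)
    adj: list[list[int]] = [[] for _ in probes]
    for i, j in tree.query_pairs(params.linkage_radius):
        adj[i].append(j)
        adj[j].append(i)

    parent: dict[int, int] = {}
    members_of: dict[int, list[int]] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in order:
        parent[idx] = idx
        members_of[idx] = [idx]
        for nb in adj[idx]:
            if nb in parent:  # active neighbor
                ra, rb = find(idx), find(nb)
                if ra != rb:
                    if len(members_of[ra]) < len(members_of[rb]):
                        ra, rb = rb, ra
                    parent[rb] = ra
                    members_of[ra].extend(members_of.pop(rb))
        if len(members_of[find(idx)]) >= params.p_num:
            break

    return _collect(probes, members_of)


def brute_force_cluster_oracle(
    probes: list[Probe], params: ClusteringParams | None = None
) -> list[Cluster]:
    """Same contract as :func:`cluster_probes`, as a direct transcription of
    the threshold loop without any spatial index (test oracle, <= 500 probes)."""
    params = params or ClusteringParams()
    if not probes:
        return []
    order = _insertion_order(probes)
    e_min = probes[order[0]].e_vdw
    if params.require_negative_start and e_min >= 0:
        return []

    pos = [np.asarray(p.position, dtype=float) for p in probes]
    clusters: list[list[int]] = []  # each a list of active probe indices
    threshold = e_min
    next_up = 0  # next probe (in order) not yet active
    e_max = max(p.e_vdw for p in probes)
    done = False
    while not done:
        # activate every probe at or below the current threshold, in order
        while next_up < len(order) and probes[order[next_up]].e_vdw <= threshold:
            idx = order[next_up]
            next_up += 1
            touching = []
            for ci, members in enumerate(clusters):
                if any(np.linalg.norm(pos[idx] - pos[m]) <= params.linkage_radius
                       for m in members):
                    touching.append(ci)
            if not touching:
                clusters.append([idx])
                grown = clusters[-1]
            else:
                # join the first touching cluster, then merge the rest into it
                grown = clusters[touching[0]]
                grown.append(idx)
                for ci in reversed(touching[1:]):
                    grown.extend(clusters.pop(ci))
            if len(grown) >= params.p_num:
                done = True
                break
        if next_up >= len(order):
            break  # every probe active and no cluster reached the cap
        if not done and threshold > e_max:
            break
        threshold += params.threshold_step

    members_of = {i: m for i, m in enumerate(clusters)}
    return _collect(probes, members_of)
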