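"""Conservation-weighted probe scoring and cluster ranking.

Each probe i gets the weighted score

    E_i = sum_j ( w1 * E_ij + w2 * C_j + w3 * E_ij * C_j )

where j runs over the protein atoms within the 10 A energy cutoff, E_ij is
the Lennard-Jones pair energy, and C_j is the conservation score of atom
j's residue -- but only if that residue has at least one atom within 6 A of
the probe; more distant residues contribute C_j = 0 on the grounds that
amino acids far from a bound ligand have little influence on binding.  The
C_score of a residue applies to all of its atoms.  Default weights
(w1, w2, w3) = (1, -0.05, 9); with w2 = w3 = 0 the score reduces exactly to
the raw van der Waals energy (energy-only mode).

Clusters are ranked by ascending sum of member probe scores.  For
multimers, symmetric copies of the same site on different chains are near
duplicates; with deduplication on, clusters whose chain-stripped contact
residue sets overlap strongly (Jaccard >= 0.7) and whose totals agree
within 10 % keep only the lowest-scoring copy as representative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .clustering import Cluster
from .conservation import ConservationProfile
from .energy_grid import CARBON_PROBE, Probe
from .structure_io import ProteinStructure


@dataclass
class Weights:
    w1: float = 1.0
    w2: float = -0.05
    w3: float = 9.0

    @property
    def energy_only(self) -> bool:
        return self.w2 == 0.0 and self.w3 == 0.0


@dataclass
class RankedSite:
    rank: int  # 1-based; a suppressed duplicate carries its representative's rank
    cluster: Cluster
    contact_residues: set[tuple[str, int, str]]
    representative: bool = True

    @property
    def total_e_weighted(self) -> float:
        return self.cluster.total_e_weighted


class ProbeScorer:
    """Evaluates the weighted probe score against one structure.

    Parameters
    ----------
    conservation : mapping chain_id -> ConservationProfile, or None
        When None (or a contacting chain is missing), C = 0 is used; with
        ``strict=True`` a missing chain raises instead.
    cross_term_gated : bool
        Whether the w3 cross term uses the same <= 6 A residue gate as the
        w2 term (default) or applies conservation out to the energy cutoff.
    """

    def __init__(
        self,
        structure: ProteinStructure,
        conservation: dict[str, ConservationProfile] | None,
        weights: Weights | None = None,
        energy_cutoff: float = 10.0,
        conservation_cutoff: float = 6.0,
        probe_type: tuple[float, float] = CARBON_PROBE,
        strict: bool = False,
        cross_term_gated: bool = True,
    ) -> None:
        self.structure = structure
        self.weights = weights or Weights()
        self.energy_cutoff = energy_cutoff
        self.conservation_cutoff = conservation_cutoff
        self.probe_type = probe_type
        self.cross_term_gated = cross_term_gated
        self._coords = structure.coords()
        self._tree = cKDTree(self._coords)
        self._R, self._eps = structure.vdw_params()
        self._atom_res = structure.atom_residue_indices()
        # per-residue conservation score (0 where unknown)
        self._res_c = np.zeros(len(structure.residues))
        missing: set[str] = set()
        if conservation is not None:
            for ri, res in enumerate(structure.residues):
                prof = conservation.get(res.chain_id)
                if prof is None:
                    missing.add(res.chain_id)
                    continue
                self._res_c[ri] = prof.c_scores.get(
                    (res.residue_seq, res.icode), 0.0
                )
            if missing:
                msg = f"no conservation profile for chain(s) {sorted(missing)}; using C=0"
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)

    def score_components(self, position: np.ndarray) -> tuple[float, float, float]:
        """Per-probe sums (sum_E, sum_C, sum_EC) over atoms in the energy
        cutoff; the weighted score is their dot product with (w1, w2, w3)."""
        pos = np.asarray(position, dtype=float)
        idx = np.asarray(self._tree.query_ball_point(pos, self.energy_cutoff), dtype=int)
        if idx.size == 0:
            return 0.0, 0.0, 0.0
        d = np.linalg.norm(self._coords[idx] - pos, axis=1)
        R_p, eps_p = self.probe_type
        s6 = ((R_p + self._R[idx]) / d) ** 6
        e_pair = np.sqrt(eps_p * self._eps[idx]) * (s6 * s6 - 2.0 * s6)
        c = self._res_c[self._atom_res[idx]].copy()
        # residues with no atom within the conservation cutoff contribute C=0
        near = np.asarray(
            self._tree.query_ball_point(pos, self.conservation_cutoff), dtype=int
        )
        near_res = set(self._atom_res[near].tolist()) if near.size else set()
        gate = np.array([r in near_res for r in self._atom_res[idx]])
        c_gated = np.where(gate, c, 0.0)
        c_cross = c_gated if self.cross_term_gated else c
        return (float(np.sum(e_pair)), float(np.sum(c_gated)),
                float(np.sum(e_pair * c_cross)))

    def score_position(self, position: np.ndarray) -> float:
        """Weighted score E_i of a probe at ``position``."""
        s_e, s_c, s_ec = self.score_components(position)
        w = self.weights
        return w.w1 * s_e + w.w2 * s_c + w.w3 * s_ec

    def score_probes(self, probes: list[Probe]) -> None:
        """Fill ``e_weighted`` on every probe, in place."""
        for p in probes:
            p.e_weighted = self.score_position(p.position)


def weighted_probe_score(
    probe: Probe,
    structure: ProteinStructure,
    conservation: dict[str, ConservationProfile] | None,
    weights: Weights | None = None,
    energy_cutoff: float = 10.0,
    conservation_cutoff: float = 6.0,
    probe_type: tuple[float, float] = CARBON_PROBE,
    **kwargs,
) -> float:
    """One-shot form of :meth:`ProbeScorer.score_position`."""
    scorer = ProbeScorer(
        structure, conservation, weights, energy_cutoff,
        conservation_cutoff, probe_type, **kwargs,
    )
    return scorer.score_position(probe.position)


def contact_residues(
    cluster: Cluster,
    probes: list[Probe],
    structure: ProteinStructure,
    radius: float = 5.0,
    heavy_only: bool = False,
) -> set[tuple[str, int, str]]:
    """Residues with any atom within ``radius`` of any member probe."""
    atoms = structure.atoms
    coords = structure.coords()
    keep = np.ones(len(atoms), dtype=bool)
    if heavy_only:
        keep = np.array([not a.is_hydrogen for a in atoms])
    tree = cKDTree(coords[keep])
    kept_idx = np.flatnonzero(keep)
    atom_res = structure.atom_residue_indices()
    hit: set[int] = set()
    for pi in cluster.probe_indices:
        for local in tree.query_ball_point(probes[pi].position, radius):
            hit.add(int(atom_res[kept_idx[local]]))
    return {structure.residues[ri].key for ri in hit}


def _stripped(
    residue_keys: set[tuple[str, int, str]], structure: ProteinStructure
) -> frozenset[tuple[int, str, str]]:
    """Chain-independent residue identity: (residue_seq, icode, residue_name)."""
    rmap = {r.key: r for r in structure.residues}
    return frozenset(
        (k[1], k[2], rmap[k].residue_name) for k in residue_keys if k in rmap
    )


def rank_clusters(
    clusters: list[Cluster],
    probes: list[Probe],
    structure: ProteinStructure,
    dedup: bool = True,
    jaccard_threshold: float = 0.7,
    score_tolerance: float = 0.10,
    contact_radius: float = 5.0,
) -> list[RankedSite]:
    """Rank clusters ascending by total weighted score; optionally merge
    symmetric multimer duplicates down to one representative.

    Every cluster's ``total_e_weighted`` must already be the sum of its
    member probes' weighted scores (see :meth:`ProbeScorer.score_probes`).
    The returned list has representatives first, ranks consecutive from 1;
    suppressed duplicates follow, each carrying its representative's rank.
    """
    for c in clusters:
        c.total_e_weighted = float(
            sum(probes[i].e_weighted for i in c.probe_indices)
        )
    order = sorted(
        range(len(clusters)),
        key=lambda i: (
            clusters[i].total_e_weighted,
            clusters[i].total_e_vdw,
            clusters[i].min_grid_index,
        ),
    )
    contacts = {
        i: contact_residues(clusters[i], probes, structure, radius=contact_radius)
        for i in order
    }
    suppressed_by: dict[int, int] = {}  # cluster -> representative cluster
    if dedup:
        stripped = {i: _stripped(contacts[i], structure) for i in order}
        chains_of = {
            i: frozenset(k[0] for k in contacts[i]) for i in order
        }
        for a_pos, i in enumerate(order):
            if i in suppressed_by:
                continue
            for j in order[a_pos + 1:]:
                if j in suppressed_by:
                    continue
                if chains_of[i] and chains_of[i] == chains_of[j]:
                    continue  # same chain(s): genuinely distinct sites
                sa, sb = stripped[i], stripped[j]
                if not sa or not sb:
                    continue
                jac = len(sa & sb) / len(sa | sb)
                ta, tb = clusters[i].total_e_weighted, clusters[j].total_e_weighted
                denom = max(abs(ta), abs(tb))
                close = denom == 0 or abs(ta - tb) <= score_tolerance * denom
                if jac >= jaccard_threshold and close:
                    suppressed_by[j] = i  # i ranks lower (earlier in order)

    sites: list[RankedSite] = []
    rank_of: dict[int, int] = {}
    rank = 0
    for i in order:
        if i in suppressed_by:
            continue
        rank += 1
        rank_of[i] = rank
        sites.append(RankedSite(rank=rank, cluster=clusters[i],
                                contact_residues=contacts[i]))
    for i in order:
        if i in suppressed_by:
            sites.append(RankedSite(
                rank=rank_of[suppressed_by[i]], cluster=clusters[i],
                contact_residues=contacts[i], representative=False,
            ))
    return sites
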