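"""Evaluation of predicted sites against known ligands.

Two protocols:

* binding-space precision -- the percentage of a cluster's probes lying
  within 1.6 A of any ligand heavy atom; a cluster with precision >= 25 %
  counts as a correct prediction of the binding space;
* binding-residue agreement -- residues within 5 A of any cluster probe are
  the predicted binding residues, residues within 4 A of any ligand heavy
  atom are the true ones, and the confusion table over all residues yields
  S_residue (residue-level precision, %) and the Matthews correlation
  coefficient.

Top-k success asks whether any of the k best-ranked sites meets the chosen
criterion; ratios over a set of structures are the headline success rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .clustering import Cluster
from .energy_grid import Probe
from .structure_io import LigandGroup, ProteinStructure


@dataclass
class SpaceEvaluation:
    precision: float  # percent of member probes overlapping the ligand
    success: bool
    n_overlap: int
    member_count: int


@dataclass
class ResidueEvaluation:
    tp: int
    fp: int
    fn: int
    tn: int
    s_residue: float  # percent
    mcc: float


def space_precision(
    cluster: Cluster,
    probes: list[Probe],
    ligand: LigandGroup,
    overlap_radius: float = 1.6,
    success_threshold: float = 25.0,
) -> SpaceEvaluation:
    """Fraction of cluster probes within ``overlap_radius`` of the ligand."""
    if cluster.member_count == 0:
        raise ValueError("empty cluster")
    lig = ligand.heavy_coords()
    if len(lig) == 0:
        raise ValueError("ligand has no heavy atoms")
    tree = cKDTree(lig)
    pos = np.array([probes[i].position for i in cluster.probe_indices])
    d, _ = tree.query(pos, k=1)
    n_overlap = int(np.sum(d <= overlap_radius))
    precision = 100.0 * n_overlap / cluster.member_count
    return SpaceEvaluation(
        precision=precision,
        success=precision >= success_threshold,
        n_overlap=n_overlap,
        member_count=cluster.member_count,
    )


def true_binding_residues(
    structure: ProteinStructure,
    ligands: list[LigandGroup],
    radius: float = 4.0,
) -> set[tuple[str, int, str]]:
    """Residues with any atom within ``radius`` of any ligand heavy atom,
    unioned over all ligands."""
    if not ligands:
        raise ValueError("no ligands: ground truth undefined")
    tree = cKDTree(structure.coords())
    atom_res = structure.atom_residue_indices()
    hit: set[int] = set()
    for lig in ligands:
        for pos in lig.heavy_coords():
            for ai in tree.query_ball_point(pos, radius):
                hit.add(int(atom_res[ai]))
    return {structure.residues[ri].key for ri in hit}


def residue_metrics(
    predicted: set,
    truth: set,
    universe: set,
) -> ResidueEvaluation:
    """Confusion counts, S_residue and MCC over the residue universe.

    S_residue = 100 * TP / (TP + FP), 0 when nothing is predicted.
    MCC uses the convention 0 when any marginal of the table is zero.
    """
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth must be subsets of the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    s_residue = 100.0 * tp / (tp + fp) if tp + fp > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return ResidueEvaluation(tp=tp, fp=fp, fn=fn, tn=tn,
                             s_residue=s_residue, mcc=float(mcc))


def topk_success(
    metric_by_rank: list[float], k: int, threshold: float = 25.0
) -> bool:
    """True iff any of the k best-ranked values meets the threshold."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return any(v >= threshold for v in metric_by_rank[:k])


def success_ratio(flags: list[bool]) -> float:
    """Percent of structures with a successful prediction."""
    if not flags:
        return 0.0
    return 100.0 * sum(flags) / len(flags)


def average_over_successes(values: list[float], flags: list[bool]) -> float:
    """Mean metric over the structures flagged as successes (0 if none)."""
    chosen = [v for v, f in zip(values, flags) if f]
    return float(np.mean(chosen)) if chosen else 0.0
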