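"""End-to-end prediction and evaluation over one structure.

``predict`` wires the stages together: parse -> assign parm94 parameters ->
probe grid -> Lennard-Jones energies -> prune -> incremental-threshold
clustering -> conservation -> weighted scoring -> ranking/deduplication.
``evaluate`` scores a prediction against the ligands found in the same (or
a reference) PDB file, or against a residue-truth table for unbound
structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, energy_grid, evaluation, scoring, structure_io
from .config import RunConfig
from .conservation import (
    ConservationProfile, load_background, parse_pssm, profile_from_msa,
    conservation_for_chain,
)

logger = logging.getLogger("consite")


@dataclass
class PredictionResult:
    structure: structure_io.ProteinStructure
    het_records: list[structure_io.HetAtom]
    grid: energy_grid.GridSpec
    probes: list[energy_grid.Probe]        # pruned probes, cluster indices refer here
    clusters: list[clustering.Cluster]
    sites: list[scoring.RankedSite]
    config: RunConfig
    energy_only: bool

    @property
    def representative_sites(self) -> list[scoring.RankedSite]:
        return [s for s in self.sites if s.representative]


@dataclass
class StructureReport:
    """Both evaluation protocols for one structure."""

    precisions: list[float] = field(default_factory=list)   # by rank
    s_residues: list[float] = field(default_factory=list)   # by rank
    mccs: list[float] = field(default_factory=list)         # by rank
    top1_space_success: bool = False
    topk_space_success: bool = False
    top1_residue_success: bool = False
    topk_residue_success: bool = False
    top1_mcc: float = 0.0
    n_ligands: int = 0


def load_conservation(
    structure: structure_io.ProteinStructure,
    inputs: dict[str, str | Path],
    background_name: str = "blosum62",
) -> dict[str, ConservationProfile]:
    """Map chain id -> conservation profile from PSSM or aligned-FASTA files.

    A chain id of '*' applies one file to every chain (homomultimers).
    File kind is sniffed: FASTA if the first non-blank character is '>'.
    """
    background = load_background(background_name)
    expanded: dict[str, Path] = {}
    for chain, path in inputs.items():
        if chain == "*":
            for ch in structure.chains:
                expanded.setdefault(ch, Path(path))
        else:
            expanded[chain] = Path(path)
    out: dict[str, ConservationProfile] = {}
    for chain, path in expanded.items():
        text = path.read_text()
        first = next((c for c in text if not c.isspace()), "")
        if first == ">":
            profile = profile_from_msa(path)
        else:
            profile = parse_pssm(path, background)
        out[chain] = conservation_for_chain(profile, background, structure, chain)
    return out


def predict(
    pdb_path: str | Path,
    conservation_inputs: dict[str, str | Path] | None = None,
    config: RunConfig | None = None,
) -> PredictionResult:
    """Run the full prediction pipeline on one PDB file.

    Without conservation input the run is energy-only: w2 and w3 are forced
    to zero and ranking reduces to raw van der Waals totals.
    """
    config = config or RunConfig()
    structure, het = structure_io.parse_structure(pdb_path)
    if config.ignore_hydrogens:
        structure = structure.drop_hydrogens()
    structure_io.assign_parameters(structure)

    grid = energy_grid.build_grid(structure, spacing=config.spacing,
                                  margin=config.margin)
    logger.info("grid %s = %d probes", grid.shape, grid.n_probes)
    probes = energy_grid.compute_probe_energies(
        grid.positions(), structure, cutoff=config.cutoff,
        grid_indices=grid.indices(),
    )
    probes = energy_grid.prune_probes(probes, e_max=config.prune_e_max)
    logger.info("%d probes kept after pruning", len(probes))

    params = clustering.ClusteringParams(
        p_num=config.p_num, threshold_step=config.threshold_step,
        linkage_radius=config.linkage_radius,
    )
    clusters = clustering.cluster_probes(probes, params)
    logger.info("%d clusters at termination", len(clusters))

    weights = config.weights
    energy_only = conservation_inputs is None
    conservation = None
    if energy_only:
        if not weights.energy_only:
            logger.info("no conservation input: forcing (w2, w3) = (0, 0)")
            weights = scoring.Weights(w1=weights.w1, w2=0.0, w3=0.0)
    else:
        conservation = load_conservation(structure, conservation_inputs,
                                         config.background)

    scorer = scoring.ProbeScorer(
        structure, conservation, weights,
        energy_cutoff=config.cutoff,
        conservation_cutoff=config.conservation_cutoff,
        strict=config.strict_conservation,
        cross_term_gated=config.cross_term_gated,
    )
    member = sorted({i for c in clusters for i in c.probe_indices})
    scorer.score_probes([probes[i] for i in member])

    sites = scoring.rank_clusters(
        clusters, probes, structure,
        dedup=config.dedup, contact_radius=config.contact_radius,
    )
    return PredictionResult(structure, het, grid, probes, clusters, sites,
                            config, energy_only)


def evaluate(
    result: PredictionResult,
    ligand_source: str | Path | None = None,
    truth_residues: set[tuple[str, int, str]] | None = None,
) -> StructureReport:
    """Evaluate a prediction with both protocols.

    Ligands come from the prediction's own HETATM records, or from
    ``ligand_source`` (a reference complex PDB).  For unbound structures a
    ``truth_residues`` set (chain, residue_seq, icode) enables the residue
    protocol alone.
    """
    config = result.config
    structure = result.structure
    report = StructureReport()

    ligands: list[structure_io.LigandGroup] = []
    if truth_residues is None:
        het = result.het_records
        if ligand_source is not None:
            ref_structure, het = structure_io.parse_structure(ligand_source)
        else:
            ref_structure = structure
        ligands = structure_io.select_ligands(het, ref_structure)
        if not ligands:
            raise ValueError("no ligand passed the biological filter; "
                             "provide truth_residues for unbound structures")
        truth = evaluation.true_binding_residues(
            structure, ligands, radius=config.truth_radius
        )
    else:
        truth = {k for k in truth_residues}
    report.n_ligands = len(ligands)

    union = None
    if ligands:
        union = structure_io.LigandGroup(
            heavy_atoms=[a for g in ligands for a in g.heavy_atoms],
            component_names=[n for g in ligands for n in g.component_names],
            n_contacts=sum(g.n_contacts for g in ligands),
        )

    universe = {r.key for r in structure.residues}
    truth &= universe
    for site in result.representative_sites:
        if union is not None:
            sp = evaluation.space_precision(
                site.cluster, result.probes, union,
                overlap_radius=config.overlap_radius,
                success_threshold=config.precision_threshold,
            )
            report.precisions.append(sp.precision)
        rm = evaluation.residue_metrics(site.contact_residues & universe,
                                        truth, universe)
        report.s_residues.append(rm.s_residue)
        report.mccs.append(rm.mcc)

    k = config.top_k
    if report.precisions:
        report.top1_space_success = evaluation.topk_success(
            report.precisions, 1, config.precision_threshold)
        report.topk_space_success = evaluation.topk_success(
            report.precisions, k, config.precision_threshold)
    if report.s_residues:
        report.top1_residue_success = evaluation.topk_success(
            report.s_residues, 1, config.s_residue_threshold)
        report.topk_residue_success = evaluation.topk_success(
            report.s_residues, k, config.s_residue_threshold)
        report.top1_mcc = report.mccs[0]
    return report


def rerank(
    result: PredictionResult,
    weights: scoring.Weights,
    conservation_inputs: dict[str, str | Path] | None = None,
) -> PredictionResult:
    """Re-score and re-rank an existing prediction under different weights.

    Clustering uses raw energies only, so the probe grid, energies and
    clusters are reused; only the weighted scores and ranking change.  The
    input result is left untouched (probes and clusters are copied).
    """
    config = result.config
    conservation = None
    if conservation_inputs is not None:
        conservation = load_conservation(result.structure, conservation_inputs,
                                         config.background)
    elif not weights.energy_only:
        raise ValueError("non-zero w2/w3 need conservation input")
    scorer = scoring.ProbeScorer(
        result.structure, conservation, weights,
        energy_cutoff=config.cutoff,
        conservation_cutoff=config.conservation_cutoff,
        strict=config.strict_conservation,
        cross_term_gated=config.cross_term_gated,
    )
    probes = [energy_grid.Probe(p.position, p.e_vdw, p.grid_index, p.e_weighted)
              for p in result.probes]
    clusters = [clustering.Cluster(list(c.probe_indices), c.total_e_vdw,
                                   min_grid_index=c.min_grid_index)
                for c in result.clusters]
    member = sorted({i for c in clusters for i in c.probe_indices})
    scorer.score_probes([probes[i] for i in member])
    sites = scoring.rank_clusters(
        clusters, probes, result.structure,
        dedup=config.dedup, contact_radius=config.contact_radius,
    )
    return PredictionResult(result.structure, result.het_records, result.grid,
                            probes, clusters, sites, config,
                            conservation is None)


def weight_grid(
    pdb_path: str | Path,
    conservation_inputs: dict[str, str | Path],
    w2_values: list[float],
    w3_values: list[float],
    config: RunConfig | None = None,
    w1: float = 1.0,
) -> list[dict]:
    """Exhaustive (w2, w3) grid evaluation on one structure.

    The expensive stages (grid, energies, clustering, per-probe score
    components) run once; every cell is a linear re-weighting.  Returns one
    row per cell with the evaluation of both protocols.
    """
    config = config or RunConfig()
    if not w2_values or not w3_values:
        raise ValueError("empty weight ranges")
    result = predict(pdb_path, conservation_inputs, config)
    conservation = load_conservation(result.structure, conservation_inputs,
                                     config.background)
    scorer = scoring.ProbeScorer(
        result.structure, conservation, scoring.Weights(w1, 0, 0),
        energy_cutoff=config.cutoff,
        conservation_cutoff=config.conservation_cutoff,
        cross_term_gated=config.cross_term_gated,
    )
    member = sorted({i for c in result.clusters for i in c.probe_indices})
    comps = {i: scorer.score_components(result.probes[i].position) for i in member}
    rows = []
    for w2 in w2_values:
        for w3 in w3_values:
            for i in member:
                s_e, s_c, s_ec = comps[i]
                result.probes[i].e_weighted = w1 * s_e + w2 * s_c + w3 * s_ec
            sites = scoring.rank_clusters(
                result.clusters, result.probes, result.structure,
                dedup=config.dedup, contact_radius=config.contact_radius,
            )
            trial = PredictionResult(result.structure, result.het_records,
                                     result.grid, result.probes,
                                     result.clusters, sites, config, False)
            report = evaluate(trial)
            rows.append({
                "w1": w1, "w2": w2, "w3": w3,
                "top1_space_success": report.top1_space_success,
                "topk_space_success": report.topk_space_success,
                "top1_precision": report.precisions[0] if report.precisions else 0.0,
                "top1_s_residue": report.s_residues[0] if report.s_residues else 0.0,
                "top1_mcc": report.top1_mcc,
            })
    return rows


# ---------------------------------------------------------------------------
# report output


def sites_to_tsv(result: PredictionResult) -> str:
    """Ranked-site table: rank, size, totals, centroid, contact residues."""
    rows = ["rank\trepresentative\tsize\ttotal_e_vdw\ttotal_e_weighted"
            "\tcentroid_x\tcentroid_y\tcentroid_z\tcontact_residues"]
    for s in result.sites:
        pos = np.array([result.probes[i].position for i in s.cluster.probe_indices])
        cx, cy, cz = pos.mean(axis=0)
        contacts = ",".join(
            f"{ch}:{seq}{ic}" for ch, seq, ic in sorted(s.contact_residues)
        )
        rows.append(
            f"{s.rank}\t{int(s.representative)}\t{s.cluster.member_count}"
            f"\t{s.cluster.total_e_vdw:.4f}\t{s.cluster.total_e_weighted:.4f}"
            f"\t{cx:.2f}\t{cy:.2f}\t{cz:.2f}\t{contacts}"
        )
    return "\n".join(rows) + "\n"


def clusters_to_pdb(result: PredictionResult, max_sites: int = 10) -> str:
    """Probe clusters as a multi-model PDB of pseudo-atoms (for viewers);
    the weighted probe score is written in the B-factor column."""
    lines = []
    for s in result.representative_sites[:max_sites]:
        lines.append(f"MODEL     {s.rank:>4d}")
        for n, i in enumerate(s.cluster.probe_indices, start=1):
            p = result.probes[i]
            x, y, z = p.position
            lines.append(
                f"HETATM{n:>5d}  C   PRB P{s.rank:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{p.e_weighted:6.2f}"
                f"           C"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
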