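"""Synthetic, download-free test structures with a geometric pocket.

The generator builds a "cup" protein: two concentric spherical shells of
small pseudo-residues (ALA/GLY, standard atom names so parm94 typing needs
no fallback) with a circular opening, so the inside of the inner shell is a
concave cavity.  A pseudo-ligand of carbon atoms (HETATM, residue LIG) is
planted in the cavity with enough heavy atoms and protein contacts to pass
the biological-ligand filter (>= 10 heavy atoms, >= 70 contacts at 4 A).
Variants: an exact translated copy of the chain (homodimer, two symmetric
pockets on chains A and B) and a two-pocket monomer whose second pocket is
an exact 180-degree rotation of the first (identical geometry, one chain),
used to test whether conservation alone can pick a pocket.

Matching conservation input is emitted as a sampled FASTA alignment plus a
PSI-BLAST-style ASCII PSSM computed from that alignment's column
frequencies, with pocket-lining positions drawn nearly single-letter
(highly conserved) and all other positions drawn from the background.

Everything is deterministic in the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .conservation import AA_ORDER, AA_INDEX, load_background
from .evaluation import true_binding_residues
from .structure_io import (
    HetAtom, ProteinStructure, Residue, TypedAtom, parse_structure,
    select_ligands,
)

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class FixtureError(ValueError):
    """Raised when the requested geometry cannot satisfy the ligand filter."""


@dataclass
class PocketFixtureSpec:
    """Parameters of the synthetic pocket; deterministic in ``seed``."""

    pocket_radius: float = 7.0   # radius of the inner wall shell (A)
    pocket_depth: float = 10.0   # cavity depth from rim to bottom (A)
    wall_site_count: int = 220   # residue sites on the inner shell
    shell_gap: float = 2.8       # inner-to-outer shell separation (A)
    ligand_size: int = 12        # pseudo-ligand heavy atoms
    conserved_pocket: bool = True
    dimer: bool = False
    two_pocket: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pocket_radius, self.pocket_depth, self.shell_gap) <= 0:
            raise FixtureError("geometric parameters must be positive")
        if self.wall_site_count < 10 or self.ligand_size < 1:
            raise FixtureError("too few wall sites or ligand atoms")
        if self.dimer and self.two_pocket:
            raise FixtureError("dimer and two_pocket are mutually exclusive")


@dataclass
class PocketFixture:
    pdb_text: str
    ligand_coords: np.ndarray            # (n, 3) planted ligand heavy atoms
    truth_residues: set[tuple[str, int, str]]
    pocket_positions: set[int]           # 1-based sequence positions lining the pocket
    sequence: str                        # chain A sequence (chains are copies)


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(normal, helper)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(normal, t1)


def _pocket_atoms(spec: PocketFixtureSpec, rng: np.random.Generator):
    """One pocket centred at the origin, opening along +z.

    Returns (residue list, ligand coords); each residue is
    (residue_name, [(atom_name, element, position), ...]).
    """
    cap_z = spec.pocket_depth - spec.pocket_radius  # wall exists for z <= cap_z
    cap_z = min(cap_z, 0.85 * spec.pocket_radius)
    dirs = _fibonacci_directions(spec.wall_site_count)
    dirs = dirs[dirs[:, 2] * spec.pocket_radius <= cap_z]
    if len(dirs) < 10:
        raise FixtureError("pocket opening leaves too little wall; increase depth")

    residues = []
    for shell_r in (spec.pocket_radius, spec.pocket_radius + spec.shell_gap):
        for d in dirs:
            site = d * shell_r + rng.uniform(-0.05, 0.05, size=3)
            out = site / np.linalg.norm(site)
            t1, t2 = _frame(out)
            name = "ALA" if rng.random() < 0.6 else "GLY"
            atoms = [
                ("N", "N", site + 1.46 * t1),
                ("CA", "C", site),
                ("C", "C", site - 1.46 * t1 + 0.3 * t2),
                ("O", "O", site - 1.46 * t1 + 0.3 * t2 + 1.23 * out),
            ]
            if name == "ALA":
                atoms.append(("CB", "C", site + 1.53 * out))
            residues.append((name, atoms))

    # pseudo-ligand: carbons on a small sphere facing the closed wall
    lig_r = spec.pocket_radius - 3.4
    lig_dirs = _fibonacci_directions(4 * spec.ligand_size)
    lig_dirs = lig_dirs[lig_dirs[:, 2] < 0.35][: spec.ligand_size]
    if len(lig_dirs) < spec.ligand_size:
        raise FixtureError("cannot place the requested number of ligand atoms")
    ligand = lig_dirs * lig_r
    return residues, ligand


def _transform(atoms_residues, ligand, R=None, t=None):
    R = np.eye(3) if R is None else R
    t = np.zeros(3) if t is None else t
    out = [
        (name, [(an, el, R @ p + t) for an, el, p in atoms])
        for name, atoms in atoms_residues
    ]
    return out, ligand @ R.T + t


def make_pocket_structure(spec: PocketFixtureSpec) -> PocketFixture:
    """Emit the fixture as PDB text plus planted ligand and truth residues.

    The emitted file round-trips through :func:`parse_structure`; the planted
    ligand is checked to pass :func:`select_ligands` with default filters
    (>= 10 heavy atoms, >= 70 contacts at 4 A), otherwise a
    :class:`FixtureError` explains which requirement failed.
    """
    rng = np.random.default_rng(spec.seed)
    base_res, base_lig = _pocket_atoms(spec, rng)

    chains: list[tuple[str, list, np.ndarray]] = []
    if spec.two_pocket:
        # two pockets on ONE chain: second is an exact 180-deg rotation about z
        # of the first, displaced so both cavities are well separated.
        Rz = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]])
        offset = 2.0 * (spec.pocket_radius + spec.shell_gap) + 9.0
        offset = np.round(offset * 2) / 2  # keep the grid commensurate
        r1, l1 = _transform(base_res, base_lig, t=np.array([-offset / 2, 0, 0]))
        r2, l2 = _transform(base_res, base_lig, R=Rz, t=np.array([offset / 2, 0, 0]))
        chains.append(("A", r1 + r2, np.vstack([l1, l2])))
    else:
        chains.append(("A", base_res, base_lig))
        if spec.dimer:
            shift = 2.0 * (spec.pocket_radius + spec.shell_gap) + 9.0
            shift = np.round(shift * 2) / 2
            r2, l2 = _transform(base_res, base_lig, t=np.array([shift, 0.0, 0.0]))
            chains.append(("B", r2, l2))

    lines: list[str] = []
    serial = 0
    sequence_a = ""
    ligand_all: list[np.ndarray] = []
    for chain_id, residues, ligand in chains:
        for seq, (resname, atoms) in enumerate(residues, start=1):
            if chain_id == "A":
                sequence_a += {"ALA": "A", "GLY": "G"}[resname]
            for atom_name, element, pos in atoms:
                serial += 1
                lines.append(_format_record("ATOM", serial, atom_name, element,
                                            resname, chain_id, seq, pos))
        lines.append("TER")
        ligand_all.append(ligand)
    for chain_id, _, ligand in chains:
        for k, pos in enumerate(ligand, start=1):
            serial += 1
            lines.append(_format_record("HETATM", serial, f"C{k}", "C", "LIG",
                                        chain_id.lower(), 900, pos))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    ligand_coords = np.vstack(ligand_all)

    # self-check: the planted ligand must pass the default biological filter
    import io, tempfile, os
    with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
        fh.write(pdb_text)
        tmp = fh.name
    try:
        structure, het = parse_structure(tmp)
    finally:
        os.unlink(tmp)
    groups = select_ligands(het, structure)
    expected = len(chains) if not spec.two_pocket else 2
    if spec.two_pocket:
        # the two planted ligands are far apart, hence two groups
        expected = 2
    if len(groups) != expected:
        detail = [(g.n_heavy, g.n_contacts) for g in groups]
        raise FixtureError(
            f"planted ligand(s) fail the biological filter "
            f"(got {len(groups)} group(s), sizes/contacts {detail}); "
            "increase wall_site_count or ligand_size"
        )
    truth = true_binding_residues(structure, groups)
    pocket_positions = {
        seq for (ch, seq, ic) in truth if ch == "A"
    }
    return PocketFixture(
        pdb_text=pdb_text,
        ligand_coords=ligand_coords,
        truth_residues=truth,
        pocket_positions=pocket_positions,
        sequence=sequence_a,
    )


def _format_record(record, serial, name, element, resname, chain, seq, pos):
    n = name if len(name) >= 4 or len(element) >= 2 else " " + name
    return (
        f"{record:<6s}{serial:>5d} {n:<4s}{'':1s}{resname:>3s} "
        f"{chain:1s}{seq:>4d}{'':1s}   "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


# ---------------------------------------------------------------------------
# conservation input


def make_conservation_files(
    spec: PocketFixtureSpec,
    fixture: PocketFixture | None = None,
    high: float = 0.95,
    low: float | None = None,
    n_sequences: int = 60,
    conserved_positions: set[int] | None = None,
) -> tuple[str, str]:
    """Emit a matched (PSSM text, MSA text) pair for chain A.

    Pocket-lining positions (or ``conserved_positions``, 1-based) receive a
    near-single-letter profile with weight ``high`` on the query letter when
    ``spec.conserved_pocket`` is true; every other position uses the
    background distribution (or query weight ``low`` if given).  An alignment
    of ``n_sequences`` sequences is sampled from those profiles, and the PSSM
    percentages are the alignment's column frequencies, so both inputs are
    mutually consistent up to percentage rounding.
    """
    if fixture is None:
        fixture = make_pocket_structure(spec)
    if not 0.0 < high <= 1.0:
        raise ValueError("high must be in (0, 1]")
    rng = np.random.default_rng(spec.seed + 104729)
    background = load_background().frequencies
    if conserved_positions is None:
        conserved_positions = fixture.pocket_positions if spec.conserved_pocket else set()

    seq = fixture.sequence
    profiles = np.empty((len(seq), 20))
    for pos0, letter in enumerate(seq):
        qi = AA_INDEX[letter]
        if (pos0 + 1) in conserved_positions:
            p = (1.0 - high) * background.copy()
            p[qi] += high
        elif low is not None:
            p = (1.0 - low) * background.copy()
            p[qi] += low
        else:
            p = background.copy()
        profiles[pos0] = p / p.sum()

    # sample the alignment (first sequence = query, ungapped)
    letters = np.array(list(AA_ORDER))
    msa_rows = [seq]
    for _ in range(n_sequences - 1):
        row = "".join(
            letters[rng.choice(20, p=profiles[pos0])] for pos0 in range(len(seq))
        )
        msa_rows.append(row)
    msa_text = "".join(
        f">seq{k}\n{row}\n" for k, row in enumerate(msa_rows)
    )

    # PSSM percentages = column frequencies of the sampled alignment
    counts = np.zeros((len(seq), 20))
    for row in msa_rows:
        for pos0, letter in enumerate(row):
            counts[pos0, AA_INDEX[letter]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pssm_text = pssm_text_from_frequencies(seq, freqs, background)
    return pssm_text, msa_text


def pssm_text_from_frequencies(
    query: str, freqs: np.ndarray, background: np.ndarray
) -> str:
    """Render per-position frequencies in the PSI-BLAST ASCII PSSM layout."""
    head = "  ".join(AA_ORDER)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + head + "   " + head,
    ]
    for pos0, letter in enumerate(query):
        with np.errstate(divide="ignore"):
            odds = np.where(
                freqs[pos0] > 0,
                np.round(2.0 * np.log2(np.maximum(freqs[pos0], 1e-9) / background)),
                -4.0,
            )
        odds = np.clip(odds, -9, 13).astype(int)
        pct = np.round(freqs[pos0] * 100).astype(int)
        lines.append(
            f"{pos0 + 1:>5d} {letter} "
            + " ".join(f"{v:>3d}" for v in odds)
            + "  "
            + " ".join(f"{v:>3d}" for v in pct)
            + "  0.50 1.00"
        )
    lines.append("")
    return "\n".join(lines) + "\n"


def write_fixture(
    spec: PocketFixtureSpec, out_dir: str | Path, high: float = 0.95
) -> dict[str, Path]:
    """Write pocket.pdb, chain PSSM/MSA and truth.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixture = make_pocket_structure(spec)
    pssm, msa = make_conservation_files(spec, fixture, high=high)
    paths = {
        "pdb": out / "pocket.pdb",
        "pssm": out / "chainA.pssm",
        "msa": out / "chainA.fasta",
        "truth": out / "truth.tsv",
    }
    paths["pdb"].write_text(fixture.pdb_text)
    paths["pssm"].write_text(pssm)
    paths["msa"].write_text(msa)
    truth_lines = ["chain\tresidue_seq\ticode"]
    for ch, seq, ic in sorted(fixture.truth_residues):
        truth_lines.append(f"{ch}\t{seq}\t{ic}")
    paths["truth"].write_text("\n".join(truth_lines) + "\n")
    return paths
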