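"""Read PDB structures into a typed atom model and select relevant ligands.

The atom model carries, per atom, the parm94 van der Waals parameters
(R*, the van der Waals radius in Angstrom, and epsilon, the well depth in
kcal/mol) needed by the Lennard-Jones 6-12 probe energy.  Parameter
assignment is a deterministic lookup: PDB atom name -> parm94 atom type ->
(R*, epsilon), driven by two editable plain-text tables shipped with the
package.

Ligand selection reproduces the biologically-relevant-ligand filter used to
build apo/holo binding-site benchmarks: non-water HETATM molecules are merged
into connected groups by single linkage at 4 A, and a group counts as a
ligand only if it has at least 10 heavy atoms and makes at least 70
interatomic contacts with protein atoms within 4 A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: element-generic parm94 types used when an atom name has no mapping
ELEMENT_FALLBACK = {
    "C": "CT",
    "N": "N",
    "O": "O",
    "S": "S",
    "SE": "S",
    "P": "P",
    "H": "HC",
    "D": "HC",
}


class StructureError(ValueError):
    """Raised for unreadable or empty structure input."""


class TypingError(ValueError):
    """Raised when atoms cannot be assigned van der Waals parameters."""


@dataclass
class TypedAtom:
    """One protein atom with coordinates and parm94 vdW parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str
    position: np.ndarray  # (3,) float, Angstrom
    vdw_radius_R: float = 0.0
    vdw_depth_eps: float = 0.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.icode)


@dataclass
class Residue:
    chain_id: str
    residue_seq: int
    icode: str
    residue_name: str
    atom_indices: list[int] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.icode)


@dataclass
class HetAtom:
    """A raw HETATM record kept aside for ligand selection."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str
    position: np.ndarray


@dataclass
class ProteinStructure:
    """Atoms grouped into residues and chains, plus cached coordinate arrays."""

    atoms: list[TypedAtom]
    residues: list[Residue]
    chains: list[str]

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_residue_indices(self) -> np.ndarray:
        """Index into ``self.residues`` for every atom."""
        out = np.empty(len(self.atoms), dtype=int)
        for ri, res in enumerate(self.residues):
            out[res.atom_indices] = ri
        return out

    def vdw_params(self) -> tuple[np.ndarray, np.ndarray]:
        R = np.array([a.vdw_radius_R for a in self.atoms], dtype=float)
        eps = np.array([a.vdw_depth_eps for a in self.atoms], dtype=float)
        return R, eps

    def chain_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chain_sequence(self, chain_id: str) -> str:
        """One-letter sequence of the chain's observed residues (X if unknown)."""
        return "".join(
            THREE_TO_ONE.get(r.residue_name, "X") for r in self.chain_residues(chain_id)
        )

    def drop_hydrogens(self) -> "ProteinStructure":
        keep = [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]
        return _rebuild(self, keep)

    def to_pdb_string(self) -> str:
        lines = []
        serial = 0
        for res in self.residues:
            for ai in res.atom_indices:
                a = self.atoms[ai]
                serial += 1
                lines.append(_pdb_atom_line("ATOM", serial, a))
        lines.append("END")
        return "\n".join(lines) + "\n"


@dataclass
class LigandGroup:
    """A connected group of non-water HETATM heavy atoms that passed the filter."""

    heavy_atoms: list[tuple[str, np.ndarray]]  # (element, position)
    component_names: list[str]
    n_contacts: int
    het_indices: list[int] = field(default_factory=list)

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_atoms)

    def heavy_coords(self) -> np.ndarray:
        return np.array([p for _, p in self.heavy_atoms], dtype=float)


THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


def _rebuild(structure: ProteinStructure, keep: Sequence[int]) -> ProteinStructure:
    old_to_new = {old: new for new, old in enumerate(keep)}
    atoms = [structure.atoms[i] for i in keep]
    residues = []
    for res in structure.residues:
        idx = [old_to_new[i] for i in res.atom_indices if i in old_to_new]
        if idx:
            residues.append(Residue(res.chain_id, res.residue_seq, res.icode,
                                    res.residue_name, idx))
    chains = sorted({r.chain_id for r in residues})
    return ProteinStructure(atoms, residues, chains)


def _pdb_atom_line(record: str, serial: int, a) -> str:
    name = a.name
    # PDB column rule: 1-letter elements start at column 14
    if len(name) < 4 and len(a.element) < 2:
        name = " " + name
    x, y, z = a.position
    return (
        f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
        f"{a.chain_id:1s}{a.residue_seq:>4d}{a.icode:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2s}"
    )


def parse_structure(
    path: str | Path,
    model_index: int = 0,
    altloc_policy: str = "highest_occupancy",
) -> tuple[ProteinStructure, list[HetAtom]]:
    """Parse a PDB file into a ProteinStructure plus raw HETATM records.

    Only the model selected by ``model_index`` is read.  For alternate
    locations the default policy keeps the highest-occupancy copy of each
    atom (ties broken by file order).  ATOM records become protein atoms;
    HETATM records (waters included) are returned separately for ligand
    selection.

    Raises
    ------
    StructureError
        If the file cannot be read or contains no ATOM records.
    """
    if altloc_policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    if model_index >= len(st):
        raise StructureError(
            f"{path}: model_index {model_index} out of range ({len(st)} models)"
        )
    model = st[model_index]

    atoms: list[TypedAtom] = []
    residues: list[Residue] = []
    het: list[HetAtom] = []
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            picked = _resolve_altlocs(res, altloc_policy)
            if is_het:
                for at in picked:
                    het.append(HetAtom(
                        serial=at.serial, name=at.name,
                        element=_element_of(at),
                        residue_name=res.name,
                        residue_seq=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    ))
                continue
            r = Residue(chain.name, res.seqid.num, res.seqid.icode.strip(), res.name)
            for at in picked:
                r.atom_indices.append(len(atoms))
                atoms.append(TypedAtom(
                    serial=at.serial, name=at.name,
                    element=_element_of(at),
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    chain_id=chain.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                ))
            if r.atom_indices:
                residues.append(r)

    if not atoms:
        raise StructureError(f"{path}: no ATOM records (empty structure)")
    chains = sorted({r.chain_id for r in residues})
    return ProteinStructure(atoms, residues, chains), het


def _element_of(at: gemmi.Atom) -> str:
    el = at.element.name.upper()
    if el and el != "X":
        return el
    # fall back on the first alphabetic character of the atom name
    for ch in at.name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _resolve_altlocs(res: gemmi.Residue, policy: str) -> list[gemmi.Atom]:
    """Pick exactly one atom per atom name among alternate locations."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        prev = by_name.get(at.name)
        if prev is None:
            by_name[at.name] = at
            order.append(at.name)
        elif policy == "highest_occupancy" and at.occ > prev.occ:
            by_name[at.name] = at
    return [by_name[n] for n in order]


# ---------------------------------------------------------------------------
# parameter assignment


def load_vdw_table(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    """Load the parm94 (R*, epsilon) table, type -> (R, eps)."""
    text = _read_asset("parm94_vdw.dat", path)
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        typ, r, eps = line.split()
        table[typ] = (float(r), float(eps))
    return table


def load_name_map(path: str | Path | None = None) -> dict[tuple[str, str], str]:
    """Load the (residue_name, atom_name) -> parm94 type map ('*' wildcards)."""
    text = _read_asset("atom_types.dat", path)
    out: dict[tuple[str, str], str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, name, typ = line.split()
        out[(res, name)] = typ
    return out


def _read_asset(default_name: str, path: str | Path | None) -> str:
    if path is not None:
        return Path(path).read_text()
    return resources.files("consite.data").joinpath(default_name).read_text()


def assign_parameters(
    structure: ProteinStructure,
    param_table: dict[str, tuple[float, float]] | None = None,
    name_map: dict[tuple[str, str], str] | None = None,
    fallback: bool = True,
) -> ProteinStructure:
    """Assign parm94 (R*, epsilon) to every atom, in place.

    Atoms whose (residue, name) pair is not in the map fall back to
    element-generic parameters with a warning; with ``fallback=False`` such
    atoms raise :class:`TypingError` listing the offenders.
    """
    if param_table is None:
        param_table = load_vdw_table()
    if name_map is None:
        name_map = load_name_map()
    unmapped: list[str] = []
    for a in structure.atoms:
        typ = name_map.get((a.residue_name, a.name)) or name_map.get(("*", a.name))
        if typ is None:
            el = a.element
            typ = ELEMENT_FALLBACK.get(el)
            unmapped.append(f"{a.chain_id}/{a.residue_name}{a.residue_seq}/{a.name}")
            if typ is None:
                raise TypingError(f"no parameters for element {el!r} ({unmapped[-1]})")
        R, eps = param_table[typ]
        a.vdw_radius_R = R
        a.vdw_depth_eps = eps
    if unmapped:
        if not fallback:
            raise TypingError(
                "atoms without a type mapping: " + ", ".join(unmapped)
            )
        warnings.warn(
            f"{len(unmapped)} atom(s) typed by element fallback: "
            + ", ".join(unmapped[:10]) + ("..." if len(unmapped) > 10 else ""),
            stacklevel=2,
        )
    return structure


# ---------------------------------------------------------------------------
# ligand selection


def select_ligands(
    het_records: Iterable[HetAtom],
    structure: ProteinStructure,
    min_heavy: int = 10,
    min_contacts: int = 70,
    contact_cutoff: float = 4.0,
    cluster_cutoff: float = 4.0,
) -> list[LigandGroup]:
    """Select biologically relevant ligands from HETATM records.

    Waters are dropped, the remaining heavy atoms are merged into connected
    groups by single linkage at ``cluster_cutoff``, and each group is kept iff
    it has >= ``min_heavy`` heavy atoms and >= ``min_contacts`` (ligand heavy
    atom, protein atom) pairs within ``contact_cutoff``.
    """
    het = [
        (i, h) for i, h in enumerate(het_records)
        if h.residue_name not in WATER_NAMES and h.element not in ("H", "D")
    ]
    if not het:
        return []
    coords = np.array([h.position for _, h in het])
    # single-linkage connected components at cluster_cutoff
    parent = list(range(len(het)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cluster_cutoff):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    groups: dict[int, list[int]] = {}
    for k in range(len(het)):
        groups.setdefault(find(k), []).append(k)

    prot_tree = cKDTree(structure.coords())
    out: list[LigandGroup] = []
    for members in groups.values():
        if len(members) < min_heavy:
            continue
        pos = coords[members]
        n_contacts = sum(
            len(nb) for nb in prot_tree.query_ball_point(pos, contact_cutoff)
        )
        if n_contacts < min_contacts:
            continue
        names: list[str] = []
        for m in members:
            nm = het[m][1].residue_name
            if nm not in names:
                names.append(nm)
        out.append(LigandGroup(
            heavy_atoms=[(het[m][1].element, het[m][1].position) for m in members],
            component_names=names,
            n_contacts=int(n_contacts),
            het_indices=[het[m][0] for m in members],
        ))
    # stable order: largest group first, then by first serial
    out.sort(key=lambda g: (-g.n_heavy, g.het_indices[0] if g.het_indices else 0))
    return out
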