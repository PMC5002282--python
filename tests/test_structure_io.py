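"""Structure parsing, parm94 parameter assignment and ligand selection."""

import numpy as np
import pytest

from consite.structure_io import (
    HetAtom, StructureError, TypingError, assign_parameters, load_name_map,
    load_vdw_table, parse_structure, select_ligands,
)


def _line(record, serial, name, resname, chain, seq, x, y, z,
          occ=1.00, altloc=" ", element=None):
    element = element or name[0]
    n = name if len(name) >= 4 or len(element) >= 2 else " " + name
    return (f"{record:<6s}{serial:>5d} {n:<4s}{altloc}{resname:>3s} "
            f"{chain}{seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


TWO_RESIDUE_PDB = "\n".join([
    _line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
    _line("ATOM", 2, "CA", "ALA", "A", 1, 1.46, 0.0, 0.0),
    _line("ATOM", 3, "C", "ALA", "A", 1, 2.0, 1.4, 0.0),
    _line("ATOM", 4, "O", "ALA", "A", 1, 1.5, 2.5, 0.0),
    _line("ATOM", 5, "CB", "ALA", "A", 1, 1.9, -0.9, 1.2),
    _line("ATOM", 6, "N", "GLY", "A", 2, 3.3, 1.3, 0.0),
    _line("ATOM", 7, "CA", "GLY", "A", 2, 4.1, 2.5, 0.2),
    _line("ATOM", 8, "C", "GLY", "A", 2, 5.5, 2.2, 0.6),
    _line("ATOM", 9, "O", "GLY", "A", 2, 6.0, 1.1, 0.4),
    "END",
]) + "\n"


@pytest.fixture
def two_residue_pdb(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_RESIDUE_PDB)
    return p


class TestParseStructure:
    def test_counts_match_input(self, two_residue_pdb):
        st, het = parse_structure(two_residue_pdb)
        assert len(st.atoms) == 9
        assert len(st.residues) == 2
        assert [r.residue_name for r in st.residues] == ["ALA", "GLY"]
        assert st.chains == ["A"]
        assert het == []
        assert st.chain_sequence("A") == "AG"

    def test_model_isolation(self, tmp_path):
        text = "MODEL        1\n" + TWO_RESIDUE_PDB.replace("END\n", "ENDMDL\n") \
            + "MODEL        2\n" \
            + _line("ATOM", 1, "CA", "GLY", "A", 1, 9.0, 9.0, 9.0) \
            + "\nENDMDL\nEND\n"
        p = tmp_path / "models.pdb"
        p.write_text(text)
        st, _ = parse_structure(p, model_index=0)
        assert len(st.atoms) == 9
        st2, _ = parse_structure(p, model_index=1)
        assert len(st2.atoms) == 1

    def test_altloc_highest_occupancy(self, tmp_path):
        text = "\n".join([
            _line("ATOM", 1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.6, altloc="A"),
            _line("ATOM", 2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.4, altloc="B"),
            "END",
        ]) + "\n"
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        st, _ = parse_structure(p)
        assert len(st.atoms) == 1
        assert st.atoms[0].position[0] == pytest.approx(0.0, abs=1e-6)

    def test_no_atoms_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(StructureError):
            parse_structure(p)

    def test_round_trip(self, two_residue_pdb, tmp_path):
        st, _ = parse_structure(two_residue_pdb)
        out = tmp_path / "rt.pdb"
        out.write_text(st.to_pdb_string())
        st2, _ = parse_structure(out)
        assert len(st2.atoms) == len(st.atoms)
        for a, b in zip(st.atoms, st2.atoms):
            assert (a.name, a.residue_name, a.residue_seq, a.chain_id) == \
                (b.name, b.residue_name, b.residue_seq, b.chain_id)
            assert np.allclose(a.position, b.position, atol=1.5e-3)
        assert [r.atom_indices for r in st2.residues] == \
            [r.atom_indices for r in st.residues]


class TestAssignParameters:
    def test_alanine_cb_gets_aliphatic_carbon(self, two_residue_pdb):
        st, _ = parse_structure(two_residue_pdb)
        assign_parameters(st)
        table = load_vdw_table()
        cb = next(a for a in st.atoms if a.name == "CB")
        assert (cb.vdw_radius_R, cb.vdw_depth_eps) == table["CT"]
        n = next(a for a in st.atoms if a.name == "N")
        assert (n.vdw_radius_R, n.vdw_depth_eps) == table["N"]

    def test_backbone_amide_hydrogen(self, tmp_path):
        text = "\n".join([
            _line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
            _line("ATOM", 2, "H", "ALA", "A", 1, -0.9, 0.3, 0.0, element="H"),
            "END",
        ]) + "\n"
        p = tmp_path / "h.pdb"
        p.write_text(text)
        st, _ = parse_structure(p)
        assign_parameters(st)
        h = next(a for a in st.atoms if a.name == "H")
        assert h.is_hydrogen
        assert (h.vdw_radius_R, h.vdw_depth_eps) == load_vdw_table()["H"]

    def test_no_fallback_raises_listing_atoms(self, tmp_path):
        text = "\n".join([
            _line("ATOM", 1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
            _line("ATOM", 2, "XQ1", "ALA", "A", 1, 2.0, 0.0, 0.0, element="C"),
            "END",
        ]) + "\n"
        p = tmp_path / "odd.pdb"
        p.write_text(text)
        st, _ = parse_structure(p)
        with pytest.raises(TypingError, match="XQ1"):
            assign_parameters(st, fallback=False)
        with pytest.warns(UserWarning, match="fallback"):
            assign_parameters(st)  # element-generic carbon
        assert st.atoms[1].vdw_radius_R == load_vdw_table()["CT"][0]

    def test_full_coverage_no_warning(self, two_residue_pdb, recwarn):
        st, _ = parse_structure(two_residue_pdb)
        names_before = [a.name for a in st.atoms]
        assign_parameters(st)
        assert [a.name for a in st.atoms] == names_before
        assert not recwarn.list
        assert all(a.vdw_radius_R > 0 for a in st.atoms)

    def test_name_map_covers_standard_residues(self):
        name_map = load_name_map()
        table = load_vdw_table()
        assert all(t in table for t in name_map.values())
        # every standard residue has side-chain entries (GLY/ALA via backbone)
        residues = {res for res, _ in name_map if res != "*"}
        for res in ("ARG", "ASP", "HIS", "TRP", "TYR", "VAL", "MET", "LYS"):
            assert res in residues


def _blob_structure(n, center):
    """n protein atoms in a tiny blob (all within 4 A of `center` only)."""
    from tests.conftest import build_structure
    pos = np.asarray(center) + 0.002 * np.arange(n)[:, None] * [1, 0, 0]
    return build_structure(pos)


def _het(positions, resname="LIG", chain="a"):
    return [
        HetAtom(i + 1, f"C{i+1}", "C", resname, 900, "", chain, np.asarray(p, float))
        for i, p in enumerate(positions)
    ]


class TestSelectLigands:
    def _ligand_line(self, n):
        # >= 4 A apart from each other's contact shells, < 4 A for linkage
        return [(3.9 * i, 0.0, 0.0) for i in range(n)]

    def test_min_heavy_boundary(self):
        protein = _blob_structure(70, center=(0.0, 3.5, 0.0))
        nine = _het(self._ligand_line(9))
        assert select_ligands(nine, protein) == []
        ten = _het(self._ligand_line(10))
        assert len(select_ligands(ten, protein)) == 1

    def test_min_contacts_boundary(self):
        lig = _het(self._ligand_line(12))
        assert select_ligands(lig, _blob_structure(69, (0.0, 3.5, 0.0))) == []
        got = select_ligands(lig, _blob_structure(70, (0.0, 3.5, 0.0)))
        assert len(got) == 1
        assert got[0].n_contacts == 70
        assert got[0].n_heavy == 12

    def test_water_excluded(self):
        protein = _blob_structure(70, (0.0, 3.5, 0.0))
        waters = _het(self._ligand_line(12), resname="HOH")
        assert select_ligands(waters, protein) == []

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        protein = _blob_structure(80, (0.0, 3.5, 0.0))
        het = _het(rng.uniform(-2, 8, size=(30, 3)))
        base = select_ligands(het, protein, min_heavy=5, min_contacts=10)
        for mh, mc in [(6, 10), (5, 40), (10, 80)]:
            tighter = select_ligands(het, protein, min_heavy=mh, min_contacts=mc)
            assert len(tighter) <= len(base)

    def test_grouping_matches_connected_components_oracle(self):
        rng = np.random.default_rng(11)
        protein = _blob_structure(5, (50.0, 50.0, 50.0))  # far: no contacts
        pts = rng.uniform(0, 12, size=(40, 3))
        het = _het(pts)
        groups = select_ligands(het, protein, min_heavy=1, min_contacts=0)
        got = sorted(frozenset(g.het_indices) for g in groups)
        # brute-force single-linkage components at 4 A
        n = len(pts)
        adj = [[j for j in range(n) if j != i
                and np.linalg.norm(pts[i] - pts[j]) <= 4.0] for i in range(n)]
        seen, comps = set(), []
        for s in range(n):
            if s in seen:
                continue
            stack, comp = [s], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(adj[v])
            seen |= comp
            comps.append(frozenset(comp))
        assert got == sorted(comps)
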