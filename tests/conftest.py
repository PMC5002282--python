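"""Shared fixtures: toy structures and session-scoped end-to-end runs.

The end-to-end predictions (full 0.5 A grid, P_num = 500) are the expensive
part of the suite, so each synthetic-pocket variant is computed once per
session and reused by every test that needs it.
"""

from __future__ import annotations

import numpy as np
import pytest

from consite.config import RunConfig
from consite.fixtures import (
    PocketFixtureSpec, make_conservation_files, make_pocket_structure,
)
from consite.pipeline import evaluate, predict
from consite.structure_io import ProteinStructure, Residue, TypedAtom

CARBON = (1.908, 0.1094)


def build_structure(positions, residue_names=None, chain_id="A",
                    atom_name="CA", element="C", params=CARBON):
    """CA-only structure with one atom per residue at the given positions."""
    positions = np.asarray(positions, dtype=float)
    atoms, residues = [], []
    for i, pos in enumerate(positions):
        name = residue_names[i] if residue_names else "ALA"
        atoms.append(TypedAtom(i + 1, atom_name, element, name, i + 1, "",
                               chain_id, pos, params[0], params[1]))
        residues.append(Residue(chain_id, i + 1, "", name, [i]))
    return ProteinStructure(atoms, residues, [chain_id])


@pytest.fixture
def toy_structure_factory():
    return build_structure


# ---------------------------------------------------------------------------
# session-scoped synthetic pocket runs


@pytest.fixture(scope="session")
def pocket_files(tmp_path_factory):
    """Default pocket fixture written to disk (PDB + PSSM + MSA)."""
    d = tmp_path_factory.mktemp("pocket")
    spec = PocketFixtureSpec()
    fx = make_pocket_structure(spec)
    pssm, msa = make_conservation_files(spec, fx)
    (d / "pocket.pdb").write_text(fx.pdb_text)
    (d / "chainA.pssm").write_text(pssm)
    (d / "chainA.fasta").write_text(msa)
    return {"dir": d, "spec": spec, "fixture": fx,
            "pdb": d / "pocket.pdb", "pssm": d / "chainA.pssm",
            "msa": d / "chainA.fasta"}


@pytest.fixture(scope="session")
def pocket_run(pocket_files):
    return predict(pocket_files["pdb"], {"*": pocket_files["pssm"]})


@pytest.fixture(scope="session")
def pocket_report(pocket_run):
    return evaluate(pocket_run)


@pytest.fixture(scope="session")
def dimer_files(tmp_path_factory):
    d = tmp_path_factory.mktemp("dimer")
    spec = PocketFixtureSpec(dimer=True)
    fx = make_pocket_structure(spec)
    pssm, _ = make_conservation_files(spec, fx)
    (d / "pocket.pdb").write_text(fx.pdb_text)
    (d / "chain.pssm").write_text(pssm)
    return {"dir": d, "spec": spec, "fixture": fx,
            "pdb": d / "pocket.pdb", "pssm": d / "chain.pssm"}


@pytest.fixture(scope="session")
def dimer_run(dimer_files):
    return predict(dimer_files["pdb"], {"*": dimer_files["pssm"]})


@pytest.fixture(scope="session")
def twopocket_files(tmp_path_factory):
    """Two identical pockets on one chain; PSSMs conserving either pocket."""
    d = tmp_path_factory.mktemp("twopocket")
    spec = PocketFixtureSpec(two_pocket=True)
    fx = make_pocket_structure(spec)
    half = len(fx.sequence) // 2
    pocket1 = {p for p in fx.pocket_positions if p <= half}
    pocket2 = {p for p in fx.pocket_positions if p > half}
    pssm1, _ = make_conservation_files(spec, fx, conserved_positions=pocket1)
    pssm2, _ = make_conservation_files(spec, fx, conserved_positions=pocket2)
    (d / "pocket.pdb").write_text(fx.pdb_text)
    (d / "conserve1.pssm").write_text(pssm1)
    (d / "conserve2.pssm").write_text(pssm2)
    return {"dir": d, "spec": spec, "fixture": fx, "pdb": d / "pocket.pdb",
            "pssm1": d / "conserve1.pssm", "pssm2": d / "conserve2.pssm"}


@pytest.fixture(scope="session")
def twopocket_run(twopocket_files):
    """Prediction with pocket 1 conserved."""
    return predict(twopocket_files["pdb"], {"*": twopocket_files["pssm1"]})


def pocket_of_site(site, result):
    """Which pocket (-1: x<0, +1: x>0) a ranked site's centroid falls in."""
    pos = np.array([result.probes[i].position for i in site.cluster.probe_indices])
    return -1 if pos.mean(axis=0)[0] < 0 else 1
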