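"""Carbon-probe grid placement and Lennard-Jones 6-12 probe energies.

A single carbon atom probe is placed at every node of a 0.5 A grid covering
the protein's bounding box plus a margin.  Each probe's van der Waals energy
is the sum, over protein atoms within a 10 A cutoff, of the 6-12 potential

    E_ij = sqrt(eps_i * eps_j) * [ ((R_i+R_j)/r_ij)^12 - 2 ((R_i+R_j)/r_ij)^6 ]

with parm94 (R*, eps) parameters; eps under the radical is the geometric
mean of the probe's and the atom's well depths.  The probe is a single
carbon rather than a methyl group so that no hydrogen rotation has to be
sampled; the energy ranks cavities, it is not a physical binding energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ProteinStructure, TypingError

#: parm94 aliphatic sp3 carbon (CT): the default probe parameters
CARBON_PROBE = (1.9080, 0.1094)


@dataclass
class GridSpec:
    """Axis-aligned probe grid: position = origin + spacing * index."""

    origin: np.ndarray  # (3,)
    spacing: float
    shape: tuple[int, int, int]
    margin: float

    @property
    def n_probes(self) -> int:
        return int(np.prod(self.shape))

    def positions(self) -> np.ndarray:
        """All grid-node positions, C-order over the index triple."""
        ax = [self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def indices(self) -> np.ndarray:
        """Integer index triples matching :meth:`positions` order."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])


@dataclass
class Probe:
    """One grid probe with its raw and (later) weighted energy."""

    position: np.ndarray
    e_vdw: float
    grid_index: tuple[int, int, int]
    e_weighted: float = 0.0


def build_grid(
    structure: ProteinStructure, spacing: float = 0.5, margin: float = 8.0
) -> GridSpec:
    """Grid covering the protein bounding box expanded by ``margin`` per side."""
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    coords = structure.coords()
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = tuple(int(np.floor((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    return GridSpec(origin=lo, spacing=spacing, shape=shape, margin=margin)


def lj_energy(r_ij, R_i, eps_i, R_j, eps_j):
    """Lennard-Jones 6-12 energy of one pair (kcal/mol); vectorized in r_ij.

    Minimum of exactly -sqrt(eps_i*eps_j) at r_ij = R_i + R_j; zero crossing
    at (R_i+R_j)/2**(1/6).
    """
    r = np.asarray(r_ij, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    s6 = ((R_i + R_j) / r) ** 6
    out = np.sqrt(eps_i * eps_j) * (s6 * s6 - 2.0 * s6)
    return float(out) if np.isscalar(r_ij) else out


def compute_probe_energies(
    probe_positions: np.ndarray,
    structure: ProteinStructure,
    cutoff: float = 10.0,
    probe_type: tuple[float, float] = CARBON_PROBE,
    grid_indices: np.ndarray | None = None,
    chunk_size: int = 20000,
) -> list[Probe]:
    """Sum the pair energy over protein atoms within ``cutoff`` of each probe.

    Uses a KD-tree on the protein atoms and evaluates the pair terms in
    vectorized chunks; results are identical to the all-pairs double loop.
    Probes with no atom in range get exactly 0.
    """
    R_atoms, eps_atoms = structure.vdw_params()
    if np.any(R_atoms <= 0) or np.any(eps_atoms < 0):
        bad = int(np.argmax((R_atoms <= 0) | (eps_atoms < 0)))
        a = structure.atoms[bad]
        raise TypingError(
            f"atom {a.chain_id}/{a.residue_name}{a.residue_seq}/{a.name} "
            "has no van der Waals parameters; run assign_parameters first"
        )
    coords = structure.coords()
    R_p, eps_p = probe_type
    tree = cKDTree(coords)
    pos = np.asarray(probe_positions, dtype=float)
    if grid_indices is None:
        grid_indices = np.zeros((len(pos), 3), dtype=int)

    energies = np.zeros(len(pos))
    # probes with no atom within the cutoff are exactly zero: skip them
    d_nearest, _ = tree.query(pos, k=1, distance_upper_bound=cutoff)
    active = np.flatnonzero(np.isfinite(d_nearest))
    for start in range(0, len(active), chunk_size):
        sel = active[start:start + chunk_size]
        block = pos[sel]
        neigh = tree.query_ball_point(block, cutoff)
        counts = np.fromiter((len(n) for n in neigh), dtype=int, count=len(neigh))
        if counts.sum() == 0:
            continue
        flat = np.concatenate([np.asarray(n, dtype=int) for n in neigh if n])
        probe_of_pair = np.repeat(np.arange(len(block)), counts)
        d = np.linalg.norm(block[probe_of_pair] - coords[flat], axis=1)
        rsum6 = ((R_p + R_atoms[flat]) / d) ** 6
        e = np.sqrt(eps_p * eps_atoms[flat]) * (rsum6 * rsum6 - 2.0 * rsum6)
        np.add.at(energies, sel[probe_of_pair], e)

    return [
        Probe(position=pos[i], e_vdw=float(energies[i]),
              grid_index=tuple(int(v) for v in grid_indices[i]))
        for i in range(len(pos))
    ]


def brute_force_probe_energies(
    probe_positions: np.ndarray,
    structure: ProteinStructure,
    cutoff: float = 10.0,
    probe_type: tuple[float, float] = CARBON_PROBE,
) -> np.ndarray:
    """Literal all-pairs double loop over probes and atoms (test oracle)."""
    R_p, eps_p = probe_type
    out = np.zeros(len(probe_positions))
    for i, p in enumerate(np.asarray(probe_positions, dtype=float)):
        total = 0.0
        for a in structure.atoms:
            r = float(np.linalg.norm(p - a.position))
            if r <= cutoff:
                total += lj_energy(r, R_p, eps_p, a.vdw_radius_R, a.vdw_depth_eps)
        out[i] = total
    return out


def prune_probes(probes: list[Probe], e_max: float = 0.0) -> list[Probe]:
    """Drop probes with e_vdw > e_max (clashes and vacuum, by default).

    Clustering grows from the lowest energies upward, so as long as it
    terminates at a threshold <= e_max the pruned and unpruned runs produce
    identical clusters.
    """
    return [p for p in probes if p.e_vdw <= e_max]
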