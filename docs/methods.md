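# Methods

## Model

`consite` treats binding-site prediction as two questions answered in
sequence: *where would a small apolar atom sit comfortably?* and *of those
places, which one does evolution care about?*

**Probe energies.** A virtual carbon atom is placed at every node of an
axis-aligned grid (spacing 0.5 Å) covering the protein bounding box plus a
margin. Its interaction with the protein is the Lennard-Jones 6-12 sum

    E_vdw(i) = Σ_j  √(ε_i ε_j) · [ ((R_i+R_j)/r_ij)^12 − 2 ((R_i+R_j)/r_ij)^6 ]

over atoms j within a 10 Å cutoff (hard truncation, no switching).
Parameters are parm94 nonbonded values: every atom is mapped from its PDB
name to a parm94 atom type by a shipped plain-text table, then to
(R*, ε). The probe uses the aliphatic sp3 carbon type (R* = 1.908 Å,
ε = 0.1094 kcal/mol). ε under the radical is the geometric mean of the two
well depths (the standard combination when each atom carries its own ε).
The energy is a cavity detector, not a binding free energy: concave
regions surround a probe with more atoms near the well distance and score
deeper sums.

**Clustering.** The deepest probe defines the starting threshold; the
threshold then rises in 0.1 kcal/mol steps. Probes at or below the
threshold are active; an active probe within 1 Å of a cluster member joins
that cluster, mutually-near active probes found new clusters, and clusters
whose nearest members come within 1 Å merge (single linkage). The process
stops the moment any cluster holds P_num = 500 probes, and every cluster
existing at that instant is returned. The size cap plays the role of a
fixed energy threshold in other energy-based pocket finders but adapts the
effective threshold per protein.

Because probes activate strictly in (energy, grid-index) order, the
stepped threshold is observationally identical to inserting probes one at
a time in that order; both the production implementation (KD-tree
neighbours, union-find) and the brute-force oracle (literal O(n²) scan)
are written that way and are tested for identical cluster membership.
Grid-index ordering makes the result independent of probe input order.
Note one consequence of stopping on a merge: the probe that triggers the
stop may fuse two clusters, so the capped cluster can momentarily exceed
P_num; the guarantee is that the stop fires at the *first* instant any
cluster reaches P_num.

**Conservation.** The C_score of a residue is the Jensen-Shannon
divergence, base 2, between its position's amino-acid distribution P and a
background Q:

    JSD(P, Q) = ½ KL(P‖M) + ½ KL(Q‖M),   M = ½(P+Q),  0·log 0 := 0

so C_score ∈ [0, 1]. P comes either from the weighted-observed-percentage
block of a PSI-BLAST ASCII PSSM (columns 23–42, divided by 100 and
renormalized; zero rows fall back to the background) or from the column
frequencies of a FASTA alignment. Q defaults to the BLOSUM62 marginal
frequencies (the standard background for divergence-based conservation
scoring); a uniform 1/20 background and user tables are supported. The
exact background used to train the published weights is not recoverable,
so tests probe ranking behaviour rather than absolute C_score values.
Sequence positions are mapped to structure residues by global alignment of
the profile query against the chain's observed sequence (Biopython
PairwiseAligner; ≥ 90 % identity over the aligned region required);
unaligned residues are flagged and given the chain median.

**Weighted score and ranking.** Probe i is re-scored as

    E_i = Σ_j ( w1·E_ij + w2·C_j + w3·E_ij·C_j ),   defaults (1, −0.05, 9)

with j over atoms within the 10 Å energy cutoff and C_j the residue
C_score **gated at 6 Å**: a residue contributes its C_score (to all of its
atoms) only if at least one of its atoms lies within 6 Å of the probe,
otherwise C_j = 0. Both conservation-containing terms are gated — a live
w3·E·C term at 6–10 Å would contradict the premise that residues far from
the site have little influence; the flag `cross_term_gated=False` exposes
the alternative reading. Clustering uses raw energies only; weighting
affects ranking, so weight scans reuse the clusters and are linear in the
per-probe components (ΣE, ΣC, ΣEC).

Clusters are ranked by ascending total weighted score (ties: lower raw
energy, then smallest grid index). For multimers, clusters on different
chains whose chain-stripped contact-residue sets (residue number + name)
overlap with Jaccard ≥ 0.7 and whose totals agree within 10 % are treated
as symmetric copies; only the lowest-scoring copy stays representative.
Both thresholds are configurable; the suppressed copy carries its
representative's rank in reports.

## Evaluation protocols

*Binding space*: the precision of a cluster is the percentage of its
probes within 1.6 Å of any ligand heavy atom; precision ≥ 25 % is a
success (both thresholds as used by grid-probe methods, so results are
directly comparable). *Binding residues*: residues with any atom within
5 Å of any cluster probe are the predicted binding residues; residues
within 4 Å of any ligand heavy atom (unioned over ligands) are the truth.
S_residue = 100·TP/(TP+FP) (:= 0 when nothing is predicted) and MCC with
the zero-denominator convention MCC := 0. Ligands are non-water HETATM
groups, single-linkage-merged at 4 Å, kept if ≥ 10 heavy atoms and ≥ 70
protein contacts within 4 Å. Top-k success asks whether any of the k
best-ranked representative sites meets the criterion; because "average
precision" can be read over successes or over all structures, the
aggregation helpers expose the over-successes mean explicitly.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| grid spacing | 0.5 | Å | probe placement density |
| grid margin | 8.0 | Å | box extension beyond the protein (own choice; covers surface pockets while bounding probe count) |
| energy cutoff | 10.0 | Å | atoms summed into E_vdw |
| probe type | CT (1.908, 0.1094) | Å, kcal/mol | carbon probe parameters |
| prune threshold | 0.0 | kcal/mol | probes with E_vdw above it dropped before clustering (no effect on results when clustering terminates below it; verified by an equivalence test) |
| P_num | 500 | probes | cluster size cap / stop rule |
| threshold step | 0.1 | kcal/mol | clustering threshold increment |
| linkage radius | 1.0 | Å | probe/cluster linkage (boundary inclusive) |
| conservation gate | 6.0 | Å | residues contributing C to a probe |
| (w1, w2, w3) | (1, −0.05, 9) | — | weighted-score coefficients |
| overlap radius | 1.6 | Å | space-precision probe/ligand match |
| contact radius | 5.0 | Å | predicted binding residues |
| truth radius | 4.0 | Å | true binding residues |
| dedup Jaccard / score tol | 0.7 / 10 % | — | multimer duplicate detection |

## Synthetic fixtures

The generator emits a "cup" pseudo-protein: two concentric spherical
shells (radius 7 Å and 9.8 Å) of ALA/GLY residues with standard backbone
atom names, a circular opening, and small coordinate jitter; a
12-carbon pseudo-ligand (HETATM `LIG`) sits in the cavity and passes the
biological-ligand filter by construction. Variants translate an exact copy
of the chain (homodimer; the 24-grid-cell shift keeps probe grids
commensurate, so the two pockets score near-identically) or rotate a copy
by 180° into the same chain (two identical pockets, for conservation
discrimination). Conservation files are sampled: pocket-lining positions
draw ~95 % of their letters from the query letter, all others from the
background; the PSSM percentages are the sampled alignment's column
frequencies, so the two input routes agree up to integer rounding.

What the fixtures do **not** emulate: real protein packing and secondary
structure, chemically sensible ligands, heterogeneous pocket shapes,
alignment gaps/indels, and PSSM pseudocount behaviour. Passing tests
demonstrate that the machinery implements its definitions and recovers a
planted geometric/evolutionary signal — not field performance on crystal
structures, which requires real benchmark sets and PSI-BLAST profiles.

## Numerical and design choices

- Altloc policy: highest occupancy, ties to file order; one model read.
- Hydrogens are used if present, never added; `ignore_hydrogens` drops
  them. Missing side chains are an input precondition.
- Non-standard ATOM residues (e.g. MSE) type by element fallback with a
  warning (C→CT, N→N, O→O, S→S, H→HC, P→P).
- All distance comparisons are boundary-inclusive (≤).
- Clustering requires a strictly negative starting energy; structures
  whose best probe is non-negative yield no sites.
- Degenerate input with fewer than P_num probes in total: the threshold
  loop ends once every probe is active; all clusters are returned.
- Probes with no atom inside the cutoff score exactly 0 (skipped by an
  exact nearest-neighbour prefilter, identical to the double loop).
- Missing conservation for a contacting chain: C = 0 with a warning by
  default; `strict_conservation` turns it into an error. Without any
  conservation input, (w2, w3) are forced to 0 and the run is logged as
  energy-only.
- Fixture/test problem sizes: the pocket shell holds ~310 residues giving
  ~400k grid probes per structure; the acceptance batch uses three
  single-pocket structures plus the dimer and two-pocket variants — sizes
  chosen so a complete run stays in the minutes range on one CPU while the
  cavity still dwarfs the 500-probe cap.

## Known limitations

- parm94 typing covers the 20 standard residues and common polar
  hydrogens; exotic hydrogen naming schemes fall back to element-generic
  parameters (warned, configurable via the editable data tables).
- The stop-on-first-cap reading of the clustering termination is
  implemented; capping each cluster independently and continuing is a
  plausible alternative reading and is noted, not implemented.
- JSD conservation is per-position; no sequence-window averaging or gap
  penalty is applied.
- Evaluation against multiple ligands uses the union of their heavy atoms;
  per-ligand evaluation is available by passing a single LigandGroup.
- Unbound-structure evaluation maps residues by chain + residue number
  identity with the bound form; large renumbering between forms is not
  reconciled automatically.
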