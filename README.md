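# consite

Ligand-binding site prediction for protein structures, combining an
energy-based pocket search with amino-acid sequence conservation.

Most small-molecule ligands bind in surface cavities where a probe atom
feels a deep van der Waals well, and the residues lining functional sites
tend to be conserved among homologues. `consite` exploits both signals: it
finds energetically favourable probe clusters on a grid around the protein
and re-ranks them by the conservation of the residues they touch.

## Method

1. **Probe grid.** A single carbon atom probe is placed at every node of a
   0.5 Å grid covering the protein plus a margin. A lone carbon (rather
   than a methyl group) avoids sampling hydrogen rotations.
2. **Van der Waals energy.** Each probe *i* gets
   `E_vdw(i) = Σ_j √(ε_i ε_j) [((R_i+R_j)/r_ij)^12 − 2((R_i+R_j)/r_ij)^6]`
   summed over protein atoms *j* within 10 Å, with AMBER parm94 radii `R`
   and well depths `ε` assigned from atom names. The energy ranks
   cavities; it is not a physical binding free energy.
3. **Clustering.** Starting from the lowest probe energy, a threshold rises
   in 0.1 kcal/mol steps; probes below it join, found, or merge clusters
   under single linkage at 1 Å. Clustering stops the moment a cluster
   holds `P_num = 500` probes, adapting the final energy threshold to each
   protein.
4. **Conservation.** Per-residue `C_score` is the Jensen–Shannon divergence
   (base 2) between the position's amino-acid frequencies — from a
   PSI-BLAST ASCII PSSM or a FASTA alignment — and the BLOSUM62 background.
5. **Weighted score.** Each probe is re-scored as
   `E_i = Σ_j (w1·E_ij + w2·C_j + w3·E_ij·C_j)` with defaults
   `(w1, w2, w3) = (1, −0.05, 9)`, where `C_j` is the C_score of atom *j*'s
   residue if that residue has an atom within 6 Å of the probe, else 0.
6. **Ranking.** Clusters are ranked by ascending total weighted score; on
   multimers, symmetric copies of one site are collapsed to a single
   representative.

Predictions are evaluated with two protocols: **binding-space precision**
(percent of a cluster's probes within 1.6 Å of a ligand heavy atom;
success at ≥ 25 %) and **binding-residue agreement** (residues within 5 Å
of cluster probes vs residues within 4 Å of the ligand, scored as
`S_residue` — residue-level precision — and the Matthews correlation
coefficient). Ligands count as biologically relevant if they are non-water
HETATM groups with ≥ 10 heavy atoms and ≥ 70 protein contacts within 4 Å.

## Worked example

`consite` ships a synthetic-structure generator (a cup-shaped pseudo-protein
with a planted ligand and matched conservation files) so the whole pipeline
runs without downloads:

```sh
python examples/01_predict_sites.py
```

prints

```
grid (62, 62, 48) -> 116546 attractive probes, 1 cluster(s) at termination
rank 1: 500 probes, E_vdw   -5495.0 kcal/mol, weighted  -20282.2, centroid (0.0, 0.0, -2.0), 157 contact residues
```

— the rank-1 site is the capped 500-probe cluster, its centroid sits inside
the pocket cavity (the fixture's pocket is centred at the origin), and its
contact residues are the predicted binding residues. Evaluating the same
prediction (`examples/03_evaluate_prediction.py`):

```
rank 1: precision  29.4 %   S_residue  56.1 %   MCC 0.624
Top-1 space success: True
Top-1 residue success: True
```

29.4 % of the cluster's probes overlap the planted ligand (above the 25 %
success bar) and 56 % of the predicted binding residues are genuine.

Other examples: `02_conservation_scores.py` (C_score of hand-written PSSM
columns), `04_weight_grid.py` (scanning the conservation weights).

A thin CLI wraps the same pipeline:

```sh
consite fixtures out/ --seed 3          # write a synthetic test structure
consite predict out/pocket.pdb -c '*'=out/chainA.pssm -o pred/
consite evaluate out/pocket.pdb -c '*'=out/chainA.pssm
```

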