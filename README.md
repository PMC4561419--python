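# seventm

Comparative structural analysis of seven-transmembrane (7TM) receptors:
motif-anchored Ballesteros–Weinstein numbering of class-A GPCR sequences,
helix-restricted sequence identity, Kabsch superposition and selection RMSD
between structures, and physicochemical profiling of binding cavities
(class-partitioned solvent-accessible surface area and grid-based enclosed
volume).

It is written for structural bioinformaticians who compare receptor subtypes
— for example homology models of a receptor family against a crystal
structure — and need the whole chain from raw FASTA/PDB files to a
comparison table to be scripted, deterministic and testable. A synthetic-data
module generates motif-bearing sequences, idealized helix bundles and
hollow-cavity fixtures with known ground truth, so every stage can be
validated without downloading anything.

## Methods in brief

**Motif-anchored numbering.** Class-A GPCR helices carry conserved sequence
fingerprints (`GX3N` for helix 1, `N(S,H)LX3DX7,8,9P` for helix 2,
`SX3LX2IX2D(E,H)RY` for helix 3, `WX8,9P`, `FX2PX7Y`, `FX2CW(Y,F)XP`, and
`LX3NX3N(D)PX2YX5,6F` for helices 7/8), where `Xn` is *n* arbitrary residues
and `(A,B)` lists alternatives for the preceding letter. The package parses
this grammar, finds every occurrence exhaustively, and anchors each helix at
its most conserved residue, which receives the Ballesteros–Weinstein index
X.50 (helix number X); neighbours are numbered relative to it, so the
residue ten positions past the helix-2 anchor is 2.60. Helix-restricted
identity between two aligned sequences is
`100 × (identical columns) / (gap-free columns)` over the helix columns.

**Superposition.** Rigid-body fitting is the classic Kabsch solution: centre
both coordinate sets, take the SVD of the covariance matrix, and correct the
sign so the rotation is proper (det +1). RMSD is
`sqrt(mean ||x_i − y_i||²)` over matched atoms (backbone N/CA/C/O, CA-only,
or all atoms), optionally after fitting.

**Cavity profiling.** SASA uses the Shrake–Rupley method with a
deterministic golden-spiral lattice (960 points/atom, probe 1.4 Å, Bondi
radii); the exposure of cavity-lining residues is computed in the context of
the intact structure and partitioned into hydrophilic, aromatic and
aliphatic classes (hydrophobic = aromatic + aliphatic; percent
hydrophilicity = 100 × phil / (phil + phob)). Cavity volume counts grid
voxels that are outside every van der Waals sphere, inside the convex hull
of the selection, and unreachable by bulk solvent (rolling-probe flood fill
from the box boundary), times the voxel volume.

## Worked example

```sh
python examples/identity_matrix.py
```

```
193 helix columns
               FFA1_like   FFA2_like   FFA3_like
   FFA1_like         100          32          33
   FFA2_like          32         100          49
   FFA3_like          33          49         100
```

The three sequences are synthetic stand-ins for the free-fatty-acid receptor
paralogs, generated with pairwise transmembrane identities of 32/33/49 % as
targets; the matrix shows the pipeline (motif matching → helix annotation →
anchored alignment → helix-restricted identity) recovering those parameters
from the raw sequences. `examples/number_sequences.py` prints the
marker-residue numbering the same way (e.g. `residue K62 -> 2.60`),
`examples/superpose_structures.py` shows the noise-RMSD law
(`unsuperposed backbone RMSD: 1.742 A (expected ~1.73)` for 1 Å Gaussian
noise), and `examples/profile_cavity.py` reports
`hollow shell volume: 277.2 A^3 (analytic 268.1)` for the closed-form
cavity fixture. `examples/full_pipeline.py` runs everything through one
config and writes the JSON/TSV report; the `seventm` command exposes the
same stages as subcommands (`number`, `identity`, `superpose`, `profile`,
`compare`, `synth`).

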