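# Methods

This note documents the models, numerical choices and limitations behind
`seventm`. It describes what the code computes and why the defaults are what
they are; every number quoted here is produced by the test suite or
`scripts/acceptance.py` at run time.

## Motif grammar and matching

Transmembrane helices of class-A GPCRs are located by conserved sequence
fingerprints rather than by hydrophobicity analysis. A motif string is a
list of literal residue tokens (with `(A,B)` alternatives folded into the
preceding literal) and spacer tokens `Xn` or `Xn,m,k` that match exactly the
stated number of arbitrary residues; a bare `X` is a spacer of length 1.
Matching is exhaustive: every start position and every admissible
combination of spacer lengths is reported, ordered by start and then by
spacer choice. This makes the matcher directly comparable with a brute-force
enumeration oracle, which the tests exercise on random sequences.

The anchor literal of each motif — the residue that receives the generic
number X.50 — is configurable per pattern. The defaults are the canonical
most-conserved class-A positions: N (helix 1), D (helix 2), the arginine of
the D-R-Y triad (helix 3), W (helix 4), P (helix 5), the proline of C-W-x-P
(helix 6) and the proline of N-P-x-x-Y (helix 7/8). This is the only
self-consistent reading of the motif set: each choice is the single residue
in its motif that the class-A numbering convention defines as .50.

## Helix boundaries

Motifs pin anchors, not helix extents. Helix spans are defined as
`anchor − up .. anchor + down` with per-helix defaults
h1 (12,12), h2 (12,13), h3 (22,12), h4 (10,12), h5 (17,10), h6 (20,10),
h7 (16,8), chosen so that the positions commonly indexed in binding-site
work (2.58–2.63, 3.30–3.37, 4.54–4.61, 5.35–5.43, 6.51–6.55, 7.35–7.53) fall
inside their helix while consecutive helices stay disjoint at typical
class-A anchor spacings. If user-supplied offsets make neighbouring spans
overlap, the spans are clipped at the midpoint between the two anchors and a
warning is logged; residues outside every span carry no generic number.
When a motif matches more than once, the match downstream of the previous
helix with the smallest start wins (or, when expected anchor spacings are
configured, the match closest to the expected position); every such
resolution is logged.

## Alignment

Pairwise global alignment uses Needleman–Wunsch with affine gaps
(Biopython's `PairwiseAligner`, BLOSUM62). The gap-cost convention is:
a gap of length k costs `open + (k−1)·extend`, with
open = 10 and extend = 1 by default. Ties in the traceback are resolved by
the aligner's fixed enumeration order (the first optimal alignment it
reports), which is deterministic across runs. The exhaustive-enumeration
oracle in the tests uses the same cost convention, so score agreement is
exact for short sequences.

Anchored adjustment operates on an existing alignment: for each helix in
order, the target anchor column is the right-most current anchor column
over rows, and rows whose anchor sits left of it receive gaps immediately
before the first residue of that helix — in the preceding loop, never
inside a helix. Gaps are only inserted, so stripping gaps always reproduces
the input sequences, and a second application is a no-op (idempotence).
Multi-sequence identity runs therefore do not depend on loop alignment
quality: identity is measured over helix columns only, as
`100 × identical / gap-free` columns, with half-up rounding for display and
full precision retained internally. Full-width identity is available as an
alternative mode because which columns a given publication counted is
rarely stated.

## Superposition and RMSD

Kabsch fitting is implemented directly (SVD of the centred covariance with
determinant correction) because it is a core quantity of the package; an
independent rotation solver (`scipy.spatial.transform.Rotation.align_vectors`)
serves as the cross-check oracle in tests, never as the implementation.
Atoms are matched across structures by (mapped chain, residue index, atom
name); the chain map defaults to identity and is configurable because
models and crystal files rarely share chain ids. "Backbone" means
{N, CA, C, O}; CA-only and all-atom modes exist because published
helix-backbone RMSDs do not always state the atom set. Hydrogens are
excluded from RMSD, SASA and volume by default (crystal structures
typically have none); a flag includes them. Point sets with fewer than
three atoms or rank-deficient covariance are rejected rather than fitted.

## SASA

Shrake–Rupley with a deterministic golden-spiral lattice: each atom's
sphere of radius (vdW + probe) is sampled with `n` points (default 960,
probe 1.4 Å) and a point is occluded when it lies strictly inside a
neighbouring atom's expanded sphere. Van der Waals radii default to Bondi
values (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å; 1.70 Å
fallback) and are overridable. Determinism follows from the fixed lattice;
doubling the point count changes per-atom values by well under 2 % on the
test fixtures, and an isolated carbon reproduces the analytic sphere area
4π(1.7+1.4)² ≈ 120.76 Å² to lattice precision. Because the occlusion test
is strict, two atoms at identical coordinates do not occlude each other;
they report equal exposure, which is the coherent reading of that
degenerate case. Cavity SASA is always computed on the whole structure and
then summed over the cavity-lining residues per class, since lining
residues are part of an intact receptor, not an isolated fragment.

Residue classes default to hydrophilic {R,K,H,D,E,N,Q,S,T,C}, aromatic
{F,Y,W}, aliphatic {A,V,L,I,M,P}, glycine unclassified; hydrophobic is
defined as aromatic ∪ aliphatic, and percent hydrophilicity as
100 × phil/(phil+phob). The scheme is fully configurable; all raw fields
are reported so alternative conventions can be applied downstream.

## Cavity volume

The volume estimator is grid-based: voxels (default 0.5 Å) spanning the
selection's bounding box are counted as cavity when they are (i) outside
every atom's vdW sphere, (ii) inside the convex hull of the selected atoms,
and (iii) not reachable by bulk solvent, where the bulk region is grown by
6-connected flood fill from the box boundary through voxels a probe centre
can occupy (≥ vdW + probe from every atom) and then dilated by the probe
radius. This cavity definition is the package's own; proprietary pocket
tools use different definitions, so agreement with numbers produced by such
tools is expected to be approximate. On the hollow-shell fixture the
estimator returns the analytic 4/3·π·r³ within 5 % at 0.5 Å spacing and
converges under grid refinement. Degenerate (coplanar) selections are
rejected; clusters without an interior void report 0.

## Synthetic data

The generators emulate exactly the features the analysis consumes and
nothing else. Sequences: motif occurrences at recorded positions separated
by filler drawn from an alphabet free of motif-literal letters (default
`AKMQTV`), so spurious matches cannot arise from filler; emitted sequences
are verified to match each pattern exactly once. Structures: ideal
alpha-helices (rise 1.5 Å, twist 100°, CA radius 2.3 Å) placed on a ring
with alternating orientation, CA-only or with a schematic N/CA/C/O backbone;
the geometry is deliberately idealized (no side chains, no membrane, no
physical backbone geometry beyond distinct atom positions), which is
sufficient for superposition, selection and SASA-partition code paths but
says nothing about force-field realism. Hollow shells provide the
closed-form volume oracle and are leak-tested at construction.

The FFA-like paralog trio deserves emphasis: the three sequences are
*synthetic stand-ins*, not the real free-fatty-acid receptor sequences.
Helix anchor positions, marker residues (e.g. the 2.60 lysine, the
anchoring arginines at 5.39 and 7.35) and the pairwise transmembrane
identities 32/33/49 % are taken from the receptor-family literature as
generator parameters; identity is planted by exact category counts over the
non-motif helix columns, so recovery is deterministic up to integer
rounding. Passing these checks demonstrates that the numbering and identity
machinery recovers planted ground truth through the full pipeline; it does
not demonstrate agreement with the real receptor sequences, which are not
redistributed here.

## Problem sizes and determinism

Default problem sizes are small by design: 200-residue random sequences for
the matcher oracle, sequence pairs of length ≤ 8 for the alignment oracle
(exhaustive enumeration grows exponentially), 210-atom bundles for RMSD
statistics (100 noise replicates give a standard error of ~0.005 Å on the
mean), 350-atom shells and 0.5 Å grids for volume. Every stochastic step
takes an explicit seed; `scripts/acceptance.py` derives all of its streams
from a single `--seed` and is bit-reproducible for a fixed seed.

## Known limitations

- Helix extents are offset-based, not structure-based; unusually long or
  short helices need user-supplied offsets (or an externally provided
  alignment with helix blocks).
- The anchored-alignment step registers anchors but does not optimally
  align loops; loop-sensitive analyses should supply a curated alignment.
- The volume definition (hull + flood fill) underestimates open-mouthed
  pockets, since solvent-reachable voxels are excluded by construction.
- The crystal-structure reproduction path (cavity profile of the receptor
  crystal structure, PDB 4PHU) requires the user to supply the coordinate
  file at `data/4phu.pdb`; coordinates are not redistributed with the
  package, and the corresponding acceptance test fails until the file is
  provided.
- mmCIF reading uses author residue numbering throughout, matching how
  residues are indexed in the structural literature.
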