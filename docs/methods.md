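# Methods

This note documents the models, geometric rules, parameter choices and
numerical conventions behind `caifp`, and what the synthetic fixtures do and
do not establish about real data.

## Structures and the binding-site axis

PDB and PDBQT files are parsed by fixed-width columns. The element symbol is
taken from columns 77–78 (PDBQT: the AutoDock atom type, mapped to an
element), falling back to atom-name heuristics when absent. When alternate
locations are present, the highest-occupancy conformer of each atom is kept;
ties resolve toward altLoc `A`. Waters can be stripped on read, as can
single-atom ion residues other than zinc — the catalytic zinc of carbonic
anhydrase II always stays with the receptor. SDF and MOL2 inputs go through
RDKit, which also supplies bonds and formal charges; for formats without
connectivity, bonds are perceived by distance (Pyykkö–Atsumi covalent radii,
factor 1.3).

The binding site is the union, over a set of complexes, of receptor residues
with any atom within a cutoff (default 7 Å) of any ligand atom. Hydrogens
participate in the distance test by default because inputs are assumed
prepared with hydrogens; a heavy-only switch exists. Single-atom ion residues
are excluded from the site by default (switchable): the fingerprint axis is
meant to be amino acids, and zinc's contribution is captured instead through
its optional role as a cationic center. Residues are ordered by (chain,
residue number, insertion code), which fixes the bit layout; a site file plus
a SHA-1 checksum (`site_tag`) bind every fingerprint to that ordering and
make mixing incompatible axes a hard error.

Receptor superposition pairs Cα atoms by (chain, residue number, insertion
code) — no sequence alignment, since cross-docking uses structures of the
same protein — and solves the least-squares rigid transform (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`). At least three paired Cα
atoms are required.

## Interaction detection

Seven interaction types are detected per (site residue, ligand pose) pair and
collapsed to binary per-residue flags; multiple qualifying atom pairs do not
accumulate. Defaults (all configurable, distances in Å, angles in degrees):

| parameter | default | role |
|---|---|---|
| `hbond_max_da_dist` | 3.5 | donor–acceptor heavy-atom distance |
| `hbond_max_deviation` | 50 | deviation of D–H···A from 180° |
| `hydrophobic_max_cc_dist` | 4.0 | apolar C–C contact |
| `pipi_max_centroid_dist` | 7.5 | parallel-stack centroid distance |
| `pipi_max_plane_angle` | 30 | parallel-stack plane angle |
| `pipi_projection_padding` | 0.75 | ring-perimeter slack for the projection test |
| `tstack_max_centroid_dist` | 5.0 | T-stack centroid distance |
| `tstack_plane_angle_window` | ±30 around 90 | T-stack plane angle |
| `catpi_max_dist` | 6.0 | cation to ring centroid |
| `saltbridge_max_dist` | 5.5 | distance between opposite charged centers |

The hydrogen-bond angle criterion is deliberately defined as the deviation of
the D–H···A angle from linearity (so 50° admits angles ≥ 130°); the cutoff
value alone does not determine the convention, and this reading matches
standard geometric detectors. Donors are N/O heavy atoms with a bound
hydrogen; acceptors are N and O (S behind a flag, default off). Hydrophobic
carbons are those whose heavy neighbours are only C or S, which excludes
carbonyl/carboxyl carbons. Receptor aromatic rings come from residue
templates (PHE, TYR, HIS, both TRP rings); ligand rings are 5–6-membered
bond-graph cycles passing a 0.35 Å coplanarity test, with the normal from the
best-fit plane (SVD). Charged centers use residue templates on the receptor
side (ARG, LYS, doubly protonated HIS, ASP, GLU, free termini, optionally
the zinc ion) and substructure rules plus recorded formal charges on the
ligand side (carboxylate/sulfonate/phosphate oxygens −, quaternary sp³
nitrogen and guanidinium-like groups +). The parallel-stack test additionally
requires one ring centroid to project inside the other ring's perimeter plus
padding; the T-stack test does not. Halogen bonds, metal coordination and
water bridges are intentionally not flags.

## Fingerprints, reference and Tc-IFP

Bit `7·i + j` encodes interaction `j` at site residue `i`; a 44-residue site
yields 308 bits. The consensus reference sets a bit iff at least
`min_support` (default 3) training fingerprints have it — interactions shown
by fewer ligands are treated as noise. Per-bit support counts are retained
and serialised.

The Tanimoto score uses the standard set-union denominator
`|A∩B| / (|A|+|B|−|A∩B|)`, under which identical non-empty fingerprints score
1.0. A literal prose reading of the coefficient as `|A∩B| / (|A|+|B|)` would
cap identity at 0.5; it is available behind `denominator="sum"` for
comparison but is not the default. Two all-zero fingerprints score 0.0 (0/0
convention, logged): an interaction-free pose carries no evidence.

## Rescoring and evaluation

Poses are scored against the reference and ranked descending; ties break
toward the lower pose index (the docking engine's own ordering) and are
logged. The selected pose's RMSD versus the crystallographic pose is computed
over heavy atoms in the shared receptor frame with no refitting, minimised
over element-labelled automorphisms of the heavy-atom bond graph (networkx
VF2), so chemically equivalent atom relabelings — a flipped phenyl, a rotated
carboxylate — do not inflate the error. Past 10⁴ automorphisms the identity
mapping is used with a warning. aRMSD is the arithmetic mean of selected-pose
RMSDs; NLRD is the fraction strictly below the threshold (default 2.0 Å;
"below" is read as a strict inequality and tested at the boundary). The
cross-docking planner emits the full ligand × receptor Cartesian product,
deduplicating with a warning.

## Clustering

Ligand fingerprints are compared all-against-all; complete-linkage
agglomerative clustering runs on d = 1 − Tc and merges while the smallest
complete-link distance is strictly below 1 − threshold (default Tc 0.40), so
a pair at exactly the threshold does not merge (`inclusive=True` switches to
≥). Complete linkage guarantees every within-cluster pair exceeds the
threshold, which is asserted in tests. Equal merge distances break toward the
lexicographically smallest member-label pair, making the partition invariant
under input permutation. Singletons ("unique fingerprint profile" ligands)
are reported separately, along with per-cluster consensus bits.

## Synthetic fixtures

The generator builds minimal two-fragment systems from idealized side-chain
templates (SER, LEU, PHE, ASP; ARG/LYS/HIS/ALA also available) and small
probes (carbonyl, hydroxyl, methane, benzene, 1,3,5-triazine, ammonium,
acetate). "Satisfy" placements stay at least ~0.1 Å / 5° inside the default
cutoffs, "violate" placements at least 0.3 Å / 10° outside, avoiding
float-boundary flakiness; probe geometry is additionally chosen so no *other*
interaction fires incidentally (e.g. the T-stack probe is a triazine with
nitrogens at the contact vertices, parallel-stacked benzene sits at ≥ 4.6 Å
so no C–C pair comes under the hydrophobic cutoff). A planted training
complex therefore has an exactly known fingerprint, which the detector — an
independent code path from the generator — must reproduce bit for bit.

Training families place one residue per site slot 15 Å apart along an axis
(beyond every cutoff, so slots cannot cross-talk), with one template per slot
consistent across the family; contradictory type requests at a slot raise a
generation error. Pose ensembles are rigid-body jitters of a native pose:
rotation up to 25°/Å of scale about the heavy-atom centroid plus an isotropic
Gaussian translation of the given scale per axis; mean ensemble RMSD grows
monotonically with the scale.

What passing on these fixtures shows: the geometric rules, bit bookkeeping,
consensus thresholding, ranking, statistics and clustering are implemented
correctly and deterministically. What it does not show: performance on real
co-crystal structures — toy probes have none of the conformational coupling,
steric context, protonation ambiguity or interaction density of real CAII
inhibitors, and synthetic ensembles are rigid jitters rather than docking
minima. Headline accuracy numbers on real data require the actual complex
set plus a docking engine and are out of scope here.

## Problem sizes and numerics

The default test and acceptance runs use desk-scale sizes chosen to exercise
every code path: 6–12-residue sites, 25–100-pose ensembles, 50-seed
repetitions for the selection-vs-random comparison (paired sign test at
α = 0.01), 100 fixtures per interaction type for oracle comparison, and
50 random matrices for the clustering guarantee. All generators accept a
seed and are bit-reproducible. Angles are computed through clipped arccos;
ring normals have unit norm by construction; fingerprint I/O is bit-exact
round-trip and checksum-verified against the site.
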