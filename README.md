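# caifp

Interaction-fingerprint rescoring of protein–ligand docking poses, built
around the carbonic anhydrase II (CAII) use case.

Docking search engines routinely generate near-native ligand poses that their
own energy-based scoring functions fail to rank first. `caifp` implements a
knowledge-based alternative for targets with many co-crystal structures:
encode the ligand–protein interactions seen in known complexes as binary
**interaction fingerprints (IFPs)**, condense them into a consensus
**reference fingerprint**, and re-rank each docking ensemble by Tanimoto
similarity to that reference.

## Method

For a binding site of *n* residues, each ligand pose is described by a
7-bit-per-residue binary string of length 7 *n* (308 bits for the 44-residue
CAII site). The seven flags per residue, in fixed order, are:

1. H-bond (ligand as acceptor)
2. H-bond (ligand as donor)
3. hydrophobic contact
4. π–π stacking
5. T-stacking
6. cation–π interaction
7. salt bridge

Flags are set by purely geometric rules: donor–acceptor distance ≤ 3.5 Å with
a D–H···A deviation from linearity ≤ 50°; carbon–carbon contacts ≤ 4.0 Å
between apolar carbons; ring-centroid distance, plane angle and perimeter
projection for stacking; distance cutoffs between charged centers and ring
centroids for cation–π and salt bridges. Every cutoff is configurable
(`GeometryConfig`, YAML-serialisable).

The reference fingerprint over a training set of complexes keeps a bit only
when at least `min_support` complexes (default 3) show that interaction;
rarer bits are treated as noise. A pose with fingerprint *A* is scored
against the reference *B* by the Tanimoto coefficient

    Tc-IFP = |A ∩ B| / (|A| + |B| − |A ∩ B|)

and the pose with the highest Tc-IFP is selected. Selection quality is
summarised by **aRMSD** (mean heavy-atom RMSD of selected poses versus the
crystallographic pose, symmetry-corrected through bond-graph automorphisms)
and **NLRD** (fraction of ligands whose selected pose has RMSD strictly below
2.0 Å). Ligands can further be grouped by all-pairs fingerprint similarity
with complete-linkage clustering at a Tc threshold of 0.40, which guarantees
every within-cluster pair exceeds the threshold.

A synthetic-fixture module generates toy receptor/ligand systems with planted,
exactly known interactions, perturbed pose ensembles and whole training
families, so the entire pipeline is testable without any structure download.

## Worked example

```python
import numpy as np
from caifp import (FixtureSpec, make_training_set, make_pose_ensemble,
                   detect_interactions, encode_fingerprint, rescore_pose_set, evaluate)
from caifp.fingerprints import build_reference

spec = FixtureSpec(seed=0, site_size=6, planted_interactions=[
    [(0, "hbond_acceptor"), (2, "hydrophobic"), (3, "pi_pi"), (4, "salt_bridge")]])
ts = make_training_set(spec)
native = ts.ligands[0]

profile = detect_interactions(ts.receptor, native, ts.site)
fp = encode_fingerprint(profile, ts.site, label="native")
print("fingerprint length:", len(fp), "bits on:", [int(i) for i in np.flatnonzero(fp.bits)])

ref = build_reference([fp], min_support=1)
poses, rmsds = make_pose_ensemble(native, 50, 1.5, seed=42, include_native=True)
result = rescore_pose_set(poses, ts.receptor, ts.site, ref)
print("best pose:", result.best_pose_index,
      "Tc-IFP: %.3f" % result.scores[result.best_pose_index],
      "RMSD: %.3f A" % rmsds[result.best_pose_index])

stats = evaluate([rmsds[i] for i in result.ranking[:10]], threshold=2.0)
print("aRMSD %.2f A, NLRD %.1f%% over the 10 top-ranked poses"
      % (stats.arms_d, stats.nlrd_percent))
```

Output:

```
fingerprint length: 42 bits on: [0, 16, 24, 34]
best pose: 0 Tc-IFP: 1.000 RMSD: 0.000 A
aRMSD 2.82 A, NLRD 30.0% over the 10 top-ranked poses
```

The six-residue site gives a 42-bit fingerprint; the four on-bits are the
four planted interactions (bit 7·i + j for interaction j at residue i). With
the native pose's own fingerprint as reference, rescoring a 50-pose jittered
ensemble that contains the native recovers the native at Tc-IFP = 1.0 and
RMSD 0; the aRMSD/NLRD summary then quantifies the quality of the ten
best-ranked poses.

The same pipeline is available from the shell: `caifp simulate`,
`derive-site`, `fingerprint`, `build-ref`, `rescore`, `evaluate`, `cluster`
(see `caifp --help`).

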