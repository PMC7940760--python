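# soltemp

Replica exchange with solute tempering (REST2) on decomposable toy
Hamiltonians, together with the complete trajectory-analysis pipeline used to
characterise an intrinsically disordered peptide binding a globular,
multi-domain receptor: DSSP-style secondary-structure assignment, RMSD
conformational clustering, density-based binding-pose clustering, and
contact / salt-bridge / hydrogen-bond analytics.  Every analysis stage is
validated against synthetic ensembles with planted, audited ground truth.

The package is aimed at people who work with enhanced-sampling simulations
of disordered peptides (amyloid-β and its relatives) and want either a
self-contained, testable implementation of the REST2 bookkeeping, or a
reference implementation of the standard analysis stack that can be checked
against data where the right answer is known by construction.

## The model

**Solute tempering.**  The potential energy of a solvated system is
decomposed into the solute internal energy *E*<sub>pp</sub>, the
solute–solvent interaction *E*<sub>pw</sub> and the solvent self-energy
*E*<sub>ww</sub>.  Replica *i* runs at the common bath temperature
*T*<sub>0</sub> on the deformed surface

> *E*<sub>i</sub> = λ<sub>i</sub> *E*<sub>pp</sub> + λ<sub>i</sub> *E*<sub>pw</sub> + *E*<sub>ww</sub>,  λ<sub>i</sub> = *T*<sub>0</sub>/*T*<sub>eff,i</sub>,

which is equivalent to heating the solute to the effective temperature
*T*<sub>eff,i</sub> while the solvent stays cold.  (The canonical REST2
derivation scales *E*<sub>pw</sub> by √λ instead; both variants are
available through `pw_exponent`.)  The effective-temperature ladder is
geometric: *T*<sub>i</sub> = *T*<sub>0</sub>(*T*<sub>max</sub>/*T*<sub>0</sub>)<sup>i/(n−1)</sup>.
Neighbouring replicas attempt Metropolis exchanges with

> Δ = [*E*<sub>i</sub>(x<sub>j</sub>) + *E*<sub>j</sub>(x<sub>i</sub>)] − [*E*<sub>i</sub>(x<sub>i</sub>) + *E*<sub>j</sub>(x<sub>j</sub>)],  p = min(1, e<sup>−β₀Δ</sup>),

in which *E*<sub>ww</sub> cancels algebraically, so acceptance depends only
on solute-related terms — the property that makes partial tempering cheap
for large systems, and one the test suite checks to machine precision.
The replica-exchange driver is exercised on a toy system (harmonic-bond
solute chain + Lennard-Jones solvent, Metropolis Monte Carlo propagation)
that satisfies the same energy-decomposition contract.

**Analysis.**  Secondary structure follows the Kabsch–Sander recipe: amide
hydrogens are reconstructed on the backbone, hydrogen bonds are scored with
*E* = 0.084·(1/r<sub>ON</sub> + 1/r<sub>CH</sub> − 1/r<sub>OH</sub> −
1/r<sub>CN</sub>)·332 kcal/mol (bond if *E* < −0.5), and bridges, ladders,
helices, turns and bends give per-residue labels {E, B, H, T, S, C}.
Conformational clustering is the neighbour-count algorithm behind
`gmx cluster` at a 0.2 nm backbone-RMSD cutoff; binding poses are ligand
centre-of-mass points after receptor superposition, partitioned with
DBSCAN.  A contact is two heavy atoms within 5.4 Å; binding propensity is
the fraction of frames a residue contacts the partner; a salt bridge is an
acidic-side-chain oxygen within 4 Å of a basic-side-chain nitrogen.
Conserved β-regions group residues that form strands in more than two
cluster representatives.

## Worked example

```python
import numpy as np
from soltemp.rest2 import LadderSpec, make_ladder
from soltemp.synthetic_traj import SynthConfig, generate_ensemble, build_receptor_topology
from soltemp.secondary_structure import assign_trajectory, ss_content, residue_beta_profile
from soltemp.clustering import pose_points, pose_cluster

print(", ".join(f"{t:.1f}" for t in make_ladder(LadderSpec(300.0, 600.0, 16))))
# 300.0, 314.2, 329.0, 344.6, 360.9, 378.0, 395.9, 414.6, 434.2, 454.7,
# 476.2, 498.7, 522.3, 547.0, 572.9, 600.0

cfg = SynthConfig(n_frames=200, seed=11)     # hairpin planted in half the frames
traj, truth = generate_ensemble(cfg)

ss = assign_trajectory(traj, chain="ligand")
print(ss_content(ss))
# {'coil': 0.689, 'beta_sheet': 0.182, 'bridge': 0.0, 'helix': 0.0,
#  'turn': 0.0, 'bend': 0.13}
profile, mean = residue_beta_profile(ss)
print(round(profile[16], 3), round(truth.beta_labels[:, 16].mean(), 3))
# 0.545 0.545    <- recovered beta probability at L17 equals the planted one

_, rec = build_receptor_topology()
ref = np.vstack([np.zeros((traj.n_atoms - rec.shape[0], 3)), rec])
points = pose_points(traj, reference_frame=ref)
poses = pose_cluster(points, eps=3.0, min_samples=8)
print(len(poses.centers), np.round(poses.populations, 3))
# 5 [0.325 0.16  0.2   0.08  0.175]   <- all five planted binding sites
```

The 16-rung ladder spans 300–600 K with λ from 1.0 down to 0.5; the
secondary-structure content of the synthetic ensemble reflects the planted
hairpin (14 of 42 residues in strands, present in roughly half the frames,
hence a β-sheet content near 0.5 × 14/42 ≈ 0.17); and DBSCAN on the
superposed centre-of-mass cloud finds exactly the five planted binding
sites with their configured weights.

A command-line interface mirrors the library (`soltemp ladder`,
`soltemp synth`, `soltemp ss`, `soltemp cluster`, `soltemp poses`,
`soltemp contacts`, `soltemp saltbridges`, `soltemp regions`,
`soltemp report` for a YAML-configured end-to-end run with a checksummed
manifest).

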