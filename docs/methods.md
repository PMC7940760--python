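# Methods

This note records the models, parameter choices and numerical decisions
behind `soltemp`, and what the synthetic validation does and does not
establish about real data.

## Solute-tempering machinery

The REST2 bookkeeping operates on an energy decomposition
(Epp, Epw, Eww) and a geometric effective-temperature ladder
`T_i = T0 * (Tmax/T0)**(i/(n-1))`.  Endpoints are set exactly
(the closed form already yields them to machine precision; pinning them
avoids spurious last-digit drift for extreme ratios).  `lambda = T0/T_eff`
is restricted to (0, 1]: a replica colder than the bath is rejected as a
specification error rather than extrapolated.

The deformed potential is `lam*Epp + lam**pw * Epw + Eww`.  `pw = 1`
(lambda on both scaled terms) is the default; `pw = 0.5` gives the
canonical REST2 deformation in which the solute–solvent term is scaled by
sqrt(lambda).  The choice changes the ladder's overlap properties but not
any of the bookkeeping, so it is a plain flag.

Exchange swaps rung assignments (lambda values), not coordinates — the two
conventions generate identical chains and the rung swap is cheaper.
Neighbour attempts alternate between even pairs (0–1, 2–3, …) and odd
pairs (1–2, 3–4, …), the standard scheme when nothing else is specified.
The acceptance probability is computed from the solute-related terms only;
because Eww enters every replica unscaled it cancels identically in Delta,
and a test drives this with solvent energies five orders of magnitude
larger than the solute terms (the reference value is accumulated in
extended precision so the check measures the implementation, not the
oracle's rounding).

Boltzmann's constant is 0.0083144621 kJ/mol/K for physical-unit ladders;
the toy systems use reduced units with kB = 1 throughout, which removes
unit bookkeeping from every statistical test.

Diagnostics: per-replica dwell-time fractions (rows sum to 1; the
cross-replica mean at each rung is exactly 1/n because occupancy is a
permutation at every step — 6.25% for 16 replicas), mean exchange
acceptance, and completed bottom–top–bottom round trips.

## Toy Hamiltonians

The propagated system is a solute bead chain (harmonic bonds
`k/2 (r - r0)^2` between consecutive beads, truncated unshifted
Lennard-Jones between non-bonded bead pairs) in a Lennard-Jones solvent
bath, periodic cubic box, minimum image.  Defaults: 10 solute beads, 100
solvent beads, box 10 sigma, k = 100 eps/sigma^2, r0 = sigma = eps = 1,
cutoff 2.5 sigma, displacement moves of 0.1 sigma, one attempted move per
bead per sweep.  Truncation without shifting keeps the decomposition
exactly additive; the discontinuity at the cutoff is irrelevant for
Metropolis sampling.  Single-bead moves are deliberate — correctness and
auditability over speed at desk scale.

Solute moves are accepted on `lam*dEpp + lam**pw*dEpw`, solvent moves on
`lam**pw*dEpw + dEww`, both with `exp(-dE/T0)`.  For a two-bead harmonic
dimer this makes the sampled bond-length variance `kB*(T0/lam)/k` — the
operational meaning of "heating the solute to T0/lambda" — and the
statistical tests verify the 1/lambda scaling at lambda in {1, 0.75, 0.5}
over 1e5 sweeps (1D dimer, so the closed form is exact; in 3D the r^2
Jacobian would bias the variance at the percent level).  The cached energy
decomposition is updated incrementally on accepted moves and resynchronised
against a full recomputation every 1000 sweeps; a consistency test bounds
the drift at 1e-9.

Statistical checks use deliberately small systems where the result is
analytically forced or the estimator converges quickly: dwell-fraction
conservation holds for any run, so it is demonstrated with a solvent-free
dimer at 16 rungs and 1e4 sweeps; the detailed-balance check uses a
discrete two-state solute where the Boltzmann weights are exact.

## Synthetic ensembles with planted ground truth

The generator emulates the data layout of a solute-tempering study of a
42-residue disordered peptide (sequence DAEFRHDSGY EVHHQKLVFF AEDVGSNKGA
IIGLMVGGVV IA) binding a rigid multi-domain receptor.  Reduced topology:
backbone N, CA, C, O plus one side-chain tip pseudo-atom per non-glycine
residue, typed by residue class (acidic O, basic N, polar O, hydrophobic
C); the receptor is three 20-residue lobes (CA + tip per residue) on
spheres of radius 10 Å whose centres are 40 Å apart — a deliberately
unphysical bead cloud that is rigid across frames, which is the property
the superposition-based pose analysis actually relies on.

Hairpin geometry: two antiparallel strands along ±x with a 3.45 Å rise,
carbonyls alternating along the ±y inter-strand axis, strand lines 4.13 Å
apart so donor–acceptor N···O distances are 2.9 Å and every cross-strand
Kabsch–Sander pair scores about −2.9 kcal/mol — nearly six times the bond
threshold, so 0.05 Å coordinate noise cannot flip an assignment.  One
anchor residue preceding each strand sits on the strand line so the first
strand residue has a correctly oriented amide hydrogen.  Non-strand
residues follow a wide arc 12 Å above the sheet plane with carbonyls
alternating out of plane; this produces no β structure.  Defaults plant
one hairpin over L17–D23 / A30–V36 (the classic aggregation-prone pairing)
with probability 0.5 per frame.

Poses: five sites on the receptor surface with weights
0.30/0.25/0.20/0.15/0.10 and 1 Å positional spread, pairwise separations
at least 31 Å; 4% of frames are unbound, placed at 90–130 Å so the
20 Å unbound margin is unambiguous against the 5.4 Å contact cutoff.
The peptide is randomly oriented each frame and placed by mass-weighted
centre of mass, so the pose observable (ligand COM after receptor
superposition) recovers the planted site centres exactly up to the drawn
noise.  Planted salt bridges (defaults: K28 and K16 to acidic receptor
residues, probabilities 0.5 and 0.3, bound frames only) are realised by
moving the ligand side-chain tip within 3.2 Å of the receptor tip — a
label-level construction, not side-chain physics.

Every frame is audited against the emitted coordinates before it is
accepted: the secondary-structure assignment must reproduce the planted
β set exactly, unbound frames must be ≥ 20 Å from the receptor, and forced
bridges must satisfy the 4 Å predicate.  Contact ground truth is the
geometric 5.4 Å predicate evaluated at generation time.  Identical
configuration and seed give bitwise-identical coordinates.

What passing these tests shows: the analysis operators implement their
definitions correctly and recover planted signal at the configured noise
level.  What it does not show: robustness to real backbone geometry
(imperfect strands, bulges, PP-II), side-chain rotamer effects, receptor
flexibility, or force-field-dependent quantities — none of which the
generator models.

## Analysis pipeline

Secondary structure: Kabsch–Sander energy with H reconstructed 1.0 Å from
N along the reversed C(i−1)→O(i−1) direction; the first residue of a chain
is never a donor; bonds with immediate sequence neighbours are excluded;
bridges need |i−j| ≥ 3; adjacent bridges of the same type form ladders (E),
isolated bridges give B, two consecutive i→i+4 turns give H (all helix
classes collapse to H), single i→i+3/4/5 turns give T, CA angles above 70°
give S; priority E > B > H > T > S > C; residues with missing backbone
atoms are coil.  "β-sheet" content counts E only; folding B in is a flag,
since sheet-vs-bridge is precisely the distinction per-residue β profiles
rely on.

Superposition is Kabsch via SVD with determinant correction; pairwise RMSD
matrices reuse the singular values directly.  The neighbour-count (Daura)
clustering breaks ties toward the lowest frame index.  DBSCAN is delegated
to scikit-learn behind the module surface; the tests compare it against an
explicit density-reachability oracle.  DBSCAN defaults (eps 3 Å,
min_samples 20) are declared choices, not inferred ones.

Contacts/propensity use all frames in the denominator ("percentage of
snapshots").  Salt bridges use side-chain O/N atoms only; histidine is
treated as neutral-polar (standard protonation at pH 7), and terminal
amine/carboxylate participation is available behind a flag (off by
default) because a reported D1 bridge is ambiguous between side chain and
terminus.  Hydrogen bonds use 3.5 Å donor–acceptor distance and a 30°
H–donor–acceptor angle — the common MD-tool default.

β regions: a residue qualifies when it forms a strand in at least
`region_min_clusters` (default 3, i.e. "more than two") of the per-cluster
representatives; maximal runs of qualifying residues become regions, and a
gap of at most one residue is bridged only when the gap residue itself has
strand evidence in at least one cluster.  The support condition is the
package's resolution of a genuine ambiguity: unconditional single-gap
merging reproduces regions that break at a single residue (Q15–V24) but
would also fuse the two regions separated only by H14, which the
region decomposition treats as a hard separator because that residue never
forms a strand.  Sheet association between two regions in a frame requires
at least two backbone hydrogen bonds connecting E-labelled residues — one
bond is the module's reading of where a "dashed connection" between
strands becomes real pairing, and two is the minimum for a ladder.

RMSF is the per-residue CA fluctuation about the mean structure after
least-squares fitting each frame to the reference on a selection.

## CLI and reproducibility

Each pipeline stage derives its RNG seed from the global seed by stable
stage-name hashing (CRC32), so inserting a stage never perturbs the
randomness of the others.  The manifest (inputs, versions, per-stage seeds,
SHA-256 checksums of every output) is written even when a stage fails,
with the failure recorded.  Re-running an identical configuration and seed
reproduces all outputs bitwise.

## Problem sizes

The validation sizes are chosen so every statistical band is comfortably
resolved: 1000-frame ensembles for parameter recovery (binomial 3σ bands
of a few percent), 1e5 Monte-Carlo sweeps for the dimer variance (5%
band), 1e4 sweeps for replica-exchange diagnostics, and ≤ 200-point
instances for brute-force clustering oracles (the oracles are quadratic to
cubic and exist only to certify the production implementations).

## Known limitations

* The toy propagator is Metropolis Monte Carlo; there is no molecular
  dynamics, thermostat or barostat, and no claim that toy acceptance rates
  transfer to all-atom systems.
* The printed 16-rung ladder of the motivating study deviates from exact
  geometric spacing by a few tenths of a kelvin at some rungs (the
  generating script is unspecified there); the geometric formula is taken
  as the definition and only rungs where rounding agrees are used as
  anchors.
* The Kabsch–Sander implementation covers the label classes {E, B, H, T,
  S, C} with 4-helices only; 3-10/π helices are absorbed into H, which is
  adequate for β-statistics but not for helix sub-typing.
* Hydrogen-bond detection on reduced topologies reconstructs backbone
  amides and assumes side-chain tip donors point along CA→tip; on
  full-atom inputs with explicit hydrogens this approximation is not
  replaced automatically.
* The force-field interaction energies between peptide and receptor
  (electrostatic/van der Waals decompositions) are out of scope; the toy
  Hamiltonians provide their own decomposable energies instead.
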