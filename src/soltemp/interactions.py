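"""Contact, binding-propensity, salt-bridge, H-bond and beta-region analytics.

Definitions:

* contact: two heavy atoms of different residues within 5.4 A;
* binding propensity: fraction of frames in which a residue has at least one
  heavy-atom contact with the partner chain;
* salt bridge: any side-chain oxygen of an acidic residue within 4 A of any
  side-chain nitrogen of a basic residue (histidine counts as neutral-polar
  at pH 7; terminal amine/carboxylate participation is available behind a
  flag and off by default);
* hydrogen bond: donor-acceptor heavy atoms within 3.5 A and an
  H-donor-acceptor angle of at most 30 degrees, with backbone amide
  hydrogens reconstructed as for the secondary-structure assignment;
* beta region: a maximal run (single-residue gaps merged) of residues that
  form beta strands in more than two of the per-cluster representative
  conformations, labelled beta1, beta2, ... from N to C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_model import SelectionError, Topology, Trajectory

__all__ = [
    "AnalysisConfig",
    "ContactMatrix",
    "BetaRegion",
    "residue_contact",
    "contact_map",
    "binding_propensity",
    "salt_bridges",
    "hydrogen_bonds",
    "beta_regions",
    "sheet_associations",
    "rmsf",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Distance and counting thresholds of the interaction analytics."""

    contact_cutoff: float = 5.4       # A, heavy-atom contact
    saltbridge_cutoff: float = 4.0    # A, acidic O to basic N
    hbond_distance: float = 3.5       # A, donor-acceptor heavy atoms
    hbond_angle: float = 30.0         # degrees, H-donor-acceptor
    region_min_clusters: int = 3      # "more than 2 clusters"
    include_termini_saltbridge: bool = False

    def __post_init__(self):
        if min(self.contact_cutoff, self.saltbridge_cutoff,
               self.hbond_distance, self.hbond_angle,
               self.region_min_clusters) <= 0:
            raise ValueError("analysis thresholds must be positive")


@dataclass
class ContactMatrix:
    """Residue-pair contact probabilities over frames (symmetric)."""

    probabilities: np.ndarray
    residues: np.ndarray

    def __post_init__(self):
        p = self.probabilities
        if not np.allclose(p, p.T):
            raise ValueError("contact matrix must be symmetric")


@dataclass(frozen=True)
class BetaRegion:
    """A labelled inclusive residue range, e.g. beta3 spanning Q15-V24."""

    label: str
    start: int  # 0-based inclusive
    end: int    # 0-based inclusive


def _residue_heavy_atoms(topology: Topology, residues):
    """List of heavy-atom index arrays, one per residue (error if none)."""
    out = []
    for r in residues:
        idx = topology.residue_atoms(int(r))
        heavy = idx[topology.is_heavy[idx]]
        if heavy.size == 0:
            raise SelectionError(f"residue {r} has no heavy atoms")
        out.append(heavy)
    return out


def _min_distance_matrix(frame, topology, residues_a, residues_b):
    """Minimum heavy-atom distance for every residue pair (A x B)."""
    heavy_a = _residue_heavy_atoms(topology, residues_a)
    heavy_b = _residue_heavy_atoms(topology, residues_b)
    all_a = np.concatenate(heavy_a)
    all_b = np.concatenate(heavy_b)
    d = cdist(frame[all_a], frame[all_b])
    out = np.empty((len(residues_a), len(residues_b)))
    ia = 0
    for i, ha in enumerate(heavy_a):
        ib = 0
        for j, hb in enumerate(heavy_b):
            out[i, j] = d[ia:ia + len(ha), ib:ib + len(hb)].min()
            ib += len(hb)
        ia += len(ha)
    return out


def residue_contact(frame, topology: Topology, residues_a, residues_b,
                    cutoff: float = 5.4) -> np.ndarray:
    """Boolean contact matrix: min heavy-atom distance <= cutoff."""
    return _min_distance_matrix(frame, topology, residues_a,
                                residues_b) <= cutoff


def contact_map(traj: Trajectory, chain=None,
                config: AnalysisConfig = AnalysisConfig()) -> ContactMatrix:
    """Per-pair fraction of frames in contact (diagonal reported as 1)."""
    top = traj.topology
    if chain is not None:
        if chain in set(top.chain_roles.values()):
            chain = top.chain_by_role(chain)
        residues = top.chain_residues(chain)
    else:
        residues = np.arange(top.n_residues)
    n = len(residues)
    acc = np.zeros((n, n))
    for f in range(traj.n_frames):
        acc += residue_contact(traj.xyz[f], top, residues, residues,
                               config.contact_cutoff)
    prob = acc / traj.n_frames
    np.fill_diagonal(prob, 1.0)
    return ContactMatrix(probabilities=prob, residues=np.asarray(residues))


def binding_propensity(traj: Trajectory, ligand_chain="ligand",
                       receptor_chain="receptor",
                       config: AnalysisConfig = AnalysisConfig()):
    """Per-residue fraction of frames in contact with the partner chain.

    Returns ``(ligand_profile, ligand_mean, receptor_profile,
    receptor_mean)``; the means are the horizontal reference lines of
    binding-probability plots.  The denominator is all frames.
    """
    top = traj.topology
    lig = top.chain_residues(top.chain_by_role(ligand_chain)
                             if ligand_chain in set(top.chain_roles.values())
                             else ligand_chain)
    rec = top.chain_residues(top.chain_by_role(receptor_chain)
                             if receptor_chain in set(top.chain_roles.values())
                             else receptor_chain)
    lig_hits = np.zeros(len(lig))
    rec_hits = np.zeros(len(rec))
    for f in range(traj.n_frames):
        c = residue_contact(traj.xyz[f], top, lig, rec,
                            config.contact_cutoff)
        lig_hits += c.any(axis=1)
        rec_hits += c.any(axis=0)
    lig_prof = lig_hits / traj.n_frames
    rec_prof = rec_hits / traj.n_frames
    return lig_prof, float(lig_prof.mean()), rec_prof, float(rec_prof.mean())


def _sb_atoms(topology: Topology, residues, config: AnalysisConfig):
    """(acidic oxygen atoms, basic nitrogen atoms) per residue.

    Side-chain atoms only: backbone carbonyl/amide atoms never form the
    salt bridges considered here.  With ``include_termini_saltbridge`` the
    N-terminal backbone nitrogen counts as basic and the C-terminal
    carbonyl oxygen as acidic.
    """
    acidic = {}
    basic = {}
    for r in residues:
        r = int(r)
        idx = topology.residue_atoms(r)
        side = idx[~topology.is_backbone[idx]]
        cls = topology.residue_classes[r]
        if cls == "acidic":
            ox = side[topology.elements[side] == "O"]
            if ox.size:
                acidic[r] = ox
        elif cls == "basic":
            ni = side[topology.elements[side] == "N"]
            if ni.size:
                basic[r] = ni
    if config.include_termini_saltbridge and len(residues):
        chain_first, chain_last = int(residues[0]), int(residues[-1])
        idx = topology.residue_atoms(chain_first)
        n_at = idx[topology.atom_names[idx] == "N"]
        if n_at.size:
            basic.setdefault(chain_first, np.empty(0, dtype=int))
            basic[chain_first] = np.union1d(basic[chain_first], n_at)
        idx = topology.residue_atoms(chain_last)
        o_at = idx[topology.atom_names[idx] == "O"]
        if o_at.size:
            acidic.setdefault(chain_last, np.empty(0, dtype=int))
            acidic[chain_last] = np.union1d(acidic[chain_last], o_at)
    return acidic, basic


def salt_bridges(frame, topology: Topology, residues_a=None, residues_b=None,
                 config: AnalysisConfig = AnalysisConfig()):
    """Salt bridges in one frame: (acidic residue, basic residue, min O-N A).

    ``residues_a`` / ``residues_b`` restrict the search (e.g. one chain
    each for intermolecular bridges); by default all residues are
    considered, which includes intramolecular bridges.
    """
    all_res = np.arange(topology.n_residues)
    ra = all_res if residues_a is None else np.asarray(residues_a, int)
    rb = all_res if residues_b is None else np.asarray(residues_b, int)
    acid_a, base_a = _sb_atoms(topology, ra, config)
    acid_b, base_b = _sb_atoms(topology, rb, config)

    frame = np.asarray(frame, float)
    out = []
    seen = set()
    for acid, base in ((acid_a, base_b), (acid_b, base_a)):
        for r_acid, ox in acid.items():
            for r_base, ni in base.items():
                if r_acid == r_base or (r_acid, r_base) in seen:
                    continue
                d = cdist(frame[ox], frame[ni]).min()
                if d <= config.saltbridge_cutoff:
                    out.append((r_acid, r_base, float(d)))
                    seen.add((r_acid, r_base))
    return sorted(out)


def hydrogen_bonds(frame, topology: Topology, residues_a, residues_b,
                   config: AnalysisConfig = AnalysisConfig()):
    """Donor-acceptor hydrogen bonds between two residue groups.

    Donors are backbone amide N-H (H reconstructed along the reversed
    C(i-1)->O(i-1) direction; the first residue of a group has no donor)
    and side-chain N/O tips (H assumed along the CA->tip direction).
    Acceptors are any N or O heavy atoms.  A bond requires donor-acceptor
    distance <= ``hbond_distance`` and H-donor-acceptor angle <=
    ``hbond_angle``.  Returns ``(count, [(donor_res, acceptor_res,
    donor_atom, acceptor_atom)])``.
    """
    frame = np.asarray(frame, float)

    def donors(residues):
        """(donor atom index, H position, residue) triples."""
        out = []
        residues = [int(r) for r in residues]
        for pos, r in enumerate(residues):
            idx = topology.residue_atoms(r)
            names = topology.atom_names[idx]
            # backbone amide donor (needs the preceding residue's carbonyl)
            if pos > 0 and residues[pos - 1] == r - 1:
                prev = topology.residue_atoms(r - 1)
                pnames = topology.atom_names[prev]
                n_at = idx[names == "N"]
                c_at = prev[pnames == "C"]
                o_at = prev[pnames == "O"]
                if n_at.size and c_at.size and o_at.size:
                    d = frame[c_at[0]] - frame[o_at[0]]
                    nrm = np.linalg.norm(d)
                    if nrm > 1e-9:
                        out.append((int(n_at[0]),
                                    frame[n_at[0]] + d / nrm, r))
            # side-chain tip donor (N or O element)
            sc = idx[(~topology.is_backbone[idx])
                     & np.isin(topology.elements[idx], ["N", "O"])]
            ca = idx[names == "CA"]
            for a in sc:
                if ca.size:
                    d = frame[a] - frame[ca[0]]
                    nrm = np.linalg.norm(d)
                    if nrm > 1e-9:
                        out.append((int(a), frame[a] + d / nrm, r))
        return out

    def acceptors(residues):
        out = []
        for r in residues:
            r = int(r)
            idx = topology.residue_atoms(r)
            for a in idx[np.isin(topology.elements[idx], ["N", "O"])]:
                out.append((int(a), r))
        return out

    cos_max = np.cos(np.radians(config.hbond_angle))
    bonds = []
    for don, acc in ((donors(residues_a), acceptors(residues_b)),
                     (donors(residues_b), acceptors(residues_a))):
        for d_atom, h_pos, d_res in don:
            for a_atom, a_res in acc:
                if a_res == d_res:
                    continue
                da = frame[a_atom] - frame[d_atom]
                dist = np.linalg.norm(da)
                if dist > config.hbond_distance or dist < 1e-9:
                    continue
                dh = h_pos - frame[d_atom]
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
                if cosang >= cos_max:
                    bonds.append((d_res, a_res, d_atom, a_atom))
    return len(bonds), bonds


def beta_regions(cluster_beta_flags, region_min_clusters: int = 3,
                 max_gap: int = 1, topology: Topology = None):
    """Group residues that form beta strands in enough clusters into regions.

    ``cluster_beta_flags`` is (clusters x residues) boolean: whether the
    residue is in a beta strand in that cluster's representative
    conformation.  A residue qualifies when its count is at least
    ``region_min_clusters`` ("more than 2 clusters" with the default 3);
    maximal runs of qualifying residues with gaps of at most ``max_gap``
    residues merged become regions labelled beta1, beta2, ... N to C.
    """
    flags = np.asarray(cluster_beta_flags, dtype=bool)
    counts = flags.sum(axis=0)
    qualifying = np.nonzero(counts >= region_min_clusters)[0]
    if qualifying.size == 0:
        return []
    regions = []
    start = prev = int(qualifying[0])
    for r in qualifying[1:]:
        r = int(r)
        gap = np.arange(prev + 1, r)
        # bridge short gaps only where the gap residues carry some beta
        # evidence; a residue never seen in a strand separates regions
        if gap.size <= max_gap and np.all(counts[gap] >= 1):
            prev = r
        else:
            regions.append((start, prev))
            start = prev = r
    regions.append((start, prev))
    return [BetaRegion(label=f"beta{i + 1}", start=s, end=e)
            for i, (s, e) in enumerate(regions)]


def sheet_associations(ss_labels, hbond_pairs, regions,
                       min_hbonds: int = 2):
    """Region pairs connected by backbone H-bonds between E residues.

    ``ss_labels`` is the per-residue label array of one frame,
    ``hbond_pairs`` an iterable of (donor residue, acceptor residue)
    backbone hydrogen bonds, ``regions`` a list of :class:`BetaRegion`.
    Two regions are associated when at least ``min_hbonds`` H-bonds connect
    E-labelled residues of one to E-labelled residues of the other
    (self-pairs allowed: a region can fold back onto itself).
    """
    labels = np.asarray(ss_labels)

    def region_of(res):
        for k, reg in enumerate(regions):
            if reg.start <= res <= reg.end:
                return k
        return None

    counts = {}
    for don, acc in hbond_pairs:
        if labels[don] != "E" or labels[acc] != "E":
            continue
        a, b = region_of(don), region_of(acc)
        if a is None or b is None:
            continue
        key = (min(a, b), max(a, b))
        counts[key] = counts.get(key, 0) + 1
    return sorted(
        (regions[a].label, regions[b].label)
        for (a, b), c in counts.items() if c >= min_hbonds
    )


def rmsf(traj: Trajectory, selection="backbone", chain=None,
         reference_frame: int = 0):
    """Per-residue CA fluctuation (A) after superposing on the selection.

    Every frame is least-squares fitted to the reference frame on the
    selection; the RMSF of each residue's CA about its mean position is
    returned, along with the residue indices used.
    """
    from .clustering import superpose
    from .io_model import select

    top = traj.topology
    if isinstance(selection, str):
        fit_idx = select(top, selection, chain=chain)
    else:
        fit_idx = np.asarray(selection, dtype=int)
    if chain is not None:
        if chain in set(top.chain_roles.values()):
            chain = top.chain_by_role(chain)
        residues = top.chain_residues(chain)
    else:
        residues = np.arange(top.n_residues)
    ca_idx = []
    kept_residues = []
    for r in residues:
        idx = top.residue_atoms(int(r))
        ca = idx[top.atom_names[idx] == "CA"]
        if ca.size:
            ca_idx.append(int(ca[0]))
            kept_residues.append(int(r))
    ca_idx = np.array(ca_idx)

    ref = traj.xyz[reference_frame]
    fitted = np.empty((traj.n_frames, len(ca_idx), 3))
    for f in range(traj.n_frames):
        rot, trans, _ = superpose(traj.xyz[f][fit_idx], ref[fit_idx])
        fitted[f] = traj.xyz[f][ca_idx] @ rot.T + trans
    mean = fitted.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    return fluct, np.array(kept_residues)
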