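"""Kabsch-Sander-style secondary-structure assignment and beta statistics.

The assignment follows the DSSP recipe on backbone N, CA, C, O atoms: amide
hydrogens are reconstructed on each donor nitrogen (1.0 A along the reversed
C(i-1) -> O(i-1) direction; the first residue of a chain is never a donor),
backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
energy

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol,

with a bond whenever E < -0.5 kcal/mol, and bridges/ladders/turns/bends are
derived from the bond pattern.  Labels are {E, B, H, T, S, C} with priority
E > B > H > T > S > C; helix subtypes are collapsed into H.  Residues whose
geometry is undefined (missing backbone atoms) are coil.
"""

from __future__ import annotations

import numpy as np

from .io_model import Topology, Trajectory

__all__ = [
    "HBOND_CUTOFF_KCAL",
    "SSMatrix",
    "hbond_energy",
    "reconstruct_amide_h",
    "backbone_hbond_matrix",
    "assign_ss",
    "assign_trajectory",
    "ss_content",
    "residue_beta_profile",
    "beta_length_histogram",
]

#: Kabsch-Sander hydrogen-bond threshold, kcal/mol.
HBOND_CUTOFF_KCAL = -0.5
_KS_FACTOR = 0.084 * 332.0
_MIN_DIST = 0.5  # A; anything closer is a clash


def hbond_energy(donor_n, donor_h, acceptor_c, acceptor_o) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol) for one pair."""
    donor_n = np.asarray(donor_n, float)
    donor_h = np.asarray(donor_h, float)
    acceptor_c = np.asarray(acceptor_c, float)
    acceptor_o = np.asarray(acceptor_o, float)
    r_on = np.linalg.norm(acceptor_o - donor_n)
    r_ch = np.linalg.norm(acceptor_c - donor_h)
    r_oh = np.linalg.norm(acceptor_o - donor_h)
    r_cn = np.linalg.norm(acceptor_c - donor_n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        raise ValueError("atom clash in hydrogen-bond evaluation")
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def reconstruct_amide_h(n_pos, c_prev, o_prev):
    """Place the amide H on a donor N along the reversed C->O of residue i-1."""
    d = np.asarray(c_prev, float) - np.asarray(o_prev, float)
    norm = np.linalg.norm(d, axis=-1, keepdims=True)
    return np.asarray(n_pos, float) + d / norm


def _backbone_arrays(coordinates, topology: Topology, residues):
    """Per-residue N/CA/C/O coordinate arrays plus a validity mask."""
    coords = np.asarray(coordinates, float)
    n_res = len(residues)
    out = {name: np.full((n_res, 3), np.nan) for name in ("N", "CA", "C", "O")}
    valid = np.zeros(n_res, dtype=bool)
    for k, r in enumerate(residues):
        atom_idx = topology.residue_atoms(int(r))
        names = topology.atom_names[atom_idx]
        ok = True
        for name in ("N", "CA", "C", "O"):
            hits = atom_idx[names == name]
            if hits.size == 0:
                ok = False
                break
            out[name][k] = coords[hits[0]]
        valid[k] = ok
    return out["N"], out["CA"], out["C"], out["O"], valid


def backbone_hbond_matrix(coordinates, topology: Topology, residues=None):
    """Boolean donor x acceptor matrix of Kabsch-Sander H-bonds.

    Entry (i, j) is True when the amide of residue i donates to the carbonyl
    of residue j (E < -0.5 kcal/mol).  Residue indices are positions within
    ``residues`` (default: all residues of the topology).
    """
    if residues is None:
        residues = np.arange(topology.n_residues)
    N, CA, C, O, valid = _backbone_arrays(coordinates, topology, residues)
    n = len(residues)

    # donors: residue i >= 1 with valid geometry at i and i-1 (H needs the
    # preceding carbonyl); same-chain continuity is implied by the residue
    # ordering of the selection.
    donor_ok = valid.copy()
    donor_ok[0] = False
    donor_ok[1:] &= valid[:-1]
    H = np.full((n, 3), np.nan)
    if n > 1:
        d = C[:-1] - O[:-1]
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            H[1:] = N[1:] + d / norms

    def pdist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)

    with np.errstate(invalid="ignore"):
        r_on = pdist(N, O)
        r_cn = pdist(N, C)
        r_oh = pdist(H, O)
        r_ch = pdist(H, C)
        energy = _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)

    bonds = np.zeros((n, n), dtype=bool)
    finite = np.isfinite(energy)
    bonds[finite] = energy[finite] < HBOND_CUTOFF_KCAL
    bonds &= donor_ok[:, None]
    bonds &= valid[None, :]
    np.fill_diagonal(bonds, False)
    # no bond with the immediate sequence neighbours
    idx = np.arange(n)
    near = np.abs(idx[:, None] - idx[None, :]) < 2
    bonds &= ~near
    return bonds


def _bridges(bonds: np.ndarray):
    """(i, j, type) bridges with |i-j| >= 3; type in {'ap', 'p'}."""
    n = bonds.shape[0]

    def hb(a, b):
        return 0 <= a < n and 0 <= b < n and bonds[a, b]

    out = []
    for i in range(n):
        for j in range(i + 3, n):
            antiparallel = (hb(i, j) and hb(j, i)) or (
                hb(i - 1, j + 1) and hb(j - 1, i + 1)
            )
            parallel = (hb(i, j - 1) and hb(j + 1, i)) or (
                hb(i - 1, j) and hb(j, i + 1)
            )
            if antiparallel:
                out.append((i, j, "ap"))
            elif parallel:
                out.append((i, j, "p"))
    return out


def assign_ss(coordinates, topology: Topology, residues=None) -> np.ndarray:
    """Assign one {E,B,H,T,S,C} label per residue for a single frame."""
    if residues is None:
        residues = np.arange(topology.n_residues)
    residues = np.asarray(residues, dtype=int)
    n = len(residues)
    bonds = backbone_hbond_matrix(coordinates, topology, residues)
    _, CA, _, _, valid = _backbone_arrays(coordinates, topology, residues)

    labels = np.full(n, "C", dtype="U1")

    # --- sheets: bridges -> ladders (adjacent bridges of the same type)
    bridges = _bridges(bonds)
    if bridges:
        import collections

        adj = collections.defaultdict(list)
        for a in range(len(bridges)):
            ia, ja, ta = bridges[a]
            for b in range(a + 1, len(bridges)):
                ib, jb, tb = bridges[b]
                if ta == tb and abs(ia - ib) <= 1 and abs(ja - jb) <= 1:
                    adj[a].append(b)
                    adj[b].append(a)
        seen = set()
        for a in range(len(bridges)):
            if a in seen:
                continue
            comp = [a]
            seen.add(a)
            queue = [a]
            while queue:
                cur = queue.pop()
                for nb in adj[cur]:
                    if nb not in seen:
                        seen.add(nb)
                        comp.append(nb)
                        queue.append(nb)
            members = {bridges[k][0] for k in comp} | {
                bridges[k][1] for k in comp
            }
            label = "E" if len(comp) > 1 else "B"
            for r in members:
                if label == "E" or labels[r] == "C":
                    labels[r] = label

    # --- helix: two consecutive i -> i+4 turns
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        turn4[i] = bonds[i + 4, i]  # donor i+4 -> acceptor i (DSSP's i,i+4)
    for i in range(1, n - 4):
        if turn4[i] and turn4[i - 1]:
            for r in range(i + 1, i + 5):
                if labels[r] == "C":
                    labels[r] = "H"

    # --- turns: any single i -> i+3/4/5 bond marks the spanned residues
    for delta in (3, 4, 5):
        for i in range(n - delta):
            if bonds[i + delta, i]:
                for r in range(i + 1, i + delta):
                    if labels[r] == "C":
                        labels[r] = "T"

    # --- bend: CA angle over (i-2, i, i+2) above 70 degrees
    for i in range(2, n - 2):
        if not (valid[i - 2] and valid[i] and valid[i + 2]):
            continue
        v1 = CA[i] - CA[i - 2]
        v2 = CA[i + 2] - CA[i]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) > 70.0 and labels[i] == "C":
            labels[i] = "S"

    labels[~valid] = "C"
    return labels


class SSMatrix:
    """frames x residues secondary-structure labels, each in {E,B,H,T,S,C}."""

    CLASSES = ("E", "B", "H", "T", "S", "C")

    def __init__(self, labels):
        self.labels = np.asarray(labels, dtype="U1")
        if self.labels.ndim != 2:
            raise ValueError("labels must be frames x residues")
        bad = ~np.isin(self.labels, self.CLASSES)
        if np.any(bad):
            raise ValueError(f"invalid labels: {np.unique(self.labels[bad])}")

    @property
    def n_frames(self):
        return self.labels.shape[0]

    @property
    def n_residues(self):
        return self.labels.shape[1]

    def to_strings(self):
        return ["".join(row) for row in self.labels]


def assign_trajectory(traj: Trajectory, chain=None) -> SSMatrix:
    """Assign secondary structure for every frame of a trajectory."""
    top = traj.topology
    if chain is not None:
        if chain in set(top.chain_roles.values()):
            chain = top.chain_by_role(chain)
        residues = top.chain_residues(chain)
    else:
        residues = np.arange(top.n_residues)
    rows = [assign_ss(traj.xyz[f], top, residues)
            for f in range(traj.n_frames)]
    return SSMatrix(np.array(rows))


def ss_content(ss: SSMatrix, include_bridge_in_beta: bool = False) -> dict:
    """Average probability of each secondary-structure content.

    Returns fractions over frames x residues for coil, beta-sheet, bridge,
    helix, turn and bend; the fractions sum to 1.  ``include_bridge_in_beta``
    folds isolated bridges (B) into the beta-sheet figure.
    """
    flat = ss.labels.ravel()
    n = flat.size
    frac = {c: float(np.sum(flat == c)) / n for c in SSMatrix.CLASSES}
    beta = frac["E"] + (frac["B"] if include_bridge_in_beta else 0.0)
    return {
        "coil": frac["C"],
        "beta_sheet": beta,
        "bridge": 0.0 if include_bridge_in_beta else frac["B"],
        "helix": frac["H"],
        "turn": frac["T"],
        "bend": frac["S"],
    }


def residue_beta_profile(ss: SSMatrix, include_bridge: bool = False):
    """Per-residue beta-sheet probability and its mean over residues.

    The mean is the horizontal reference line drawn through residue-specific
    beta profiles.
    """
    is_beta = ss.labels == "E"
    if include_bridge:
        is_beta |= ss.labels == "B"
    profile = is_beta.mean(axis=0)
    return profile, float(profile.mean())


def beta_length_histogram(ss: SSMatrix) -> dict:
    """Distribution of maximal E-run lengths over all frames.

    Returns ``{length: probability}`` normalised over all runs observed.
    """
    counts = {}
    for row in ss.labels:
        run = 0
        for lab in list(row) + ["C"]:
            if lab == "E":
                run += 1
            elif run:
                counts[run] = counts.get(run, 0) + 1
                run = 0
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(counts.items())}
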