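"""Superposition, RMSD, conformational clustering and pose clustering.

Conformational clustering uses the iterative neighbour-count algorithm of
Daura et al. (the one behind ``gmx cluster``): the frame with the most
neighbours within an RMSD cutoff becomes a cluster centre, it and its
neighbours are removed, and the procedure repeats.  Binding poses (ligand
centre-of-mass points after superposing the receptor onto a reference frame)
are partitioned with DBSCAN; unassigned points are noise (label -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import SelectionError, Topology, Trajectory, center_of_mass, select

__all__ = [
    "ClusterResult",
    "superpose",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "pose_points",
    "dbscan",
]


@dataclass
class ClusterResult:
    """Cluster labels, representative centres and population fractions.

    For conformational clustering ``centers`` holds representative frame
    indices and every frame is assigned; for pose clustering ``centers``
    holds centroid points and label -1 marks noise (excluded from the
    populations, which therefore sum to <= 1).
    """

    labels: np.ndarray
    centers: list
    populations: np.ndarray


def superpose(mobile, reference, indices=None):
    """Least-squares rigid superposition (Kabsch) of two coordinate sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` on the
    selected atoms; a proper rotation is enforced by determinant correction.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if indices is not None:
        sel_m = mobile[np.asarray(indices, int)]
        sel_r = reference[np.asarray(indices, int)]
    else:
        sel_m, sel_r = mobile, reference
    if sel_m.shape != sel_r.shape or sel_m.shape[0] < 3:
        raise ValueError("superposition needs >= 3 matched atoms")

    cm = sel_m.mean(axis=0)
    cr = sel_r.mean(axis=0)
    a = sel_m - cm
    b = sel_r - cr
    if np.linalg.matrix_rank(a) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")

    cov = a.T @ b
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    moved = a @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rotation, translation, rmsd


def pairwise_rmsd_matrix(traj: Trajectory, atom_indices) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs (A) on a selection."""
    atom_indices = np.asarray(atom_indices, int)
    coords = traj.xyz[:, atom_indices, :]
    n = traj.n_frames
    # centre once; RMSD after optimal rotation via the Kabsch singular values
    centred = coords - coords.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", centred, centred)
    mat = np.zeros((n, n))
    for i in range(n):
        a = centred[i]
        for j in range(i + 1, n):
            b = centred[j]
            cov = a.T @ b
            u, s, vt = np.linalg.svd(cov)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            s[-1] *= d
            msd = (sq[i] + sq[j] - 2.0 * s.sum()) / a.shape[0]
            mat[i, j] = mat[j, i] = np.sqrt(max(msd, 0.0))
    return mat


def gromos_cluster(traj: Trajectory, selection="backbone", cutoff: float = 2.0,
                   chain=None, rmsd_matrix=None) -> ClusterResult:
    """Neighbour-count (Daura) clustering at an RMSD cutoff in Angstroms.

    The conventional cutoff for backbone clustering is 0.2 nm = 2.0 A.
    Ties in neighbour counts are broken towards the lowest frame index so
    the partition is deterministic.
    """
    if rmsd_matrix is None:
        if isinstance(selection, str):
            atom_indices = select(traj.topology, selection, chain=chain)
        else:
            atom_indices = np.asarray(selection, int)
        rmsd_matrix = pairwise_rmsd_matrix(traj, atom_indices)
    n = rmsd_matrix.shape[0]
    neighbors = rmsd_matrix <= cutoff
    np.fill_diagonal(neighbors, True)

    labels = np.full(n, -1, dtype=int)
    centers = []
    remaining = np.ones(n, dtype=bool)
    cluster_id = 0
    while remaining.any():
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbors[center] & remaining)[0]
        labels[members] = cluster_id
        centers.append(center)
        remaining[members] = False
        cluster_id += 1

    populations = np.array(
        [np.sum(labels == c) / n for c in range(cluster_id)]
    )
    return ClusterResult(labels=labels, centers=centers,
                         populations=populations)


def pose_points(traj: Trajectory, reference_frame=0,
                receptor_chain="receptor", ligand_chain="ligand",
                geometric: bool = False) -> np.ndarray:
    """Ligand COM per frame after superposing the receptor backbone.

    Every frame is superposed onto the reference (a frame index, default
    the starting structure, or an explicit (n_atoms, 3) coordinate array)
    using the receptor backbone atoms; the resulting rigid transform is
    applied to all atoms and the (mass-weighted by default) ligand centre
    of mass is returned.
    """
    top = traj.topology
    rec_idx = select(top, "backbone", chain=receptor_chain)
    lig_idx = select(top, "all", chain=ligand_chain)
    if np.ndim(reference_frame) == 2:
        ref = np.asarray(reference_frame, float)
    else:
        ref = traj.xyz[int(reference_frame)]
    points = np.empty((traj.n_frames, 3))
    for f in range(traj.n_frames):
        frame = traj.xyz[f]
        rot, trans, _ = superpose(frame[rec_idx], ref[rec_idx])
        moved = frame @ rot.T + trans
        points[f] = center_of_mass(moved, top.masses, lig_idx,
                                   geometric=geometric)
    return points


def dbscan(points, eps: float = 3.0, min_samples: int = 20) -> np.ndarray:
    """Density-based clustering of pose points; label -1 marks noise.

    A core point has at least ``min_samples`` points (itself included)
    within ``eps``; clusters are the connected components of core points
    plus any border points they reach.  Implemented with scikit-learn,
    whose border-point assignment (first reaching cluster in scan order)
    is deterministic for a fixed input ordering.
    """
    from sklearn.cluster import DBSCAN

    points = np.asarray(points, float)
    if eps <= 0 or min_samples < 1:
        raise ValueError("require eps > 0 and min_samples >= 1")
    if len(points) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_samples).fit(points).labels_


def pose_cluster(points, eps: float = 3.0, min_samples: int = 20) -> ClusterResult:
    """DBSCAN on pose points packaged with centroids and populations."""
    labels = dbscan(points, eps=eps, min_samples=min_samples)
    ids = sorted(set(labels.tolist()) - {-1})
    points = np.asarray(points, float)
    centers = [points[labels == c].mean(axis=0) for c in ids]
    populations = np.array(
        [np.sum(labels == c) / len(points) for c in ids]
    )
    return ClusterResult(labels=labels, centers=centers,
                         populations=populations)
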