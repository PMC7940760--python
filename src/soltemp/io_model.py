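"""Reduced-atom data model and multi-model PDB I/O.

The native representation is a reduced protein topology: backbone N, CA, C, O
plus one optional side-chain tip pseudo-atom ("SC") per residue, typed by the
residue class (acidic tips are oxygen-like, basic tips nitrogen-like).
Full-atom PDB files are accepted as-is; extra atoms are simply retained as
side-chain heavy atoms so that heavy-atom contact analysis still works.

Coordinates are in Angstroms throughout.  Residue indices are 0-based
internally; user-facing labels are 1-based in the usual ``D1 ... A42`` style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "PDBFormatError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
    "center_of_mass",
    "radius_of_gyration",
    "ELEMENT_MASSES",
    "RESIDUE_CLASSES",
    "ONE_TO_THREE",
    "THREE_TO_ONE",
]


class PDBFormatError(ValueError):
    """Raised when a multi-model PDB file cannot be parsed consistently."""


class SelectionError(ValueError):
    """Raised for empty or malformed atom selections."""


# Fixed element -> mass table (daltons).  Unknown elements are an error, never
# a silent zero mass.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O"})

# Residue classification used for salt bridges and the binding-propensity
# colouring: D/E acidic, K/R basic, H/S/T/N/Q/Y/G polar (histidine is treated
# as neutral-polar at pH 7), everything else hydrophobic.
_ACIDIC = set("DE")
_BASIC = set("KR")
_POLAR = set("HSTNQYGCW")

RESIDUE_CLASSES = {}
for _aa in "ACDEFGHIKLMNPQRSTVWY":
    if _aa in _ACIDIC:
        RESIDUE_CLASSES[_aa] = "acidic"
    elif _aa in _BASIC:
        RESIDUE_CLASSES[_aa] = "basic"
    elif _aa in _POLAR:
        RESIDUE_CLASSES[_aa] = "polar"
    else:
        RESIDUE_CLASSES[_aa] = "hydrophobic"

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a (possibly reduced) topology."""

    atom_name: str
    element: str
    residue_index: int  # 0-based, global over all chains
    residue_name: str   # 3-letter code
    chain_id: str
    mass: float

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_ATOM_NAMES

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


def _mass_for(element: str) -> float:
    try:
        return ELEMENT_MASSES[element]
    except KeyError:
        raise PDBFormatError(f"unknown element {element!r}: no mass available")


class Topology:
    """Ordered atom list plus residue- and chain-level metadata.

    Parameters
    ----------
    atoms
        Ordered :class:`AtomRecord` list; residue indices must be contiguous
        and non-decreasing.
    chain_roles
        Optional map chain id -> ``"ligand"`` or ``"receptor"``.
    """

    def __init__(self, atoms, chain_roles=None):
        self.atoms = list(atoms)
        if not self.atoms:
            raise ValueError("topology must contain at least one atom")
        self.chain_roles = dict(chain_roles or {})

        self.atom_names = np.array([a.atom_name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.atom_residue = np.array(
            [a.residue_index for a in self.atoms], dtype=int
        )
        self.atom_chain = np.array([a.chain_id for a in self.atoms])
        self.is_backbone = np.array([a.is_backbone for a in self.atoms])
        self.is_heavy = np.array([a.is_heavy for a in self.atoms])

        # residue table
        res_ids = []
        res_names = []
        res_chains = []
        seen = {}
        for a in self.atoms:
            if a.residue_index not in seen:
                seen[a.residue_index] = True
                res_ids.append(a.residue_index)
                res_names.append(a.residue_name)
                res_chains.append(a.chain_id)
        if res_ids != list(range(len(res_ids))):
            raise ValueError("residue indices must be contiguous from 0")
        self.residue_names = list(res_names)
        self.residue_chains = np.array(res_chains)
        self.residue_classes = [
            RESIDUE_CLASSES.get(THREE_TO_ONE.get(n, "X"), "hydrophobic")
            for n in res_names
        ]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def chain_residues(self, chain_id: str) -> np.ndarray:
        """0-based residue indices belonging to one chain."""
        return np.nonzero(self.residue_chains == chain_id)[0]

    def chain_by_role(self, role: str) -> str:
        for cid, r in self.chain_roles.items():
            if r == role:
                return cid
        raise KeyError(f"no chain with role {role!r}")

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        return np.nonzero(self.atom_residue == residue_index)[0]

    def residue_label(self, residue_index: int) -> str:
        """1-based user-facing label, e.g. ``D1`` for the first aspartate."""
        name = self.residue_names[residue_index]
        one = THREE_TO_ONE.get(name, "X")
        chain = self.residue_chains[residue_index]
        first = int(np.nonzero(self.residue_chains == chain)[0][0])
        return f"{one}{residue_index - first + 1}"

    def residue_labels(self, residues=None):
        if residues is None:
            residues = range(self.n_residues)
        return [self.residue_label(int(r)) for r in residues]


@dataclass
class Frame:
    """One coordinate snapshot (Angstroms), shape (n_atoms, 3)."""

    coordinates: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


class Trajectory:
    """A topology plus an ordered stack of frames, ``xyz`` (F, N, 3) in A."""

    def __init__(self, topology: Topology, xyz: np.ndarray):
        xyz = np.asarray(xyz, dtype=float)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if xyz.shape[0] < 1:
            raise ValueError("trajectory must have at least one frame")
        if xyz.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {xyz.shape[1]} != topology atom count "
                f"{topology.n_atoms}"
            )
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        self.topology = topology
        self.xyz = xyz

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.xyz[i], frame_index=i)

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# PDB read / write (biotite does the fixed-column parsing)
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path, chain_roles=None) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    MODEL/ENDMDL records delimit frames; a single-model file yields a
    one-frame trajectory.  Atom order must be identical in every model.
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError and friends
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc

    n_models = stack.stack_depth()
    if n_models < 1 or stack.array_length() < 1:
        raise PDBFormatError(f"no atoms found in {path}")

    atoms = []
    res_index = -1
    last_key = None
    for i in range(stack.array_length()):
        chain = str(stack.chain_id[i])
        res_id = int(stack.res_id[i])
        key = (chain, res_id, str(stack.ins_code[i]) if hasattr(stack, "ins_code") else "")
        if key != last_key:
            res_index += 1
            last_key = key
        element = str(stack.element[i]).strip().capitalize()
        if not element:
            raise PDBFormatError(
                f"atom {i} in {path} has no element; cannot assign a mass"
            )
        atoms.append(
            AtomRecord(
                atom_name=str(stack.atom_name[i]),
                element=element,
                residue_index=res_index,
                residue_name=str(stack.res_name[i]),
                chain_id=chain,
                mass=_mass_for(element),
            )
        )
    topology = Topology(atoms, chain_roles=chain_roles)
    return Trajectory(topology, stack.coord.copy())


def write_multimodel_pdb(path, trajectory: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    top = trajectory.topology
    n = top.n_atoms
    template = struc.AtomArray(n)
    template.chain_id = top.atom_chain
    # 1-based residue numbering restarting per chain
    res_ids = np.empty(top.n_residues, dtype=int)
    for cid in dict.fromkeys(top.residue_chains.tolist()):
        idx = np.nonzero(top.residue_chains == cid)[0]
        res_ids[idx] = np.arange(1, len(idx) + 1)
    template.res_id = res_ids[top.atom_residue]
    template.res_name = np.array(
        [top.residue_names[r] for r in top.atom_residue]
    )
    template.atom_name = top.atom_names
    template.element = np.char.upper(top.elements.astype("U2"))
    template.hetero = np.zeros(n, dtype=bool)

    stack = struc.stack([template] * trajectory.n_frames)
    stack.coord = trajectory.xyz.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections and geometric observables
# ---------------------------------------------------------------------------

def select(topology: Topology, query: str = "all", chain=None,
           residue_range=None) -> np.ndarray:
    """Resolve a selection to a strictly increasing atom-index array.

    Parameters
    ----------
    query
        One of ``"backbone"`` (N, CA, C, O), ``"heavy"`` (element != H) or
        ``"all"``.
    chain
        Optional chain id, or a role name (``"ligand"`` / ``"receptor"``) if
        the topology carries chain roles.
    residue_range
        Optional inclusive ``(first, last)`` pair of 0-based residue indices.

    Raises
    ------
    SelectionError
        If the query is unknown or resolves to no atoms.
    """
    if query == "backbone":
        mask = topology.is_backbone.copy()
    elif query == "heavy":
        mask = topology.is_heavy.copy()
    elif query == "all":
        mask = np.ones(topology.n_atoms, dtype=bool)
    else:
        raise SelectionError(f"unknown selection query {query!r}")

    if chain is not None:
        if chain not in set(topology.atom_chain):
            if chain in set(topology.chain_roles.values()):
                chain = topology.chain_by_role(chain)
            else:
                raise SelectionError(f"unknown chain {chain!r}")
        mask &= topology.atom_chain == chain
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (topology.atom_residue >= lo) & (topology.atom_residue <= hi)

    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise SelectionError(
            f"selection (query={query!r}, chain={chain!r}, "
            f"residue_range={residue_range!r}) matched no atoms"
        )
    return indices


def center_of_mass(coordinates, masses, indices=None, geometric=False):
    """Mass-weighted (default) or geometric centre of a selection, in A.

    ``coordinates`` is (n_atoms, 3); ``masses`` may be a Topology or an array.
    """
    if isinstance(masses, Topology):
        masses = masses.masses
    coords = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if indices is not None:
        indices = np.asarray(indices, dtype=int)
        if indices.size == 0:
            raise SelectionError("center_of_mass of an empty selection")
        coords = coords[indices]
        masses = masses[indices]
    if coords.shape[0] == 0:
        raise SelectionError("center_of_mass of an empty selection")
    if geometric:
        return coords.mean(axis=0)
    total = masses.sum()
    return (coords * masses[:, None]).sum(axis=0) / total


def radius_of_gyration(coordinates, masses, indices=None, geometric=False):
    """Mass-weighted radius of gyration about the selection COM, in A."""
    if isinstance(masses, Topology):
        masses = masses.masses
    coords = np.asarray(coordinates, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if indices is not None:
        indices = np.asarray(indices, dtype=int)
        if indices.size == 0:
            raise SelectionError("radius_of_gyration of an empty selection")
        coords = coords[indices]
        masses = masses[indices]
    if coords.shape[0] == 0:
        raise SelectionError("radius_of_gyration of an empty selection")
    com = center_of_mass(coords, masses, geometric=geometric)
    d2 = np.sum((coords - com) ** 2, axis=1)
    if geometric:
        return float(np.sqrt(d2.mean()))
    return float(np.sqrt((masses * d2).sum() / masses.sum()))
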