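"""Molecular systems, trajectories and multi-model PDB interchange.

The interchange format is plain multi-model PDB (one frame per MODEL block);
parsing and serialization are delegated to biotite, with element-based van
der Waals radii and a polar/apolar partition attached on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "MolecularSystem",
    "Trajectory",
    "StructureError",
    "VDW_RADII",
    "read_pdb",
    "write_pdb",
    "BACKBONE_NAMES",
]


class StructureError(ValueError):
    """Raised on invalid structures or trajectories."""


#: Element -> van der Waals radius (Angstrom). Configurable per call site.
VDW_RADII: dict[str, float] = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}

#: Backbone atom names (heavy); used for hydrogen-bond kind assignment.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_BASIC_RESNAMES = frozenset({"ARG", "LYS", "HIS", "HSD", "HSE", "HSP"})
_ACIDIC_RESNAMES = frozenset({"ASP", "GLU"})


def _polarity_for(element: str, name: str, sulfur_polar: bool = False) -> str:
    """Conventional partition: N/O polar, C apolar, S configurable.

    Hydrogens inherit from the heavy atom they are attached to; that is
    resolved in :meth:`MolecularSystem.__post_init__` via proximity.
    """
    if element in ("N", "O"):
        return "polar"
    if element == "S":
        return "polar" if sulfur_polar else "apolar"
    return "apolar"


@dataclass
class MolecularSystem:
    """Atoms with identity, coordinates, radii and a polarity class.

    Coordinates are the reference frame (Angstrom, shape ``(n_atoms, 3)``).
    Radii default to the element table; polarity defaults to the
    conventional partition with hydrogens inheriting from their nearest
    heavy atom (within 1.3 A).
    """

    names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    vdw_radii: np.ndarray | None = None
    polarity: np.ndarray | None = None
    sulfur_polar: bool = False

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.chains = np.asarray(self.chains, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.names.size
        if self.coords.shape != (n, 3):
            raise StructureError("coords must have shape (n_atoms, 3)")
        for chain in np.unique(self.chains):
            ids = self.res_ids[self.chains == chain]
            if np.any(np.diff(ids) < 0):
                raise StructureError(
                    f"residue ids must be non-decreasing within chain {chain!r}"
                )
        if self.vdw_radii is None:
            self.vdw_radii = np.array(
                [VDW_RADII.get(e, 1.7) for e in self.elements], dtype=float
            )
        else:
            self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        if np.any(self.vdw_radii <= 0):
            raise StructureError("van der Waals radii must be positive")
        if self.polarity is None:
            self.polarity = self._assign_polarity()
        else:
            self.polarity = np.asarray(self.polarity, dtype=object)
            bad = set(self.polarity) - {"polar", "apolar"}
            if bad:
                raise StructureError(f"unknown polarity classes: {bad}")

    def _assign_polarity(self) -> np.ndarray:
        pol = np.array(
            [
                _polarity_for(e, nm, self.sulfur_polar)
                for e, nm in zip(self.elements, self.names)
            ],
            dtype=object,
        )
        h_idx = np.where(self.elements == "H")[0]
        heavy_idx = np.where(self.elements != "H")[0]
        if h_idx.size and heavy_idx.size:
            from scipy.spatial import cKDTree

            tree = cKDTree(self.coords[heavy_idx])
            dist, j = tree.query(self.coords[h_idx])
            for hi, d, jj in zip(h_idx, dist, j):
                if d <= 1.3:
                    pol[hi] = pol[heavy_idx[jj]]
        return pol

    @property
    def n_atoms(self) -> int:
        return self.names.size

    def select(self, mask: np.ndarray) -> np.ndarray:
        """Indices of atoms matching a boolean mask."""
        return np.where(mask)[0]

    def ca_indices(self) -> np.ndarray:
        return np.where((self.names == "CA") & (self.elements != "H"))[0]

    def backbone_mask(self) -> np.ndarray:
        return np.array([nm in BACKBONE_NAMES for nm in self.names])

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique ``(chain, res_id, res_name)`` keys."""
        seen: dict[tuple[str, int, str], None] = {}
        for ch, ri, rn in zip(self.chains, self.res_ids, self.res_names):
            seen.setdefault((str(ch), int(ri), str(rn)))
        return list(seen)

    def is_basic(self, i: int) -> bool:
        return str(self.res_names[i]) in _BASIC_RESNAMES

    def is_acidic(self, i: int) -> bool:
        return str(self.res_names[i]) in _ACIDIC_RESNAMES


@dataclass
class Trajectory:
    """Ordered coordinate frames congruent with a :class:`MolecularSystem`."""

    frames: np.ndarray
    frame_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise StructureError("trajectory needs >= 1 frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    @classmethod
    def from_system(cls, sys: MolecularSystem) -> "Trajectory":
        return cls(frames=sys.coords[None, :, :].copy())


def read_pdb(path: str | Path) -> tuple[MolecularSystem, Trajectory]:
    """Read a (multi-model) PDB file into a system plus trajectory.

    Occupancy and B-factor columns are tolerated and ignored. All models
    must share the same atom inventory; frame 0 becomes the system's
    reference coordinates.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    arr0 = stack[0]
    elements = np.array(
        [e.capitalize() if e else "C" for e in arr0.element], dtype=object
    )
    sys = MolecularSystem(
        names=arr0.atom_name.astype(object),
        elements=elements,
        res_names=arr0.res_name.astype(object),
        res_ids=arr0.res_id,
        chains=arr0.chain_id.astype(object),
        coords=np.asarray(arr0.coord, dtype=float),
    )
    traj = Trajectory(frames=np.asarray(stack.coord, dtype=float))
    return sys, traj


def write_pdb(
    path: str | Path, sys: MolecularSystem, traj: Trajectory | None = None
) -> None:
    """Write a system (and optional trajectory) as multi-model PDB."""
    frames = traj.frames if traj is not None else sys.coords[None]
    if frames.shape[1] != sys.n_atoms:
        raise StructureError("trajectory is not congruent with the system")
    n = sys.n_atoms
    arrays = []
    for frame in frames:
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(frame, dtype=np.float32)
        arr.atom_name = sys.names.astype("U6")
        arr.element = np.array([e.upper() for e in sys.elements], dtype="U2")
        arr.res_name = sys.res_names.astype("U5")
        arr.res_id = sys.res_ids
        arr.chain_id = sys.chains.astype("U4")
        arr.hetero = np.zeros(n, dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
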