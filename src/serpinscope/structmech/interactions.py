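"""Hydrogen bonds and salt bridges with per-frame presence and occupancy.

Occupancy is the fraction of trajectory frames in which an interaction's
geometric criteria hold. The geometric criteria are conventional defaults
(donor-acceptor distance plus donor-H-acceptor angle); when a structure has
no hydrogens, detection falls back to a tighter heavy-atom distance cutoff
with a donor-antecedent angle proxy, which is an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from serpinscope.structmech.system import (
    BACKBONE_NAMES,
    MolecularSystem,
    Trajectory,
    StructureError,
)

__all__ = [
    "HydrogenBond",
    "SaltBridge",
    "InteractionSet",
    "detect_hbonds",
    "detect_salt_bridges",
    "filter_by_occupancy",
]

_BASIC_SIDECHAIN_N = frozenset({"NE", "NH1", "NH2", "NZ", "ND1", "NE2"})
_ACIDIC_SIDECHAIN_O = frozenset({"OD1", "OD2", "OE1", "OE2"})

_COVALENT_H_CUTOFF = 1.3  # A, H attached to heavy atom
_NO_H_DISTANCE = 3.0  # A, heavy-atom fallback cutoff
_NO_H_ANGLE_MIN = 90.0  # deg, antecedent-donor-acceptor proxy


@dataclass(frozen=True)
class HydrogenBond:
    donor: int
    hydrogen: int | None
    acceptor: int
    occupancy: float
    kind: str  # "backbone" | "sidechain"


@dataclass(frozen=True)
class SaltBridge:
    basic_residue: tuple[str, int, str]
    acidic_residue: tuple[str, int, str]
    occupancy: float


@dataclass(frozen=True)
class InteractionSet:
    hbonds: tuple[HydrogenBond, ...] = ()
    salt_bridges: tuple[SaltBridge, ...] = ()

    def counts(self) -> dict[str, int]:
        """Interaction counts by kind."""
        backbone = sum(1 for h in self.hbonds if h.kind == "backbone")
        return {
            "hbonds_total": len(self.hbonds),
            "hbonds_backbone": backbone,
            "hbonds_sidechain": len(self.hbonds) - backbone,
            "salt_bridges": len(self.salt_bridges),
        }


def _residue_key(sys: MolecularSystem, i: int) -> tuple[str, int, str]:
    return (str(sys.chains[i]), int(sys.res_ids[i]), str(sys.res_names[i]))


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _attached_hydrogens(sys: MolecularSystem) -> dict[int, list[int]]:
    """Heavy-atom index -> indices of covalently attached hydrogens."""
    h_idx = np.where(sys.elements == "H")[0]
    heavy_idx = np.where(sys.elements != "H")[0]
    attached: dict[int, list[int]] = {}
    if h_idx.size == 0 or heavy_idx.size == 0:
        return attached
    tree = cKDTree(sys.coords[heavy_idx])
    dist, j = tree.query(sys.coords[h_idx])
    for hi, d, jj in zip(h_idx, dist, j):
        if d <= _COVALENT_H_CUTOFF:
            attached.setdefault(int(heavy_idx[jj]), []).append(int(hi))
    return attached


def _antecedent(sys: MolecularSystem, donor: int) -> int | None:
    """Nearest heavy atom in the same residue: proxy for the bonded neighbor."""
    mask = (
        (sys.res_ids == sys.res_ids[donor])
        & (sys.chains == sys.chains[donor])
        & (sys.elements != "H")
    )
    idx = np.where(mask)[0]
    idx = idx[idx != donor]
    if idx.size == 0:
        return None
    d = np.linalg.norm(sys.coords[idx] - sys.coords[donor], axis=1)
    return int(idx[np.argmin(d)])


def detect_hbonds(
    traj: Trajectory,
    sys: MolecularSystem,
    d_DA_max_A: float = 3.5,
    angle_min_deg: float = 150.0,
) -> InteractionSet:
    """Geometric hydrogen-bond detection with per-frame occupancy.

    With explicit hydrogens a bond is present in a frame iff the
    donor-acceptor distance is <= ``d_DA_max_A`` and the donor-H-acceptor
    angle is >= ``angle_min_deg``. Without hydrogens, presence means
    donor-acceptor distance <= 3.0 A and antecedent-donor-acceptor angle
    >= 90 deg (documented approximation).
    """
    if traj.n_atoms != sys.n_atoms:
        raise StructureError("trajectory is not congruent with the system")
    polar = np.where((sys.elements == "N") | (sys.elements == "O"))[0]
    if polar.size == 0:
        return InteractionSet()

    attached = _attached_hydrogens(sys)
    have_h = bool(attached)
    if have_h:
        donors = [i for i in polar if attached.get(int(i))]
    else:
        donors = [int(i) for i in polar if sys.elements[i] == "N"] + [
            int(i) for i in polar if sys.elements[i] == "O"
        ]
    acceptors = [int(i) for i in polar]
    d_cut = d_DA_max_A if have_h else _NO_H_DISTANCE

    antecedents = {d: _antecedent(sys, d) for d in donors} if not have_h else {}
    backbone = sys.backbone_mask()

    counts: dict[tuple[int, int | None, int], int] = {}
    for frame in traj.frames:
        tree = cKDTree(frame[acceptors])
        for d in donors:
            near = tree.query_ball_point(frame[d], d_cut)
            for k in near:
                a = acceptors[k]
                if a == d or _residue_key(sys, a) == _residue_key(sys, d):
                    continue
                if have_h:
                    ok = False
                    best_h = None
                    for h in attached[d]:
                        if _angle_deg(frame[d], frame[h], frame[a]) >= angle_min_deg:
                            ok, best_h = True, h
                            break
                    if not ok:
                        continue
                    key = (d, best_h, a)
                else:
                    ante = antecedents.get(d)
                    if ante is not None and (
                        _angle_deg(frame[ante], frame[d], frame[a]) < _NO_H_ANGLE_MIN
                    ):
                        continue
                    key = (d, None, a)
                counts[key] = counts.get(key, 0) + 1

    hbonds = []
    for (d, h, a), c in sorted(counts.items()):
        kind = "backbone" if backbone[d] and backbone[a] else "sidechain"
        hbonds.append(
            HydrogenBond(
                donor=d, hydrogen=h, acceptor=a, occupancy=c / traj.n_frames, kind=kind
            )
        )
    return InteractionSet(hbonds=tuple(hbonds))


def detect_salt_bridges(
    traj: Trajectory, sys: MolecularSystem, d_max_A: float = 4.0
) -> InteractionSet:
    """Salt bridges between basic side-chain N and acidic side-chain O atoms.

    A bridge is present in a frame iff any such N-O pair of the residue pair
    is within ``d_max_A``; occupancy counts frames as for hydrogen bonds.
    """
    if traj.n_atoms != sys.n_atoms:
        raise StructureError("trajectory is not congruent with the system")
    basic_atoms: dict[tuple[str, int, str], list[int]] = {}
    acidic_atoms: dict[tuple[str, int, str], list[int]] = {}
    for i in range(sys.n_atoms):
        nm = str(sys.names[i])
        if sys.is_basic(i) and nm in _BASIC_SIDECHAIN_N:
            basic_atoms.setdefault(_residue_key(sys, i), []).append(i)
        elif sys.is_acidic(i) and nm in _ACIDIC_SIDECHAIN_O:
            acidic_atoms.setdefault(_residue_key(sys, i), []).append(i)
    if not basic_atoms or not acidic_atoms:
        return InteractionSet()

    counts: dict[tuple, int] = {}
    for frame in traj.frames:
        for bkey, bidx in basic_atoms.items():
            for akey, aidx in acidic_atoms.items():
                d = np.linalg.norm(
                    frame[bidx][:, None, :] - frame[aidx][None, :, :], axis=2
                )
                if d.min() <= d_max_A:
                    counts[(bkey, akey)] = counts.get((bkey, akey), 0) + 1

    bridges = tuple(
        SaltBridge(basic_residue=b, acidic_residue=a, occupancy=c / traj.n_frames)
        for (b, a), c in sorted(counts.items())
    )
    return InteractionSet(salt_bridges=bridges)


def filter_by_occupancy(iset: InteractionSet, min_occ: float = 0.5) -> InteractionSet:
    """Keep interactions with occupancy strictly greater than ``min_occ``."""
    return InteractionSet(
        hbonds=tuple(h for h in iset.hbonds if h.occupancy > min_occ),
        salt_bridges=tuple(s for s in iset.salt_bridges if s.occupancy > min_occ),
    )
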