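"""Shrake-Rupley solvent-accessible surface area with a polar/apolar split."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from serpinscope.structmech.system import MolecularSystem, StructureError

__all__ = ["SasaResult", "shrake_rupley_sasa", "sphere_points"]


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and class-summed solvent-accessible surface areas (A^2)."""

    total_A2: float
    polar_A2: float
    apolar_A2: float
    per_atom: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_atom", np.asarray(self.per_atom, dtype=float))


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_sasa(
    sys: MolecularSystem,
    probe_A: float = 1.4,
    n_sphere_points: int = 960,
    coords: np.ndarray | None = None,
) -> SasaResult:
    """Shrake-Rupley SASA: test points on probe-expanded spheres.

    A test point on atom *i*'s expanded sphere (radius ``r_i + probe``)
    counts as exposed iff it lies outside every other atom's expanded
    sphere; the atom's area is the exposed fraction times the full sphere
    area. Polar and apolar sums follow the system's polarity classes.

    ``coords`` overrides the system's reference coordinates (e.g. to
    evaluate a single trajectory frame).
    """
    xyz = sys.coords if coords is None else np.asarray(coords, dtype=float)
    if xyz.shape != (sys.n_atoms, 3):
        raise StructureError("coordinate shape mismatch")
    if not np.all(np.isfinite(xyz)):
        raise StructureError("non-finite coordinates")
    radii = sys.vdw_radii + probe_A

    tree = cKDTree(xyz)
    dup = tree.query_pairs(1e-9)
    if dup:
        raise StructureError(f"overlapping identical atom coordinates: {sorted(dup)[0]}")

    unit = sphere_points(n_sphere_points)
    max_r = radii.max()
    per_atom = np.empty(sys.n_atoms)
    neighbor_lists = tree.query_ball_tree(tree, 2.0 * max_r)
    for i in range(sys.n_atoms):
        pts = xyz[i] + radii[i] * unit
        nbrs = [j for j in neighbor_lists[i] if j != i]
        if nbrs:
            nbrs = np.array(nbrs)
            # keep only neighbors whose expanded sphere can reach atom i's shell
            d = np.linalg.norm(xyz[nbrs] - xyz[i], axis=1)
            nbrs = nbrs[d < radii[i] + radii[nbrs]]
        if len(nbrs) == 0:
            exposed = n_sphere_points
        else:
            diff = pts[:, None, :] - xyz[nbrs][None, :, :]
            inside = (diff**2).sum(axis=2) < (radii[nbrs] ** 2)[None, :]
            exposed = int((~inside.any(axis=1)).sum())
        per_atom[i] = exposed / n_sphere_points * 4.0 * np.pi * radii[i] ** 2

    polar = float(per_atom[sys.polarity == "polar"].sum())
    apolar = float(per_atom[sys.polarity == "apolar"].sum())
    return SasaResult(
        total_A2=polar + apolar,
        polar_A2=polar,
        apolar_A2=apolar,
        per_atom=per_atom,
    )
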