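"""Three-term empirical free-energy decomposition between conformers.

The stability change of an alternate conformer relative to a reference is
estimated as the sum of a surface term (apolar/polar SASA differences
weighted by empirical surface-tension coefficients), a hydrogen-bond term
(a fixed stabilization per stable bond) and a side-chain configurational
entropy term (per-residue exposure changes weighted by an empirical
residue-type scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from serpinscope.structmech.interactions import detect_hbonds, filter_by_occupancy
from serpinscope.structmech.sasa import shrake_rupley_sasa
from serpinscope.structmech.system import (
    BACKBONE_NAMES,
    MolecularSystem,
    Trajectory,
)

__all__ = [
    "FreeEnergyParams",
    "FreeEnergyBreakdown",
    "dg_sasa",
    "dg_hb",
    "dg_entropy",
    "total_dg",
    "conformer_dg",
]

_STANDARD_RESIDUES = 20


def _load_table(name: str) -> dict[str, float]:
    text = resources.files("serpinscope.data").joinpath(name).read_text()
    raw = json.loads(text)
    return {k: float(v) for k, v in raw.items() if k != "comment"}


@dataclass(frozen=True)
class FreeEnergyParams:
    """Coefficients of the decomposition.

    ``sigma_apol`` / ``sigma_pol`` are in cal mol^-1 A^-2, ``e_hb`` in
    kcal mol^-1 per hydrogen bond; ``entropy_coeffs`` maps residue type to
    kcal mol^-1 per unit change in relative side-chain exposure.
    """

    sigma_apol: float = 49.6
    sigma_pol: float = 19.1
    e_hb: float = 0.5
    entropy_coeffs: dict[str, float] = field(default_factory=dict)
    max_exposure: dict[str, float] = field(default_factory=dict)
    hb_occupancy_min: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_apol <= 0 or self.sigma_pol <= 0:
            raise ValueError("surface coefficients must be positive")
        if self.e_hb <= 0:
            raise ValueError("per-bond energy must be positive")
        if not self.entropy_coeffs:
            object.__setattr__(
                self, "entropy_coeffs", _load_table("sidechain_entropy_kcal.json")
            )
        if not self.max_exposure:
            object.__setattr__(
                self, "max_exposure", _load_table("max_sidechain_exposure_A2.json")
            )
        if len(self.entropy_coeffs) < _STANDARD_RESIDUES:
            raise ValueError("entropy table must cover all 20 residue types")


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    """All terms in kcal/mol, relative to the named reference conformer."""

    dg_sasa: float
    dg_hb: float
    dg_s: float
    dg_total: float
    reference: str = "reference"
    details: dict = field(default_factory=dict)


def dg_sasa(
    delta_sasa_apol_A2: float,
    delta_sasa_pol_A2: float,
    params: FreeEnergyParams | None = None,
) -> float:
    """Surface term: (sigma_apol * dApol - sigma_pol * dPol) / 1000 kcal/mol."""
    p = params or FreeEnergyParams()
    return (p.sigma_apol * delta_sasa_apol_A2 - p.sigma_pol * delta_sasa_pol_A2) / 1000.0


def dg_hb(delta_n_hb: int, params: FreeEnergyParams | None = None) -> float:
    """Hydrogen-bond term: -e_hb per additional stable bond (kcal/mol)."""
    p = params or FreeEnergyParams()
    return -p.e_hb * delta_n_hb


def dg_entropy(
    exposure_change: dict[str, float] | list[tuple[str, float]],
    params: FreeEnergyParams | None = None,
) -> float:
    """Side-chain entropy term from relative exposure changes (kcal/mol).

    ``exposure_change`` maps residue type (three-letter code, possibly
    suffixed for uniqueness, e.g. ``"ARG:17"``) to the change in relative
    side-chain exposure (alternate minus reference, each in [0, 1]).
    Burial (negative change) costs entropy, so it contributes positively.
    """
    p = params or FreeEnergyParams()
    items = exposure_change.items() if isinstance(exposure_change, dict) else exposure_change
    total = 0.0
    for key, delta in items:
        res_type = key.split(":")[0].upper()
        if res_type not in p.entropy_coeffs:
            raise ValueError(f"residue type {res_type!r} missing from entropy table")
        total += p.entropy_coeffs[res_type] * (-delta)
    return total


def total_dg(
    dg_sasa_kcal: float,
    dg_hb_kcal: float,
    dg_s_kcal: float,
    reference: str = "reference",
) -> FreeEnergyBreakdown:
    """Combine the three terms; the total is their exact sum."""
    return FreeEnergyBreakdown(
        dg_sasa=dg_sasa_kcal,
        dg_hb=dg_hb_kcal,
        dg_s=dg_s_kcal,
        dg_total=dg_sasa_kcal + dg_hb_kcal + dg_s_kcal,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------

def _time_averaged_sasa(
    sys: MolecularSystem, traj: Trajectory, probe_A: float, n_points: int
):
    per_atom = np.zeros(sys.n_atoms)
    apol = pol = 0.0
    for frame in traj.frames:
        res = shrake_rupley_sasa(sys, probe_A=probe_A, n_sphere_points=n_points, coords=frame)
        per_atom += res.per_atom
        apol += res.apolar_A2
        pol += res.polar_A2
    n = traj.n_frames
    return per_atom / n, apol / n, pol / n


def _relative_exposures(
    sys: MolecularSystem, per_atom_sasa: np.ndarray, params: FreeEnergyParams
) -> dict[tuple[str, int, str], float]:
    """Mean relative side-chain exposure per residue, clipped to [0, 1]."""
    sidechain = ~np.array(
        [nm in BACKBONE_NAMES or el == "H" for nm, el in zip(sys.names, sys.elements)]
    )
    out: dict[tuple[str, int, str], float] = {}
    for key in sys.residue_keys():
        chain, rid, rname = key
        if rname not in params.max_exposure:
            continue
        mask = (
            (sys.chains == chain) & (sys.res_ids == rid) & sidechain
        )
        area = float(per_atom_sasa[mask].sum())
        out[key] = float(np.clip(area / params.max_exposure[rname], 0.0, 1.0))
    return out


def conformer_dg(
    traj_ref: Trajectory,
    traj_alt: Trajectory,
    sys_ref: MolecularSystem,
    sys_alt: MolecularSystem,
    params: FreeEnergyParams | None = None,
    probe_A: float = 1.4,
    n_sphere_points: int = 960,
    reference: str = "reference",
) -> FreeEnergyBreakdown:
    """Full decomposition of ``alt`` relative to ``ref`` from trajectories.

    SASA and exposures are time-averaged over all frames; hydrogen bonds
    are counted after the stable-occupancy filter. Residues present in only
    one conformer (e.g. across a cleavage) are excluded from the entropy
    term and reported in ``details["unmatched_residues"]``.
    """
    p = params or FreeEnergyParams()

    per_ref, apol_ref, pol_ref = _time_averaged_sasa(sys_ref, traj_ref, probe_A, n_sphere_points)
    per_alt, apol_alt, pol_alt = _time_averaged_sasa(sys_alt, traj_alt, probe_A, n_sphere_points)
    d_apol = apol_alt - apol_ref
    d_pol = pol_alt - pol_ref
    term_sasa = dg_sasa(d_apol, d_pol, p)

    n_ref = len(filter_by_occupancy(detect_hbonds(traj_ref, sys_ref), p.hb_occupancy_min).hbonds)
    n_alt = len(filter_by_occupancy(detect_hbonds(traj_alt, sys_alt), p.hb_occupancy_min).hbonds)
    delta_n = n_alt - n_ref
    term_hb = dg_hb(delta_n, p)

    exp_ref = _relative_exposures(sys_ref, per_ref, p)
    exp_alt = _relative_exposures(sys_alt, per_alt, p)
    common = sorted(set(exp_ref) & set(exp_alt))
    unmatched = sorted(set(exp_ref) ^ set(exp_alt))
    changes = [
        (f"{rname}:{chain}{rid}", exp_alt[(chain, rid, rname)] - exp_ref[(chain, rid, rname)])
        for chain, rid, rname in common
    ]
    term_s = dg_entropy(changes, p)

    out = total_dg(term_sasa, term_hb, term_s, reference=reference)
    details = {
        "delta_sasa_apol_A2": d_apol,
        "delta_sasa_pol_A2": d_pol,
        "n_hb_ref": n_ref,
        "n_hb_alt": n_alt,
        "delta_n_hb": delta_n,
        "unmatched_residues": unmatched,
    }
    return FreeEnergyBreakdown(
        dg_sasa=out.dg_sasa,
        dg_hb=out.dg_hb,
        dg_s=out.dg_s,
        dg_total=out.dg_total,
        reference=reference,
        details=details,
    )
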