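"""Seeded generators for every input the analysis modules consume.

Emission spectra are sums of Gaussian bands at the tryptophan-class centers
plus a tyrosine band, a tyrosinate band, a narrow Rayleigh elastic peak and
additive Gaussian noise; each recipe carries analytic ground truth (band
fractions, the fingerprint R, emission maximum). Toy structures and
trajectories provide scripted hydrogen bonds, salt bridges and per-residue
displacements with closed-form expected values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from serpinscope.spectra import (
    CLASS_BAND_SIGMAS,
    TYR_BAND_NM,
    TYROSINATE_BAND_NM,
    EmissionSpectrum,
)
from serpinscope.structmech.system import MolecularSystem, Trajectory

__all__ = [
    "EMISSION_GRID_NM",
    "SpectrumRecipe",
    "SpectrumTruth",
    "make_spectrum_pair",
    "make_conformer_presets",
    "ToyStructureRecipe",
    "ToyTruth",
    "make_toy_system",
    "make_recovery_suite",
    "make_collective_motion",
    "build_backbone",
    "HELIX_PHI_PSI",
    "STRAND_PHI_PSI",
    "SHEET_PHI_PSI",
]

#: Fixed emission grid: 260-520 nm in 1 nm steps.
EMISSION_GRID_NM = np.arange(260.0, 521.0, 1.0)

TYR_CENTER_NM, TYR_SIGMA_NM = TYR_BAND_NM
TYROSINATE_CENTER_NM, TYROSINATE_SIGMA_NM = TYROSINATE_BAND_NM
RAYLEIGH_SIGMA_NM = 1.5

#: Band widths (nm) used by the conformer presets: the analysis-side class
#: shapes, so pinned-model fits see in-model data.
PRESET_SIGMAS = dict(CLASS_BAND_SIGMAS)

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def _gauss_area(lam: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    amp = area / (sigma * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)


@dataclass(frozen=True)
class SpectrumRecipe:
    """Everything needed to synthesize one 275/295 nm excitation pair."""

    band_spec: tuple[tuple[float, float, float], ...]  # (center, sigma, area)
    tyr_area: float = 0.0
    tyrosinate_area: float = 0.0
    rayleigh_height: float = 0.0
    noise_sigma: float = 0.0  # relative to the noiseless peak
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if any(a < 0 for _, _, a in self.band_spec):
            raise ValueError("band areas must be non-negative")
        if self.tyr_area < 0 or self.tyrosinate_area < 0 or self.noise_sigma < 0:
            raise ValueError("areas and noise level must be non-negative")


@dataclass(frozen=True)
class SpectrumTruth:
    """Analytic ground truth implied by a noiseless recipe."""

    fractions: dict[float, float]
    r_value: float
    tyr_area: float
    tyrosinate_area: float
    emission_max_275_nm: float


def _trp_model(lam: np.ndarray, recipe: SpectrumRecipe) -> np.ndarray:
    out = np.zeros_like(lam)
    for center, sigma, area in recipe.band_spec:
        out += _gauss_area(lam, center, sigma, area)
    return out


def _model_275(lam: np.ndarray, recipe: SpectrumRecipe) -> np.ndarray:
    return (
        _trp_model(lam, recipe)
        + _gauss_area(lam, TYR_CENTER_NM, TYR_SIGMA_NM, recipe.tyr_area)
        + _gauss_area(
            lam, TYROSINATE_CENTER_NM, TYROSINATE_SIGMA_NM, recipe.tyrosinate_area
        )
    )


def make_spectrum_pair(
    recipe: SpectrumRecipe,
) -> tuple[EmissionSpectrum, EmissionSpectrum, SpectrumTruth]:
    """Synthesize the 275/295 nm excitation pair plus its analytic truth.

    The 295 nm spectrum holds the tryptophan bands only; the 275 nm
    spectrum adds the tyrosine and tyrosinate bands. Both get a Rayleigh
    peak at their excitation wavelength and seeded additive noise.
    """
    lam = EMISSION_GRID_NM.copy()
    m295 = _trp_model(lam, recipe)
    m275 = _model_275(lam, recipe)

    peak = max(float(m275.max()), float(m295.max()))
    rng = np.random.default_rng(recipe.seed)
    noise = recipe.noise_sigma * peak

    def realize(model: np.ndarray, lam_ex: float) -> np.ndarray:
        y = model + recipe.rayleigh_height * np.exp(
            -0.5 * ((lam - lam_ex) / RAYLEIGH_SIGMA_NM) ** 2
        )
        if noise > 0:
            y = y + rng.normal(0.0, noise, size=lam.size)
        return y

    spec_275 = EmissionSpectrum(
        lambda_nm=lam,
        intensity=realize(m275, 275.0),
        lambda_ex_nm=275.0,
        label=f"{recipe.label}:ex275",
    )
    spec_295 = EmissionSpectrum(
        lambda_nm=lam,
        intensity=realize(m295, 295.0),
        lambda_ex_nm=295.0,
        label=f"{recipe.label}:ex295",
    )

    def at(model: np.ndarray, x: float) -> float:
        return float(np.interp(x, lam, model))

    total_area = sum(a for _, _, a in recipe.band_spec)
    fractions = {c: a / total_area for c, _, a in recipe.band_spec}
    r = (at(m275, 304.0) / at(m275, 331.0)) / (at(m295, 304.0) / at(m295, 331.0))
    truth = SpectrumTruth(
        fractions=fractions,
        r_value=r,
        tyr_area=recipe.tyr_area,
        tyrosinate_area=recipe.tyrosinate_area,
        emission_max_275_nm=float(lam[int(np.argmax(m275))]),
    )
    return spec_275, spec_295, truth


def _solve_tyr_area(
    band_spec: tuple[tuple[float, float, float], ...],
    target_r: float,
    tyrosinate_ratio: float,
) -> tuple[float, float]:
    """Tyr/tyrosinate areas that give a recipe an exact analytic R.

    With the tryptophan model fixed, R is a Moebius function of the Tyr
    band area, so the target is reached by solving one linear equation;
    the tyrosinate area is tied to the Tyr area by ``tyrosinate_ratio``.
    """
    lam = EMISSION_GRID_NM
    dummy = SpectrumRecipe(band_spec=band_spec)
    trp = _trp_model(lam, dummy)

    def at(model: np.ndarray, x: float) -> float:
        return float(np.interp(x, lam, model))

    t304, t331 = at(trp, 304.0), at(trp, 331.0)
    gy = _gauss_area(lam, TYR_CENTER_NM, TYR_SIGMA_NM, 1.0)
    gt = _gauss_area(lam, TYROSINATE_CENTER_NM, TYROSINATE_SIGMA_NM, 1.0)
    rho = t304 / t331
    k = target_r * rho
    denom = (at(gy, 304.0) - k * at(gy, 331.0)) - tyrosinate_ratio * (
        k * at(gt, 331.0) - at(gt, 304.0)
    )
    a_y = (k * t331 - t304) / denom
    if a_y < 0:
        raise ValueError("target R not reachable with non-negative Tyr area")
    return a_y, tyrosinate_ratio * a_y


def _bands(weights: dict[float, float]) -> tuple[tuple[float, float, float], ...]:
    return tuple((c, PRESET_SIGMAS[c], w) for c, w in sorted(weights.items()))


def make_conformer_presets(
    noise_sigma: float = 0.01, seed: int = 0, rayleigh_height: float = 0.5
) -> dict[str, SpectrumRecipe]:
    """The four named conformer recipes.

    Monomer presets are tuned so that the analytic fingerprints are exactly
    R = 1.33 (native), 1.42 (cleaved) and 1.55 (latent); the polymer preset
    red-shifts the band weights so its emission maximum exceeds the native
    one by at least 5 nm. Tyrosinate weight is stronger in the native and
    polymeric forms.
    """
    trp_weights = {
        "native": {304.0: 0.108, 318.0: 0.170, 331.0: 0.300, 344.0: 0.270, 360.0: 0.152},
        "cleaved": {304.0: 0.143, 318.0: 0.160, 331.0: 0.280, 344.0: 0.270, 360.0: 0.147},
        "latent": {304.0: 0.132, 318.0: 0.160, 331.0: 0.300, 344.0: 0.260, 360.0: 0.148},
        "polymer": {304.0: 0.050, 318.0: 0.080, 331.0: 0.200, 344.0: 0.400, 360.0: 0.270},
    }
    targets = {"native": 1.33, "cleaved": 1.42, "latent": 1.55, "polymer": 1.40}
    tyrosinate_ratio = {"native": 0.55, "cleaved": 0.20, "latent": 0.20, "polymer": 0.70}

    presets = {}
    for name, weights in trp_weights.items():
        bands = _bands(weights)
        a_y, a_t = _solve_tyr_area(bands, targets[name], tyrosinate_ratio[name])
        presets[name] = SpectrumRecipe(
            band_spec=bands,
            tyr_area=a_y,
            tyrosinate_area=a_t,
            rayleigh_height=rayleigh_height,
            noise_sigma=noise_sigma,
            seed=seed,
            label=name,
        )
    return presets


def make_recovery_suite(
    master_seed: int = 37, n: int = 100, noise_sigma: float = 0.01
) -> list[SpectrumRecipe]:
    """Random conformer-like five-band recipes for parameter-recovery suites.

    Weights are drawn from a Dirichlet concentrated around a monomer-like
    composition (polymer-like spectra with a near-empty 304 nm band are
    excluded on purpose: their fingerprint carries almost no information at
    this noise level and they are classified by red-shift, not by R).
    """
    rng = np.random.default_rng(master_seed)
    centers = sorted(PRESET_SIGMAS)
    recipes = []
    for k in range(n):
        w = rng.dirichlet(np.array([3.0, 3.5, 5.0, 4.5, 3.0]) * 4.0)
        recipes.append(
            SpectrumRecipe(
                band_spec=tuple(
                    (c, PRESET_SIGMAS[c], float(a)) for c, a in zip(centers, w)
                ),
                tyr_area=float(rng.uniform(0.03, 0.12)),
                tyrosinate_area=float(rng.uniform(0.0, 0.05)),
                rayleigh_height=0.5,
                noise_sigma=noise_sigma,
                seed=int(rng.integers(0, 2**31)),
                label=f"random-{k}",
            )
        )
    return recipes


# ---------------------------------------------------------------------------
# toy structures & trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyStructureRecipe:
    """Recipe for a scripted toy structure/trajectory with analytic truth."""

    kind: str  # isolated_atoms | dimer | helix | sheet | peptide_pair
    n_res: int = 6
    n_frames: int = 1
    distance_A: float = 2.0
    spacing_A: float = 100.0
    hbond_script: tuple[bool, ...] | None = None
    saltbridge_script: tuple[bool, ...] | None = None
    displacement_script: dict[int, tuple[float, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for script in (self.hbond_script, self.saltbridge_script):
            if script is not None and len(script) != self.n_frames:
                raise ValueError("script length must equal n_frames")
        if self.displacement_script is not None:
            for offsets in self.displacement_script.values():
                if len(offsets) != self.n_frames:
                    raise ValueError("displacement script length must equal n_frames")


@dataclass(frozen=True)
class ToyTruth:
    """Closed-form expectations for a toy recipe."""

    sasa_total_A2: float | None = None
    hbond_occupancy: float | None = None
    saltbridge_occupancy: float | None = None
    rmsf_A: dict[int, float] | None = None
    mode1_variance_fraction: float | None = None


# --- internal backbone builder (NeRF) --------------------------------------

_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.5


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom."""
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: list[tuple[float, float]], chain: str = "A", res_name: str = "ALA", res_id_start: int = 1):
    """Poly-residue backbone (N, CA, C, O per residue) from dihedral angles.

    Returns parallel lists of (name, element, res_name, res_id, chain) and
    an ``(n_atoms, 3)`` coordinate array. Standard bond lengths and angles;
    omega fixed at 180 degrees.
    """
    names, coords = [], []
    n_prev = ca_prev = c_prev = None
    for i, (phi, psi) in enumerate(phi_psi):
        if i == 0:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([_BOND_N_CA, 0.0, 0.0])
            ang = np.radians(_ANG_N_CA_C)
            c = ca + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n = _place(n_prev, ca_prev, c_prev, _BOND_C_N, _ANG_CA_C_N, psi_prev)
            ca = _place(ca_prev, c_prev, n, _BOND_N_CA, _ANG_C_N_CA, 180.0)
            c = _place(c_prev, n, ca, _BOND_CA_C, _ANG_N_CA_C, phi)
        o = _place(n, ca, c, _BOND_C_O, _ANG_CA_C_O, psi + 180.0)
        for nm, xyz in (("N", n), ("CA", ca), ("C", c), ("O", o)):
            names.append((nm, nm[0], res_name, res_id_start + i, chain))
            coords.append(xyz)
        n_prev, ca_prev, c_prev, psi_prev = n, ca, c, psi
    return names, np.array(coords)


def _system_from_atoms(atoms: list[tuple], coords: np.ndarray) -> MolecularSystem:
    return MolecularSystem(
        names=np.array([a[0] for a in atoms], dtype=object),
        elements=np.array([a[1] for a in atoms], dtype=object),
        res_names=np.array([a[2] for a in atoms], dtype=object),
        res_ids=np.array([a[3] for a in atoms], dtype=int),
        chains=np.array([a[4] for a in atoms], dtype=object),
        coords=coords,
    )


#: Fully extended dihedrals used for the model sheet (exactly periodic).
SHEET_PHI_PSI = (-180.0, 180.0)


def _axis_align(xyz: np.ndarray) -> np.ndarray:
    """Rotate a strand so its axis runs along +x and its plane normal +z."""
    ca = xyz[1::4]
    d = ca[-1] - ca[0]
    d /= np.linalg.norm(d)
    centered = xyz - xyz.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    xax = d - (d @ normal) * normal
    xax /= np.linalg.norm(xax)
    yax = np.cross(normal, xax)
    rot = np.vstack([xax, yax, normal])
    out = centered @ rot.T
    return out - out.min(axis=0)


def _build_sheet(n_res: int) -> tuple[list[tuple], np.ndarray]:
    """Two antiparallel fully extended strands, registered for H-bonding.

    The partner strand is the first strand rotated 180 degrees about the
    sheet normal; its in-plane offset is found by a deterministic grid
    search maximizing the number of inter-strand N...O contacts at
    hydrogen-bonding distance.
    """
    atoms_a, xyz_a = build_backbone([SHEET_PHI_PSI] * n_res, chain="A")
    atoms_b, xyz_b = build_backbone([SHEET_PHI_PSI] * n_res, chain="B")
    xyz_a = _axis_align(xyz_a)
    xyz_b = _axis_align(xyz_b) @ np.diag([-1.0, -1.0, 1.0]).T

    na, oa = xyz_a[0::4], xyz_a[3::4]
    nb, ob = xyz_b[0::4], xyz_b[3::4]
    x_hi = xyz_a[:, 0].max()
    best = (-1, 0.0, 0.0)
    for tx in np.arange(x_hi - 9.0, x_hi - 1.0, 0.05):
        for ty in np.arange(4.0, 7.5, 0.05):
            t = np.array([tx, ty, 0.0])
            d1 = np.linalg.norm(na[:, None] - (ob + t)[None], axis=2)
            d2 = np.linalg.norm(oa[:, None] - (nb + t)[None], axis=2)
            score = int(((d1 > 2.75) & (d1 < 3.1)).sum()) + int(
                ((d2 > 2.75) & (d2 < 3.1)).sum()
            )
            if score > best[0]:
                best = (score, tx, ty)
    xyz_b = xyz_b + np.array([best[1], best[2], 0.0])
    return atoms_a + atoms_b, np.vstack([xyz_a, xyz_b])


def _make_peptide_pair(recipe: ToyStructureRecipe):
    """Donor/acceptor glycine pair with scripted interactions.

    Residue A1 carries an N-H donor aimed along +x; residue B1 an acceptor
    O placed 2.9 A (bond on) or 10 A (off) from the donor N. An optional
    ARG/GLU side-chain pair toggles a salt bridge at 3.0 / 8.0 A.
    """
    atoms = [
        ("N", "N", "GLY", 1, "A"),
        ("H", "H", "GLY", 1, "A"),
        ("CA", "C", "GLY", 1, "A"),
        ("C", "C", "GLY", 1, "A"),
        ("O", "O", "GLY", 2, "B"),
        ("C", "C", "GLY", 2, "B"),
        ("CA", "C", "GLY", 2, "B"),
        ("NH1", "N", "ARG", 3, "A"),
        ("CZ", "C", "ARG", 3, "A"),
        ("OE1", "O", "GLU", 4, "B"),
        ("CD", "C", "GLU", 4, "B"),
    ]
    base = np.array(
        [
            [0.0, 0.0, 0.0],  # N donor
            [1.0, 0.0, 0.0],  # H along +x
            [-0.8, 1.2, 0.0],  # CA
            [-1.6, 0.1, 0.9],  # C
            [2.9, 0.0, 0.0],  # acceptor O (on position)
            [3.9, 0.6, 0.0],
            [5.0, -0.3, 0.5],
            [0.0, 20.0, 0.0],  # ARG NH1
            [-1.2, 20.5, 0.0],
            [3.0, 20.0, 0.0],  # GLU OE1 (on position)
            [4.1, 20.6, 0.0],
        ]
    )
    frames = np.repeat(base[None, :, :], recipe.n_frames, axis=0)
    if recipe.hbond_script is not None:
        for f, on in enumerate(recipe.hbond_script):
            if not on:
                frames[f, 4:7, 0] += 7.1  # push acceptor group to 10 A
    if recipe.saltbridge_script is not None:
        for f, on in enumerate(recipe.saltbridge_script):
            if not on:
                frames[f, 9:11, 0] += 5.0  # 3.0 -> 8.0 A
    return atoms, base, frames


def make_toy_system(
    recipe: ToyStructureRecipe,
) -> tuple[MolecularSystem, Trajectory, ToyTruth]:
    """Build a toy system, its trajectory and closed-form expected values."""
    probe = 1.4
    if recipe.kind == "isolated_atoms":
        n = max(1, recipe.n_res)
        atoms = [("C", "C", "ALA", i + 1, "A") for i in range(n)]
        coords = np.array([[i * recipe.spacing_A, 0.0, 0.0] for i in range(n)])
        truth = ToyTruth(sasa_total_A2=n * 4 * np.pi * (1.7 + probe) ** 2)
        frames = np.repeat(coords[None], recipe.n_frames, axis=0)
    elif recipe.kind == "dimer":
        atoms = [("C", "C", "ALA", 1, "A"), ("C", "C", "ALA", 2, "A")]
        coords = np.array([[0.0, 0.0, 0.0], [recipe.distance_A, 0.0, 0.0]])
        truth = ToyTruth()
        frames = np.repeat(coords[None], recipe.n_frames, axis=0)
    elif recipe.kind == "helix":
        atoms, coords = build_backbone([HELIX_PHI_PSI] * recipe.n_res)
        truth = ToyTruth()
        frames = np.repeat(coords[None], recipe.n_frames, axis=0)
    elif recipe.kind == "sheet":
        atoms, coords = _build_sheet(recipe.n_res)
        truth = ToyTruth()
        frames = np.repeat(coords[None], recipe.n_frames, axis=0)
    elif recipe.kind == "peptide_pair":
        atoms, coords, frames = _make_peptide_pair(recipe)
        hb = (
            sum(recipe.hbond_script) / recipe.n_frames
            if recipe.hbond_script is not None
            else None
        )
        sb = (
            sum(recipe.saltbridge_script) / recipe.n_frames
            if recipe.saltbridge_script is not None
            else None
        )
        truth = ToyTruth(hbond_occupancy=hb, saltbridge_occupancy=sb)
    else:
        raise ValueError(f"unknown toy kind {recipe.kind!r}")

    rmsf_truth: dict[int, float] | None = None
    if recipe.displacement_script is not None:
        sys_tmp = _system_from_atoms(atoms, coords)
        targets = sys_tmp.ca_indices()
        if targets.size == 0:
            # no C-alphas (e.g. isolated atoms): one atom per residue
            _, targets = np.unique(sys_tmp.res_ids, return_index=True)
        rmsf_truth = {}
        for res_idx, offsets in recipe.displacement_script.items():
            off = np.asarray(offsets, dtype=float)
            frames[:, targets[res_idx], 2] += off
            rmsf_truth[res_idx] = float(np.sqrt(np.mean((off - off.mean()) ** 2)))
        truth = ToyTruth(
            sasa_total_A2=truth.sasa_total_A2,
            hbond_occupancy=truth.hbond_occupancy,
            saltbridge_occupancy=truth.saltbridge_occupancy,
            rmsf_A=rmsf_truth,
        )

    sys = _system_from_atoms(atoms, coords)
    return sys, Trajectory(frames=frames), truth


def make_collective_motion(
    n_res: int = 12, n_frames: int = 20, amplitude_A: float = 1.0, seed: int = 0
) -> tuple[MolecularSystem, Trajectory, ToyTruth]:
    """A C-alpha chain with a single scripted collective (rank-1) motion.

    The displacement pattern is orthogonalized against rigid translations
    and in-plane rotations so that frame alignment leaves the motion
    intact; all positional variance sits in one essential mode.
    """
    atoms = [("CA", "C", "ALA", i + 1, "A") for i in range(n_res)]
    x = 3.8 * np.arange(n_res)
    coords = np.column_stack([x, np.zeros(n_res), np.zeros(n_res)])

    pattern = np.sin(np.linspace(0, 3 * np.pi, n_res)) ** 2
    # remove components along rigid z-translation (1) and rotation (~x)
    for basis in (np.ones(n_res), x - x.mean()):
        basis = basis / np.linalg.norm(basis)
        pattern = pattern - (pattern @ basis) * basis
    pattern /= np.max(np.abs(pattern))

    amps = amplitude_A * np.sin(2 * np.pi * np.arange(n_frames) / n_frames)
    frames = np.repeat(coords[None], n_frames, axis=0)
    frames[:, :, 2] += amps[:, None] * pattern[None, :]
    truth = ToyTruth(mode1_variance_fraction=1.0)
    return (
        _system_from_atoms(atoms, coords),
        Trajectory(frames=frames),
        truth,
    )
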