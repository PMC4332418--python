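"""Far-UV circular dichroism: unit conversion and secondary-structure fitting.

Observed ellipticity (degrees) is converted to the mean-residue differential
extinction coefficient, then decomposed onto user-supplied per-class basis
spectra by non-negative least squares. The shipped default basis is a set of
synthetic idealized helix/sheet/other curves meant for testing, not a
replacement for curated protein reference sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "CDSpectrum",
    "SampleInfo",
    "SecondaryStructureFractions",
    "ellipticity_to_delta_eps",
    "fit_secondary_structure",
    "default_basis",
    "largest_remainder_counts",
    "DEFAULT_CD_GRID_NM",
]

#: Conversion constant relating degrees of ellipticity to delta-epsilon.
ELLIPTICITY_CONSTANT = 32.982


class CDError(ValueError):
    """Raised on invalid CD inputs."""


@dataclass(frozen=True)
class SampleInfo:
    """Cuvette/sample metadata needed for the mean-residue conversion."""

    path_cm: float
    conc_molar: float
    n_res: int

    def __post_init__(self) -> None:
        if self.path_cm <= 0:
            raise CDError("path length must be positive")
        if self.conc_molar <= 0:
            raise CDError("concentration must be positive")
        if self.n_res < 1 or int(self.n_res) != self.n_res:
            raise CDError("residue count must be a positive integer")


@dataclass(frozen=True)
class CDSpectrum:
    """Observed ellipticity (degrees) on a wavelength grid, with sample info."""

    lambda_nm: np.ndarray
    theta_deg: np.ndarray
    sample: SampleInfo

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_nm, dtype=float)
        theta = np.asarray(self.theta_deg, dtype=float)
        if lam.ndim != 1 or theta.shape != lam.shape:
            raise CDError("grid/ellipticity shape mismatch")
        object.__setattr__(self, "lambda_nm", lam)
        object.__setattr__(self, "theta_deg", theta)


@dataclass(frozen=True)
class SecondaryStructureFractions:
    f_helix: float
    f_sheet: float
    f_other: float
    counts: tuple[int, ...]
    uncertainty: tuple[float, ...]

    def fractions(self) -> np.ndarray:
        return np.array([self.f_helix, self.f_sheet, self.f_other])


def ellipticity_to_delta_eps(spec: CDSpectrum) -> np.ndarray:
    """Mean-residue differential extinction, per wavelength (M^-1 cm^-1).

    delta_eps = theta / (n_res * path_cm * conc_molar * 32.982)
    """
    s = spec.sample
    denom = s.n_res * s.path_cm * s.conc_molar * ELLIPTICITY_CONSTANT
    return spec.theta_deg / denom


def default_basis(lambda_nm: np.ndarray) -> np.ndarray:
    """Synthetic idealized 3-class basis (columns: helix, sheet, other).

    Shapes qualitatively mimic far-UV CD signatures: helix with a positive
    band near 193 nm and double negative bands at 208/222 nm; sheet with a
    195 nm positive and 218 nm negative band; disordered with a deep
    negative band near 198 nm. Units are arbitrary but fixed.
    """
    lam = np.asarray(lambda_nm, dtype=float)

    def g(center, sigma, amp):
        return amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)

    helix = g(192, 4.5, 10.0) + g(208, 4.5, -6.0) + g(223, 5.0, -5.5)
    sheet = g(196, 4.5, 8.0) + g(217, 5.5, -5.0)
    other = g(199, 5.5, -9.0) + g(224, 7.0, 2.0)
    return np.column_stack([helix, sheet, other])


#: Recommended acquisition grid for the synthetic basis (nm).
DEFAULT_CD_GRID_NM = np.arange(185.0, 260.5, 0.5)


def largest_remainder_counts(fractions: np.ndarray, n_res: int) -> tuple[int, ...]:
    """Integer class counts summing exactly to ``n_res``."""
    raw = np.asarray(fractions, dtype=float) * n_res
    base = np.floor(raw).astype(int)
    short = n_res - int(base.sum())
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i % len(base)]] += 1
    return tuple(int(c) for c in base)


def fit_secondary_structure(
    delta_eps: np.ndarray,
    basis: np.ndarray,
    n_res: int,
    n_boot: int = 200,
    seed: int = 0,
) -> SecondaryStructureFractions:
    """Non-negative basis fit with sum-to-one renormalization.

    Uncertainties come from a seeded residual bootstrap: residuals of the
    best fit are resampled, added back to the model prediction, and the fit
    repeated; the half-width is the standard deviation across replicates.
    """
    y = np.asarray(delta_eps, dtype=float)
    B = np.asarray(basis, dtype=float)
    if B.ndim != 2 or B.shape[0] != y.size:
        raise CDError("basis does not cover the data wavelength range")
    if B.shape[1] < 2:
        raise CDError("need >= 2 basis classes")
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise CDError("rank-deficient basis")

    def solve(target: np.ndarray) -> np.ndarray:
        coef, _ = nnls(B, target)
        total = coef.sum()
        if total == 0:
            return np.full(B.shape[1], 1.0 / B.shape[1])
        return coef / total

    frac = solve(y)
    # bootstrap on the residuals of the un-normalized NNLS solution
    coef0, _ = nnls(B, y)
    resid = y - B @ coef0
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, B.shape[1]))
    for k in range(n_boot):
        y_star = B @ coef0 + rng.choice(resid, size=resid.size, replace=True)
        reps[k] = solve(y_star)
    unc = tuple(float(u) for u in reps.std(axis=0))

    counts = largest_remainder_counts(frac, n_res)
    return SecondaryStructureFractions(
        f_helix=float(frac[0]),
        f_sheet=float(frac[1]),
        f_other=float(frac[2]) if frac.size > 2 else 0.0,
        counts=counts,
        uncertainty=unc,
    )
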