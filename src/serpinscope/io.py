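"""Plain-text readers/writers for spectra and basis matrices.

Spectrum files are two-column delimited text (wavelength_nm, value) with
``#`` comment lines; metadata travels as ``# key = value`` header comments
(recognized keys: ``lambda_ex``, ``label``).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from serpinscope.spectra import EmissionSpectrum, CorrectionCurve

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_correction_curve",
    "read_two_column",
    "read_matrix",
]

_KEY_RE = re.compile(r"^#\s*(\w+)\s*=\s*(.+?)\s*$")


def _read_header_keys(path: str | Path) -> dict[str, str]:
    keys: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _KEY_RE.match(line)
            if m:
                keys[m.group(1)] = m.group(2)
    return keys


def read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two-column data")
    return data[:, 0], data[:, 1]


def read_spectrum(
    path: str | Path,
    lambda_ex_nm: float | None = None,
    label: str | None = None,
) -> EmissionSpectrum:
    """Read an emission spectrum; CLI metadata overrides header keys."""
    keys = _read_header_keys(path)
    lam, inten = read_two_column(path)
    if lambda_ex_nm is None:
        if "lambda_ex" not in keys:
            raise ValueError(f"{path}: no excitation wavelength (header or flag)")
        lambda_ex_nm = float(keys["lambda_ex"])
    if label is None:
        label = keys.get("label", Path(path).stem)
    return EmissionSpectrum(
        lambda_nm=lam, intensity=inten, lambda_ex_nm=lambda_ex_nm, label=label
    )


def write_spectrum(path: str | Path, spec: EmissionSpectrum) -> None:
    header = f"lambda_ex = {spec.lambda_ex_nm:g}\nlabel = {spec.label}"
    np.savetxt(
        path,
        np.column_stack([spec.lambda_nm, spec.intensity]),
        fmt="%.6g",
        header=header,
    )


def read_correction_curve(path: str | Path) -> CorrectionCurve:
    lam, fac = read_two_column(path)
    return CorrectionCurve(lambda_nm=lam, factor=fac)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace/comma-delimited numeric matrix (``#`` comments)."""
    try:
        return np.loadtxt(path, comments="#")
    except ValueError:
        return np.loadtxt(path, comments="#", delimiter=",")
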