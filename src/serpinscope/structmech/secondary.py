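"""Backbone hydrogen-bond-pattern secondary-structure assignment.

Labels each residue helix / sheet / other from backbone N-H...O=C hydrogen
bonds scored with the classic electrostatic approximation (cutoff -0.5
kcal/mol). Helices come from i -> i+4 bond runs, sheets from parallel or
antiparallel bridge ladders. Amide hydrogens are taken from the structure
when present, otherwise placed 1 A from N along the preceding carbonyl
C -> O direction reversed (the standard reconstruction).
"""

from __future__ import annotations

import numpy as np

from serpinscope.structmech.system import MolecularSystem, StructureError

__all__ = ["assign_secondary_structure", "backbone_hbond_energy_matrix"]

_Q1Q2_F = 0.084 * 332.0  # kcal/mol * A, electrostatic H-bond model constant
_ENERGY_CUTOFF = -0.5  # kcal/mol
_MIN_SEQ_SEP = 2  # exclude i, i+1 and i+2 partners


def _backbone_table(sys: MolecularSystem):
    """Per-residue dict of backbone atom coordinates, in chain order."""
    residues: list[dict] = []
    index: dict[tuple[str, int], int] = {}
    for i in range(sys.n_atoms):
        key = (str(sys.chains[i]), int(sys.res_ids[i]))
        if key not in index:
            index[key] = len(residues)
            residues.append({"chain": key[0], "res_id": key[1]})
        nm = str(sys.names[i])
        if nm in ("N", "CA", "C", "O", "H", "HN"):
            residues[index[key]]["H" if nm == "HN" else nm] = sys.coords[i]
    return residues


def _amide_hydrogens(residues: list[dict]) -> list[np.ndarray | None]:
    hs: list[np.ndarray | None] = []
    for k, res in enumerate(residues):
        if "H" in res:
            hs.append(res["H"])
            continue
        prev = residues[k - 1] if k > 0 else None
        chain_ok = prev is not None and prev["chain"] == res["chain"]
        if (
            chain_ok
            and "N" in res
            and "C" in prev
            and "O" in prev
            and np.linalg.norm(res["N"] - prev["C"]) < 2.5
        ):
            d = prev["C"] - prev["O"]
            hs.append(res["N"] + d / np.linalg.norm(d))
        else:
            hs.append(None)  # chain start / break: no amide H
    return hs


def backbone_hbond_energy_matrix(sys: MolecularSystem) -> tuple[np.ndarray, list[dict]]:
    """Electrostatic backbone H-bond energies E[donor_res, acceptor_res].

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, with
    the donor residue providing N-H and the acceptor providing C=O.
    Entries default to 0 (no bond possible).
    """
    residues = _backbone_table(sys)
    n = len(residues)
    hs = _amide_hydrogens(residues)
    energy = np.zeros((n, n))
    for d in range(n):
        if hs[d] is None or "N" not in residues[d]:
            continue
        nd, hd = residues[d]["N"], hs[d]
        for a in range(n):
            if a == d:
                continue
            ra = residues[a]
            if "C" not in ra or "O" not in ra:
                continue
            if residues[d]["chain"] == ra["chain"] and abs(
                residues[d]["res_id"] - ra["res_id"]
            ) < _MIN_SEQ_SEP:
                continue
            r_on = np.linalg.norm(ra["O"] - nd)
            if r_on > 5.2:
                continue
            r_ch = np.linalg.norm(ra["C"] - hd)
            r_oh = np.linalg.norm(ra["O"] - hd)
            r_cn = np.linalg.norm(ra["C"] - nd)
            energy[d, a] = _Q1Q2_F * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
    return energy, residues


def assign_secondary_structure(
    sys: MolecularSystem,
) -> tuple[list[str], dict[str, int]]:
    """Per-residue labels {helix, sheet, other} and class counts.

    Helix: residues covered by an i(C=O) <- i+4(N-H) bond, requiring two
    consecutive such bonds (the standard run criterion). Sheet: residues in
    parallel or antiparallel bridges extended into ladders; isolated
    bridges still count as sheet here, a deliberate simplification.
    """
    energy, residues = backbone_hbond_energy_matrix(sys)
    n = len(residues)
    if n == 0:
        return [], {"helix": 0, "sheet": 0, "other": 0}
    hbond = energy < _ENERGY_CUTOFF  # hbond[d, a]: d's N-H donates to a's C=O

    labels = ["other"] * n

    def same_chain(i: int, j: int) -> bool:
        return residues[i]["chain"] == residues[j]["chain"]

    # helix: 4-turns at i and i+1 -> residues i+1 .. i+4 helical
    turn4 = [
        i + 4 < n and same_chain(i, i + 4) and hbond[i + 4, i] for i in range(n)
    ]
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            for k in range(i + 1, i + 6):
                if k < n:
                    labels[k] = "helix"

    # bridges (sheet)
    bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3 and same_chain(i, j):
                continue
            para = (hbond[j, i - 1] and hbond[i + 1, j]) or (
                hbond[i, j - 1] and hbond[j + 1, i]
            )
            anti = (hbond[i, j] and hbond[j, i]) or (
                hbond[i + 1, j - 1] and hbond[j + 1, i - 1]
            )
            if para or anti:
                bridge[i] = bridge[j] = True
    for i in range(n):
        if bridge[i] and labels[i] != "helix":
            labels[i] = "sheet"

    counts = {
        "helix": labels.count("helix"),
        "sheet": labels.count("sheet"),
        "other": labels.count("other"),
    }
    return labels, counts
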