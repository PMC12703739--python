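"""Independent oracles used by the test suite.

Each function here deliberately recomputes a quantity by a different route
than the package: quaternion-eigenvalue superposition instead of SVD
Kabsch, O(N^2) all-pairs loops instead of KD-trees, a residue-composition
mass table instead of pyteomics, and direct closed forms for the 1:1
binding model.
"""

from __future__ import annotations

import re

import numpy as np

# ---------------------------------------------------------------------------
# quaternion-eigenvalue superposition (Horn's method)


def quaternion_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Optimal-superposition RMSD via the largest eigenvalue of Horn's 4x4 key matrix."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    n = len(a)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    m = b0.T @ a0  # correlation of b against a
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    sq = (np.sum(a0**2) + np.sum(b0**2) - 2.0 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


# ---------------------------------------------------------------------------
# all-pairs contact sets


def brute_force_contacts(structure, chain_a: str, chain_b: str, cutoff: float,
                         atom_mode: str = "heavy"):
    """(residues_a, residues_b, pairs) by explicit double loops."""
    def atoms(chain):
        out = []
        for res in chain.residues:
            for at in res.atoms:
                if atom_mode == "ca" and at.name != "CA":
                    continue
                if atom_mode == "heavy" and at.is_hydrogen:
                    continue
                out.append((res.index, at.coord))
        return out

    aa = atoms(structure.chain(chain_a))
    bb = atoms(structure.chain(chain_b))
    pairs = set()
    for ra, ca in aa:
        for rb, cb in bb:
            if np.sqrt(np.sum((ca - cb) ** 2)) <= cutoff:
                pairs.add((ra, rb))
    res_a = {(chain_a, ra) for ra, _ in pairs}
    res_b = {(chain_b, rb) for _, rb in pairs}
    return res_a, res_b, pairs


# ---------------------------------------------------------------------------
# residue-composition average-mass table (CIAAW atomic weights)

_WEIGHTS = {"H": 1.00794, "C": 12.0107, "N": 14.0067, "O": 15.9994, "S": 32.065}
_COMPOSITIONS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO", "V": "C5H9NO",
    "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO", "I": "C6H11NO", "N": "C4H6N2O2",
    "D": "C4H5NO3", "Q": "C5H8N2O2", "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS",
    "H": "C6H7N3O", "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}


def _formula_mass(formula: str) -> float:
    return sum(
        _WEIGHTS[el] * (int(n) if n else 1)
        for el, n in re.findall(r"([A-Z])(\d*)", formula)
    )


WATER_MASS = _formula_mass("H2O")

RESIDUE_AVERAGE_MASS = {aa: _formula_mass(f) for aa, f in _COMPOSITIONS.items()}


def peptide_average_mass(seq: str) -> float:
    """Average peptide mass from the residue table, independent of pyteomics."""
    return sum(RESIDUE_AVERAGE_MASS[a] for a in seq) + WATER_MASS


# ---------------------------------------------------------------------------
# 1:1 Langmuir closed forms


def langmuir_curve(t, conc, t_assoc, kon, koff, rmax):
    """Association/dissociation closed form, written out pointwise."""
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    out = np.empty_like(np.asarray(t, float))
    for i, ti in enumerate(np.asarray(t, float)):
        if ti <= t_assoc:
            out[i] = req * (1.0 - np.exp(-(kon * conc + koff) * ti))
        else:
            r_end = req * (1.0 - np.exp(-(kon * conc + koff) * t_assoc))
            out[i] = r_end * np.exp(-koff * (ti - t_assoc))
    return out
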