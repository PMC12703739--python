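"""Per-design structural and confidence metrics.

The filtering quantities for masked-binder triage: interface contact sets,
mask coverage of the binder-receptor interface, mask orientation relative
to the binder termini, mean pLDDT over a residue selection, interchain PAE,
and Kabsch-superposed Cα RMSD between models.

Contact definitions default to heavy atoms (all non-hydrogen): side-chain
occlusion is the physical mechanism of steric masking, so Cα-only contacts
would undercount.  A ``ca`` mode is retained for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structio import Chain, ChainRole, Structure

__all__ = [
    "InterfaceReport",
    "CoverageResult",
    "OrientationResult",
    "SuperpositionResult",
    "interface_residues",
    "mask_coverage",
    "orientation_check",
    "mean_plddt",
    "interchain_pae",
    "kabsch_superpose",
    "ca_rmsd",
]

ORIENTATION_TIE_TOL = 1e-6  # Angstrom; ties count as not C-terminal


@dataclass
class InterfaceReport:
    contact_cutoff: float
    residues_a: set[tuple[str, int]]
    residues_b: set[tuple[str, int]]
    n_pairs: int


@dataclass
class CoverageResult:
    interface_residues: set[tuple[str, int]]
    blocked_residues: set[tuple[str, int]]
    coverage: float
    empty_interface: bool = False


@dataclass
class OrientationResult:
    d_cterm: float
    d_nterm: float
    c_terminal_orientation: bool


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def _chain_atom_coords(chain: Chain, atom_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """(coords, residue indices) over the chosen atom set of a chain."""
    coords: list[np.ndarray] = []
    res_idx: list[int] = []
    for res in chain.residues:
        if atom_mode == "ca":
            ca = res.ca
            if ca is None:
                raise ValueError(
                    f"atom_mode='ca' but chain {chain.id} residue {res.index} lacks CA"
                )
            coords.append(ca.coord)
            res_idx.append(res.index)
        else:
            for a in res.atoms:
                if not a.is_hydrogen:
                    coords.append(a.coord)
                    res_idx.append(res.index)
    return np.asarray(coords), np.asarray(res_idx, dtype=int)


def interface_residues(
    s: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
    atom_mode: str = "heavy",
) -> InterfaceReport:
    """Residues of each chain with any atom within ``cutoff`` of the partner.

    A residue is at the interface iff its minimum inter-atomic distance (over
    the chosen atom set) to the partner chain is <= cutoff.  ``n_pairs``
    counts residue pairs in contact.  Default cutoff 5.0 Å.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if atom_mode not in ("heavy", "ca"):
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    ca_coords, ca_res = _chain_atom_coords(s.chain(chain_a), atom_mode)
    cb_coords, cb_res = _chain_atom_coords(s.chain(chain_b), atom_mode)
    pairs: set[tuple[int, int]] = set()
    if len(ca_coords) and len(cb_coords):
        tree_b = cKDTree(cb_coords)
        hits = cKDTree(ca_coords).query_ball_tree(tree_b, r=cutoff)
        for ia, neigh in enumerate(hits):
            for ib in neigh:
                pairs.add((int(ca_res[ia]), int(cb_res[ib])))
    res_a = {(chain_a, ra) for ra, _ in pairs}
    res_b = {(chain_b, rb) for _, rb in pairs}
    return InterfaceReport(cutoff, res_a, res_b, n_pairs=len(pairs))


def mask_coverage(
    binder_receptor_model: Structure,
    binder_mask_model: Structure,
    cutoff: float = 5.0,
    atom_mode: str = "heavy",
) -> CoverageResult:
    """Fraction of binder interface residues sterically blocked by the mask.

    The interface set is computed on the binder-receptor model; the blocked
    subset holds interface residues whose same-index counterpart in the
    binder-mask model lies within ``cutoff`` of the mask chain.  An empty
    interface yields coverage 0.0 with ``empty_interface=True`` rather than
    an error, so batch triage never aborts on a degenerate design.
    """
    binder_br = binder_receptor_model.chain_by_role(ChainRole.BINDER)
    receptor = binder_receptor_model.chain_by_role(ChainRole.RECEPTOR)
    binder_bm = binder_mask_model.chain_by_role(ChainRole.BINDER)
    mask = binder_mask_model.chain_by_role(ChainRole.MASK)
    if len(binder_br) != len(binder_bm):
        raise ValueError(
            f"binder length mismatch between models: {len(binder_br)} vs {len(binder_bm)}"
        )
    iface = interface_residues(
        binder_receptor_model, binder_br.id, receptor.id, cutoff, atom_mode
    ).residues_a
    interface_set = {(binder_br.id, idx) for _, idx in iface}
    near_mask = interface_residues(
        binder_mask_model, binder_bm.id, mask.id, cutoff, atom_mode
    ).residues_a
    near_mask_idx = {idx for _, idx in near_mask}
    blocked = {(cid, idx) for cid, idx in interface_set if idx in near_mask_idx}
    if not interface_set:
        return CoverageResult(set(), set(), 0.0, empty_interface=True)
    return CoverageResult(interface_set, blocked, len(blocked) / len(interface_set))


def orientation_check(binder_mask_model: Structure) -> OrientationResult:
    """Is the mask N-terminus near the binder C-terminus?

    Distances are between Cα atoms of the terminal residues.  Ties within
    1e-6 Å resolve as not C-terminal (conservative for cloning order).
    """
    binder = binder_mask_model.chain_by_role(ChainRole.BINDER)
    mask = binder_mask_model.chain_by_role(ChainRole.MASK)
    terms = {
        "binder N": binder.residues[0], "binder C": binder.residues[-1],
        "mask N": mask.residues[0], "mask C": mask.residues[-1],
    }
    cas = {}
    for label, res in terms.items():
        ca = res.ca
        if ca is None:
            raise ValueError(f"missing terminal CA on {label} (residue {res.index})")
        cas[label] = ca.coord
    d_cterm = float(np.linalg.norm(cas["binder C"] - cas["mask N"]))
    d_nterm = float(np.linalg.norm(cas["binder N"] - cas["mask C"]))
    return OrientationResult(d_cterm, d_nterm, (d_nterm - d_cterm) > ORIENTATION_TIE_TOL)


def mean_plddt(conf, selection="all") -> float:
    """Arithmetic mean pLDDT over a residue selection (or the whole model)."""
    if isinstance(selection, str) and selection == "all":
        return float(np.mean(conf.plddt))
    keys = list(selection)
    if not keys:
        raise ValueError("empty selection")
    return float(np.mean(conf.plddt[conf.positions(keys)]))


def interchain_pae(conf, set_a, set_b) -> float:
    """Mean PAE over both off-diagonal blocks, equally weighted per entry."""
    keys_a, keys_b = list(set_a), list(set_b)
    if not keys_a or not keys_b:
        raise ValueError("residue sets must be non-empty")
    if set(map(tuple, keys_a)) & set(map(tuple, keys_b)):
        raise ValueError("residue sets overlap")
    ia = conf.positions(keys_a)
    ib = conf.positions(keys_b)
    block_ab = conf.pae[np.ix_(ia, ib)]
    block_ba = conf.pae[np.ix_(ib, ia)]
    return float(np.concatenate([block_ab.ravel(), block_ba.ravel()]).mean())


def kabsch_superpose(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of B onto A (Kabsch, SVD).

    Returns the proper rotation (det +1, reflections corrected), the
    translation mapping ``R @ b + t`` onto A, and the residual RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching N x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be a non-negative N-vector with positive sum")
        w = w / w.sum()
    cen_a = w @ a
    cen_b = w @ b
    a0 = a - cen_a
    b0 = b - cen_b
    cov = (a0 * w[:, None]).T @ b0
    u, s, vt = np.linalg.svd(cov)
    if np.sum(s > s[0] * 1e-10 if s[0] > 0 else s > 0) < 2:
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rotation = u @ corr @ vt
    translation = cen_a - rotation @ cen_b
    diff = a0 - b0 @ rotation.T
    rmsd = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return SuperpositionResult(rotation, translation, rmsd)


def _paired_ca(model_a: Structure, model_b: Structure, selection) -> tuple[np.ndarray, np.ndarray]:
    def key_map(st: Structure) -> dict[tuple[str, int], np.ndarray]:
        out = {}
        for ch in st.chains:
            # pair by role when assigned, else by chain id, so models with
            # different chain naming still align
            key = ch.role.value if ch.role != ChainRole.UNASSIGNED else ch.id
            for res in ch.residues:
                ca = res.ca
                if ca is None:
                    raise ValueError(f"missing CA on chain {ch.id} residue {res.index}")
                out[(key, res.index)] = ca.coord
        return out

    map_a = key_map(model_a)
    map_b = key_map(model_b)
    if isinstance(selection, str) and selection == "all":
        keys = sorted(map_a)
        if set(keys) != set(map_b):
            raise ValueError("models have unpaired residues")
    else:
        keys = sorted(tuple(k) for k in selection)
        missing = [k for k in keys if k not in map_a or k not in map_b]
        if missing:
            raise ValueError(f"unpaired residues in selection: {missing[:5]}")
    return (np.array([map_a[k] for k in keys]), np.array([map_b[k] for k in keys]))


def ca_rmsd(model_a: Structure, model_b: Structure, selection="all") -> float:
    """Kabsch-superposed Cα RMSD between two models.

    Residues pair by (chain role, residue index), falling back to chain id
    where roles are unassigned.  The design-model acceptance gate used in
    triage passes iff this is below 1.5 Å.
    """
    ca, cb = _paired_ca(model_a, model_b, selection)
    return kabsch_superpose(ca, cb).rmsd
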