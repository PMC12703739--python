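"""Filter cascade, ranking and diverse shortlist selection for mask designs.

The cascade applies the in-silico acceptance gates used to shortlist
masked-binder candidates from predicted structures: complex pLDDT > 90,
mask pLDDT > 80, interchain PAE <= 8 Å, interface coverage >= 60 %
(tunable up to 80 %), C-terminal mask orientation, and — when a design
backbone is supplied — Cα RMSD to the prediction < 1.5 Å.  Inequality
strictness is fixed: pLDDT strictly greater, PAE inclusive (so a design
printing exactly the threshold passes), coverage inclusive, RMSD strict.

Survivors are ranked (coverage desc, interchain PAE asc, complex pLDDT
desc, design id) and a diverse shortlist — default five per binder — is
drawn by greedy max-min selection on mask-sequence distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align

from . import metrics
from .structio import ChainRole, ConfidenceData, Structure

__all__ = [
    "TriageThresholds",
    "DesignBundle",
    "DesignRecord",
    "evaluate_design",
    "rank_designs",
    "select_diverse",
    "sequence_identity",
    "sequence_distance",
]

LENGTH_WEIGHT = 0.2  # weight of the length term in the diversity distance


@dataclass
class TriageThresholds:
    min_complex_plddt: float = 90.0
    min_mask_plddt: float = 80.0
    max_interchain_pae: float = 8.0
    min_coverage: float = 0.60
    require_c_terminal: bool = True
    max_design_rmsd: float = 1.5
    contact_cutoff: float = 5.0

    def __post_init__(self) -> None:
        import math

        vals = [
            self.min_complex_plddt, self.min_mask_plddt, self.max_interchain_pae,
            self.min_coverage, self.max_design_rmsd, self.contact_cutoff,
        ]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("thresholds must be finite")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError("min_coverage must lie in [0, 1]")


@dataclass
class DesignBundle:
    """Everything needed to evaluate one candidate design."""

    design_id: str
    binder_mask: Structure  # predicted binder+mask complex, roles assigned
    confidence: ConfidenceData  # aligned to binder_mask
    binder_receptor: Structure  # reference binder-receptor complex
    design_backbone: Structure | None = None  # generative-model backbone, optional


@dataclass
class DesignRecord:
    design_id: str
    mask_sequence: str
    metrics: dict[str, float | bool | None]
    flags: dict[str, bool]
    passed: bool

    def to_row(self) -> dict:
        row = {"design_id": self.design_id, "mask_sequence": self.mask_sequence}
        row.update({k: v for k, v in self.metrics.items()})
        row.update({f"pass_{k}": v for k, v in self.flags.items()})
        row["passed"] = self.passed
        return row


def evaluate_design(bundle: DesignBundle, thresholds: TriageThresholds | None = None) -> DesignRecord:
    """Compute all triage metrics for one design and apply the cascade."""
    th = thresholds or TriageThresholds()
    bm = bundle.binder_mask
    binder = bm.chain_by_role(ChainRole.BINDER)
    mask = bm.chain_by_role(ChainRole.MASK)
    binder_keys = [(binder.id, r.index) for r in binder.residues]
    mask_keys = [(mask.id, r.index) for r in mask.residues]

    complex_plddt = metrics.mean_plddt(bundle.confidence, binder_keys + mask_keys)
    mask_plddt = metrics.mean_plddt(bundle.confidence, mask_keys)
    pae = metrics.interchain_pae(bundle.confidence, binder_keys, mask_keys)
    cov = metrics.mask_coverage(bundle.binder_receptor, bm, cutoff=th.contact_cutoff)
    if cov.empty_interface:
        warnings.warn(f"{bundle.design_id}: empty binder-receptor interface; coverage set to 0")
    orient = metrics.orientation_check(bm)
    design_rmsd = None
    if bundle.design_backbone is not None:
        design_rmsd = metrics.ca_rmsd(bundle.design_backbone, bm, selection="all")

    vals: dict[str, float | bool | None] = {
        "complex_plddt": complex_plddt,
        "mask_plddt": mask_plddt,
        "interchain_pae": pae,
        "coverage": cov.coverage,
        "c_terminal_orientation": orient.c_terminal_orientation,
        "design_rmsd": design_rmsd,
    }
    flags = {
        "complex_plddt": complex_plddt > th.min_complex_plddt,
        "mask_plddt": mask_plddt > th.min_mask_plddt,
        "interchain_pae": pae <= th.max_interchain_pae,
        "coverage": cov.coverage >= th.min_coverage,
    }
    if th.require_c_terminal:
        flags["orientation"] = orient.c_terminal_orientation
    if design_rmsd is not None:
        flags["design_rmsd"] = design_rmsd < th.max_design_rmsd
    return DesignRecord(
        design_id=bundle.design_id,
        mask_sequence=mask.sequence,
        metrics=vals,
        flags=flags,
        passed=all(flags.values()),
    )


def _rank_key(rec: DesignRecord):
    return (
        not rec.passed,
        -rec.metrics["coverage"],
        rec.metrics["interchain_pae"],
        -rec.metrics["complex_plddt"],
        rec.design_id,
    )


def rank_designs(records: list[DesignRecord]) -> list[DesignRecord]:
    """Deterministic total order: survivors first, then by
    (coverage desc, interchain PAE asc, complex pLDDT desc, design id)."""
    return sorted(records, key=_rank_key)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -1.0


def sequence_identity(a: str, b: str) -> float:
    """Normalized global identity: alignment score (match 1, mismatch 0,
    linear gap -1), clipped at 0, over the longer length."""
    if not a or not b:
        return 0.0
    score = _aligner.score(a, b)
    return max(score, 0.0) / max(len(a), len(b))


def sequence_distance(a: str, b: str) -> float:
    """Diversity distance: (1 - identity) + 0.2 * |len(a)-len(b)| / max length."""
    if not a and not b:
        return 0.0
    max_len = max(len(a), len(b))
    return (1.0 - sequence_identity(a, b)) + LENGTH_WEIGHT * abs(len(a) - len(b)) / max_len


def select_diverse(records: list[DesignRecord], k: int = 5) -> list[DesignRecord]:
    """Greedy max-min shortlist of k survivors by mask-sequence distance.

    Seeds with the top-ranked record, then repeatedly adds the candidate
    whose minimum distance to the chosen set is largest (rank order breaks
    ties), so the shortlist is diverse in both composition and length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = rank_designs(records)
    if len(ranked) <= k:
        return ranked
    chosen = [ranked[0]]
    remaining = ranked[1:]
    while len(chosen) < k:
        best_i, best_d = 0, -1.0
        for i, cand in enumerate(remaining):
            d = min(sequence_distance(cand.mask_sequence, c.mask_sequence) for c in chosen)
            if d > best_d + 1e-12:
                best_i, best_d = i, d
        chosen.append(remaining.pop(best_i))
    # canonical rank order on output, so selection is idempotent
    return rank_designs(chosen)
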