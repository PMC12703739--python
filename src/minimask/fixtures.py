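"""Synthetic masked-design bundles with planted ground truth.

Emulates the study system at desk scale: a three-helix-bundle binder
(ideal Cα-trace helices), a flat two-helix "receptor" slab placed to
define a known binder-receptor interface, and a fourth masking helix
(15-25 residues) laid along the interface groove.  Sliding the mask along
the bundle axis controls how many interface residues it blocks, so any
target coverage is planted up to one-residue granularity; unrealizable
requests round to the nearest achievable placement.  Mask chain direction
realizes the requested N-/C-terminal orientation.  Confidence files carry
requested block means for pLDDT and intra-/inter-chain PAE with seeded
Gaussian jitter.

Every fixture is self-validating: the planted interface and blocked sets
and all pass/fail flags are measured from the emitted coordinates and
confidence arrays by this module's own O(N^2) double-loop distance
verifier and direct block means — deliberately independent of the
KD-tree code paths in :mod:`minimask.metrics` — so re-measuring a fixture
with the metrics modules must reproduce its truth exactly.

Sequences follow an amphipathic pattern (hydrophobic residues facing the
bundle core, polar residues facing solvent), which keeps helical-wheel
analyses on fixture sequences meaningful.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .helixtools import HelixParams, make_ideal_helix
from .structio import (
    Atom,
    Chain,
    ChainRole,
    ConfidenceData,
    Residue,
    Structure,
    align_confidence,
    write_structure,
)
from .triage import TriageThresholds

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "BundleFixture",
    "make_bundle_fixture",
    "make_confidence_fixture",
    "random_fixture_specs",
    "write_fixture_suite",
]

HELIX_LEN = 14  # residues per binder/receptor helix
_HELIX = HelixParams()
_RISE = _HELIX.rise_per_residue
_Z_TOP = (HELIX_LEN - 1) * _RISE

# bundle layout (x, y) of helix axes; receptor slab on the -x side of helix 1
_BINDER_AXES = [(0.0, 0.0), (10.0, 0.0), (5.0, 8.5)]
_RECEPTOR_AXES = [(-8.0, 0.0), (-8.0, 7.0)]
_MASK_AXIS_X, _MASK_AXIS_Y = -7.0, 0.0
_FAR_AWAY = 200.0  # x-shift used to plant zero coverage

_HYDROPHOBIC = "LILVLF"
_POLAR = "EKSQER"


@dataclass
class FixtureSpec:
    mask_length: int = 20  # residues, band 15-25
    target_coverage: float = 0.8
    orientation: str = "c_terminal"  # or "n_terminal"
    complex_plddt_mean: float = 93.0
    mask_plddt_mean: float = 88.0
    pae_intra_mean: float = 4.0
    pae_inter_mean: float = 6.0
    jitter_sd: float = 0.8
    seed: int = 0
    n_helices_binder: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_coverage <= 1.0:
            raise ValueError("target_coverage must lie in [0, 1]")
        if self.mask_length < 2:
            raise ValueError("mask_length must be >= 2")
        if self.orientation not in ("c_terminal", "n_terminal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.n_helices_binder != 3:
            raise ValueError("the bundle fixture models three-helix binders")


@dataclass
class FixtureTruth:
    interface_residues: set[tuple[str, int]]
    blocked_residues: set[tuple[str, int]]
    coverage: float
    target_coverage: float
    orientation_c_terminal: bool
    complex_plddt: float
    mask_plddt: float
    interchain_pae: float
    flags: dict[str, bool]
    passed: bool

    def to_json(self) -> dict:
        d = asdict(self)
        d["interface_residues"] = sorted(self.interface_residues)
        d["blocked_residues"] = sorted(self.blocked_residues)
        return d


@dataclass
class BundleFixture:
    design_id: str
    spec: FixtureSpec
    binder_receptor: Structure
    binder_mask: Structure
    confidence: ConfidenceData
    truth: FixtureTruth


# ---------------------------------------------------------------------------
# independent distance verifier (no KD-tree; plain double loop)


def _brute_contact_residues(chain_a: Chain, chain_b: Chain, cutoff: float) -> set[int]:
    """Residue indices of chain_a with any atom within cutoff of chain_b."""
    out = set()
    for ra in chain_a.residues:
        hit = False
        for aa in ra.atoms:
            for rb in chain_b.residues:
                for ab in rb.atoms:
                    if np.sqrt(np.sum((aa.coord - ab.coord) ** 2)) <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                break
        if hit:
            out.add(ra.index)
    return out


# ---------------------------------------------------------------------------
# geometry


def _amphipathic_sequence(n: int, phase: float, core_angle: float, rng) -> str:
    """Hydrophobic residues where the wheel points toward the core."""
    seq = []
    for i in range(n):
        ang = np.deg2rad(phase + i * _HELIX.twist)
        toward_core = np.cos(ang - np.deg2rad(core_angle))
        pool = _HYDROPHOBIC if toward_core > 0.3 else _POLAR
        seq.append(pool[int(rng.integers(len(pool)))])
    return "".join(seq)


def _helix_chain(
    n: int, origin, direction, phase: float, chain_id: str, start_index: int, rng
, core_angle: float) -> list[Residue]:
    seq = _amphipathic_sequence(n, phase, core_angle, rng)
    st = make_ideal_helix(
        n, _HELIX, axis_origin=origin, axis_direction=direction, phase=phase,
        chain_id=chain_id, sequence=seq, start_index=start_index,
    )
    return st.chains[0].residues


def _build_binder(rng) -> Chain:
    """Three-helix bundle, chain A.

    Chain order runs scaffold helix -> second helix -> interface helix, so
    the binder C-terminus sits at the bottom of the interface groove (where
    a C-terminal mask extension would attach) and the N-terminus at the top
    of the scaffold helix on the far side of the bundle.
    """
    residues: list[Residue] = []
    L = HELIX_LEN
    specs = [
        # (axis xy, direction, phase, core direction in the xy plane)
        (_BINDER_AXES[2], (0, 0, -1), 250.0, 270.0),  # scaffold helix, N-term on top
        (_BINDER_AXES[1], (0, 0, 1), 20.0, 180.0),    # second helix
        (_BINDER_AXES[0], (0, 0, -1), 160.0, 180.0),  # interface helix, C-term at z=0
    ]
    for k, ((x, y), direction, phase, core) in enumerate(specs):
        z0 = 0.0 if direction[2] > 0 else _Z_TOP
        residues.extend(
            _helix_chain(L, (x, y, z0), direction, phase, "A", k * L + 1, rng, core)
        )
    return Chain("A", residues, role=ChainRole.BINDER)


def _build_receptor(rng) -> Chain:
    residues: list[Residue] = []
    for k, (x, y) in enumerate(_RECEPTOR_AXES):
        residues.extend(
            _helix_chain(
                HELIX_LEN, (x, y, 0.0), (0, 0, 1), 0.0, "R", k * HELIX_LEN + 1, rng, 0.0
            )
        )
    return Chain("R", residues, role=ChainRole.RECEPTOR)


_TAIL_STANDOFF = 6.0  # Angstrom; outside the 5 A contact cutoff


def _build_mask(spec: FixtureSpec, z_low: float, rng, binder: Chain) -> Chain:
    """Mask chain: an interface-groove helix plus one linker-attachment residue.

    The helix spans [z_low, z_low + (k-2)*rise] along the groove.  The
    attachment residue sits 6 Å outward from the binder terminus the mask
    extends (C-terminus for c_terminal orientation, N for n_terminal) —
    just outside the contact cutoff, so it never perturbs the planted
    blocked set but makes the planted orientation geometrically
    unambiguous for every mask placement.
    """
    k = spec.mask_length
    helix_len = k - 1
    ca_all = np.array([r.ca.coord for r in binder.residues])
    centroid = ca_all.mean(axis=0)
    origin = (_MASK_AXIS_X, _MASK_AXIS_Y, z_low)
    if spec.orientation == "c_terminal":
        helix = _helix_chain(helix_len, origin, (0, 0, 1), 0.0, "M", 2, rng, 0.0)
        anchor = binder.residues[-1].ca.coord
        out = anchor - centroid
        tail_pos = anchor + _TAIL_STANDOFF * out / np.linalg.norm(out)
        residues = [Residue(1, "GLY", [Atom("CA", "C", tail_pos)])] + helix
    else:
        helix = _helix_chain(helix_len, origin, (0, 0, 1), 0.0, "M", 1, rng, 0.0)
        anchor = binder.residues[0].ca.coord
        out = anchor - centroid
        tail_pos = anchor + _TAIL_STANDOFF * out / np.linalg.norm(out)
        residues = helix + [Residue(k, "GLY", [Atom("CA", "C", tail_pos)])]
    return Chain("M", residues, role=ChainRole.MASK)


def _shift_chain(chain: Chain, shift) -> Chain:
    shift = np.asarray(shift, dtype=float)
    residues = [
        Residue(r.index, r.name, [Atom(a.name, a.element, a.coord + shift)
                                  for a in r.atoms])
        for r in chain.residues
    ]
    return Chain(chain.id, residues, role=chain.role)


def make_bundle_fixture(spec: FixtureSpec, design_id: str = "fixture") -> BundleFixture:
    """Build one self-validating design bundle from a fixture spec."""
    rng = np.random.default_rng(spec.seed)
    binder = _build_binder(rng)
    receptor = _build_receptor(rng)
    binder_receptor = Structure([binder, receptor], model_id=f"{design_id}_br")

    cutoff = TriageThresholds().contact_cutoff
    interface_idx = _brute_contact_residues(binder, receptor, cutoff)
    n_iface = len(interface_idx)

    # slide the mask window along z to hit the target coverage
    best = None
    k = spec.mask_length
    if spec.target_coverage == 0.0:
        candidates = [None]  # far translation
    else:
        # windows slide from "fully covering" (z_low <= 0) to "above the
        # bundle" (z_low near the top), keeping mask termini on the side of
        # the groove that makes the planted orientation geometrically clean
        grid = np.arange(-6.0, _Z_TOP + 2 * _RISE, _RISE / 2)
        candidates = list(grid) + [None]
    for z_low in candidates:
        if z_low is None:
            # shift along the bundle axis, signed so the mask end that models
            # the linker attachment stays the nearer one and the planted
            # orientation survives the translation
            sign = 1.0 if spec.orientation == "c_terminal" else -1.0
            mask = _shift_chain(
                _build_mask(spec, 0.0, np.random.default_rng(spec.seed + 1), binder),
                (0.0, 0.0, sign * _FAR_AWAY),
            )
        else:
            mask = _build_mask(spec, float(z_low), np.random.default_rng(spec.seed + 1), binder)
        blocked = _brute_contact_residues(binder, mask, cutoff) & interface_idx
        cov = len(blocked) / n_iface if n_iface else 0.0
        err = abs(cov - spec.target_coverage)
        if best is None or err < best[0] - 1e-12:
            best = (err, mask, blocked, cov)
    _, mask, blocked_idx, coverage = best
    binder_mask = Structure([binder, mask], model_id=f"{design_id}_bm")

    # orientation truth, measured directly from terminal CA coordinates
    d_cterm = float(np.linalg.norm(binder.residues[-1].ca.coord - mask.residues[0].ca.coord))
    d_nterm = float(np.linalg.norm(binder.residues[0].ca.coord - mask.residues[-1].ca.coord))
    orientation = (d_nterm - d_cterm) > 1e-6

    nb, nm = len(binder), len(mask)
    binder_mean = (spec.complex_plddt_mean * (nb + nm) - spec.mask_plddt_mean * nm) / nb
    binder_mean = float(np.clip(binder_mean, 0.0, 100.0))
    conf = make_confidence_fixture(
        chain_sizes=[("A", nb), ("M", nm)],
        plddt_means=[binder_mean, spec.mask_plddt_mean],
        pae_intra_mean=spec.pae_intra_mean,
        pae_inter_mean=spec.pae_inter_mean,
        jitter_sd=spec.jitter_sd,
        seed=spec.seed + 2,
    )
    align_confidence(conf, binder_mask)

    # truth metrics measured from the emitted arrays (block means)
    complex_plddt = float(np.mean(conf.plddt))
    mask_plddt = float(np.mean(conf.plddt[nb:]))
    inter = float(
        np.concatenate([conf.pae[:nb, nb:].ravel(), conf.pae[nb:, :nb].ravel()]).mean()
    )
    th = TriageThresholds()
    flags = {
        "complex_plddt": complex_plddt > th.min_complex_plddt,
        "mask_plddt": mask_plddt > th.min_mask_plddt,
        "interchain_pae": inter <= th.max_interchain_pae,
        "coverage": coverage >= th.min_coverage,
        "orientation": orientation,
    }
    truth = FixtureTruth(
        interface_residues={("A", i) for i in interface_idx},
        blocked_residues={("A", i) for i in blocked_idx},
        coverage=coverage,
        target_coverage=spec.target_coverage,
        orientation_c_terminal=orientation,
        complex_plddt=complex_plddt,
        mask_plddt=mask_plddt,
        interchain_pae=inter,
        flags=flags,
        passed=all(flags.values()),
    )
    return BundleFixture(design_id, spec, binder_receptor, binder_mask, conf, truth)


def make_confidence_fixture(
    chain_sizes: list[tuple[str, int]],
    plddt_means: list[float],
    pae_intra_mean: float,
    pae_inter_mean: float,
    jitter_sd: float,
    seed: int,
) -> ConfidenceData:
    """Block-structured confidence data with seeded Gaussian jitter.

    pLDDT means are per chain block; the PAE matrix has one mean for the
    diagonal (intra-chain) blocks and one for all off-diagonal blocks.
    Values are clipped to their valid ranges after jittering.
    """
    for m in plddt_means:
        if not 0.0 <= m <= 100.0:
            raise ValueError("pLDDT means must lie in [0, 100]")
    if min(pae_intra_mean, pae_inter_mean) < 0:
        raise ValueError("PAE means must be non-negative")
    if len(chain_sizes) != len(plddt_means):
        raise ValueError("one pLDDT mean per chain block required")
    rng = np.random.default_rng(seed)
    sizes = [n for _, n in chain_sizes]
    n_tot = sum(sizes)
    plddt = np.empty(n_tot)
    start = 0
    for n, m in zip(sizes, plddt_means):
        plddt[start : start + n] = m + rng.normal(0.0, jitter_sd, n)
        start += n
    pae = np.full((n_tot, n_tot), pae_inter_mean)
    start = 0
    for n in sizes:
        pae[start : start + n, start : start + n] = pae_intra_mean
        start += n
    pae = pae + rng.normal(0.0, jitter_sd, pae.shape)
    plddt = np.clip(plddt, 0.0, 100.0)
    pae = np.clip(pae, 0.0, None)
    residue_map = [
        (cid, i + 1) for cid, n in chain_sizes for i in range(n)
    ]
    return ConfidenceData(plddt, pae, residue_map)


# ---------------------------------------------------------------------------
# suites


def random_fixture_specs(n: int, seed: int) -> list[FixtureSpec]:
    """n fixture specs mixing clear passes with single-criterion failures.

    Planted condition levels sit well away from the triage thresholds
    (e.g. complex pLDDT 93 vs 86 around the >90 gate) so the intended flag
    survives the confidence jitter; truth is nevertheless re-measured from
    the emitted data.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        fail_axis = int(rng.integers(0, 6))  # 0: none (pass), else one criterion
        complex_m, mask_m = 93.0, 88.0
        pae_inter = 6.0
        coverage = float(rng.choice([0.7, 0.8, 0.9, 1.0]))
        orientation = "c_terminal"
        if fail_axis == 1:
            complex_m, mask_m = 86.0, 82.0
        elif fail_axis == 2:
            complex_m, mask_m = 92.0, 78.0
        elif fail_axis == 3:
            pae_inter = 10.5
        elif fail_axis == 4:
            coverage = float(rng.choice([0.0, 0.2, 0.3]))
        elif fail_axis == 5:
            orientation = "n_terminal"
        specs.append(
            FixtureSpec(
                mask_length=int(rng.integers(15, 26)),
                target_coverage=coverage,
                orientation=orientation,
                complex_plddt_mean=complex_m,
                mask_plddt_mean=mask_m,
                pae_inter_mean=pae_inter,
                jitter_sd=0.8,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def write_fixture_suite(n: int, seed: int, out_dir: str | Path) -> list[str]:
    """Write n fixture bundles in the pipeline's directory layout.

    Layout: ``<out>/binder_receptor.pdb`` (shared) plus, per design,
    ``<out>/<id>/binder_mask.pdb``, ``confidence.json`` (plain dialect),
    ``mask.fasta`` and ``truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = []
    for i, spec in enumerate(random_fixture_specs(n, seed)):
        design_id = f"design_{i:03d}"
        fx = make_bundle_fixture(spec, design_id)
        ddir = out_dir / design_id
        ddir.mkdir(exist_ok=True)
        if i == 0:
            write_structure(fx.binder_receptor, out_dir / "binder_receptor.pdb")
        write_structure(fx.binder_mask, ddir / "binder_mask.pdb")
        with open(ddir / "confidence.json", "w") as fh:
            json.dump({"plddt": fx.confidence.plddt.tolist(),
                       "pae": fx.confidence.pae.tolist()}, fh)
        with open(ddir / "truth.json", "w") as fh:
            json.dump(fx.truth.to_json(), fh, indent=1)
        mask_chain = fx.binder_mask.chain("M")
        with open(ddir / "mask.fasta", "w") as fh:
            fh.write(f">{design_id}_mask\n{mask_chain.sequence}\n")
        ids.append(design_id)
    return ids
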