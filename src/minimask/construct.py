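"""Assembly and in-silico cleavage of activatable masked-binder constructs.

A masked binder is an ordered run of sequence segments, N to C:
His-tag — binder — GS linker — protease-cleavable motif — mask.  The default
cleavable motif is the canonical MMP2/MMP9 substrate PLG|LAG (scissile bond
between G and L); photo-activatable constructs instead carry an
o-nitrophenyl (NP) photolinker installed by cysteine-maleimide conjugation,
modeled here purely as mass/sequence bookkeeping with fragment masses drawn
from a configurable modification table.

Masses are computed from sequence + modifications on either the average or
the monoisotopic scale; average is the default because LC-MS deconvolution
of ~10 kDa proteins reports average mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from pyteomics import mass as pmass

from .structio import STANDARD_AA

__all__ = [
    "Segment",
    "CleavageSite",
    "ConstructSpec",
    "ModificationTable",
    "CleavageProducts",
    "ConstructOptions",
    "assemble_construct",
    "simulate_cleavage",
    "peptide_mass",
    "WATER_AVERAGE",
    "WATER_MONO",
    "default_modification_table",
]

WATER_AVERAGE = pmass.calculate_mass(formula="H2O", average=True)  # 18.015 Da
WATER_MONO = pmass.calculate_mass(formula="H2O")

SEGMENT_LABELS = ("his_tag", "binder", "gs_linker", "cleavable_motif", "mask", "custom")

DEFAULT_HIS_TAG = "MHHHHHH"
DEFAULT_GS_LINKER = "GSGS"
DEFAULT_MMP_MOTIF = "GPLGLAG"
DEFAULT_MMP_SCISSILE_OFFSET = 4  # GPLG | LAG


def _check_seq(seq: str, where: str) -> str:
    bad = set(seq.upper()) - STANDARD_AA
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in {where}")
    return seq.upper()


@dataclass
class Segment:
    label: str
    sequence: str
    modifications: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not self.sequence:
            raise ValueError(f"segment {self.label!r} has empty sequence")
        self.sequence = _check_seq(self.sequence, f"segment {self.label}")
        for pos, _name in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside segment {self.label}")


@dataclass(frozen=True)
class CleavageSite:
    """Cleavage after ``offset`` residues of the named segment."""

    segment_label: str
    offset: int
    agent: str  # "mmp" or "photo"


@dataclass
class ConstructSpec:
    segments: list[Segment]
    cleavage_sites: list[CleavageSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments]
        for site in self.cleavage_sites:
            if site.segment_label not in labels:
                raise ValueError(f"cleavage site references missing segment {site.segment_label!r}")
            seg = self.segment(site.segment_label)
            if not 1 <= site.offset < len(seg.sequence):
                raise ValueError(
                    f"cleavage offset {site.offset} not inside segment {site.segment_label!r}"
                )

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(f"no segment {label!r}")

    @property
    def full_sequence(self) -> str:
        return "".join(s.sequence for s in self.segments)

    def absolute_position(self, site: CleavageSite) -> int:
        """Residues N-terminal of the scissile bond in the full sequence."""
        pos = 0
        for s in self.segments:
            if s.label == site.segment_label:
                return pos + site.offset
            pos += len(s.sequence)
        raise KeyError(f"no segment {site.segment_label!r}")

    def all_modifications(self) -> list[tuple[int, str]]:
        """Modifications as (absolute 1-based position, name)."""
        out = []
        pos = 0
        for s in self.segments:
            out.extend((pos + p, name) for p, name in s.modifications)
            pos += len(s.sequence)
        return out


@dataclass
class ModificationTable:
    """Mod name -> (average Da, monoisotopic Da) mass deltas."""

    entries: dict[str, tuple[float, float]]

    def delta(self, name: str, scale: str) -> float:
        if name not in self.entries:
            raise KeyError(f"unknown modification {name!r}")
        avg, mono = self.entries[name]
        return avg if scale == "average" else mono

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModificationTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = {}
        for name, val in raw.items():
            entries[name] = (float(val["average"]), float(val["monoisotopic"]))
        return cls(entries)


def _formula_entry(formula: str) -> tuple[float, float]:
    return (
        pmass.calculate_mass(formula=formula, average=True),
        pmass.calculate_mass(formula=formula),
    )


def default_modification_table() -> ModificationTable:
    """Built-in modification masses, all derived from element compositions.

    The maleimide-propanoyl entries model the cysteine-maleimide conjugation
    handle before and after ring hydrolysis (hydrolysis opens the ring,
    adding one water).  The NP photolinker entries are nominal bookkeeping
    masses for the 2-methoxy-5-nitrophenoxy unit and the fragments each
    product retains after 365 nm photolysis; real constructs should override
    them with the compositions of the linker actually synthesized.
    """
    mal = "C7H7NO3"  # 3-maleimidopropanoyl adduct
    np_unit = "C10H11NO5"  # methoxy-nitrophenoxy photolinker unit
    np_n = "C10H9NO4"  # nitroso-ketone fragment retained on the N-side product
    entries = {
        "maleimide_propanoyl": _formula_entry(mal),
        "hydrolyzed_maleimide_propanoyl": _formula_entry(mal + "H2O"),
        "np_photolinker": _formula_entry(np_unit),
        "np_fragment_n": _formula_entry(np_n),
        "np_fragment_c": _formula_entry("H2O"),
    }
    return ModificationTable(entries)


@dataclass
class CleavageProducts:
    n_product: tuple[str, float]  # (sequence, mass Da)
    c_product: tuple[str, float]
    agent: str
    water_added: float  # Da gained relative to the parent construct


@dataclass
class ConstructOptions:
    """Segment defaults for assembly; empty/None disables a segment."""

    his_tag: str | None = DEFAULT_HIS_TAG
    gs_linker: str | None = DEFAULT_GS_LINKER
    motif: str | None = DEFAULT_MMP_MOTIF
    scissile_offset: int = DEFAULT_MMP_SCISSILE_OFFSET
    photo_linker: str | None = None  # sequence of a custom NP-carrying segment
    photo_offset: int = 1  # scissile position inside the photo linker segment
    photo_mod: str = "np_photolinker"


def assemble_construct(
    binder_seq: str, mask_seq: str, options: ConstructOptions | None = None
) -> ConstructSpec:
    """Build the default N-to-C construct: tag - binder - linker - motif - mask.

    Every segment except binder and mask can be disabled by setting its
    option to None/empty.  An MMP cleavage site is registered inside the
    motif; when a photo linker segment is configured it replaces the motif's
    role and registers a photo site instead.
    """
    opts = options or ConstructOptions()
    if not binder_seq or not mask_seq:
        raise ValueError("binder and mask sequences are both required")
    segments = []
    if opts.his_tag:
        segments.append(Segment("his_tag", opts.his_tag))
    segments.append(Segment("binder", binder_seq))
    if opts.gs_linker:
        segments.append(Segment("gs_linker", opts.gs_linker))
    sites = []
    if opts.photo_linker:
        mods = [(min(opts.photo_offset, len(opts.photo_linker)), opts.photo_mod)]
        segments.append(Segment("custom", opts.photo_linker, modifications=mods))
        sites.append(CleavageSite("custom", opts.photo_offset, "photo"))
    elif opts.motif:
        segments.append(Segment("cleavable_motif", opts.motif))
        sites.append(CleavageSite("cleavable_motif", opts.scissile_offset, "mmp"))
    segments.append(Segment("mask", mask_seq))
    return ConstructSpec(segments, sites)


def peptide_mass(
    seq: str,
    mods: list[tuple[int, str]] | None = None,
    scale: str = "average",
    table: ModificationTable | None = None,
) -> float:
    """Mass of a peptide: residue masses + one water + modification deltas."""
    if scale not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass scale {scale!r}")
    if not seq:
        raise ValueError("empty sequence")
    seq = _check_seq(seq, "peptide")
    total = pmass.calculate_mass(sequence=seq, average=(scale == "average"))
    if mods:
        table = table or default_modification_table()
        for _pos, name in mods:
            total += table.delta(name, scale)
    return float(total)


def simulate_cleavage(
    construct: ConstructSpec,
    agent: str,
    scale: str = "average",
    table: ModificationTable | None = None,
) -> CleavageProducts:
    """Cleave a construct at its registered site for the given agent.

    MMP cleavage is hydrolytic: the two peptide products jointly gain one
    water relative to the parent.  Photo cleavage splits the NP unit; each
    product additionally retains the fragment mass registered in the
    modification table (``np_fragment_n`` / ``np_fragment_c``) in place of
    the intact photolinker.  With multiple sites for an agent the leftmost
    is used and a multiplicity warning is emitted.
    """
    table = table or default_modification_table()
    sites = [s for s in construct.cleavage_sites if s.agent == agent]
    if not sites:
        raise ValueError(f"no cleavage site for agent {agent!r}")
    sites.sort(key=construct.absolute_position)
    if len(sites) > 1:
        warnings.warn(f"{len(sites)} cleavage sites for {agent!r}; using leftmost")
    site = sites[0]
    pos = construct.absolute_position(site)
    full = construct.full_sequence
    n_seq, c_seq = full[:pos], full[pos:]
    n_mods = [(p, m) for p, m in construct.all_modifications() if p <= pos]
    c_mods = [(p - pos, m) for p, m in construct.all_modifications() if p > pos]
    if agent == "photo":
        # the intact NP unit is destroyed; products retain its fragments
        n_mods = [(p, m) for p, m in n_mods if m != "np_photolinker"] + [(pos, "np_fragment_n")]
        c_mods = [(p, m) for p, m in c_mods if m != "np_photolinker"] + [(1, "np_fragment_c")]
    n_mass = peptide_mass(n_seq, n_mods, scale, table)
    c_mass = peptide_mass(c_seq, c_mods, scale, table)
    parent = peptide_mass(full, construct.all_modifications(), scale, table)
    return CleavageProducts(
        n_product=(n_seq, n_mass),
        c_product=(c_seq, c_mass),
        agent=agent,
        water_added=n_mass + c_mass - parent,
    )
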