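"""Structure, confidence and sequence IO.

Defines the shared structural data model (Atom/Residue/Chain/Structure),
readers for PDB/mmCIF coordinate files and for structure-prediction
confidence files (per-residue pLDDT vector plus pairwise PAE matrix in
several JSON dialects), and FASTA helpers.

Residue numbering is 1-based and sequential within each chain; author
numbering from the coordinate file is kept only as metadata
(``Residue.author_seqid``).  All downstream metrics are index-based across
models of the same sequence, so order — not author numbering — is the
alignment key.  Files with insertion codes are rejected rather than
silently renumbered, because renumbering would corrupt cross-model residue
mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ChainRole",
    "Structure",
    "ConfidenceData",
    "StructIOError",
    "read_structure",
    "write_structure",
    "read_confidence",
    "align_confidence",
    "read_fasta",
    "write_fasta",
    "THREE_TO_ONE",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructIOError(ValueError):
    """Raised for unreadable or unsupported structure/confidence input."""


class ChainRole(str, Enum):
    BINDER = "binder"
    MASK = "mask"
    RECEPTOR = "receptor"
    UNASSIGNED = "unassigned"


@dataclass
class Atom:
    """A single atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError("atom coordinate must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One amino-acid residue: 1-based chain position, 3-letter name, atoms."""

    index: int
    name: str
    atoms: list[Atom]
    author_seqid: int | None = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("residue index must be >= 1")
        if not self.atoms:
            raise ValueError("residue must contain at least one atom")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if not a.is_hydrogen]
        return np.array(coords) if coords else np.empty((0, 3))


@dataclass
class Chain:
    id: str
    residues: list[Residue]
    role: ChainRole = ChainRole.UNASSIGNED

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"chain {self.id}: residue indices not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"chain {self.id} has no residue {index}")


@dataclass
class Structure:
    chains: list[Chain]
    model_id: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique within a structure")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.model_id!r}")

    def chain_by_role(self, role: ChainRole | str) -> Chain:
        role = ChainRole(role)
        hits = [c for c in self.chains if c.role == role]
        if len(hits) != 1:
            raise KeyError(f"expected exactly one chain with role {role.value}, found {len(hits)}")
        return hits[0]

    def assign_roles(self, mapping: dict[str, ChainRole | str]) -> "Structure":
        for cid, role in mapping.items():
            self.chain(cid).role = ChainRole(role)
        return self

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered (chain id, residue index) keys, chain order then residue order."""
        return [(c.id, r.index) for c in self.chains for r in c.residues]


@dataclass
class ConfidenceData:
    """Per-residue pLDDT and pairwise PAE, order-aligned to a structure.

    ``residue_map`` lists (chain id, residue index) pairs giving, for each
    row/column of the arrays, the structure residue it describes.  It is set
    by :func:`align_confidence`; until then positions are anonymous.
    """

    plddt: np.ndarray
    pae: np.ndarray
    residue_map: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        n = self.plddt.shape[0]
        if self.plddt.ndim != 1:
            raise StructIOError("plddt must be a 1-D vector")
        if self.pae.shape != (n, n):
            raise StructIOError(
                f"dimension mismatch: plddt length {n}, pae shape {self.pae.shape}"
            )
        if np.any(self.pae < 0):
            raise StructIOError("negative PAE entries")
        if np.any((self.plddt < 0) | (self.plddt > 100)):
            raise StructIOError("pLDDT values must lie in [0, 100]")
        if self.residue_map is not None and len(self.residue_map) != n:
            raise StructIOError("residue_map length does not match plddt length")

    @property
    def n_residues(self) -> int:
        return int(self.plddt.shape[0])

    def positions(self, keys: Iterable[tuple[str, int]]) -> np.ndarray:
        """Array positions for (chain id, residue index) keys via residue_map."""
        if self.residue_map is None:
            raise StructIOError("confidence data not aligned to a structure")
        lookup = {k: i for i, k in enumerate(self.residue_map)}
        try:
            return np.array([lookup[tuple(k)] for k in keys], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown residue {exc.args[0]} in confidence residue_map") from None


# ---------------------------------------------------------------------------
# structure reading / writing


def _from_gemmi(st: gemmi.Structure, model_id: str) -> Structure:
    st.remove_empty_chains()
    model = st[0]
    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            if str(res.seqid.icode).strip():
                raise StructIOError(
                    f"residue insertion codes present (chain {ch.name} {res.seqid}); unsupported"
                )
            # resolve altlocs to highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in best.values()
            ]
            residues.append(
                Residue(len(residues) + 1, res.name, atoms, author_seqid=res.seqid.num)
            )
        if residues:
            chains.append(Chain(ch.name, residues))
    if not chains:
        raise StructIOError("zero protein residues")
    return Structure(chains, model_id=model_id)


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into the package's structural model.

    Only amino-acid residues are kept (waters/ligands dropped); alternate
    locations resolve to highest occupancy; hydrogens are retained.
    ``format`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise StructIOError(f"unknown structure format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
    except StructIOError:
        raise
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise StructIOError(f"unreadable {format} file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructIOError("zero protein residues")
    return _from_gemmi(st, model_id=path.stem)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file (single model)."""
    st = gemmi.Structure()
    st.name = structure.model_id or "model"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coord)
                ga.occ = 1.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# confidence files

_DIALECTS = ("plain", "af_pkl_json", "afdb")


def _pae_from_triplets(obj: dict) -> np.ndarray:
    r1 = np.asarray(obj["residue1"], dtype=int)
    r2 = np.asarray(obj["residue2"], dtype=int)
    d = np.asarray(obj["distance"], dtype=float)
    n = int(max(r1.max(), r2.max()))
    pae = np.full((n, n), np.nan)
    pae[r1 - 1, r2 - 1] = d
    if np.any(np.isnan(pae)):
        raise StructIOError("afdb triplet list does not cover the full PAE matrix")
    return pae


def read_confidence(path: str | Path, dialect: str = "plain") -> ConfidenceData:
    """Read a confidence JSON file in one of three dialects.

    plain:       {"plddt": [...], "pae": [[...], ...]}
    af_pkl_json: {"plddt": [...], "predicted_aligned_error": [[...], ...]}
    afdb:        1-based triplet lists {"residue1": [...], "residue2": [...],
                 "distance": [...]} for the PAE, either under a "pae" key in a
                 dict that also carries "plddt", or as a bare list of such
                 objects (one of which must carry "plddt").
    """
    if dialect not in _DIALECTS:
        raise StructIOError(f"unknown confidence dialect {dialect!r}")
    with open(path) as fh:
        data = json.load(fh)
    if dialect == "plain":
        plddt, pae = data["plddt"], np.asarray(data["pae"], dtype=float)
    elif dialect == "af_pkl_json":
        plddt, pae = data["plddt"], np.asarray(data["predicted_aligned_error"], dtype=float)
    else:
        if isinstance(data, list):
            plddt = None
            pae_obj = None
            for entry in data:
                if "residue1" in entry:
                    pae_obj = entry
                if "plddt" in entry:
                    plddt = entry["plddt"]
            if pae_obj is None:
                raise StructIOError("afdb file contains no PAE triplet object")
            if plddt is None:
                raise StructIOError("afdb file carries no plddt vector")
        else:
            plddt = data.get("plddt")
            pae_obj = data["pae"]
            if isinstance(pae_obj, list):
                pae_obj = pae_obj[0]
            if plddt is None:
                raise StructIOError("afdb file carries no plddt vector")
        pae = _pae_from_triplets(pae_obj)
    return ConfidenceData(np.asarray(plddt, dtype=float), pae)


def align_confidence(conf: ConfidenceData, structure: Structure) -> ConfidenceData:
    """Attach a residue_map aligning confidence positions to a structure by order."""
    keys = structure.residue_keys()
    if len(keys) != conf.n_residues:
        raise StructIOError(
            f"dimension mismatch: structure has {len(keys)} residues, "
            f"confidence has {conf.n_residues}"
        )
    conf.residue_map = keys
    return conf


# ---------------------------------------------------------------------------
# FASTA

_LEGAL = STANDARD_AA | {"X"}


def _check_sequence(seq: str, where: str) -> str:
    bad = set(seq.upper()) - _LEGAL
    if bad:
        raise StructIOError(f"illegal residue character(s) {sorted(bad)} in {where}")
    return seq.upper()


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) pairs; one-letter amino-acid codes only."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _check_sequence(str(rec.seq), rec.id)))
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs, wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(_check_sequence(seq, rid)), id=rid, description="")
        for rid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)
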