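"""Helical-wheel projections, hydrophobic moments and ideal helix geometry.

Amphipathicity of the masking helix — hydrophobic residues facing the
binder core, polar residues facing solvent — is quantified with the
Eisenberg consensus hydrophobicity scale, the field standard for helical
hydrophobic moments.  Ideal Cα-trace helices (rise 1.5 Å/residue, twist
100°/residue, radius 2.3 Å) provide exact synthetic geometry for bundles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import Atom, Chain, ONE_TO_THREE, Residue, Structure

__all__ = [
    "HelixParams",
    "WheelProjection",
    "EISENBERG",
    "helical_wheel",
    "hydrophobic_moment",
    "make_ideal_helix",
]

# Eisenberg consensus hydrophobicity scale (normalized)
EISENBERG: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


@dataclass
class HelixParams:
    """Ideal alpha-helix geometry: rise per residue, twist per residue, radius."""

    rise_per_residue: float = 1.5  # Angstrom
    twist: float = 100.0  # degrees
    radius: float = 2.3  # Angstrom

    def __post_init__(self) -> None:
        if min(self.rise_per_residue, self.twist, self.radius) <= 0:
            raise ValueError("helix parameters must be positive")

    @property
    def ca_ca_distance(self) -> float:
        """Closed-form consecutive Cα-Cα distance."""
        chord = 2.0 * self.radius * np.sin(np.deg2rad(self.twist) / 2.0)
        return float(np.hypot(self.rise_per_residue, chord))


@dataclass
class WheelProjection:
    sequence: str
    twist: float
    angles: np.ndarray  # degrees in [0, 360) per residue
    hydrophobicity: np.ndarray  # scale value per residue
    moment: float  # per-residue-normalized magnitude
    moment_direction: float  # degrees

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "twist_deg": self.twist,
            "angles_deg": self.angles.tolist(),
            "hydrophobicity": self.hydrophobicity.tolist(),
            "moment": self.moment,
            "moment_direction_deg": self.moment_direction,
        }


def _scale_values(seq: str, scale: dict[str, float]) -> np.ndarray:
    try:
        return np.array([scale[aa] for aa in seq.upper()])
    except KeyError as exc:
        raise ValueError(f"no hydrophobicity value for residue {exc.args[0]!r}") from None


def helical_wheel(
    seq: str, twist: float = 100.0, scale: dict[str, float] | None = None
) -> WheelProjection:
    """Project a sequence onto the helical wheel: angle(i) = (i-1)*twist mod 360."""
    if not seq:
        raise ValueError("empty sequence")
    h = _scale_values(seq, scale or EISENBERG)
    angles = (np.arange(len(seq)) * twist) % 360.0
    theta = np.deg2rad(angles)
    vx = float(np.sum(h * np.cos(theta)))
    vy = float(np.sum(h * np.sin(theta)))
    moment = float(np.hypot(vx, vy)) / len(seq)
    direction = float(np.rad2deg(np.arctan2(vy, vx)) % 360.0)
    return WheelProjection(seq.upper(), twist, angles, h, moment, direction)


def hydrophobic_moment(
    seq: str, twist: float = 100.0, scale: dict[str, float] | None = None
) -> float:
    """Per-residue-normalized helical hydrophobic moment magnitude.

    |sum_i h_i (cos θ_i, sin θ_i)| / N with θ_i the wheel angles.  Length
    normalization keeps masks of different length (15-25 residues)
    comparable.
    """
    if len(seq) < 2:
        raise ValueError("hydrophobic moment needs at least 2 residues")
    return helical_wheel(seq, twist, scale).moment


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to the given unit direction."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, direction)
    c = float(np.dot(z, direction))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_ideal_helix(
    n: int,
    params: HelixParams | None = None,
    axis_origin=(0.0, 0.0, 0.0),
    axis_direction=(0.0, 0.0, 1.0),
    phase: float = 0.0,
    chain_id: str = "A",
    sequence: str | None = None,
    start_index: int = 1,
) -> Structure:
    """Cα-only ideal helix about an arbitrary axis.

    Residue i sits at angle phase + (i-1)*twist around the axis, radius
    ``params.radius`` out, advanced (i-1)*rise along the axis from
    ``axis_origin``.  Residue names come from ``sequence`` (default ALA).
    """
    if n < 2:
        raise ValueError("helix needs at least 2 residues")
    params = params or HelixParams()
    direction = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("zero axis direction vector")
    direction = direction / norm
    if sequence is not None and len(sequence) != n:
        raise ValueError("sequence length must equal n")
    theta = np.deg2rad(phase + np.arange(n) * params.twist)
    local = np.column_stack(
        [
            params.radius * np.cos(theta),
            params.radius * np.sin(theta),
            params.rise_per_residue * np.arange(n),
        ]
    )
    rot = _rotation_to(direction)
    coords = local @ rot.T + np.asarray(axis_origin, dtype=float)
    residues = []
    for i in range(n):
        name = ONE_TO_THREE.get(sequence[i].upper(), "ALA") if sequence else "ALA"
        residues.append(
            Residue(start_index + i, name, [Atom("CA", "C", coords[i])])
        )
    return Structure([Chain(chain_id, residues)], model_id="ideal_helix")
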