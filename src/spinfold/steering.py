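"""Transient backbone manipulation: an enforced-rotation potential on the
C-terminal residue and a harmonic position restraint on the N-terminal
residue, both active only during the steered phase.

The rotation bias is a pinned rotating-reference harmonic: each steered
bead i is tethered with stiffness k_rot to the image of its initial
position rotated by theta(t) = sense * rate * t about a fixed axis through
the pivot,

    E(t) = k_rot/2 * sum_i | R(theta) (y0_i - u) - (x_i - u) |^2 .

Defaults follow the reference protocol: rate 0.36 deg/ps (one full turn
per ns), k_rot 10,000 kJ/mol/nm^2, rotation sense -1 (against the helix
direction), axis +X.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import rotation_about_axis

__all__ = [
    "RotationProtocol",
    "RestraintSpec",
    "rotation_energy_force",
    "restraint_energy_force",
    "schedule_active",
    "reference_angle",
]

DEFAULT_RATE = 0.36  # degree/ps: 1 rotation per ns
DEFAULT_K_ROT = 10_000.0  # kJ/mol/nm^2
DEFAULT_K_RES = 1_000.0  # kJ/mol/nm^2
STEERED_FRACTION = 0.05  # default duration as a fraction of total run time


@dataclass
class RotationProtocol:
    """Enforced-rotation settings for the steered phase."""

    group: np.ndarray  # bead indices of the rotated (C-terminal) residue
    reference_positions: np.ndarray  # y0: initial positions of the group (nm)
    duration: float  # ps; 0 = control (never active)
    rate: float = DEFAULT_RATE  # degree/ps
    force_constant: float = DEFAULT_K_ROT
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    pivot: Optional[np.ndarray] = None  # defaults to initial group centroid
    sense: int = -1
    # When True, deviations along the rotation axis are not penalised (the
    # flexible-axis spirit: beads are dragged around the axis but may slide
    # along it, so the chain can contract while being cranked).  The
    # default False is the fully pinned rotating reference.
    axial_free: bool = False

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        self.reference_positions = np.asarray(self.reference_positions, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm < 1e-12:
            raise ValueError("rotation axis must be a nonzero vector")
        self.axis = self.axis / norm
        if self.group.size == 0:
            raise ValueError("rotation group must be non-empty")
        if self.reference_positions.shape != (self.group.size, 3):
            raise ValueError("reference positions must match the group size")
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.sense not in (-1, 1):
            raise ValueError("sense must be +1 or -1")
        if self.pivot is None:
            self.pivot = self.reference_positions.mean(axis=0)
        else:
            self.pivot = np.asarray(self.pivot, dtype=float)


@dataclass
class RestraintSpec:
    """Harmonic position restraint on the N-terminal residue's beads."""

    group: np.ndarray
    reference_positions: np.ndarray
    force_constant: float = DEFAULT_K_RES

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        self.reference_positions = np.asarray(self.reference_positions, dtype=float)
        if self.group.size == 0:
            raise ValueError("restraint group must be non-empty")
        if self.reference_positions.shape != (self.group.size, 3):
            raise ValueError("reference positions must match the group size")
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")


def reference_angle(t: float, proto: RotationProtocol) -> float:
    """Accumulated reference angle theta(t) in degrees (signed)."""
    return proto.sense * proto.rate * t


def schedule_active(t: float, proto: RotationProtocol) -> str:
    """Protocol phase at time t: 'steered' on [0, duration), 'free' after.

    Rotation and restraint switch off together at t = duration.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    return "steered" if t < proto.duration else "free"


def rotation_energy_force(
    positions: np.ndarray, t: float, proto: RotationProtocol
) -> tuple[float, np.ndarray]:
    """Energy and forces of the rotating-reference harmonic on the group.

    `positions` are the current positions of the group's beads, in group
    order.  Outside the steered phase the bias is inactive (zero energy
    and forces).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape != proto.reference_positions.shape:
        raise ValueError("positions must match the rotation group size")
    if schedule_active(t, proto) == "free":
        return 0.0, np.zeros_like(positions)
    theta = np.radians(reference_angle(t, proto))
    rot = rotation_about_axis(proto.axis, theta)
    ref = (proto.reference_positions - proto.pivot) @ rot.T + proto.pivot
    delta = ref - positions
    if proto.axial_free:
        delta = delta - np.outer(delta @ proto.axis, proto.axis)
    energy = 0.5 * proto.force_constant * float(np.sum(delta**2))
    forces = proto.force_constant * delta
    return energy, forces


def restraint_energy_force(
    positions: np.ndarray, spec: RestraintSpec
) -> tuple[float, np.ndarray]:
    """Harmonic position-restraint energy and forces on the group."""
    positions = np.asarray(positions, dtype=float)
    if positions.shape != spec.reference_positions.shape:
        raise ValueError("positions must match the restraint group size")
    delta = spec.reference_positions - positions
    energy = 0.5 * spec.force_constant * float(np.sum(delta**2))
    forces = spec.force_constant * delta
    return energy, forces
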