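"""Extended-chain construction and box placement.

The chain is a 3-bead-per-residue backbone (N, CA, C) built from internal
coordinates with standard peptide geometry.  Starting structures are built
fully extended (phi = psi = 180 deg), then settled by a bounded dihedral-only
relaxation into the beta basin — the local minimum an extended chain with
sterics actually occupies — which slightly contracts the chain from its
ideal maximal extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import place_atom, principal_axis, rotation_about_axis

logger = logging.getLogger(__name__)

# Standard backbone geometry (nm / degrees), trans peptide bond.
BOND_N_CA = 0.146
BOND_CA_C = 0.152
BOND_C_N = 0.133
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9
OMEGA = 180.0

# Beta-basin dihedrals used by the bounded relaxation: midpoint of the
# canonical parallel (-119, 113) and antiparallel (-139, 135) strand values.
PHI_BETA = -129.0
PSI_BETA = 124.0

BEADS_PER_RESIDUE = 3
CA_OFFSET = 1  # bead index of CA within a residue triplet (N, CA, C)


class ChainError(ValueError):
    """Invalid chain-construction request."""


class BoxError(ValueError):
    """Box cannot accommodate the chain."""


@dataclass
class BoxSpec:
    """Rectangular simulation box, lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise BoxError(f"box lengths must be 3 positive numbers, got {self.lengths}")

    @property
    def center(self) -> np.ndarray:
        return self.lengths / 2.0


@dataclass
class Conformation:
    """A single frame: bead positions (nm), optional velocities (nm/ps)."""

    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    time: float = 0.0
    phase: str = "free"  # "steered" | "free"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ChainError("positions must be an (n, 3) array")
        if not np.all(np.isfinite(self.positions)):
            raise ChainError("non-finite coordinates")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_residues(self) -> int:
        return self.positions.shape[0] // BEADS_PER_RESIDUE

    @property
    def ca_positions(self) -> np.ndarray:
        return self.positions[CA_OFFSET::BEADS_PER_RESIDUE]

    def copy(self) -> "Conformation":
        return Conformation(
            positions=self.positions.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
            time=self.time,
            phase=self.phase,
        )


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Build an N/CA/C backbone from per-residue (phi, psi), omega trans.

    phi[0] and psi[-1] are formally undefined for a real chain but are used
    here to place the chain's first and last beads consistently.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    n = phi.shape[0]
    if psi.shape[0] != n:
        raise ChainError("phi and psi must have equal length")
    pos = np.empty((3 * n, 3))
    pos[0] = (0.0, 0.0, 0.0)
    pos[1] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    pos[2] = pos[1] + (-BOND_CA_C * np.cos(ang), BOND_CA_C * np.sin(ang), 0.0)
    for i in range(1, n):
        n_prev, ca_prev, c_prev = pos[3 * i - 3], pos[3 * i - 2], pos[3 * i - 1]
        ni = place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        cai = place_atom(ca_prev, c_prev, ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        ci = place_atom(c_prev, ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        pos[3 * i] = ni
        pos[3 * i + 1] = cai
        pos[3 * i + 2] = ci
    return pos


def relax_dihedrals(
    phi: np.ndarray,
    psi: np.ndarray,
    phi0: float = PHI_BETA,
    psi0: float = PSI_BETA,
    max_steps: int = 200,
    step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Bounded steepest descent of backbone torsions toward a target basin.

    Minimises the separable objective sum(1 - cos(chi - chi0)) per torsion,
    at most `max_steps` iterations. Deterministic.
    """
    phi_r = np.radians(np.asarray(phi, dtype=float)).copy()
    psi_r = np.radians(np.asarray(psi, dtype=float)).copy()
    phi0_r = np.radians(phi0)
    psi0_r = np.radians(psi0)
    for _ in range(max_steps):
        g_phi = np.sin(phi_r - phi0_r)
        g_psi = np.sin(psi_r - psi0_r)
        if max(np.max(np.abs(g_phi)), np.max(np.abs(g_psi))) < 1e-10:
            break
        phi_r -= step * g_phi
        psi_r -= step * g_psi
    return np.degrees(phi_r), np.degrees(psi_r)


def chain_extent(positions: np.ndarray) -> float:
    """Distance between the first and last CA beads (nm)."""
    ca = positions[CA_OFFSET::BEADS_PER_RESIDUE]
    return float(np.linalg.norm(ca[-1] - ca[0]))


def build_extended(n_residues: int, relax: bool = True) -> Conformation:
    """Extended starting structure: all phi = psi = 180 deg, then a bounded
    dihedral relaxation into the beta basin.  Deterministic.
    """
    if n_residues < 2:
        raise ChainError(f"need at least 2 residues, got {n_residues}")
    phi = np.full(n_residues, 180.0)
    psi = np.full(n_residues, 180.0)
    if relax:
        phi, psi = relax_dihedrals(phi, psi)
    return Conformation(positions=build_backbone(phi, psi))


def align_to_x(conf: Conformation, box: Optional[BoxSpec] = None) -> Conformation:
    """Rigidly rotate so the principal axis is +X; centre at the box centre
    (or the origin when no box is given).  Orientation sign is fixed so the
    first-to-last bead vector points along +X.
    """
    pos = conf.positions
    axis = principal_axis(pos)  # raises on degenerate clouds
    xhat = np.array([1.0, 0.0, 0.0])
    cosang = float(np.clip(np.dot(axis, xhat), -1.0, 1.0))
    if cosang > 1.0 - 1e-12:
        rot = np.eye(3)
    elif cosang < -1.0 + 1e-12:
        rot = rotation_about_axis(np.array([0.0, 1.0, 0.0]), np.pi)
    else:
        rot_axis = np.cross(axis, xhat)
        rot = rotation_about_axis(rot_axis, np.arccos(cosang))
    centered = pos - pos.mean(axis=0)
    new = centered @ rot.T
    if new[-1, 0] - new[0, 0] < 0:
        new = new @ rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi).T
    target = box.center if box is not None else np.zeros(3)
    new = new + target
    return replace(conf, positions=new)


def fit_to_box(
    conf: Conformation,
    box: BoxSpec,
    margin: float = 0.5,
    max_compaction: float = 1.0,
) -> Conformation:
    """Place the chain inside the box with the given margin on every side.

    If the extended chain is longer than the box X-length, the chain is
    compacted by interpolating its torsions from the beta basin toward a
    tighter coil until it fits (the compaction fraction is logged).  The
    input is expected to be an extended chain from :func:`build_extended`.
    """
    n_res = conf.n_residues
    if box.lengths[0] < 0.1 * n_res:
        raise BoxError(
            f"box X-length {box.lengths[0]:.2f} nm cannot hold {n_res} residues "
            f"at any compaction"
        )
    limit = float(box.lengths[0]) - 2.0 * margin

    out = align_to_x(conf, box=box)
    if _inside(out.positions, box, margin):
        return out

    # Compaction target: interpolating the torsions toward the helical
    # basin passes through gently coiled, progressively shorter shapes.
    phi_c, psi_c = -60.0, -45.0
    for lam in np.linspace(0.05, max_compaction, 20):
        phi = np.full(n_res, (1 - lam) * PHI_BETA + lam * phi_c)
        psi = np.full(n_res, (1 - lam) * PSI_BETA + lam * psi_c)
        cand = Conformation(positions=build_backbone(phi, psi))
        cand = align_to_x(cand, box=box)
        if chain_extent(cand.positions) <= limit and _inside(cand.positions, box, margin):
            logger.info(
                "chain compacted to fit box: lambda=%.2f extent=%.2f nm (box X=%.2f)",
                lam,
                chain_extent(cand.positions),
                box.lengths[0],
            )
            cand = replace(cand, time=conf.time, phase=conf.phase)
            return cand
    raise BoxError(
        f"could not fit {n_res} residues into box {box.lengths} with margin {margin}"
    )


def _inside(positions: np.ndarray, box: BoxSpec, margin: float) -> bool:
    lo = positions.min(axis=0)
    hi = positions.max(axis=0)
    return bool(np.all(lo >= margin - 1e-9) and np.all(hi <= box.lengths - margin + 1e-9))
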