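"""Potential energy and forces for the coarse-grained structure-based model.

Terms: harmonic bonds, harmonic angles, 12-10 wells between native CA
pairs, and an r^-12 repulsion between all other bead pairs more than two
bonds apart.  Forces are the exact negative gradient.  No cutoff or
neighbour list: systems are small enough for O(n^2) pairwise evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .targets import GoParameters

__all__ = ["EnergyBreakdown", "energy_forces", "relax", "compiled"]

_MIN_SEPARATION = 1e-6  # nm; beads closer than this are an error


class TopologyError(ValueError):
    """Conformation does not match the potential's topology."""


class OverlapError(ValueError):
    """Two beads (nearly) coincide; forces are undefined."""


@dataclass
class EnergyBreakdown:
    """Per-term energies in kJ/mol; steering terms are filled in by the
    integrator when a bias is active."""

    bond: float = 0.0
    angle: float = 0.0
    native_pair: float = 0.0
    repulsion: float = 0.0
    steering: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.bond
            + self.angle
            + self.native_pair
            + self.repulsion
            + self.steering
            + self.restraint
        )

    def as_dict(self) -> dict:
        return {
            "bond": self.bond,
            "angle": self.angle,
            "native_pair": self.native_pair,
            "repulsion": self.repulsion,
            "steering": self.steering,
            "restraint": self.restraint,
            "total": self.total,
        }


class _Compiled:
    """Index arrays precomputed once per GoParameters."""

    __slots__ = ("rep_i", "rep_j")

    def __init__(self, params: "GoParameters") -> None:
        n = params.n_beads
        ii, jj = np.triu_indices(n, k=3)  # exclude pairs <= 2 bonds apart
        native = set(map(tuple, np.sort(params.pair_indices, axis=1)))
        if native:
            keep = np.array(
                [(i, j) not in native for i, j in zip(ii, jj)], dtype=bool
            )
            ii, jj = ii[keep], jj[keep]
        self.rep_i = ii
        self.rep_j = jj


def compiled(params: "GoParameters") -> _Compiled:
    hit = getattr(params, "_compiled", None)
    if hit is None:
        hit = _Compiled(params)
        params._compiled = hit
    return hit


def energy_forces(
    positions: np.ndarray, params: "GoParameters"
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Energy breakdown and per-bead forces (kJ/mol, kJ/mol/nm).

    `positions` may be a Conformation or a raw (n_beads, 3) array.
    """
    pos = getattr(positions, "positions", positions)
    pos = np.asarray(pos, dtype=float)
    if pos.shape != (params.n_beads, 3):
        raise TopologyError(
            f"positions shape {pos.shape} does not match topology "
            f"({params.n_beads} beads)"
        )
    bd = EnergyBreakdown()
    idx_chunks = []
    force_chunks = []

    # bonds: 0.5 k (r - r0)^2
    bi, bj = params.bond_indices[:, 0], params.bond_indices[:, 1]
    dvec = pos[bj] - pos[bi]
    r = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
    _check_separation(r)
    dr = r - params.bond_r0
    bd.bond = float(0.5 * params.bond_k * np.sum(dr**2))
    fpair = (params.bond_k * dr / r)[:, None] * dvec  # force on i along +dvec
    idx_chunks += [bi, bj]
    force_chunks += [fpair, -fpair]

    # angles: 0.5 k (theta - theta0)^2
    ai, aj, ak = (params.angle_indices[:, c] for c in range(3))
    u = pos[ai] - pos[aj]
    v = pos[ak] - pos[aj]
    nu = np.sqrt(np.einsum("ij,ij->i", u, u))
    nv = np.sqrt(np.einsum("ij,ij->i", v, v))
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
    dth = theta - params.angle_theta0
    bd.angle = float(0.5 * params.angle_k * np.sum(dth**2))
    coef = params.angle_k * dth / sin_t
    fi = (coef / nu)[:, None] * (vh - cos_t[:, None] * uh)
    fk = (coef / nv)[:, None] * (uh - cos_t[:, None] * vh)
    idx_chunks += [ai, ak, aj]
    force_chunks += [fi, fk, -(fi + fk)]

    # native pairs: eps (5 (r0/r)^12 - 6 (r0/r)^10), minimum -eps at r0
    if params.pair_indices.shape[0] > 0:
        pi, pj = params.pair_indices[:, 0], params.pair_indices[:, 1]
        dvec = pos[pj] - pos[pi]
        r = np.sqrt(np.einsum("ij,ij->i", dvec, dvec))
        _check_separation(r)
        s10 = (params.pair_r0 / r) ** 10
        s12 = s10 * (params.pair_r0 / r) ** 2
        bd.native_pair = float(params.epsilon * np.sum(5.0 * s12 - 6.0 * s10))
        # dE/dr = 60 eps (s10 - s12)/r ; force on i = -dE/dr * (-dvec/r)
        dEdr = 60.0 * params.epsilon * (s10 - s12) / r
        fpair = (dEdr / r)[:, None] * dvec
        idx_chunks += [pi, pj]
        force_chunks += [fpair, -fpair]

    # non-native repulsion: eps_rep (sigma/r)^12
    comp = compiled(params)
    if comp.rep_i.size > 0:
        dvec = pos[comp.rep_j] - pos[comp.rep_i]
        r2 = np.einsum("ij,ij->i", dvec, dvec)
        if np.any(r2 < _MIN_SEPARATION**2):
            raise OverlapError("overlapping beads: interparticle distance < 1e-6 nm")
        inv = params.repulsion_sigma**2 / r2
        s12 = inv**6
        bd.repulsion = float(params.repulsion_eps * np.sum(s12))
        dEdr_over_r = -12.0 * params.repulsion_eps * s12 / r2
        fpair = dEdr_over_r[:, None] * dvec
        idx_chunks += [comp.rep_i, comp.rep_j]
        force_chunks += [fpair, -fpair]

    all_idx = np.concatenate(idx_chunks)
    all_f = np.concatenate(force_chunks)
    n = pos.shape[0]
    forces = np.column_stack(
        [np.bincount(all_idx, weights=all_f[:, c], minlength=n) for c in range(3)]
    )
    return bd, forces


def _check_separation(r: np.ndarray) -> None:
    if np.any(r < _MIN_SEPARATION):
        raise OverlapError("overlapping beads: interparticle distance < 1e-6 nm")


def relax(
    positions: np.ndarray,
    params: "GoParameters",
    max_steps: int = 2000,
    force_tol: float = 1.0,
    step: float = 1e-4,
) -> np.ndarray:
    """Steepest-descent relaxation until the largest force component is
    below `force_tol` (kJ/mol/nm) or `max_steps` is reached."""
    pos = np.array(getattr(positions, "positions", positions), dtype=float)
    e_prev, f = energy_forces(pos, params)
    h = step
    for _ in range(max_steps):
        if np.max(np.abs(f)) < force_tol:
            break
        trial = pos + h * f
        e_trial, f_trial = energy_forces(trial, params)
        if e_trial.total <= e_prev.total:
            pos, f, e_prev = trial, f_trial, e_trial
            h = min(h * 1.2, 1e-2)
        else:
            h *= 0.5
    return pos
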