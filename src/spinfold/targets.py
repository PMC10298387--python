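"""Synthetic native folds and their structure-based (Go-like) potentials.

Toy targets of the four structural classes — helix, hairpin, helix bundle
analog, alpha+beta — stand in for experimentally determined domains.  Each
is a 3-bead-per-residue (N, CA, C) backbone.  From any target a
structure-based potential is derived: harmonic bonds and angles at their
native values, a 12-10 well for every native CA-CA contact, and a purely
repulsive r^-12 term for all other non-excluded bead pairs, so the native
fold is the potential's minimum by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .analysis import ContactDefinition, contact_map
from .chain import BEADS_PER_RESIDUE, CA_OFFSET, build_backbone
from .geometry import principal_axis, rotation_about_axis

__all__ = [
    "NativeReference",
    "GoParameters",
    "TargetError",
    "PackingError",
    "make_helix_target",
    "make_hairpin_target",
    "make_mixed_target",
    "derive_go_parameters",
    "from_pdb_backbone",
]

# Ideal alpha-helix backbone torsions.
PHI_HELIX = -57.0
PSI_HELIX = -47.0

# Default potential parameters (kJ/mol, nm).  Calibrated once so the toy
# 20-residue helix folds reversibly at 300 K with the default integrator
# settings; see config defaults in `dynamics`.
DEFAULT_BOND_K = 5000.0
DEFAULT_ANGLE_K = 40.0  # kJ/mol/rad^2
DEFAULT_EPSILON = 6.5
DEFAULT_REPULSION_SIGMA = 0.22
DEFAULT_REPULSION_EPS = 1.0

# Distance between paired antiparallel strands (CA-CA), nm.
STRAND_PAIR_DISTANCE = 0.50
CA_SPACING = 0.38  # virtual CA-CA distance in an extended strand


class TargetError(ValueError):
    """Invalid synthetic-target request."""


class PackingError(TargetError):
    """Sub-geometries could not be packed without steric clash."""


@dataclass
class NativeReference:
    """A coarse-grained native structure (the folding target)."""

    n_residues: int
    bead_positions: np.ndarray  # (n_beads, 3) nm
    fold_class: str  # helix | hairpin | helix_bundle | alpha_beta
    label: str = ""
    beads_per_residue: int = BEADS_PER_RESIDUE

    def __post_init__(self) -> None:
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        validate_reference(self)

    @property
    def n_beads(self) -> int:
        return self.bead_positions.shape[0]

    @property
    def residue_index_of_bead(self) -> np.ndarray:
        return np.arange(self.n_beads) // self.beads_per_residue

    @property
    def ca_positions(self) -> np.ndarray:
        return self.bead_positions[CA_OFFSET :: self.beads_per_residue]


@dataclass
class GoParameters:
    """Structure-based potential parameters derived from a native reference."""

    n_beads: int
    bond_indices: np.ndarray  # (nb, 2)
    bond_r0: np.ndarray  # nm
    bond_k: float
    angle_indices: np.ndarray  # (na, 3)
    angle_theta0: np.ndarray  # radians
    angle_k: float
    pair_indices: np.ndarray  # (np, 2) bead indices (CA beads)
    pair_r0: np.ndarray  # nm
    epsilon: float
    repulsion_sigma: float
    repulsion_eps: float
    contact_residue_pairs: np.ndarray = field(default=None)  # (np, 2) residue ids


def validate_reference(ref: NativeReference) -> None:
    """Enforce structural invariants; raise TargetError on violation."""
    pos = ref.bead_positions
    if pos.shape != (ref.n_residues * ref.beads_per_residue, 3):
        raise TargetError(
            f"bead count {pos.shape[0]} != n_residues x beads_per_residue "
            f"({ref.n_residues} x {ref.beads_per_residue})"
        )
    d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    if np.any(d < 0.1 - 1e-9) or np.any(d > 0.5 + 1e-9):
        bad = np.where((d < 0.1) | (d > 0.5))[0]
        raise TargetError(
            f"consecutive bead distance out of [0.1, 0.5] nm at bond(s) {bad[:5]}: "
            f"{d[bad[:5]]}"
        )
    n = pos.shape[0]
    ii, jj = np.triu_indices(n, k=3)  # non-bonded: bond-path >= 3
    dd = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    if np.any(dd < 0.25 - 1e-9):
        k = int(np.argmin(dd))
        raise PackingError(
            f"steric clash: beads {ii[k]} and {jj[k]} at {dd[k]:.3f} nm (< 0.25)"
        )


# ---------------------------------------------------------------------------
# generators


def make_helix_target(n_residues: int, label: str = "") -> NativeReference:
    """Ideal alpha-helix target (~0.15 nm rise per residue, 3.6 res/turn).

    Deterministic; the all-alpha analog among the toy folds.
    """
    if n_residues < 5:
        raise TargetError(
            f"helix target needs >= 5 residues for any native contact, got {n_residues}"
        )
    phi = np.full(n_residues, PHI_HELIX)
    psi = np.full(n_residues, PSI_HELIX)
    pos = build_backbone(phi, psi)
    return NativeReference(
        n_residues, pos, "helix", label or f"helix{n_residues}"
    )


def _strand_frame_beads(ca_trace: np.ndarray, start_parity: int = 0) -> np.ndarray:
    """Place N and C beads around a CA trace using per-segment frames.

    N_i sits 0.146 nm from CA_i along the segment to the previous CA, C_i
    0.152 nm along the segment to the next, each offset 0.05 nm
    perpendicular to its segment with alternating sign — so the
    C(i)-N(i+1) pseudo-bond length stays in a valid range for any CA
    spacing in [0.25, 0.45] nm, including sharp turns.
    """
    n = ca_trace.shape[0]
    zhat = np.array([0.0, 0.0, 1.0])
    yhat = np.array([0.0, 1.0, 0.0])

    def seg_frame(i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        u = ca_trace[j] - ca_trace[i]
        u = u / np.linalg.norm(u)
        m = zhat - np.dot(zhat, u) * u
        if np.linalg.norm(m) < 0.3:
            m = yhat - np.dot(yhat, u) * u
        return u, m / np.linalg.norm(m)

    beads = np.empty((3 * n, 3))
    for i in range(n):
        s = 1.0 if (i + start_parity) % 2 == 0 else -1.0
        if i > 0:
            u_prev, m_prev = seg_frame(i - 1, i)
        else:
            u_prev, m_prev = seg_frame(0, 1)
        if i < n - 1:
            u_next, m_next = seg_frame(i, i + 1)
        else:
            u_next, m_next = u_prev, m_prev
        beads[3 * i] = ca_trace[i] - 0.146 * u_prev + 0.05 * s * m_prev
        beads[3 * i + 1] = ca_trace[i]
        beads[3 * i + 2] = ca_trace[i] + 0.152 * u_next + 0.05 * s * m_next
    return beads


def _hairpin_ca_trace(n_residues: int) -> np.ndarray:
    """CA trace of two antiparallel strands joined by a 2-3 residue turn,
    pairing residue i with residue n-1-i."""
    n_turn = 2 if n_residues % 2 == 0 else 3
    s = (n_residues - n_turn) // 2
    d = STRAND_PAIR_DISTANCE
    ca = np.zeros((n_residues, 3))
    for i in range(s):
        ca[i] = (i * CA_SPACING, 0.0, 0.0)
        ca[n_residues - 1 - i] = (i * CA_SPACING, d, 0.0)
    x_end = (s - 1) * CA_SPACING
    if n_turn == 2:
        ca[s] = (x_end + 0.33, 0.05, 0.12)
        ca[s + 1] = (x_end + 0.33, d - 0.05, 0.12)
    else:
        ca[s] = (x_end + 0.30, -0.03, 0.20)
        ca[s + 1] = (x_end + 0.58, d / 2, 0.25)
        ca[s + 2] = (x_end + 0.30, d + 0.03, 0.20)
    return ca


def make_hairpin_target(n_residues: int, label: str = "") -> NativeReference:
    """Antiparallel two-strand hairpin; residue i pairs with n-1-i."""
    if n_residues < 8:
        raise TargetError(f"hairpin target needs >= 8 residues, got {n_residues}")
    ca = _hairpin_ca_trace(n_residues)
    pos = _strand_frame_beads(ca)
    return NativeReference(
        n_residues, pos, "hairpin", label or f"hairpin{n_residues}"
    )


def _route_linker(
    start: np.ndarray,
    end: np.ndarray,
    count: int,
    avoid: Optional[np.ndarray] = None,
    clearance: float = 0.42,
) -> np.ndarray:
    """CA positions for `count` linker residues between two anchors.

    Tries a straight route, then arcs lifted through +/-z of increasing
    height, keeping consecutive spacing within [0.25, 0.45] nm and staying
    `clearance` nm away from already-placed CA positions.  Raises
    PackingError when no route works.
    """
    for inner in _route_candidates(start, end, count, avoid, clearance):
        return inner
    raise PackingError(
        f"could not route a {count}-residue linker over "
        f"{np.linalg.norm(end - start):.2f} nm without clash"
    )


def _route_candidates(
    start: np.ndarray,
    end: np.ndarray,
    count: int,
    avoid: Optional[np.ndarray] = None,
    clearance: float = 0.42,
):
    """Yield candidate linker CA placements in deterministic preference
    order: straight first, then arcs of increasing lift in several
    directions; candidates passing the CA-clearance test come before
    relaxed-clearance ones."""
    gap = float(np.linalg.norm(end - start))
    n_seg = count + 1
    if gap > 0.45 * n_seg:
        raise PackingError(f"linker of {count} residues cannot bridge {gap:.2f} nm")
    mid = 0.5 * (start + end)
    r2 = 1.0 / np.sqrt(2.0)
    directions = [
        np.array(d)
        for d in [
            (0, 0, 1.0),
            (0, 0, -1.0),
            (0, 1.0, 0),
            (0, -1.0, 0),
            (0, r2, r2),
            (0, -r2, r2),
            (0, r2, -r2),
            (0, -r2, -r2),
            (1.0, 0, 0),
            (-1.0, 0, 0),
        ]
    ]

    def turn_templates() -> list[np.ndarray]:
        """Hairpin-style turn shapes for short linkers, tried in several
        bulge directions perpendicular to the anchor-anchor axis."""
        if count not in (2, 3):
            return []
        u = (end - start) / gap
        e = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(u, e)) > 0.9:
            e = np.array([0.0, 1.0, 0.0])
        w0 = e - np.dot(e, u) * u
        w0 = w0 / np.linalg.norm(w0)
        out = []
        for ang in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2, np.pi / 4, -np.pi / 4):
            w = rotation_about_axis(u, ang) @ w0
            v = np.cross(u, w)
            for vs in (1.0, -1.0):
                gv = end - start
                if count == 2:
                    pts = np.array(
                        [
                            start + 0.10 * gv + 0.33 * w + 0.12 * vs * v,
                            start + 0.90 * gv + 0.33 * w + 0.12 * vs * v,
                        ]
                    )
                else:
                    pts = np.array(
                        [
                            start - 0.06 * gv + 0.30 * w + 0.20 * vs * v,
                            start + 0.50 * gv + 0.58 * w + 0.25 * vs * v,
                            start + 1.06 * gv + 0.30 * w + 0.20 * vs * v,
                        ]
                    )
                full = np.vstack([start, pts, end])
                seg = np.linalg.norm(np.diff(full, axis=0), axis=1)
                if np.all(seg >= 0.25) and np.all(seg <= 0.45):
                    out.append(pts)
        return out

    def spaced_ok() -> list[np.ndarray]:
        out = []
        for h in [0.0, 0.15, 0.3, 0.45, 0.6, 0.8, 1.0, 1.3]:
            for direction in directions if h > 0 else directions[:1]:
                fine = _bezier(start, mid + h * direction, end)
                seglen = np.linalg.norm(np.diff(fine, axis=0), axis=1)
                cum = np.concatenate([[0.0], np.cumsum(seglen)])
                want = np.linspace(0.0, cum[-1], n_seg + 1)
                pts = np.column_stack(
                    [np.interp(want, cum, fine[:, k]) for k in range(3)]
                )
                seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                if np.any(seg < 0.25) or np.any(seg > 0.45):
                    continue
                out.append(pts[1:-1])
        return out

    candidates = turn_templates() + spaced_ok()

    def min_avoid(inner: np.ndarray) -> float:
        if avoid is None or avoid.shape[0] == 0:
            return np.inf
        return float(
            np.min(np.linalg.norm(inner[:, None, :] - avoid[None, :, :], axis=-1))
        )

    for inner in candidates:
        if min_avoid(inner) >= clearance:
            yield inner
    for inner in candidates:
        if clearance > min_avoid(inner) >= 0.28:
            yield inner


def _assemble_beads(ca: np.ndarray, bead_override: np.ndarray) -> np.ndarray:
    """Beads for a possibly partial CA trace: segment-frame beads per
    contiguous placed block, then explicit (e.g. helix) bead overrides.
    Unplaced residues stay NaN."""
    n = ca.shape[0]
    pos = np.full((3 * n, 3), np.nan)
    placed = ~np.isnan(ca[:, 0])
    i = 0
    while i < n:
        if not placed[i]:
            i += 1
            continue
        j = i
        while j < n and placed[j]:
            j += 1
        if j - i >= 2:
            pos[3 * i : 3 * j] = _strand_frame_beads(ca[i:j], start_parity=i)
        else:  # isolated residue: beads colinear along x as a placeholder
            pos[3 * i] = ca[i] - np.array([0.146, 0, 0])
            pos[3 * i + 1] = ca[i]
            pos[3 * i + 2] = ca[i] + np.array([0.152, 0, 0])
        i = j
    override = ~np.isnan(bead_override[:, 0])
    pos[override] = bead_override[override]
    return pos


def _partial_beads_valid(ca: np.ndarray, bead_override: np.ndarray) -> bool:
    """Check bond-length and clash invariants over the placed beads only."""
    pos = _assemble_beads(ca, bead_override)
    placed = ~np.isnan(pos[:, 0])
    idx = np.where(placed)[0]
    for a, b in zip(idx, idx[1:]):
        if b - a == 1:
            d = np.linalg.norm(pos[b] - pos[a])
            if d < 0.1 - 1e-9 or d > 0.5 + 1e-9:
                return False
    pts = pos[idx]
    ii, jj = np.triu_indices(len(idx), k=1)
    far = idx[jj] - idx[ii] >= 3
    if not np.any(far):
        return True
    dd = np.linalg.norm(pts[ii[far]] - pts[jj[far]], axis=1)
    return bool(np.min(dd) >= 0.25 - 1e-9)


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n_fine: int = 400) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_fine + 1)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _aligned_helix_beads(
    length: int, phase_first_ca_to_z: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal-torsion helix with axis along +x, CA centroid at the origin.

    Returns (all beads, CA trace).  Optionally phases the helix about its
    own axis so the first CA points toward +z.
    """
    pos = build_backbone(np.full(length, PHI_HELIX), np.full(length, PSI_HELIX))
    hca = pos[CA_OFFSET::BEADS_PER_RESIDUE]
    axis = principal_axis(hca)
    xhat = np.array([1.0, 0.0, 0.0])
    c = float(np.clip(np.dot(axis, xhat), -1, 1))
    center = hca.mean(axis=0)
    if c < 1 - 1e-12:
        if c < -1 + 1e-12:
            rot = rotation_about_axis(np.array([0.0, 1.0, 0.0]), np.pi)
        else:
            rot = rotation_about_axis(np.cross(axis, xhat), np.arccos(c))
    else:
        rot = np.eye(3)
    pos = (pos - center) @ rot.T
    hca = (hca - center) @ rot.T
    if hca[-1, 0] < hca[0, 0]:
        flip = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi)
        pos = pos @ flip.T
        hca = hca @ flip.T
    if phase_first_ca_to_z:
        phase = np.arctan2(hca[0, 2], hca[0, 1])
        spin = rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.pi / 2 - phase)
        pos = pos @ spin.T
        hca = hca @ spin.T
    return pos, hca


def make_mixed_target(
    helix_span: tuple[int, int],
    strand_spans: Sequence[tuple[int, int]],
    n_residues: int,
    label: str = "",
) -> NativeReference:
    """Alpha+beta target: a sheet of antiparallel strand spans packed against
    a helix span, remaining residues routed as linkers/tails.

    Spans are half-open residue ranges and must be disjoint and inside
    [0, n_residues).  With no strand spans this degenerates to a
    helix-with-tail target.
    """
    spans = [("helix", tuple(helix_span))] + [("strand", tuple(s)) for s in strand_spans]
    for kind, (a, b) in spans:
        if not (0 <= a < b <= n_residues):
            raise TargetError(f"{kind} span [{a}, {b}) outside chain of {n_residues}")
    ordered = sorted(spans, key=lambda s: s[1][0])
    for (_, (a1, b1)), (_, (a2, b2)) in zip(ordered, ordered[1:]):
        if b1 > a2:
            raise TargetError(f"overlapping spans [{a1},{b1}) and [{a2},{b2})")

    ca = np.full((n_residues, 3), np.nan)
    bead_override = np.full((3 * n_residues, 3), np.nan)

    # sheet: antiparallel strands at alternating y levels, end-aligned
    strands = [s for k, s in spans if k == "strand"]
    for k, (a, b) in enumerate(strands):
        length = b - a
        y = (k // 2) * 2 * STRAND_PAIR_DISTANCE + (k % 2) * STRAND_PAIR_DISTANCE
        if k % 2 == 0:  # forward along +x
            for j in range(length):
                ca[a + j] = (j * CA_SPACING, y, 0.0)
        else:  # antiparallel, aligned to the previous strand's end
            prev_len = strands[k - 1][1] - strands[k - 1][0]
            x0 = (prev_len - 1) * CA_SPACING
            for j in range(length):
                ca[a + j] = (x0 - j * CA_SPACING, y, 0.0)

    # helix: built from ideal torsions, axis along +x, packed below the sheet
    ha, hb = helix_span
    h_len = hb - ha
    if h_len >= 4:
        hbeads, hca = _aligned_helix_beads(h_len, phase_first_ca_to_z=True)
        if strands:
            sheet_x = np.nanmean([ca[a:b, 0].mean() for a, b in strands])
            sheet_y = np.nanmean([ca[a:b, 1].mean() for a, b in strands])
            # pack the helix against the sheet face, below it in z
            shift = np.array([sheet_x, sheet_y, -0.75])
        else:
            shift = np.zeros(3)
        ca[ha:hb] = hca + shift
        bead_override[3 * ha : 3 * hb] = hbeads + shift
    else:
        for j in range(h_len):  # too short for a helix: short straight run
            ca[ha + j] = (j * CA_SPACING, 0.0, -0.75)

    # linkers and tails
    placed = ~np.isnan(ca[:, 0])
    i = 0
    while i < n_residues:
        if placed[i]:
            i += 1
            continue
        j = i
        while j < n_residues and not placed[j]:
            j += 1
        count = j - i
        if i == 0:  # N-tail: extend backwards from the first anchor
            anchor = ca[j]
            direction = np.array([-1.0, 0.0, 0.0]) if anchor[1] >= -0.4 else np.array([-1.0, 0.0, 0.0])
            for k in range(count):
                ca[j - 1 - k] = anchor + (k + 1) * CA_SPACING * direction + np.array([0, 0, 0.2])
        elif j == n_residues:  # C-tail
            anchor = ca[i - 1]
            for k in range(count):
                ca[i + k] = anchor + (k + 1) * CA_SPACING * np.array([1.0, 0.0, 0.0]) + np.array([0, 0, 0.2])
        else:
            # avoid every placed residue except the two anchors; accept the
            # first candidate whose assembled beads stay clash-free
            mask = ~np.isnan(ca[:, 0])
            mask[i - 1] = False
            mask[j] = False
            ok = False
            for cand in _route_candidates(ca[i - 1], ca[j], count, avoid=ca[mask]):
                ca[i:j] = cand
                if _partial_beads_valid(ca, bead_override):
                    ok = True
                    break
                ca[i:j] = np.nan
            if not ok:
                raise PackingError(
                    f"could not route a {count}-residue linker at residues "
                    f"[{i}, {j}) without clash"
                )
        placed = ~np.isnan(ca[:, 0])
        i = j
    pos = _assemble_beads(ca, bead_override)
    try:
        return NativeReference(
            n_residues, pos, "alpha_beta", label or f"mixed{n_residues}"
        )
    except PackingError:
        raise
    except TargetError as exc:
        raise PackingError(f"packing produced an invalid geometry: {exc}") from exc


def make_bundle_target(n_residues: int, label: str = "") -> NativeReference:
    """Two-helix bundle analog (all-alpha, multi-segment): two antiparallel
    helices joined by a short loop."""
    if n_residues < 14:
        raise TargetError(f"bundle target needs >= 14 residues, got {n_residues}")
    n_loop = 3
    h1 = (n_residues - n_loop) // 2
    h2 = n_residues - n_loop - h1
    ca = np.full((n_residues, 3), np.nan)
    bead_override = np.full((3 * n_residues, 3), np.nan)

    beads_a, ca_a = _aligned_helix_beads(h1)
    beads_b, ca_b = _aligned_helix_beads(h2)
    # antiparallel partner: proper rotation by pi about z, packed at 0.9 nm
    flip = rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.pi)
    beads_b = beads_b @ flip.T + np.array([0.0, 0.9, 0.0])
    ca_b = ca_b @ flip.T + np.array([0.0, 0.9, 0.0])

    ca[:h1] = ca_a
    ca[h1 + n_loop :] = ca_b
    bead_override[: 3 * h1] = beads_a
    bead_override[3 * (h1 + n_loop) :] = beads_b
    avoid = np.vstack([ca[: h1 - 1], ca[h1 + n_loop + 1 :]])
    ok = False
    for cand in _route_candidates(ca[h1 - 1], ca[h1 + n_loop], n_loop, avoid=avoid):
        ca[h1 : h1 + n_loop] = cand
        if _partial_beads_valid(ca, bead_override):
            ok = True
            break
        ca[h1 : h1 + n_loop] = np.nan
    if not ok:
        raise PackingError(f"could not route the {n_loop}-residue bundle loop")
    pos = _assemble_beads(ca, bead_override)
    try:
        return NativeReference(
            n_residues, pos, "helix_bundle", label or f"bundle{n_residues}"
        )
    except PackingError:
        raise
    except TargetError as exc:
        raise PackingError(f"packing produced an invalid geometry: {exc}") from exc


# ---------------------------------------------------------------------------
# structure-based potential


def derive_go_parameters(
    native: NativeReference,
    contacts: ContactDefinition = ContactDefinition(),
    bond_k: float = DEFAULT_BOND_K,
    angle_k: float = DEFAULT_ANGLE_K,
    epsilon: float = DEFAULT_EPSILON,
    repulsion_sigma: float = DEFAULT_REPULSION_SIGMA,
    repulsion_eps: float = DEFAULT_REPULSION_EPS,
) -> GoParameters:
    """Structure-based potential whose minimum is the native reference.

    Bonds/angles are restrained at their native values; every native
    contact becomes a 12-10 well between the two CA beads at the native
    distance; all other bead pairs more than 2 bonds apart repel.
    """
    pos = native.bead_positions
    nb = pos.shape[0]
    bond_idx = np.column_stack([np.arange(nb - 1), np.arange(1, nb)])
    bond_r0 = np.linalg.norm(pos[bond_idx[:, 1]] - pos[bond_idx[:, 0]], axis=1)
    angle_idx = np.column_stack([np.arange(nb - 2), np.arange(1, nb - 1), np.arange(2, nb)])
    u = pos[angle_idx[:, 0]] - pos[angle_idx[:, 1]]
    v = pos[angle_idx[:, 2]] - pos[angle_idx[:, 1]]
    cosang = np.sum(u * v, axis=1) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    theta0 = np.arccos(np.clip(cosang, -1.0, 1.0))

    res_pairs, dists = contact_map(native.ca_positions, contacts)
    if res_pairs.shape[0] == 0:
        warnings.warn(
            f"target {native.label!r}: empty native contact map; potential has "
            "bonds/angles and repulsion only",
            stacklevel=2,
        )
    bpr = native.beads_per_residue
    pair_idx = res_pairs * bpr + CA_OFFSET
    return GoParameters(
        n_beads=nb,
        bond_indices=bond_idx,
        bond_r0=bond_r0,
        bond_k=bond_k,
        angle_indices=angle_idx,
        angle_theta0=theta0,
        angle_k=angle_k,
        pair_indices=pair_idx,
        pair_r0=dists,
        epsilon=epsilon,
        repulsion_sigma=repulsion_sigma,
        repulsion_eps=repulsion_eps,
        contact_residue_pairs=res_pairs,
    )


def from_pdb_backbone(positions_nm: np.ndarray, fold_class: str = "alpha_beta", label: str = "pdb") -> NativeReference:
    """Wrap externally supplied N/CA/C backbone coordinates (nm) as a target."""
    pos = np.asarray(positions_nm, dtype=float)
    if pos.shape[0] % BEADS_PER_RESIDUE != 0:
        raise TargetError("backbone bead count must be a multiple of 3 (N, CA, C)")
    return NativeReference(pos.shape[0] // BEADS_PER_RESIDUE, pos, fold_class, label)
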