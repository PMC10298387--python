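"""File formats: single/multi-model PDB (via biotite), XYZ trajectories,
CSV/TSV tables.

Internal coordinates are nm; PDB and XYZ files are written in Angstrom.
"""

from __future__ import annotations

import csv
from typing import TYPE_CHECKING, Optional

import numpy as np
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .chain import BEADS_PER_RESIDUE, Conformation

if TYPE_CHECKING:  # pragma: no cover
    from .analysis import ContactDefinition
    from .dynamics import Trajectory
    from .targets import NativeReference

NM_TO_ANG = 10.0
_ATOM_NAMES = ("N", "CA", "C")
_ELEMENTS = ("N", "C", "C")


def _atom_array(positions_nm: np.ndarray, box_nm: Optional[np.ndarray] = None) -> AtomArray:
    n_beads = positions_nm.shape[0]
    arr = AtomArray(n_beads)
    arr.coord = np.asarray(positions_nm) * NM_TO_ANG
    arr.chain_id[:] = "A"
    arr.res_name[:] = "ALA"
    arr.hetero[:] = False
    for i in range(n_beads):
        arr.res_id[i] = i // BEADS_PER_RESIDUE + 1
        arr.atom_name[i] = _ATOM_NAMES[i % BEADS_PER_RESIDUE]
        arr.element[i] = _ELEMENTS[i % BEADS_PER_RESIDUE]
    if box_nm is not None:
        arr.box = np.diag(np.asarray(box_nm) * NM_TO_ANG)
    return arr


def write_reference_pdb(ref: "NativeReference", path) -> None:
    """Coarse-grained native structure as a single-model PDB."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array(ref.bead_positions))
    pdb.write(str(path))


def write_conformation_pdb(
    conf: Conformation, path, box_nm: Optional[np.ndarray] = None
) -> None:
    pdb = PDBFile()
    pdb.set_structure(_atom_array(conf.positions, box_nm))
    pdb.write(str(path))


def write_trajectory_pdb(traj: "Trajectory", path) -> None:
    """Multi-model PDB, one MODEL per snapshot."""
    arrays = [_atom_array(f.positions) for f in traj.frames]
    stack = AtomArrayStack(len(arrays), arrays[0].array_length())
    stack.coord = np.stack([a.coord for a in arrays])
    for ann in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(ann, arrays[0].get_annotation(ann))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_backbone_pdb(path) -> np.ndarray:
    """N/CA/C backbone coordinates from a PDB file, in nm, ordered
    (N, CA, C) per residue.  Raises ValueError for incomplete backbones."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    mask = np.isin(arr.atom_name, _ATOM_NAMES) & ~arr.hetero
    arr = arr[mask]
    res_ids = np.unique(arr.res_id)
    coords = []
    for rid in res_ids:
        res = arr[arr.res_id == rid]
        for name in _ATOM_NAMES:
            sel = res[res.atom_name == name]
            if sel.array_length() != 1:
                raise ValueError(
                    f"residue {rid}: expected exactly one {name} atom, "
                    f"got {sel.array_length()}"
                )
            coords.append(sel.coord[0])
    return np.asarray(coords) / NM_TO_ANG


def write_trajectory_xyz(traj: "Trajectory", path) -> None:
    """Multi-frame XYZ (Angstrom) with time/phase in the comment line."""
    with open(path, "w") as fh:
        for frame in traj.frames:
            n = frame.positions.shape[0]
            fh.write(f"{n}\n")
            fh.write(f"t_ps={frame.time:.6f} phase={frame.phase}\n")
            for i, xyz in enumerate(frame.positions * NM_TO_ANG):
                el = _ELEMENTS[i % BEADS_PER_RESIDUE]
                fh.write(f"{el} {xyz[0]:.5f} {xyz[1]:.5f} {xyz[2]:.5f}\n")


def read_trajectory_xyz(path) -> list[Conformation]:
    """Read frames written by :func:`write_trajectory_xyz`."""
    frames: list[Conformation] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline().split()
            time = float(comment[0].split("=")[1])
            phase = comment[1].split("=")[1]
            pos = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                pos[i] = [float(x) for x in parts[1:4]]
            frames.append(
                Conformation(positions=pos / NM_TO_ANG, time=time, phase=phase)
            )
    return frames


def write_contacts_tsv(
    pairs: np.ndarray, distances_nm: np.ndarray, path
) -> None:
    """Native contact map as TSV: residue i, residue j, distance (nm)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["i", "j", "distance_nm"])
        for (i, j), d in zip(pairs, distances_nm):
            writer.writerow([int(i), int(j), f"{d:.6f}"])


def write_series_csv(path, times: np.ndarray, values: np.ndarray, name: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_ps", name])
        for t, v in zip(times, values):
            writer.writerow([f"{t:.4f}", f"{v:.6f}"])


def read_series_csv(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1]


def write_timeline_tsv(path, matrix: np.ndarray, times: np.ndarray) -> None:
    """Per-residue timeline (residue rows, snapshot columns)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["residue"] + [f"{t:.2f}" for t in times])
        for i, row in enumerate(matrix):
            writer.writerow([i] + [str(x) for x in row])


def write_energies_csv(traj: "Trajectory", path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["time_ps", "bond", "angle", "native_pair", "repulsion", "steering", "restraint", "total"]
        )
        for frame, bd in zip(traj.frames, traj.energies):
            d = bd.as_dict()
            writer.writerow(
                [f"{frame.time:.4f}"]
                + [f"{d[k]:.6f}" for k in ("bond", "angle", "native_pair", "repulsion", "steering", "restraint", "total")]
            )
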