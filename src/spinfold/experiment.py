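"""Experiment orchestration: triplicate assisted and control runs per
target, per-run analysis outputs, cross-run comparison, manifest and
figures.  One TOML config file fully defines an experiment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import analysis, pdbio
from .analysis import ContactDefinition, FoldingEvent, first_passage
from .chain import BoxSpec
from .dynamics import (
    BlowUpError,
    SimulationParams,
    Trajectory,
    default_protocol,
    default_restraint,
    make_start,
    run_protocol,
)
from .steering import DEFAULT_K_RES, DEFAULT_K_ROT, DEFAULT_RATE, STEERED_FRACTION
from .targets import (
    NativeReference,
    derive_go_parameters,
    from_pdb_backbone,
    make_bundle_target,
    make_hairpin_target,
    make_helix_target,
    make_mixed_target,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "make_figures", "build_target"]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    target_kind: str = "helix"  # helix | hairpin | bundle | mixed | pdb
    n_residues: int = 20
    helix_span: Optional[tuple[int, int]] = None
    strand_spans: list = field(default_factory=list)
    pdb_path: Optional[str] = None

    # integrator
    timestep: float = 0.02
    temperature: float = 300.0
    friction: float = 0.5
    n_steps: int = 150_000
    snapshot_interval: float = 6.0

    # steering protocol
    rotation_rate: float = DEFAULT_RATE
    rotation_force_constant: float = DEFAULT_K_ROT
    rotation_sense: int = -1
    rotation_axial_free: bool = False
    steering_duration: Optional[float] = None  # ps; None -> fraction of run
    steering_fraction: float = STEERED_FRACTION
    restraint_force_constant: float = DEFAULT_K_RES

    # potential
    epsilon: float = 6.5
    contact_cutoff: float = 0.8
    min_sequence_separation: int = 3

    # folding criterion
    q_threshold: float = 0.85
    dwell: Optional[float] = None  # ps; None -> 10 snapshot intervals

    # design
    n_replicates: int = 3
    master_seed: int = 2023
    box_x: Optional[float] = None
    label: str = ""
    write_pdb_trajectories: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per arm")

    @classmethod
    def from_toml(cls, path) -> "ExperimentConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat = {}
        for section in raw.values() if all(isinstance(v, dict) for v in raw.values()) else [raw]:
            flat.update(section)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "helix_span" in flat and flat["helix_span"] is not None:
            flat["helix_span"] = tuple(flat["helix_span"])
        return cls(**flat)

    def contact_definition(self) -> ContactDefinition:
        return ContactDefinition(
            cutoff=self.contact_cutoff,
            min_sequence_separation=self.min_sequence_separation,
        )

    def simulation_params(self, seed: int) -> SimulationParams:
        return SimulationParams(
            timestep=self.timestep,
            temperature=self.temperature,
            friction=self.friction,
            n_steps=self.n_steps,
            snapshot_interval=self.snapshot_interval,
            seed=seed,
        )

    def dwell_ps(self) -> float:
        return self.dwell if self.dwell is not None else 10.0 * self.snapshot_interval

    def as_dict(self) -> dict:
        return {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }


def build_target(cfg: ExperimentConfig) -> NativeReference:
    kind = cfg.target_kind
    if kind == "helix":
        return make_helix_target(cfg.n_residues, label=cfg.label)
    if kind == "hairpin":
        return make_hairpin_target(cfg.n_residues, label=cfg.label)
    if kind == "bundle":
        return make_bundle_target(cfg.n_residues, label=cfg.label)
    if kind == "mixed":
        if cfg.helix_span is None:
            raise ValueError("mixed target needs helix_span")
        spans = [tuple(s) for s in cfg.strand_spans]
        return make_mixed_target(
            cfg.helix_span, spans, cfg.n_residues, label=cfg.label
        )
    if kind == "pdb":
        if not cfg.pdb_path:
            raise ValueError("pdb target needs pdb_path")
        coords = pdbio.read_backbone_pdb(cfg.pdb_path)
        return from_pdb_backbone(coords, label=cfg.label or Path(cfg.pdb_path).stem)
    raise ValueError(f"unknown target kind {kind!r}")


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-run seeds: children of the master SeedSequence;
    assisted runs take the first n, controls the next n."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(2 * n)]


@dataclass
class RunResult:
    arm: str
    index: int
    seed: int
    traj: Optional[Trajectory]
    event: Optional[FoldingEvent]
    error: Optional[str] = None
    times: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    rmsd: Optional[np.ndarray] = None


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    native: NativeReference
    runs: list
    summary: analysis.AccelerationSummary
    outdir: Path
    manifest_path: Path


def _analyze_run(
    traj: Trajectory,
    native: NativeReference,
    cdef: ContactDefinition,
    cfg: ExperimentConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, FoldingEvent]:
    times, q = analysis.q_series(traj, native, cdef)
    _, rmsd = analysis.rmsd_series(traj, native)
    event = first_passage(times, q, cfg.q_threshold, cfg.dwell_ps())
    return times, q, rmsd, event


def run_experiment(cfg: ExperimentConfig, outdir) -> ExperimentResult:
    """Run n assisted + n control replicates, write every output, return
    the cross-run summary.  Per-run failures are recorded and the rest of
    the experiment continues."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    native = build_target(cfg)
    cdef = cfg.contact_definition()
    go = derive_go_parameters(
        native, cdef, epsilon=cfg.epsilon
    )
    pdbio.write_reference_pdb(native, outdir / "native.pdb")
    pairs, dists = analysis.contact_map(native.ca_positions, cdef)
    pdbio.write_contacts_tsv(pairs, dists, outdir / "native_contacts.tsv")

    box = None
    if cfg.box_x is not None:
        box = BoxSpec(np.array([cfg.box_x, 8.0, 8.0]))

    seeds = replicate_seeds(cfg.master_seed, cfg.n_replicates)
    runs: list[RunResult] = []
    for arm_i, arm in enumerate(("assisted", "control")):
        for rep in range(cfg.n_replicates):
            seed = seeds[arm_i * cfg.n_replicates + rep]
            run_id = f"{arm}_{rep}"
            rundir = outdir / run_id
            rundir.mkdir(exist_ok=True)
            params = cfg.simulation_params(seed)
            try:
                if arm == "control":
                    traj = run_protocol(
                        native, go, params, box=box, control=True, run_id=run_id
                    )
                else:
                    start, box_used = make_start(native, box)
                    proto = default_protocol(
                        start,
                        native,
                        params,
                        duration=(
                            cfg.steering_duration
                            if cfg.steering_duration is not None
                            else cfg.steering_fraction * params.total_time
                        ),
                        rate=cfg.rotation_rate,
                        force_constant=cfg.rotation_force_constant,
                        sense=cfg.rotation_sense,
                        axial_free=cfg.rotation_axial_free,
                    )
                    restraint = default_restraint(
                        start, native, cfg.restraint_force_constant
                    )
                    traj = run_protocol(
                        native,
                        go,
                        params,
                        proto=proto,
                        restraint=restraint,
                        box=box,
                        run_id=run_id,
                    )
            except BlowUpError as exc:
                logger.error("run %s failed: %s", run_id, exc)
                if exc.trajectory is not None and exc.trajectory.n_frames:
                    pdbio.write_trajectory_xyz(exc.trajectory, rundir / "partial.xyz")
                runs.append(RunResult(arm, rep, seed, None, None, error=str(exc)))
                continue

            times, q, rmsd, event = _analyze_run(traj, native, cdef, cfg)
            _write_run_outputs(traj, native, cdef, cfg, rundir, times, q, rmsd, event)
            runs.append(RunResult(arm, rep, seed, traj, event, None, times, q, rmsd))

    assisted = [r.event for r in runs if r.arm == "assisted" and r.event is not None]
    control = [r.event for r in runs if r.arm == "control" and r.event is not None]
    summary = analysis.acceleration_summary(assisted, control)

    summary_payload = {
        "config": cfg.as_dict(),
        "n_native_contacts": int(pairs.shape[0]),
        "runs": [
            {
                "run_id": f"{r.arm}_{r.index}",
                "arm": r.arm,
                "seed": r.seed,
                "error": r.error,
                "first_passage_ps": None
                if r.event is None or r.event.censored
                else r.event.first_passage_time,
                "censored": None if r.event is None else r.event.censored,
                "budget_ps": None if r.event is None else r.event.budget,
            }
            for r in runs
        ],
        "acceleration": {
            "ratio": summary.ratio,
            "is_lower_bound": summary.is_lower_bound,
            "median_assisted_ps": summary.median_assisted,
            "median_control_ps": summary.median_control,
            "n_censored_assisted": summary.n_censored_assisted,
            "n_censored_control": summary.n_censored_control,
        },
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary_payload, fh, indent=2)

    manifest_path = outdir / "manifest.json"
    _write_manifest(outdir, manifest_path, cfg)
    return ExperimentResult(cfg, native, runs, summary, outdir, manifest_path)


def _write_run_outputs(traj, native, cdef, cfg, rundir: Path, times, q, rmsd, event):
    pdbio.write_trajectory_xyz(traj, rundir / "traj.xyz")
    if cfg.write_pdb_trajectories:
        pdbio.write_trajectory_pdb(traj, rundir / "traj.pdb")
    pdbio.write_series_csv(rundir / "q.csv", times, q, "Q")
    pdbio.write_series_csv(rundir / "rmsd.csv", times, rmsd, "rmsd_nm")
    pdbio.write_energies_csv(traj, rundir / "energies.csv")
    ss = analysis.secondary_timeline(traj)
    pdbio.write_timeline_tsv(rundir / "secondary.tsv", ss, times)
    ct = analysis.contact_timeline(traj, native, cdef)
    pdbio.write_timeline_tsv(rundir / "contacts_per_residue.tsv", ct.astype(int), times)
    meta = dict(traj.metadata)
    meta["first_passage_ps"] = None if event.censored else event.first_passage_time
    meta["censored"] = event.censored
    with open(rundir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def _write_manifest(outdir: Path, manifest_path: Path, cfg: ExperimentConfig) -> None:
    entries = []
    for path in sorted(outdir.rglob("*")):
        if not path.is_file() or path == manifest_path:
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries.append(
            {"path": str(path.relative_to(outdir)), "sha256": digest, "bytes": path.stat().st_size}
        )
    with open(manifest_path, "w") as fh:
        json.dump(
            {"config": cfg.as_dict(), "files": entries}, fh, indent=2
        )


_SS_COLORS = {"H": "#cc00cc", "G": "#3333ff", "E": "#e6c800", "T": "#00a000", "C": "#ffffff"}


def make_figures(result: ExperimentResult, path=None) -> Path:
    """Four-panel figure per target: RMSD (A), Q (B), secondary-structure
    timeline (C), per-residue native-contact timeline (D); assisted runs in
    the left column, controls in the right; a red marker shows the end of
    the transient rotation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    ok_runs = [r for r in result.runs if r.traj is not None]
    if not ok_runs:
        raise ValueError("no completed runs to plot")
    cfg = result.config
    duration = next(
        (
            r.traj.metadata["steering_duration_ps"]
            for r in ok_runs
            if r.arm == "assisted"
        ),
        0.0,
    )
    fig, axes = plt.subplots(4, 2, figsize=(11, 12), sharex=True)
    codes = {c: i for i, c in enumerate(analysis.SS_CODES)}
    cmap = ListedColormap([_SS_COLORS[c] for c in analysis.SS_CODES])

    for col, arm in enumerate(("assisted", "control")):
        arm_runs = [r for r in ok_runs if r.arm == arm]
        missing = cfg.n_replicates - len(arm_runs)
        if missing:
            logger.warning("%d %s run(s) missing; plotting gaps", missing, arm)
        for r in arm_runs:
            axes[0][col].plot(r.times, r.rmsd, lw=0.8, label=f"run {r.index}")
            axes[1][col].plot(r.times, r.q, lw=0.8)
        axes[0][col].set_title(f"{arm} ({len(arm_runs)}/{cfg.n_replicates} runs)")
        axes[0][col].set_ylabel("RMSD (nm)")
        axes[1][col].set_ylabel("Q")
        axes[1][col].set_ylim(0, 1.05)
        if arm_runs:
            show = arm_runs[0]
            ss = analysis.secondary_timeline(show.traj)
            mat = np.vectorize(codes.get)(ss)
            axes[2][col].imshow(
                mat,
                aspect="auto",
                cmap=cmap,
                vmin=0,
                vmax=len(analysis.SS_CODES) - 1,
                extent=[show.times[0], show.times[-1], ss.shape[0], 0],
                interpolation="nearest",
            )
            cdef = cfg.contact_definition()
            ct = analysis.contact_timeline(show.traj, result.native, cdef)
            axes[3][col].imshow(
                ct.astype(int),
                aspect="auto",
                cmap="Greys",
                extent=[show.times[0], show.times[-1], ct.shape[0], 0],
                interpolation="nearest",
            )
        axes[2][col].set_ylabel("residue (2° structure)")
        axes[3][col].set_ylabel("residue (native contacts)")
        axes[3][col].set_xlabel("time (ps)")
        if arm == "assisted" and duration > 0:
            for row in range(4):
                axes[row][col].axvline(duration, color="red", lw=1.2)
    fig.suptitle(f"{result.native.label}: assisted vs control")
    fig.tight_layout()
    if path is None:
        path = result.outdir / "figure.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)
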