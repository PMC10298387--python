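# spinfold

Coarse-grained, desk-scale simulations of **rotation-assisted protein
folding**: a structure-based (Gō-like) polypeptide model is folded from the
extended state while a transient enforced rotation is applied to the
C-terminal residue and the N-terminal residue is positionally restrained;
after the transient phase all bias is removed and dynamics continue freely.
The package ships the trajectory readouts used to judge folding: RMSD to
native, fraction of native contacts Q, per-residue secondary-structure and
native-contact timelines, first-passage folding times, and an
assisted-vs-control comparison run in triplicate.

## Model

* **Targets** — synthetic native folds of four structural classes (ideal
  α-helix, β-hairpin, two-helix bundle, α+β pack), 3 backbone beads per
  residue (N, CA, C) built from standard peptide geometry. A user-supplied
  PDB can be coarse-grained instead.
* **Potential** — harmonic bonds/angles at native values, 12-10 wells
  between native CA pairs (8 Å contact map, sequence separation ≥ 3),
  r⁻¹² repulsion elsewhere. The native fold is the minimum by construction.
* **Start** — φ = ψ = 180° extended chain, bounded dihedral relaxation into
  the β basin, aligned along X and fitted into the box (with automatic
  compaction when the box is shorter than the stretched chain).
* **Steering** — rotating-reference harmonic on the C-terminal residue
  (default 0.36°/ps = 1 turn/ns, k = 10,000 kJ·mol⁻¹·nm⁻²; fully pinned
  by default, with an optional axial-free variant that lets the chain
  contract while it is cranked) plus a harmonic restraint on the
  N-terminal residue; both switch off together at the end of the transient
  phase.
* **Dynamics** — BAOAB Langevin integrator (velocity Verlet at zero
  friction), 300 K default, bit-reproducible for a fixed seed.

## CLI

```sh
# emit a toy native target (PDB + contact-map TSV)
spinfold make-target --kind helix --n-residues 20 --out targets/

# run a full experiment (n assisted + n control replicates) from a config
spinfold run --config examples/helix20.toml --out runs/helix20

# recompute Q/RMSD/first-passage for a single trajectory
spinfold analyze --traj runs/helix20/assisted_0/traj.xyz \
                 --native runs/helix20/native.pdb --out analysis/

# compare folding times between two arms
spinfold compare --assisted-dir runs/helix20/assisted_0 \
                 --control-dir runs/helix20/control_0

# regenerate the 4-panel figure (RMSD / Q / secondary / contacts,
# assisted left, control right, red line at steering switch-off)
spinfold report --experiment-dir runs/helix20
```

A minimal config:

```toml
target_kind = "helix"
n_residues = 20
temperature = 340.0
n_steps = 120000
steering_duration = 600.0   # ps
rotation_rate = 3.6         # degree/ps
rotation_axial_free = true
n_replicates = 5
master_seed = 2023
```

Every experiment directory contains per-run XYZ trajectories, Q/RMSD CSVs,
per-residue TSV timelines, energy breakdowns, a cross-run `summary.json`
and a `manifest.json` with SHA-256 checksums of every output; re-running
the same config reproduces all of them bit-exactly.

## Layout

| module | role |
| --- | --- |
| `spinfold.targets` | synthetic native folds + Gō parameter derivation |
| `spinfold.chain` | extended-chain builder, X-alignment, box fitting |
| `spinfold.energy` | potential energy / exact forces |
| `spinfold.steering` | enforced rotation + N-terminal restraint |
| `spinfold.dynamics` | BAOAB Langevin integrator, two-phase protocol |
| `spinfold.analysis` | RMSD, contacts/Q, secondary structure, kinetics |
| `spinfold.experiment` | replicate orchestration, manifests, figures |
| `spinfold.pdbio` | PDB (via biotite), XYZ, CSV/TSV |
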