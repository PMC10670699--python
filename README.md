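# gelion

Coarse-grained molecular-dynamics simulation and ion-partition analysis of
finite polyelectrolyte gels immersed in monovalent/divalent salt solutions
(implicit solvent, bead–spring star-polymer network).

The package builds a "perfect compact gel" — regular star polymers (one core
bead + `f` arms of `M` beads each) on an `Nb³` cubic lattice with the free
ends of adjacent stars bonded — adds neutralising counterions and salt ions,
evolves the system with velocity-Verlet dynamics (WCA excluded volume, stiff
harmonic bonds, Coulomb electrostatics with Bjerrum length `lB`), and
measures:

* the gel radius of gyration `Rg` and internal volume fraction `phi`,
* the charged-particle pair correlation `gq(r)` — local over system-wide ion
  concentration as a function of distance from the gel's centre of mass,
* ion partition coefficients `Qi = c_in/c_bulk` from the ratio of the
  interior and bulk plateaus of `gq(r)`, and `Q2/Q1`,
* the scaling law `Qi ~ phi^kappa * csalt^-mu` by log–log regression.

All simulation quantities are in reduced units (length σ, energy ε = kT,
time τ); "mmol" concentrations are mmol/L (mM) and are converted to reduced
number densities via `c0` derived from the aqueous Bjerrum-length mapping
(lB = 0.71 nm ↔ 2.1 σ, hence σ ≈ 0.338 nm).

## CLI

```bash
gelion build  --preset ci-small -o out/      # gel + ions -> LAMMPS data file
gelion run    --preset ci-small -o out/      # full protocol -> dump + thermo CSV
gelion analyze out/trajectory.lammpstrj --data out/system.data -o out/
gelion sweep  -c plan.yml -o sweep/          # one-axis scan + scaling fits
gelion fit    sweep/sweep.csv -o sweep/      # fit Q ~ phi^kappa csalt^-mu
gelion fixtures partition -o fix/            # synthetic ground-truth fixtures
```

Configuration is YAML with blocks mirroring the dataclasses
(`gel`, `salt`, `forcefield`, `protocol`, plus `box_length`, `seed`); two
presets ship with the package:

* `paper-full` — the published protocol (Nb=4, f=4, M=15; kT=1,
  dt=0.005 τ, 5000 τ equilibration, 150 000 τ production, Nosé–Hoover
  thermostat, Ewald electrostatics at 1e-4 accuracy). Cluster-scale.
* `ci-small` — desk-scale smoke preset (Nb=2, f=4, M=4 gel with arm slack,
  L=30 σ, Langevin thermostat, damped-shifted-force electrostatics,
  150 τ + 350 τ protocol). Minutes per run.

Every command writes a provenance JSON (config, seed, connectivity map,
`c0`) sufficient to re-run it byte-identically.

A sweep plan is YAML like:

```yaml
axis: csalt_div          # lB | csalt_mono | csalt_div
values: [1, 2, 5, 10, 20]
seeds: [0, 1]
base:
  gel: {nb: 2, f: 4, m: 4, slack: 0.85}
  salt: {c_mono: 10.0}   # e.g. fixed monovalent background + divalent axis
  forcefield: {lB: 2.1, coulomb_method: dsf}
  protocol: {t_equil: 150, t_prod: 350, thermostat: langevin}
  box_length: 30.0
```

## Package layout

| module | contents |
| --- | --- |
| `gelion.model` | `GelSpec`/`SaltSpec`/`SystemState`, gel construction, ion insertion, salt accounting |
| `gelion.forcefield` | WCA, harmonic bonds, Coulomb pair terms; DSF backend + neighbour lists |
| `gelion.ewald` | smooth Ewald summation (reference electrostatics, accuracy-tuned) |
| `gelion.dynamics` | velocity-Verlet, Nosé–Hoover chain & Langevin thermostats, run protocol |
| `gelion.analysis` | unwrapping, Rg, phi, gq(r), partition coefficients, scaling fits |
| `gelion.fixtures` | synthetic trajectories/tables/lattices with known ground truth |
| `gelion.workflow` | presets, single-run orchestration, sweeps |
| `gelion.cli` | `gelion` command-line entry point |
| `gelion.io` | LAMMPS data/dump, XYZ, thermo CSV, provenance JSON |

## Notes and deliberate deviations

* The published protocol is constant-pressure; the target pressure is not
  stated. The default ensemble here is NVT in a fixed large box whose bulk
  region acts as its own reservoir.
* The reference long-range solver is smooth Ewald rather than mesh PPPM
  (same physics; directly verifiable against image-sum oracles). The DSF
  mode is approximate and is labelled as such.
* Gel-neutralising counterions are excluded from the salt accounting
  (`csalt` counts added salt only) but are included in the monovalent
  cation species when measuring `Q1`, since they are physically identical
  ions.
* Plateau windows for `Qi` default to r ∈ [0, 0.5·Rg] (interior) and
  [max(1.5·Rg, Rg+5σ), 0.45·L] (bulk), with a flatness diagnostic; both are
  configurable (`WindowPolicy`).
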