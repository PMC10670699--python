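"""Time evolution: velocity-Verlet integration with Nose-Hoover or Langevin
thermostatting, and the equilibrate-then-sample production protocol.

Reduced units throughout (all masses are 1); temperatures are in epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InstabilityError
from .forcefield import ForceField, ForceFieldParams
from .model import SystemState


@dataclass(frozen=True)
class ProtocolParams:
    """Equilibration/production protocol settings (times in tau)."""

    kT: float = 1.0
    dt: float = 0.005
    t_equil: float = 5000.0
    t_prod: float = 150000.0
    sample_every: float = 10.0
    log_every: float = 10.0
    thermostat: str = "nose_hoover"      # "nose_hoover" | "langevin" | "none"
    thermostat_coupling: float = 0.5     # tau_damp (NH) or 1/gamma (Langevin)
    seed: int = 0
    warmup_steps: int = 0                # initial steps at dt/5 to relax contacts
    max_step_displacement: float = 0.5   # instability guard, sigma/step

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.kT <= 0:
            raise ConfigurationError("kT must be positive")
        if self.t_equil < 0 or self.t_prod < 0:
            raise ConfigurationError("t_equil and t_prod must be >= 0")
        if self.thermostat not in ("nose_hoover", "langevin", "none"):
            raise ConfigurationError(f"unknown thermostat {self.thermostat!r}")
        if self.thermostat_coupling <= 0:
            raise ConfigurationError("thermostat_coupling must be positive")


@dataclass
class Trajectory:
    """Production frames plus static topology and run records."""

    positions: np.ndarray        # (n_frames, n, 3), wrapped
    times: np.ndarray            # (n_frames,)
    species: np.ndarray
    charge: np.ndarray
    bonds: np.ndarray
    box_length: float
    metadata: dict = field(default_factory=dict)
    thermo: pd.DataFrame | None = None
    final_state: SystemState | None = None

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.positions[i]


# ---------------------------------------------------------------------------
# Velocity initialisation & thermostats
# ---------------------------------------------------------------------------

def maxwell_velocities(n: int, kT: float, rng: np.random.Generator,
                       zero_com: bool = True) -> np.ndarray:
    v = rng.normal(0.0, math.sqrt(kT), size=(n, 3))
    if zero_com and n > 1:
        v -= v.mean(axis=0)
    return v


def kinetic_temperature(velocities: np.ndarray, n_dof: int | None = None) -> float:
    n = len(velocities)
    if n_dof is None:
        n_dof = 3 * n
    if n_dof <= 0:
        raise ConfigurationError("zero degrees of freedom")
    return float((velocities ** 2).sum() / n_dof)


class NoseHooverChain:
    """Deterministic Nose-Hoover chain (default length 3) velocity scaling.

    The chain couples to the total kinetic energy; `half_step` advances the
    thermostat variables by dt/2 and rescales velocities (standard
    Martyna-Tuckerman-Klein splitting, one Suzuki-Yoshida stage).
    """

    def __init__(self, n_dof: int, kT: float, tau: float, length: int = 3):
        if n_dof <= 0:
            raise ConfigurationError("zero degrees of freedom")
        self.n_dof = n_dof
        self.kT = kT
        self.length = length
        self.Q = np.full(length, kT * tau * tau)
        self.Q[0] *= n_dof
        self.xi = np.zeros(length)    # thermostat "velocities"
        self.eta = np.zeros(length)   # thermostat "positions" (bookkeeping)

    def half_step(self, velocities: np.ndarray, dt: float) -> np.ndarray:
        dt2 = dt / 2.0
        dt4 = dt / 4.0
        kin2 = float((velocities ** 2).sum())  # 2*K for unit masses

        G = np.empty(self.length)
        G[0] = (kin2 - self.n_dof * self.kT) / self.Q[0]
        for j in range(1, self.length):
            G[j] = (self.Q[j - 1] * self.xi[j - 1] ** 2 - self.kT) / self.Q[j]

        for j in range(self.length - 1, -1, -1):
            if j < self.length - 1:
                self.xi[j] *= math.exp(-dt4 * self.xi[j + 1])
            self.xi[j] += G[j] * dt4
            if j < self.length - 1:
                self.xi[j] *= math.exp(-dt4 * self.xi[j + 1])

        scale = math.exp(-dt2 * self.xi[0])
        velocities = velocities * scale
        self.eta += self.xi * dt2
        kin2 *= scale * scale

        G[0] = (kin2 - self.n_dof * self.kT) / self.Q[0]
        for j in range(self.length):
            if j > 0:
                G[j] = (self.Q[j - 1] * self.xi[j - 1] ** 2 - self.kT) / self.Q[j]
            if j < self.length - 1:
                self.xi[j] *= math.exp(-dt4 * self.xi[j + 1])
            self.xi[j] += G[j] * dt4
            if j < self.length - 1:
                self.xi[j] *= math.exp(-dt4 * self.xi[j + 1])
        return velocities


def thermostat_step(state: SystemState, protocol: ProtocolParams,
                    rng: np.random.Generator | None = None) -> SystemState:
    """Apply one thermostat coupling interval dt to the velocities only."""
    if state.n < 2:
        raise ConfigurationError("thermostat needs >= 2 particles")
    out = state.copy()
    if protocol.thermostat == "langevin":
        if rng is None:
            rng = np.random.default_rng(protocol.seed)
        c1 = math.exp(-protocol.dt / protocol.thermostat_coupling)
        c2 = math.sqrt(protocol.kT * (1.0 - c1 * c1))
        out.velocities = c1 * out.velocities + c2 * rng.normal(size=out.velocities.shape)
    else:
        nhc = NoseHooverChain(3 * state.n - 3, protocol.kT,
                              protocol.thermostat_coupling)
        out.velocities = nhc.half_step(out.velocities, protocol.dt)
    return out


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def nve_step(state: SystemState, ff_params: ForceFieldParams, dt: float,
             forcefield: ForceField | None = None,
             forces: np.ndarray | None = None) -> SystemState:
    """One velocity-Verlet step (time-reversible); positions re-wrapped.

    ``forcefield``/``forces`` may be passed to avoid recomputation in loops.
    """
    ff = forcefield if forcefield is not None else ForceField(state, ff_params)
    if forces is None:
        _, _, _, forces = ff.compute(state.positions)
    out = state.copy()
    v = out.velocities + 0.5 * dt * forces
    dx = v * dt
    _guard_displacement(dx, 0.5, step=None)
    out.positions = out.positions + dx
    out.wrap()
    _, _, _, f_new = ff.compute(out.positions)
    out.velocities = v + 0.5 * dt * f_new
    return out


def _guard_displacement(dx: np.ndarray, limit: float, step):
    m = float(np.max(np.abs(dx))) if dx.size else 0.0
    if not np.isfinite(m) or m > limit:
        raise InstabilityError(
            f"max per-step displacement {m:.3g} sigma exceeds {limit} sigma",
            step=step)


def run_protocol(state: SystemState, ff_params: ForceFieldParams,
                 protocol: ProtocolParams) -> Trajectory:
    """Equilibrate, then sample production frames and a thermo log.

    The equilibration segment is discarded; production frames (wrapped
    positions) are recorded every ``sample_every`` tau.  On instability the
    last good state is attached to the raised error.
    """
    ff = ForceField(state, ff_params)
    rng = np.random.default_rng(protocol.seed)
    x = state.positions.copy()
    v = state.velocities.copy()
    if not np.any(v):
        v = maxwell_velocities(state.n, protocol.kT, rng)

    use_nh = protocol.thermostat == "nose_hoover"
    use_lan = protocol.thermostat == "langevin"
    nhc = None
    if use_nh:
        nhc = NoseHooverChain(3 * state.n - 3, protocol.kT,
                              protocol.thermostat_coupling)
        n_dof = 3 * state.n - 3
    else:
        n_dof = 3 * state.n
    if use_lan:
        c1 = math.exp(-protocol.dt / protocol.thermostat_coupling)
        c2 = math.sqrt(protocol.kT * (1.0 - c1 * c1))

    dt = protocol.dt
    L = state.box_length
    n_equil = int(round(protocol.t_equil / dt))
    n_prod = int(round(protocol.t_prod / dt))
    sample_stride = max(1, int(round(protocol.sample_every / dt)))
    log_stride = max(1, int(round(protocol.log_every / dt)))
    guard = protocol.max_step_displacement

    def wrap(arr):
        arr -= L * np.floor(arr / L)

    def snapshot():
        s = state.copy()
        s.positions = x.copy()
        s.velocities = v.copy()
        return s

    e_wca, e_bond, e_coul, f = ff.compute(x)

    frames, times, thermo_rows = [], [], []
    total_steps = protocol.warmup_steps + n_equil + n_prod
    step = 0
    try:
        # Warmup: small-dt Langevin-damped relaxation of initial contacts.
        for _ in range(protocol.warmup_steps):
            dts = dt / 5.0
            v += 0.5 * dts * f
            dx = v * dts
            _guard_displacement(dx, guard, step)
            x += dx
            wrap(x)
            v *= 0.9
            v += math.sqrt(protocol.kT * 0.19) * rng.normal(size=v.shape) * 0.1
            e_wca, e_bond, e_coul, f = ff.compute(x)
            v += 0.5 * dts * f
            step += 1

        for phase_steps, production in ((n_equil, False), (n_prod, True)):
            for i in range(phase_steps):
                if use_nh:
                    v = nhc.half_step(v, dt)
                    v += 0.5 * dt * f
                    dx = v * dt
                    _guard_displacement(dx, guard, step)
                    x += dx
                    wrap(x)
                    e_wca, e_bond, e_coul, f = ff.compute(x)
                    v += 0.5 * dt * f
                    v = nhc.half_step(v, dt)
                elif use_lan:
                    v += 0.5 * dt * f
                    dx0 = v * (0.5 * dt)
                    x += dx0
                    v = c1 * v + c2 * rng.normal(size=v.shape)
                    dx1 = v * (0.5 * dt)
                    _guard_displacement(dx0 + dx1, guard, step)
                    x += dx1
                    wrap(x)
                    e_wca, e_bond, e_coul, f = ff.compute(x)
                    v += 0.5 * dt * f
                else:  # NVE
                    v += 0.5 * dt * f
                    dx = v * dt
                    _guard_displacement(dx, guard, step)
                    x += dx
                    wrap(x)
                    e_wca, e_bond, e_coul, f = ff.compute(x)
                    v += 0.5 * dt * f

                step += 1
                if not np.isfinite(e_wca + e_bond + e_coul):
                    raise InstabilityError("non-finite energy", step=step)

                if production and i % sample_stride == 0:
                    frames.append(x.copy())
                    times.append((i + 1) * dt)
                if step % log_stride == 0:
                    ke = 0.5 * float((v ** 2).sum())
                    thermo_rows.append({
                        "step": step,
                        "time": step * dt,
                        "T": 2.0 * ke / n_dof,
                        "E_wca": e_wca, "E_bond": e_bond, "E_coul": e_coul,
                        "E_pot": e_wca + e_bond + e_coul,
                        "E_kin": ke,
                        "E_total": e_wca + e_bond + e_coul + ke,
                    })
    except InstabilityError as err:
        err.state = snapshot()
        raise

    final = snapshot()
    thermo = pd.DataFrame(thermo_rows)
    meta = dict(state.metadata)
    meta.update({
        "protocol": {
            "kT": protocol.kT, "dt": protocol.dt,
            "t_equil": protocol.t_equil, "t_prod": protocol.t_prod,
            "sample_every": protocol.sample_every,
            "thermostat": protocol.thermostat,
            "thermostat_coupling": protocol.thermostat_coupling,
            "seed": protocol.seed,
        },
        "total_steps": total_steps,
    })
    traj = Trajectory(
        positions=np.asarray(frames) if frames else np.empty((0, state.n, 3)),
        times=np.asarray(times),
        species=state.species.copy(),
        charge=state.charge.copy(),
        bonds=state.bonds.copy(),
        box_length=L,
        metadata=meta,
        thermo=thermo,
        final_state=final,
    )
    return traj
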