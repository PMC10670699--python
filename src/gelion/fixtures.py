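"""Synthetic configurations with known ground truth for analysis validation.

These generators build trajectories/states whose partition coefficients,
scaling exponents or electrostatic energies are known by construction, so
every analysis operation is testable without running any dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .errors import ConfigurationError
from .model import CATION_1, CATION_2, COION, GEL_SEGMENT, SystemState


@dataclass(frozen=True)
class PartitionFixtureSpec:
    """Ions at density Q_target*rho_bulk inside a ball of radius r_gel,
    rho_bulk outside; frames are i.i.d. redraws."""

    Q_targets: dict                 # species code -> Q
    r_gel: float = 8.0
    L: float = 40.0
    n_ions: int = 600               # per species
    n_frames: int = 50
    n_gel_beads: int = 300
    seed: int = 0
    include_dummy_gel: bool = True

    def __post_init__(self):
        if any(q <= 0 for q in self.Q_targets.values()):
            raise ConfigurationError("Q_target must be positive")
        if not self.r_gel < self.L / 4:
            raise ConfigurationError("need r_gel < L/4")
        v_in = 4.0 / 3.0 * math.pi * self.r_gel ** 3
        v_out = self.L ** 3 - v_in
        for q in self.Q_targets.values():
            n_in = self.n_ions * q * v_in / (q * v_in + v_out)
            if min(n_in, self.n_ions - n_in) * self.n_frames < 50:
                raise ConfigurationError(
                    "counts too small for stable plateaus (< 50 per region)")


def _uniform_in_ball(rng, n, radius, center):
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= radius * rng.random(n)[:, None] ** (1.0 / 3.0)
    return pts + center


def _uniform_outside_ball(rng, n, radius, L, center):
    out = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.random((2 * (n - got) + 16, 3)) * L
        d = cand - center
        d -= L * np.round(d / L)
        keep = cand[(d * d).sum(axis=1) > radius ** 2]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def make_partition_fixture(spec: PartitionFixtureSpec) -> Trajectory:
    """Trajectory with constructed plateau ratios Q per ion species.

    A static dummy gel (uniform ball of beads, Rg = r_gel*sqrt(3/5)) defines
    the COM; per species, round(N*Q*Vin/(Q*Vin+Vout)) ions are redrawn
    uniformly inside the ball each frame and the rest uniformly outside.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    center = np.full(3, L / 2.0)
    v_in = 4.0 / 3.0 * math.pi * spec.r_gel ** 3
    v_out = L ** 3 - v_in

    species = []
    charges = []
    if spec.include_dummy_gel:
        species += [GEL_SEGMENT] * spec.n_gel_beads
        charges += [0] * spec.n_gel_beads
    plan = []  # (code, n_in, n_out)
    for code, q in spec.Q_targets.items():
        n_in = int(round(spec.n_ions * q * v_in / (q * v_in + v_out)))
        plan.append((code, n_in, spec.n_ions - n_in))
        species += [code] * spec.n_ions
        charges += [{CATION_1: 1, CATION_2: 2, COION: -1}.get(code, 0)] * spec.n_ions

    gel_pos = _uniform_in_ball(rng, spec.n_gel_beads, spec.r_gel, center) \
        if spec.include_dummy_gel else np.empty((0, 3))

    frames = []
    for _ in range(spec.n_frames):
        parts = [gel_pos]
        for code, n_in, n_out in plan:
            parts.append(_uniform_in_ball(rng, n_in, spec.r_gel, center))
            parts.append(_uniform_outside_ball(rng, n_out, spec.r_gel, L, center))
        frames.append(np.vstack(parts))

    truth = {code: {"Q": q,
                    "rho_bulk": spec.n_ions / (q * v_in + v_out)}
             for code, q in spec.Q_targets.items()}
    return Trajectory(
        positions=np.asarray(frames),
        times=np.arange(spec.n_frames, dtype=float),
        species=np.asarray(species, dtype=np.int64),
        charge=np.asarray(charges, dtype=np.int64),
        bonds=np.empty((0, 2), dtype=np.int64),
        box_length=L,
        metadata={"fixture": "partition", "ground_truth": truth,
                  "r_gel": spec.r_gel, "seed": spec.seed},
    )


def make_scaling_table(kappa: float, mu: float, noise_cv: float,
                       phi_values, csalt_values, seed: int = 0,
                       logA: float = 0.0, n_reps: int = 1) -> pd.DataFrame:
    """Synthetic (Q, phi, csalt) rows obeying Q = A*phi^kappa*csalt^-mu.

    Lognormal multiplicative noise with coefficient of variation
    ``noise_cv``; ``noise_cv = 0`` gives the exact power law.
    """
    if noise_cv < 0:
        raise ConfigurationError("noise_cv must be non-negative")
    phi_values = np.atleast_1d(np.asarray(phi_values, dtype=float))
    csalt_values = np.atleast_1d(np.asarray(csalt_values, dtype=float))
    if len(phi_values) * len(csalt_values) * n_reps < 2:
        raise ConfigurationError("grid must contain at least 2 points")
    rng = np.random.default_rng(seed)
    sig = math.sqrt(math.log(1.0 + noise_cv ** 2))
    rows = []
    for _ in range(n_reps):
        for phi in phi_values:
            for c in csalt_values:
                q = math.exp(logA) * phi ** kappa * c ** (-mu)
                if noise_cv > 0:
                    q *= math.exp(rng.normal(-0.5 * sig * sig, sig))
                rows.append({"Q": q, "phi": phi, "csalt": c})
    return pd.DataFrame(rows)


def make_lattice_charges(kind: str, a: float, L: float,
                         separation: float | None = None) -> SystemState:
    """Neutral reference charge configurations for electrostatics oracles.

    ``dimer``: +1/-1 pair at ``separation`` (default a) on the x-axis.
    ``rocksalt``: alternating +-1 on a full cubic lattice of spacing a
    filling the periodic box (L must be an even multiple of a).
    """
    if a >= L:
        raise ConfigurationError("lattice spacing a must be < L")
    if kind == "dimer":
        r = separation if separation is not None else a
        pos = np.array([[L / 2 - r / 2, L / 2, L / 2],
                        [L / 2 + r / 2, L / 2, L / 2]])
        charge = np.array([1, -1], dtype=np.int64)
    elif kind == "rocksalt":
        n = int(round(L / a))
        if abs(n * a - L) > 1e-9 or n % 2:
            raise ConfigurationError(
                "rocksalt requires L an even integer multiple of a")
        grid = np.arange(n)
        ii, jj, kk = np.meshgrid(grid, grid, grid, indexing="ij")
        pos = a * np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
        charge = np.where((ii + jj + kk).reshape(-1) % 2 == 0, 1, -1).astype(np.int64)
    else:
        raise ConfigurationError(f"unknown lattice kind {kind!r}")
    return SystemState(
        positions=pos,
        velocities=np.zeros_like(pos),
        charge=charge,
        species=np.where(charge > 0, CATION_1, COION).astype(np.int64),
        bonds=np.empty((0, 2), dtype=np.int64),
        box_length=float(L),
        metadata={"fixture": f"lattice-{kind}", "a": a},
    )
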