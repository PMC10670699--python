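"""Force field: WCA excluded volume, stiff harmonic bonds, Coulomb electrostatics.

Two electrostatics backends are provided behind the same interface:

* ``"ewald"`` — smooth Ewald summation (reference; accuracy-controlled),
* ``"dsf"``  — damped-shifted-force truncation (approximate, cheap; used
  for scaled-down production dynamics).

All energies are reduced (epsilon = kT = 1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ConfigurationError, GelionError, NeutralityError
from .ewald import ewald_energy_forces
from .model import SystemState

R_MIN_WCA = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class ForceFieldParams:
    """Interaction parameters in reduced units."""

    epsilon: float = 1.0
    sigma: float = 1.0
    lB: float = 2.1
    k_spring: float = 1000.0
    l0: float = 0.99
    coulomb_accuracy: float = 1e-4
    r_cut_real: float | None = None      # None -> 0.49*L at evaluation time
    coulomb_method: str = "ewald"        # "ewald" | "dsf"
    dsf_alpha: float | None = None       # None -> 3/r_cut
    neighbor_skin: float = 0.6

    def __post_init__(self):
        for name in ("epsilon", "sigma", "k_spring", "l0", "neighbor_skin"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.lB < 0:
            raise ConfigurationError("lB must be non-negative")
        if not (0 < self.coulomb_accuracy <= 1e-2):
            raise ConfigurationError("coulomb_accuracy must be in (0, 1e-2]")
        if self.coulomb_method not in ("ewald", "dsf"):
            raise ConfigurationError(
                f"unknown coulomb_method {self.coulomb_method!r}")

    @property
    def r_min(self) -> float:
        return R_MIN_WCA * self.sigma


# ---------------------------------------------------------------------------
# Scalar pair terms (spec'd single-pair forms; vectorised over r)
# ---------------------------------------------------------------------------

def wca_energy(r, params: ForceFieldParams = ForceFieldParams()):
    """WCA energy and force magnitude at separation r.

    V = 4*eps*[(sig/r)^12 - (sig/r)^6] + eps for r <= 2^(1/6) sig, else 0;
    both V and F are continuous at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    eps, sig = params.epsilon, params.sigma
    inside = r <= params.r_min
    s6 = np.where(inside, (sig / r) ** 6, 0.0)
    e = np.where(inside, 4.0 * eps * (s6 * s6 - s6) + eps, 0.0)
    f = np.where(inside, 24.0 * eps * (2.0 * s6 * s6 - s6) / r, 0.0)
    if np.isscalar(r) or r.ndim == 0:
        return float(e), float(f)
    return e, f


def bond_energy(r, params: ForceFieldParams = ForceFieldParams()):
    """Stiff harmonic spring V = k (r - l0)^2."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    e = params.k_spring * (r - params.l0) ** 2
    return float(e) if e.ndim == 0 else e


def coulomb_pair_energy(r, qi, qj, lB: float):
    """Bare Coulomb pair energy lB*qi*qj/r in kT (no periodic images)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    e = lB * qi * qj / r
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# Full-system evaluation
# ---------------------------------------------------------------------------

class ForceField:
    """Evaluates total energies/forces for a fixed topology.

    Short-range WCA and DSF-Coulomb terms run over a Verlet pair list that
    is rebuilt when any particle has moved more than half the skin; the
    Ewald backend adds its real-space part over the same O(N^2) routine
    internally.
    """

    def __init__(self, state: SystemState, params: ForceFieldParams):
        self.params = params
        self.L = state.box_length
        self.charges = state.charge.astype(np.float64)
        self.bonds = np.ascontiguousarray(state.bonds, dtype=np.int64)
        if self.bonds.size == 0:
            self.bonds = self.bonds.reshape(0, 2)
        self.n = state.n

        if params.r_cut_real is not None:
            if params.r_cut_real >= self.L / 2:
                raise ConfigurationError("r_cut_real must be < L/2")
            self.r_cut = params.r_cut_real
        elif params.coulomb_method == "dsf":
            self.r_cut = min(8.0 * params.sigma, 0.45 * self.L)
        else:
            self.r_cut = 0.49 * self.L
        self.dsf_alpha = (params.dsf_alpha if params.dsf_alpha is not None
                          else 3.0 / self.r_cut)

        self.has_charges = bool(np.any(self.charges != 0.0))
        if params.coulomb_method == "dsf" and self.has_charges:
            self._list_cut = max(params.r_min * params.sigma, self.r_cut)
        else:
            self._list_cut = params.r_min * params.sigma
        self._pairs = None
        self._ref_pos = None

    # -- neighbour list -----------------------------------------------------

    def _pair_list(self, pos: np.ndarray):
        skin = self.params.neighbor_skin
        if self._pairs is not None:
            moved = _kernels.max_sq_displacement(pos, self._ref_pos, self.L)
            if moved < (skin / 2.0) ** 2:
                return self._pairs
        self._pairs = _kernels.build_pairs(pos, self.L, self._list_cut + skin)
        self._ref_pos = pos.copy()
        return self._pairs

    # -- evaluation ---------------------------------------------------------

    def compute(self, positions: np.ndarray):
        """Return (e_wca, e_bond, e_coul, forces) for the given positions."""
        pos = np.ascontiguousarray(positions, dtype=np.float64)
        forces = np.zeros_like(pos)
        pi, pj = self._pair_list(pos)

        if self.params.coulomb_method == "dsf" and self.has_charges:
            lB_eff, rc_coul = self.params.lB, self.r_cut
        else:
            lB_eff, rc_coul = 0.0, 1e-10  # Coulomb skipped in the kernel

        e_wca, e_coul, ov_i, ov_j = _kernels.pair_forces(
            pos, self.charges, self.L, pi, pj, lB_eff, self.dsf_alpha,
            rc_coul, self.params.r_min * self.params.sigma, forces)
        if ov_i >= 0:
            raise GelionError(
                f"overlapping particles {ov_i} and {ov_j} (r < 1e-6 sigma)")
        e_wca *= self.params.epsilon

        e_bond = 0.0
        if len(self.bonds):
            e_bond = _kernels.bond_forces(
                pos, self.bonds, self.L, self.params.k_spring,
                self.params.l0, forces)

        if self.params.coulomb_method == "ewald" and self.has_charges:
            if abs(self.charges.sum()) > 1e-9:
                raise NeutralityError(
                    "Ewald electrostatics requires an electroneutral system")
            e_coul, f_coul = ewald_energy_forces(
                pos, self.charges, self.L, self.params.lB,
                accuracy=self.params.coulomb_accuracy, r_cut=self.r_cut)
            forces += f_coul

        return e_wca, e_bond, e_coul, forces


def total_energy_forces(state: SystemState, params: ForceFieldParams):
    """One-shot evaluation: (E_wca, E_bond, E_coul, forces)."""
    return ForceField(state, params).compute(state.positions)
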