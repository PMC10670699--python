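"""Construction of the finite star-polymer gel network and ionic environment.

The gel is a "perfect compact" network: regular star polymers (one core bead
plus ``f`` arms of ``M`` beads) placed on a cubic lattice with the free ends
of neighbouring stars bonded together.  Every gel bead carries an integer
charge (default -1); monovalent counterions neutralise the network, and
monovalent/divalent salt is added on top at prescribed mmol/L concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import deque

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ConnectivityError, NeutralityError, PlacementError
from .units import DEFAULT_C0

# Species codes double as LAMMPS atom types.
GEL_SEGMENT = 1
GEL_CORE = 2
CATION_1 = 3
CATION_2 = 4
COION = 5

SPECIES_NAMES = {
    GEL_SEGMENT: "gel_segment",
    GEL_CORE: "gel_core",
    CATION_1: "cation_1",
    CATION_2: "cation_2",
    COION: "coion",
}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}

GEL_SPECIES = (GEL_SEGMENT, GEL_CORE)

_AXES = {
    "+x": np.array([1, 0, 0]), "-x": np.array([-1, 0, 0]),
    "+y": np.array([0, 1, 0]), "-y": np.array([0, -1, 0]),
    "+z": np.array([0, 0, 1]), "-z": np.array([0, 0, -1]),
}

# zigzag plane per arm axis (x arms wiggle in y, y in z, z in x)
_PERP = {
    "x": np.array([0.0, 1.0, 0.0]),
    "y": np.array([0.0, 0.0, 1.0]),
    "z": np.array([1.0, 0.0, 0.0]),
}


@dataclass(frozen=True)
class GelSpec:
    """Architecture of the gel network.

    nb : branch points (stars) per lattice direction.
    f : arms per star.
    m : beads per arm.
    segment_valence : integer charge on every gel bead (core included).
    lattice_constant : star-to-star spacing in sigma; ``None`` selects
        (2*m*slack + 1) * arm_bond, which leaves a bridging gap of one
        arm_bond between the arms.
    arm_bond : bead spacing along an arm (the spring rest length).
    slack : axial extension of arms relative to full stretch; values < 1
        lay the arm beads in a constant-bond-length zigzag, giving the
        network headroom to swell.
    """

    nb: int
    f: int
    m: int
    segment_valence: int = -1
    lattice_constant: float | None = None
    arm_bond: float = 0.99
    slack: float = 1.0

    def __post_init__(self):
        if self.nb < 1 or self.f < 1 or self.m < 1:
            raise ConfigurationError("nb, f and m must all be >= 1")
        if self.segment_valence == 0:
            raise ConfigurationError("segment_valence must be non-zero")
        if self.f > 6:
            raise ConnectivityError(
                f"f={self.f} arms exceed the 6 available cubic-lattice neighbors")
        if self.arm_bond <= 0:
            raise ConfigurationError("arm_bond must be positive")
        if not 0.5 < self.slack <= 1.0:
            raise ConfigurationError("slack must be in (0.5, 1]")

    @property
    def star_mass(self) -> int:
        """Beads per star, Mw = f*M + 1."""
        return self.f * self.m + 1

    @property
    def gel_mass(self) -> int:
        """Total gel beads, Mw_gel = Nb^3 * Mw."""
        return self.nb ** 3 * self.star_mass

    @property
    def spacing(self) -> float:
        if self.lattice_constant is not None:
            return self.lattice_constant
        return (2 * self.m * self.slack + 1) * self.arm_bond


@dataclass(frozen=True)
class SaltSpec:
    """Ionic composition of the bath in real (mmol/L) units.

    Cation valences are fixed at +1 (monovalent) and +2 (divalent); all
    coions are monovalent anions.  ``c0`` converts reduced number density
    (sigma^-3) to mmol/L.
    """

    c_mono: float = 0.0
    c_div: float = 0.0
    c0: float = DEFAULT_C0

    def __post_init__(self):
        if self.c_mono < 0 or self.c_div < 0:
            raise ConfigurationError("salt concentrations must be non-negative")
        if self.c0 <= 0:
            raise ConfigurationError("c0 must be positive")


@dataclass
class SystemState:
    """Single source of truth for a simulated system.

    positions are wrapped into the half-open box [0, L)^3; charges are
    integer valences; species uses the codes above; bonds is an (n_bonds, 2)
    integer array, each unordered pair listed once.
    """

    positions: np.ndarray
    velocities: np.ndarray
    charge: np.ndarray
    species: np.ndarray
    bonds: np.ndarray
    box_length: float
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def volume(self) -> float:
        return self.box_length ** 3

    @property
    def net_charge(self) -> int:
        return int(self.charge.sum())

    @property
    def gel_mask(self) -> np.ndarray:
        return np.isin(self.species, GEL_SPECIES)

    def wrap(self) -> None:
        L = self.box_length
        self.positions -= L * np.floor(self.positions / L)

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            charge=self.charge.copy(),
            species=self.species.copy(),
            bonds=self.bonds.copy(),
            box_length=self.box_length,
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# Connectivity maps
# ---------------------------------------------------------------------------

def arm_directions(f: int, site: tuple[int, int, int]) -> list[str]:
    """Arm directions for the star at lattice ``site`` under the default map.

    The default map is an alternating, layer-parity scheme that pairs every
    interior free end with a neighbouring star's free end:

    * f=1: z-dimers by site parity
    * f=2: +-z chains
    * f=3: +-z chains plus one alternating horizontal arm
    * f=4: +-z always; +-x in even-k layers, +-y in odd-k layers
    * f=5: +-x, +-y always; one z arm by site parity
    * f=6: all six lattice directions
    """
    i, j, k = site
    if f == 1:
        return ["+z"] if (i + j + k) % 2 == 0 else ["-z"]
    if f == 2:
        return ["+z", "-z"]
    if f == 3:
        horiz = ("+x" if i % 2 == 0 else "-x") if k % 2 == 0 else \
                ("+y" if j % 2 == 0 else "-y")
        return ["+z", "-z", horiz]
    if f == 4:
        return ["+z", "-z"] + (["+x", "-x"] if k % 2 == 0 else ["+y", "-y"])
    if f == 5:
        zarm = "+z" if (i + j + k) % 2 == 0 else "-z"
        return ["+x", "-x", "+y", "-y", zarm]
    if f == 6:
        return ["+x", "-x", "+y", "-y", "+z", "-z"]
    raise ConnectivityError(f"no connectivity map for f={f}")


def connectivity_description(f: int) -> dict:
    """Serializable description of the default connectivity map."""
    rules = {
        1: "z-dimer: +z if (i+j+k) even else -z",
        2: "z-chain: +z,-z",
        3: "z-chain plus one alternating horizontal arm "
           "(x in even-k layers keyed on i parity, y in odd-k layers keyed on j parity)",
        4: "alternating: +z,-z always; +x,-x in even-k layers, +y,-y in odd-k layers",
        5: "+x,-x,+y,-y always; single z arm by (i+j+k) parity",
        6: "all six lattice directions",
    }
    return {"scheme": f"default-f{f}", "rule": rules.get(f, "n/a"), "f": f}


def _opposite(d: str) -> str:
    return ("-" if d[0] == "+" else "+") + d[1]


# ---------------------------------------------------------------------------
# Gel construction
# ---------------------------------------------------------------------------

def default_box_length(spec: GelSpec) -> float:
    """Default box: 2.5x the swollen-gel diameter estimate 2*a*Nb."""
    return 2.5 * 2.0 * spec.spacing * spec.nb


def build_gel(spec: GelSpec, box_length: float | None = None,
              check_connectivity: bool = True) -> SystemState:
    """Build the gel network (beads + bonds only; no ions).

    Stars sit on an ``nb``^3 cubic lattice centred in the box; arms are laid
    out straight along their lattice directions with bead spacing
    ``spec.arm_bond``; free ends of adjacent stars are bridged according to
    the connectivity map.  Initial bond lengths above 1.5 sigma (or
    non-positive bridging gaps) are rejected.
    """
    a = spec.spacing
    b = spec.arm_bond
    s_ax = spec.slack * b                      # axial bead spacing along the arm
    h_zig = math.sqrt(b * b - s_ax * s_ax) / 2.0  # lateral zigzag amplitude
    L = float(box_length) if box_length is not None else default_box_length(spec)

    bridge_len = a - 2 * spec.m * s_ax
    if spec.nb > 1:
        if bridge_len <= 0.25:
            raise ConfigurationError(
                f"lattice_constant={a:.3f} leaves bridging gap {bridge_len:.3f} sigma; "
                "arms would overlap (need > 0.25 sigma)")
        if bridge_len > 1.5:
            raise ConfigurationError(
                f"lattice_constant={a:.3f} leaves bridging gap {bridge_len:.3f} sigma "
                "> 1.5 sigma; initial bridge bonds too long")
    if b > 1.5:
        raise ConfigurationError("arm_bond > 1.5 sigma")

    extent = a * (spec.nb - 1) + 2 * (spec.m * b + 1.0)
    if extent > L - 2.0:
        raise ConfigurationError(
            f"gel extent {extent:.1f} sigma does not fit in box L={L:.1f}")

    offset = L / 2.0 - a * (spec.nb - 1) / 2.0

    positions = []
    bonds = []
    free_end = {}  # (site, direction) -> bead index of the arm's free end

    for i in range(spec.nb):
        for j in range(spec.nb):
            for k in range(spec.nb):
                site = (i, j, k)
                core = offset + a * np.array(site, dtype=float)
                core_idx = len(positions)
                positions.append(core)
                dirs = arm_directions(spec.f, site)
                if len(dirs) != spec.f:
                    raise ConnectivityError(
                        f"connectivity map yields {len(dirs)} arms, expected f={spec.f}")
                for d in dirs:
                    unit = _AXES[d].astype(float)
                    perp = _PERP[d[1]]
                    prev = core_idx
                    for seg in range(1, spec.m + 1):
                        idx = len(positions)
                        lateral = h_zig * (1.0 if seg % 2 else -1.0)
                        positions.append(core + unit * (s_ax * seg) + perp * lateral)
                        bonds.append((prev, idx))
                        prev = idx
                    free_end[(site, d)] = prev

    # Bridge free ends of adjacent stars (positive directions only, once each).
    n_bridges = 0
    for (site, d), end_idx in list(free_end.items()):
        if d[0] != "+":
            continue
        i, j, k = site
        di, dj, dk = _AXES[d]
        nsite = (i + di, j + dj, k + dk)
        if not all(0 <= c < spec.nb for c in nsite):
            continue
        partner = free_end.get((nsite, _opposite(d)))
        if partner is not None:
            bonds.append((end_idx, partner))
            n_bridges += 1

    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    assert n == spec.gel_mass

    species = np.full(n, GEL_SEGMENT, dtype=np.int64)
    star_stride = spec.star_mass
    species[::star_stride] = GEL_CORE

    state = SystemState(
        positions=positions,
        velocities=np.zeros_like(positions),
        charge=np.full(n, spec.segment_valence, dtype=np.int64),
        species=species,
        bonds=np.asarray(bonds, dtype=np.int64),
        box_length=L,
        metadata={
            "gel_spec": {"nb": spec.nb, "f": spec.f, "m": spec.m,
                         "segment_valence": spec.segment_valence,
                         "lattice_constant": a, "arm_bond": b},
            "connectivity": connectivity_description(spec.f),
            "n_gel": n,
            "n_bridges": n_bridges,
            "n_counterions": 0,
            "n_salt_mono_pairs": 0,
            "n_salt_div": 0,
        },
    )
    state.wrap()

    if check_connectivity and not gel_is_connected(state):
        raise ConnectivityError(
            f"gel bond graph is disconnected for nb={spec.nb}, f={spec.f}: "
            "the connectivity map cannot join all stars with this few arms")
    return state


def gel_is_connected(state: SystemState) -> bool:
    """True if the gel beads form a single bonded component."""
    gel_idx = np.flatnonzero(state.gel_mask)
    if len(gel_idx) <= 1:
        return True
    adj = {int(i): [] for i in gel_idx}
    for p, q in state.bonds:
        adj[int(p)].append(int(q))
        adj[int(q)].append(int(p))
    seen = {int(gel_idx[0])}
    queue = deque(seen)
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return len(seen) == len(gel_idx)


# ---------------------------------------------------------------------------
# Ions
# ---------------------------------------------------------------------------

def salt_ion_counts(salt: SaltSpec, volume: float) -> tuple[int, int]:
    """Integer counts (monovalent pairs, divalent cations) for a target SaltSpec.

    Counts invert csalt = c0*(rho_cation + rho_matching_coion)/2 over the full
    box: a monovalent pair contributes one cation and one coion
    (c = c0*n1/V), a divalent cation comes with two coions
    (c = 1.5*c0*n2/V).
    """
    n_mono = int(round(salt.c_mono * volume / salt.c0))
    n_div = int(round(2.0 * salt.c_div * volume / (3.0 * salt.c0)))
    return n_mono, n_div


def add_ions(state: SystemState, salt: SaltSpec, seed: int,
             min_dist: float = 0.9, max_tries_per_ion: int = 2000) -> SystemState:
    """Add neutralising counterions plus salt at the requested concentrations.

    Counterions are monovalent cations neutralising the gel exactly; salt is
    added as (+1/-1) pairs and (+2/2x-1) triplets with integer counts from
    :func:`salt_ion_counts`.  Positions are drawn uniformly, rejecting any
    candidate within ``min_dist`` of an already placed particle.
    """
    gel_charge = state.net_charge
    if gel_charge > 0:
        raise NeutralityError(
            "gel carries positive net charge; monovalent cation counterions "
            "cannot neutralise it")
    n_counter = -gel_charge

    n_mono, n_div = salt_ion_counts(salt, state.volume)
    n_coion = n_mono + 2 * n_div

    species_new = (
        [CATION_1] * n_counter + [CATION_1] * n_mono +
        [CATION_2] * n_div + [COION] * n_coion
    )
    charge_new = (
        [1] * n_counter + [1] * n_mono + [2] * n_div + [-1] * n_coion
    )
    n_add = len(species_new)
    if n_add == 0:
        return state.copy()

    rng = np.random.default_rng(seed)
    L = state.box_length
    placed = state.positions.copy()
    new_pos = np.empty((n_add, 3))
    tree = cKDTree(placed, boxsize=L)
    pending = []  # accepted but not yet in the tree

    for ion in range(n_add):
        for attempt in range(max_tries_per_ion):
            cand = rng.random(3) * L
            if tree.query(cand, k=1)[0] < min_dist:
                continue
            if pending and np.any(
                    _min_image_dist(np.asarray(pending), cand, L) < min_dist):
                continue
            new_pos[ion] = cand
            pending.append(cand)
            break
        else:
            raise PlacementError(
                f"could not place ion {ion + 1}/{n_add} after "
                f"{max_tries_per_ion} attempts (min_dist={min_dist})")
        if len(pending) >= 200:
            placed = np.vstack([placed, np.asarray(pending)])
            tree = cKDTree(placed, boxsize=L)
            pending = []

    out = state.copy()
    out.positions = np.vstack([state.positions, new_pos])
    out.velocities = np.vstack([state.velocities, np.zeros((n_add, 3))])
    out.charge = np.concatenate([state.charge, np.asarray(charge_new, dtype=np.int64)])
    out.species = np.concatenate([state.species, np.asarray(species_new, dtype=np.int64)])
    out.metadata.update({
        "n_counterions": n_counter,
        "n_salt_mono_pairs": n_mono,
        "n_salt_div": n_div,
        "ion_seed": int(seed),
        "c0": salt.c0,
        "salt_spec": {"c_mono": salt.c_mono, "c_div": salt.c_div, "c0": salt.c0},
    })
    if out.net_charge != 0:
        raise NeutralityError(f"assembled system has net charge {out.net_charge}")
    return out


def _min_image_dist(points: np.ndarray, x: np.ndarray, L: float) -> np.ndarray:
    d = points - x
    d -= L * np.round(d / L)
    return np.sqrt((d * d).sum(axis=1))


def salt_concentration(state: SystemState, c0: float | None = None) -> tuple[float, float]:
    """(c_mono, c_div) in mmol/L for an assembled state.

    Gel-neutralising counterions are excluded from salt accounting; each
    valence class is scored as c0*(rho_cation + rho_matching_coion)/2 using
    number densities over the full box.
    """
    if c0 is None:
        c0 = state.metadata.get("c0", DEFAULT_C0)
    V = state.volume
    n_mono = state.metadata.get("n_salt_mono_pairs", 0)
    n_div = state.metadata.get("n_salt_div", 0)
    c_mono = c0 * (n_mono + n_mono) / (2.0 * V)
    c_div = c0 * (n_div + 2 * n_div) / (2.0 * V)
    return c_mono, c_div
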