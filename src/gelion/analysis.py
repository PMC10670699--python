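"""Gel observables and ion-partition statistics.

Implements the measurement chain: unwrap the gel over periodic boundaries,
radius of gyration Rg and internal volume fraction phi, the charged-particle
pair correlation gq(r) about the gel centre of mass, plateau-ratio partition
coefficients Qi, and the power-law fit Qi ~ phi^kappa * csalt^-mu.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import quad

from .errors import AnalysisError, ConfigurationError, FitRefusedError
from .model import GEL_SPECIES, SPECIES_CODES, SPECIES_NAMES
from .dynamics import Trajectory


# ---------------------------------------------------------------------------
# Unwrapping and gel geometry
# ---------------------------------------------------------------------------

def unwrap_gel(positions: np.ndarray, bonds: np.ndarray, box_length: float,
               gel_indices: np.ndarray | None = None) -> np.ndarray:
    """Unwrap gel beads across periodic boundaries via their bond graph.

    Breadth-first traversal from the first gel bead, choosing the
    minimum-image offset along each bond.  Returns coordinates for
    ``gel_indices`` (default: all particles appearing in ``bonds``); raises
    if the bond graph does not connect them.
    """
    L = box_length
    if gel_indices is None:
        if len(bonds) == 0:
            raise AnalysisError("no bonds: cannot unwrap")
        gel_indices = np.unique(bonds)
    gel_indices = np.asarray(gel_indices)
    n_gel = len(gel_indices)
    if n_gel == 1:
        return positions[gel_indices].astype(float)

    local = {int(g): i for i, g in enumerate(gel_indices)}
    adj = [[] for _ in range(n_gel)]
    for p, q in bonds:
        p, q = int(p), int(q)
        if p in local and q in local:
            adj[local[p]].append(local[q])
            adj[local[q]].append(local[p])

    wrapped = positions[gel_indices].astype(float)
    out = np.full((n_gel, 3), np.nan)
    out[0] = wrapped[0]
    seen = np.zeros(n_gel, dtype=bool)
    seen[0] = True
    queue = deque([0])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if not seen[v]:
                d = wrapped[v] - wrapped[u]
                d -= L * np.round(d / L)
                out[v] = out[u] + d
                seen[v] = True
                queue.append(v)
    if not seen.all():
        raise AnalysisError(
            f"gel bond graph is disconnected ({int(seen.sum())}/{n_gel} reachable)")
    return out


def _frame_gel_coords(traj: Trajectory, frame: int,
                      gel_idx: np.ndarray) -> np.ndarray:
    """Unwrapped gel coordinates for one frame (raw coords if no bonds)."""
    pos = traj.positions[frame]
    if len(traj.bonds):
        return unwrap_gel(pos, traj.bonds, traj.box_length, gel_idx)
    return pos[gel_idx].astype(float)


def _rg(coords: np.ndarray) -> float:
    com = coords.mean(axis=0)
    return float(np.sqrt(((coords - com) ** 2).sum(axis=1).mean()))


@dataclass
class GelObservables:
    rg: float
    rg_se: float
    com: np.ndarray               # per-frame COM, wrapped, (n_frames, 3)
    phi: float
    phi_se: float
    r_interior: float
    rg_series: np.ndarray = field(repr=False, default=None)


def blocked_se(series: np.ndarray, block: int | None = None) -> float:
    """Standard error of the mean with block averaging.

    Default block length is ~10 integrated autocorrelation times estimated
    from the series itself (capped at a quarter of the series).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        return float("nan")
    if block is None:
        block = max(1, int(math.ceil(10.0 * integrated_autocorr_time(x))))
    block = min(block, max(1, n // 4))
    nb = n // block
    if nb < 2:
        return float(x.std(ddof=1) / math.sqrt(n))
    means = x[:nb * block].reshape(nb, block).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(nb))


def integrated_autocorr_time(x: np.ndarray, max_lag: int | None = None) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or x.std() == 0:
        return 1.0
    xc = x - x.mean()
    if max_lag is None:
        max_lag = min(n // 4, 200)
    var = float(xc @ xc) / n
    tau = 0.5
    for lag in range(1, max_lag):
        c = float(xc[:-lag] @ xc[lag:]) / n / var
        if c < 0.05:
            break
        tau += c
    return max(2.0 * tau, 1.0)


def gel_rg(traj: Trajectory) -> tuple[float, float]:
    """Mean radius of gyration of the gel over frames, with blocked SE."""
    obs = gel_observables(traj, compute_phi=False)
    return obs.rg, obs.rg_se


def gel_observables(traj: Trajectory, r_factor: float = 0.5,
                    compute_phi: bool = True) -> GelObservables:
    """Rg, per-frame COM, internal volume fraction phi and interior radius.

    phi counts gel beads inside a sphere of radius ``r_factor * Rg`` about
    the per-frame COM, each bead contributing a hard-sphere volume
    (pi/6) sigma^3.
    """
    if traj.n_frames == 0:
        raise AnalysisError("empty trajectory")
    gel_idx = np.flatnonzero(np.isin(traj.species, GEL_SPECIES))
    if len(gel_idx) == 0:
        raise AnalysisError("trajectory contains no gel beads")
    L = traj.box_length

    rgs = np.empty(traj.n_frames)
    coms = np.empty((traj.n_frames, 3))
    for fidx in range(traj.n_frames):
        coords = _frame_gel_coords(traj, fidx, gel_idx)
        com = coords.mean(axis=0)
        rgs[fidx] = math.sqrt(((coords - com) ** 2).sum(axis=1).mean())
        coms[fidx] = com - L * np.floor(com / L)

    rg_mean = float(rgs.mean())
    rg_se = blocked_se(rgs)
    r_int = r_factor * rg_mean

    phi = phi_se = float("nan")
    if compute_phi:
        phi_frames = np.empty(traj.n_frames)
        v_int = 4.0 / 3.0 * math.pi * r_int ** 3
        for fidx in range(traj.n_frames):
            d = traj.positions[fidx][gel_idx] - coms[fidx]
            d -= L * np.round(d / L)
            cnt = int((np.einsum("ij,ij->i", d, d) <= r_int ** 2).sum())
            phi_frames[fidx] = cnt * (math.pi / 6.0) / v_int
        if phi_frames.sum() == 0:
            raise AnalysisError("no gel beads inside the interior radius")
        phi = float(phi_frames.mean())
        phi_se = blocked_se(phi_frames)

    return GelObservables(rg=rg_mean, rg_se=rg_se, com=coms, phi=phi,
                          phi_se=phi_se, r_interior=r_int, rg_series=rgs)


# ---------------------------------------------------------------------------
# Sphere-in-box shell volumes
# ---------------------------------------------------------------------------

def sphere_box_volume(r: float, L: float) -> float:
    """Exact volume of a sphere of radius r intersected with a period box.

    The sphere is centred in a cube of side L (equivalently: the volume of
    the minimum-image ball of radius r).  Piecewise exact; the edge term for
    r > L/sqrt(2) uses adaptive quadrature of the closed-form segment area.
    """
    h = L / 2.0
    if r <= 0:
        return 0.0
    if r >= h * math.sqrt(3.0):
        return L ** 3
    v = 4.0 / 3.0 * math.pi * r ** 3
    if r > h:
        cap = math.pi * (r - h) ** 2 * (2.0 * r + h) / 3.0
        v -= 6.0 * cap
    if r > h * math.sqrt(2.0):
        v += 12.0 * _edge_volume(r, h)
    return v


def _edge_volume(r: float, h: float) -> float:
    # volume of sphere(r) intersect {x > h, y > h}
    def seg_area(x):
        R2 = r * r - x * x
        if R2 <= h * h:
            return 0.0
        R = math.sqrt(R2)
        return R2 * math.acos(h / R) - h * math.sqrt(R2 - h * h)

    hi = math.sqrt(r * r - h * h)
    val, _ = quad(seg_area, h, hi, limit=200)
    return val


def shell_volumes(r_edges: np.ndarray, L: float) -> np.ndarray:
    cum = np.array([sphere_box_volume(float(r), L) for r in r_edges])
    return np.diff(cum)


# ---------------------------------------------------------------------------
# gq(r) and partition coefficients
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    """gq(r): local over system-wide concentration of one ion species."""

    species: str
    r_edges: np.ndarray
    r_centers: np.ndarray
    gq: np.ndarray
    counts: np.ndarray            # total counts per bin over all frames
    frame_counts: np.ndarray      # (n_frames, n_bins)
    shell_vols: np.ndarray
    n_frames: int
    n_particles: int
    box_length: float
    mean_density: float


def _species_code(species) -> int:
    if isinstance(species, str):
        if species not in SPECIES_CODES:
            raise ConfigurationError(f"unknown species {species!r}")
        return SPECIES_CODES[species]
    return int(species)


def charged_pair_correlation(traj: Trajectory, species, bin_width: float = 0.5,
                             r_max: float | None = None,
                             gel_obs: GelObservables | None = None) -> RadialProfile:
    """Histogram of species distances from the gel COM, normalised to gq(r).

    Local concentration per spherical shell (shells clipped exactly to the
    periodic box) divided by the system-wide species concentration,
    averaged over frames.
    """
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    code = _species_code(species)
    idx = np.flatnonzero(traj.species == code)
    if len(idx) == 0:
        raise AnalysisError(
            f"species {SPECIES_NAMES.get(code, code)} absent from trajectory")
    if traj.n_frames == 0:
        raise AnalysisError("empty trajectory")
    L = traj.box_length
    if r_max is None:
        r_max = 0.5 * L
    if gel_obs is None:
        gel_obs = gel_observables(traj, compute_phi=False)

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    nbins = len(edges) - 1
    vols = shell_volumes(edges, L)

    frame_counts = np.zeros((traj.n_frames, nbins))
    for fidx in range(traj.n_frames):
        d = traj.positions[fidx][idx] - gel_obs.com[fidx]
        d -= L * np.round(d / L)
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        frame_counts[fidx], _ = np.histogram(r, bins=edges)

    rho_bar = len(idx) / L ** 3
    mean_counts = frame_counts.mean(axis=0)
    gq = mean_counts / vols / rho_bar

    return RadialProfile(
        species=SPECIES_NAMES.get(code, str(code)),
        r_edges=edges,
        r_centers=0.5 * (edges[:-1] + edges[1:]),
        gq=gq,
        counts=frame_counts.sum(axis=0),
        frame_counts=frame_counts,
        shell_vols=vols,
        n_frames=traj.n_frames,
        n_particles=len(idx),
        box_length=L,
        mean_density=rho_bar,
    )


@dataclass(frozen=True)
class WindowPolicy:
    """Plateau windows in units of the gel Rg (bulk upper edge in units of L)."""

    inner_lo: float = 0.0
    inner_hi: float = 0.5          # x Rg
    bulk_lo_rg: float = 1.5        # x Rg ...
    bulk_lo_pad: float = 5.0       # ... or Rg + pad sigma, whichever is larger
    bulk_hi_box: float = 0.45      # x L
    flatness_threshold: float = 0.5
    n_bootstrap: int = 200
    bootstrap_seed: int = 12345


@dataclass
class PartitionResult:
    species: str
    Q: float
    se_Q: float
    c_in: float                    # reduced number density inside
    c_bulk: float
    r_in_window: tuple[float, float]
    r_bulk_window: tuple[float, float]
    flags: list = field(default_factory=list)


def _window_mean(profile: RadialProfile, lo: float, hi: float,
                 frame_counts: np.ndarray | None = None):
    """Volume-weighted mean gq over bins fully inside [lo, hi]."""
    sel = (profile.r_edges[:-1] >= lo) & (profile.r_edges[1:] <= hi)
    if not np.any(sel):
        raise AnalysisError(f"empty plateau window [{lo:.2f}, {hi:.2f}] sigma")
    fc = profile.frame_counts if frame_counts is None else frame_counts
    counts = fc[:, sel].mean(axis=0).sum()
    vol = profile.shell_vols[sel].sum()
    return counts / vol, sel


def partition_coefficients(profile: RadialProfile, gel_obs: GelObservables,
                           policy: WindowPolicy = WindowPolicy()) -> PartitionResult:
    """Qi from the ratio of gq(r) plateau heights inside vs in the bulk.

    Windows default to r in [0, 0.5*Rg] (interior) and
    [max(1.5*Rg, Rg + 5 sigma), 0.45*L] (bulk); the interface region between
    them is excluded.  A relative-slope flatness diagnostic flags windows
    that are not plateau-like; the SE comes from a frame-block bootstrap.
    """
    rg = gel_obs.rg
    L = profile.box_length
    in_lo, in_hi = policy.inner_lo * rg, policy.inner_hi * rg
    bulk_lo = max(policy.bulk_lo_rg * rg, rg + policy.bulk_lo_pad)
    bulk_hi = policy.bulk_hi_box * L
    if bulk_lo >= bulk_hi:
        raise AnalysisError(
            f"bulk window empty: lower edge {bulk_lo:.2f} >= upper {bulk_hi:.2f}")

    c_in, sel_in = _window_mean(profile, in_lo, in_hi)
    c_bulk, sel_bulk = _window_mean(profile, bulk_lo, bulk_hi)
    if c_bulk <= 0:
        raise AnalysisError("no counts in the bulk window; cannot form Qi")

    flags = []
    for name, sel in (("interior", sel_in), ("bulk", sel_bulk)):
        flat = _relative_slope(profile, sel)
        if flat is not None and flat > policy.flatness_threshold:
            flags.append(f"{name} window fails flatness test "
                         f"(relative slope {flat:.2f})")

    if c_in <= 0:
        flags.append("no counts in interior window")
        Q = 0.0
    else:
        Q = c_in / c_bulk

    se = _bootstrap_se_Q(profile, sel_in, sel_bulk, policy)
    return PartitionResult(
        species=profile.species,
        Q=Q, se_Q=se,
        c_in=c_in * profile.mean_density,
        c_bulk=c_bulk * profile.mean_density,
        r_in_window=(in_lo, in_hi),
        r_bulk_window=(bulk_lo, bulk_hi),
        flags=flags,
    )


def _relative_slope(profile: RadialProfile, sel: np.ndarray):
    # volume-weighted so tiny central shells do not dominate the diagnostic
    r = profile.r_centers[sel]
    g = profile.gq[sel]
    w = profile.shell_vols[sel]
    if len(r) < 3 or (g * w).sum() <= 0:
        return None
    slope = np.polyfit(r, g, 1, w=np.sqrt(w))[0]
    gbar = (g * w).sum() / w.sum()
    return abs(slope) * (r[-1] - r[0]) / gbar


def _bootstrap_se_Q(profile: RadialProfile, sel_in, sel_bulk,
                    policy: WindowPolicy) -> float:
    fc = profile.frame_counts
    n = len(fc)
    if n < 4:
        return float("nan")
    block = max(1, min(int(math.ceil(
        10.0 * integrated_autocorr_time(fc[:, sel_in].sum(axis=1)))), n // 4))
    nb = max(1, n // block)
    rng = np.random.default_rng(policy.bootstrap_seed)
    vol_in = profile.shell_vols[sel_in].sum()
    vol_bulk = profile.shell_vols[sel_bulk].sum()
    qs = []
    for _ in range(policy.n_bootstrap):
        starts = rng.integers(0, n - block + 1, size=nb)
        pick = np.concatenate([np.arange(s, s + block) for s in starts])
        ci = fc[pick][:, sel_in].mean(axis=0).sum() / vol_in
        cb = fc[pick][:, sel_bulk].mean(axis=0).sum() / vol_bulk
        if cb > 0:
            qs.append(ci / cb)
    if len(qs) < 10:
        return float("nan")
    return float(np.std(qs, ddof=1))


def internal_volume_fraction(traj: Trajectory,
                             gel_obs: GelObservables | None = None,
                             r_factor: float = 0.5) -> tuple[float, float]:
    """phi inside a sphere of radius ``r_factor*Rg`` about the gel COM."""
    if gel_obs is None or math.isnan(gel_obs.phi):
        gel_obs = gel_observables(traj, r_factor=r_factor)
    return gel_obs.phi, gel_obs.phi_se


def partition_ratio(result2: PartitionResult,
                    result1: PartitionResult) -> tuple[float, float]:
    """Q2/Q1 with first-order error propagation."""
    if result1.Q <= 0 or result2.Q <= 0:
        raise AnalysisError("partition coefficients must be positive for a ratio")
    ratio = result2.Q / result1.Q
    rel = 0.0
    for res in (result1, result2):
        if math.isfinite(res.se_Q):
            rel += (res.se_Q / res.Q) ** 2
    return ratio, ratio * math.sqrt(rel)


# ---------------------------------------------------------------------------
# Scaling-law fit
# ---------------------------------------------------------------------------

@dataclass
class ScalingFit:
    kappa: float
    mu: float
    logA: float
    se_kappa: float
    se_mu: float
    r_squared: float
    n_points: int
    covariates: tuple
    ranges: dict = field(default_factory=dict)


def fit_scaling(table: pd.DataFrame, covariates=("phi", "csalt"),
                q_col: str = "Q", group: str | None = None) -> ScalingFit:
    """OLS on log Q = logA + kappa*log(phi) - mu*log(csalt).

    ``covariates`` selects which exponents are fitted (single-covariate fits
    are allowed); ``group`` optionally adds per-group intercepts (dummy
    coding) so data sets with different prefactors share exponents.
    """
    df = table.copy()
    cols = [q_col] + [c for c in covariates]
    for c in cols:
        if c not in df.columns:
            raise FitRefusedError(f"missing column {c!r}")
        if np.any(~np.isfinite(df[c])) or np.any(df[c] <= 0):
            raise FitRefusedError(f"column {c!r} must be positive and finite")
    if len(df) < 3:
        raise FitRefusedError(f"need >= 3 points, got {len(df)}")

    y = np.log(df[q_col].to_numpy(dtype=float))
    X = pd.DataFrame(index=df.index)
    if "phi" in covariates:
        X["log_phi"] = np.log(df["phi"].to_numpy(dtype=float))
    if "csalt" in covariates:
        X["log_csalt"] = np.log(df["csalt"].to_numpy(dtype=float))
    if group is not None:
        dummies = pd.get_dummies(df[group], prefix="g", drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X)

    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise FitRefusedError("collinear design (degenerate covariate values)")

    res = sm.OLS(y, X).fit()
    kappa = float(res.params.get("log_phi", np.nan))
    mu = float(-res.params.get("log_csalt", np.nan))
    ranges = {c: (float(df[c].min()), float(df[c].max()))
              for c in covariates}
    return ScalingFit(
        kappa=kappa,
        mu=mu,
        logA=float(res.params["const"]),
        se_kappa=float(res.bse.get("log_phi", np.nan)),
        se_mu=float(res.bse.get("log_csalt", np.nan)),
        r_squared=float(res.rsquared),
        n_points=len(df),
        covariates=tuple(covariates),
        ranges=ranges,
    )
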