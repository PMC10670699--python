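"""Smooth Ewald summation for point charges in a cubic periodic box.

Energies are in kT with the Coulomb pair term lB*qi*qj/r; tin-foil
(conducting) boundary conditions, so the system must be electroneutral.
The splitting parameter and reciprocal cutoff are auto-tuned from the
requested relative accuracy using the standard Kolafa–Perram style bounds.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfc

from .errors import ConfigurationError, NeutralityError


def tune_ewald(L: float, r_cut: float, accuracy: float) -> tuple[float, int]:
    """Choose (alpha, kmax_integer) so truncation errors ~ ``accuracy``.

    alpha makes erfc(alpha*r_cut)/r_cut ~ accuracy; the reciprocal-space
    integer cutoff makes exp(-(pi*n/(alpha*L))^2 * ... ) comparably small.
    """
    if not (0 < accuracy <= 1e-2):
        raise ConfigurationError("coulomb_accuracy must be in (0, 1e-2]")
    if r_cut >= L / 2:
        raise ConfigurationError("r_cut_real must be < L/2")
    s = max(np.sqrt(-np.log(accuracy)), 1.0)
    alpha = s / r_cut
    nmax = int(np.ceil(s * alpha * L / np.pi))
    return alpha, max(nmax, 1)


def _kvectors(L: float, nmax: int) -> np.ndarray:
    rng = np.arange(-nmax, nmax + 1)
    n = np.array(np.meshgrid(rng, rng, rng, indexing="ij")).reshape(3, -1).T
    n = n[np.any(n != 0, axis=1)]
    n2 = (n * n).sum(axis=1)
    n = n[n2 <= nmax * nmax]
    return (2.0 * np.pi / L) * n.astype(float)


def ewald_energy_forces(positions: np.ndarray, charges: np.ndarray, L: float,
                        lB: float, accuracy: float = 1e-4,
                        r_cut: float | None = None,
                        check_neutral: bool = True):
    """Total electrostatic energy (kT) and per-particle forces.

    Splits into real-space erfc sum (minimum image, cutoff ``r_cut``,
    default 0.49*L), reciprocal sum over a sphere of k-vectors and the
    self-energy correction.
    """
    q = np.asarray(charges, dtype=float)
    pos = np.asarray(positions, dtype=float)
    n = len(q)
    if check_neutral and abs(q.sum()) > 1e-9:
        raise NeutralityError(
            f"Ewald (tin-foil) requires a neutral system; net charge {q.sum():g}")
    if not np.any(q != 0):
        return 0.0, np.zeros_like(pos)
    if r_cut is None:
        r_cut = 0.49 * L
    alpha, nmax = tune_ewald(L, r_cut, accuracy)
    V = L ** 3

    # Real space, O(N^2) with minimum image.
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r2 = (d * d).sum(axis=-1)
    np.fill_diagonal(r2, np.inf)
    r = np.sqrt(r2)
    mask = r < r_cut
    qq = q[:, None] * q[None, :]
    with np.errstate(invalid="ignore"):
        e_pair = np.where(mask, qq * erfc(alpha * r) / r, 0.0)
    e_real = 0.5 * lB * e_pair.sum()

    fr = np.where(
        mask,
        qq * (erfc(alpha * r) / r2
              + (2.0 * alpha / np.sqrt(np.pi)) * np.exp(-alpha ** 2 * r2) / r) / r,
        0.0)
    f_real = lB * (fr[:, :, None] * d).sum(axis=1)

    # Reciprocal space.
    k = _kvectors(L, nmax)
    k2 = (k * k).sum(axis=1)
    ak = np.exp(-k2 / (4.0 * alpha ** 2)) / k2          # (nk,)
    phase = k @ pos.T                                    # (nk, n)
    eikr = np.exp(1j * phase)
    S = eikr @ q                                         # (nk,)
    e_recip = lB * (2.0 * np.pi / V) * float(np.sum(ak * np.abs(S) ** 2))

    # F_i = -lB * qi * (4*pi/V) * sum_k (k/k2)*exp(-k2/4a2) * Im[e^{-ik.ri} S(k)]
    im = np.imag(np.conj(eikr) * S[:, None])             # (nk, n)
    coeff = ak[:, None] * im                             # (nk, n)
    f_recip = -lB * (4.0 * np.pi / V) * q[None, :] * (k.T @ coeff)
    f_recip = f_recip.T

    e_self = -lB * alpha / np.sqrt(np.pi) * float((q * q).sum())

    return e_real + e_recip + e_self, f_real + f_recip
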