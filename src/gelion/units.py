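"""Reduced-unit conventions and conversion to molar concentrations.

All simulation quantities are expressed in reduced units: length sigma,
energy epsilon, mass m, time tau = sigma*sqrt(m/epsilon), with kT given in
epsilon.  Concentrations in "mmol" are read as mmol/L (mM).

The conversion factor ``c0`` maps a reduced number density (particles per
sigma^3) to mmol/L.  Its default value is derived from the aqueous Bjerrum
length: lB = 0.71 nm corresponds to lB = 2.1 sigma, hence
sigma = 0.71/2.1 nm ~= 0.338 nm.
"""

from __future__ import annotations

from .errors import ConfigurationError

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Aqueous Bjerrum length in nanometres.
BJERRUM_NM_AQUEOUS = 0.71

#: Aqueous Bjerrum length in reduced units (sigma).
BJERRUM_SIGMA_AQUEOUS = 2.1


def sigma_nm(lB_reduced: float = BJERRUM_SIGMA_AQUEOUS,
             lB_nm: float = BJERRUM_NM_AQUEOUS) -> float:
    """Bead diameter sigma in nm implied by mapping ``lB_nm`` onto ``lB_reduced``."""
    if lB_reduced <= 0:
        raise ConfigurationError("lB_reduced must be positive")
    if lB_nm <= 0:
        raise ConfigurationError("lB_nm must be positive")
    return lB_nm / lB_reduced


def c0_from_sigma_nm(sig_nm: float) -> float:
    """mmol/L corresponding to a reduced number density of 1 sigma^-3.

    c0 = 1 / (N_A * sigma^3) expressed in mmol/L, with sigma^3 in litres
    (1 nm^3 = 1e-24 L).
    """
    if sig_nm <= 0:
        raise ConfigurationError("sigma must be positive")
    litres_per_sigma3 = sig_nm ** 3 * 1e-24
    mol_per_L = 1.0 / (N_AVOGADRO * litres_per_sigma3)
    return mol_per_L * 1e3


def default_c0(lB_reduced: float = BJERRUM_SIGMA_AQUEOUS) -> float:
    """Default density-to-mmol/L factor from the aqueous Bjerrum-length mapping.

    ``lB_reduced`` is the reduced Bjerrum length identified with the aqueous
    value of 0.71 nm; sigma follows by division and c0 by unit conversion.
    """
    return c0_from_sigma_nm(sigma_nm(lB_reduced))


#: Default conversion factor (mmol/L per sigma^-3) for sigma ~= 0.338 nm.
DEFAULT_C0 = default_c0()
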