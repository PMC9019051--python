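"""Unit system and physical constants.

Internal units throughout the package:

========  ==========================
energy    kcal/mol
time      fs
angle     rad (degrees only at user-facing interfaces)
mass      amu (Cartesian) / kcal mol^-1 fs^2 rad^-2 (reduced inertias)
length    Angstrom
========  ==========================

All conversions are derived from scipy.constants so there is a single
source of truth.
"""

import math

from scipy import constants as _c

#: thermochemical kcal/mol expressed in J (per particle basis uses N_A below)
_KCAL = _c.calorie * 1000.0

#: 1 J (per particle) in kcal/mol
J_TO_KCALMOL = _c.Avogadro / _KCAL

#: hbar in kcal/mol * fs
HBAR = _c.hbar * J_TO_KCALMOL * 1e15

#: 1 amu * Angstrom^2 expressed in kcal/mol * fs^2  (inertia conversion)
AMU_AA2 = _c.atomic_mass * 1e-20 * J_TO_KCALMOL * 1e30

#: 1 eV in kcal/mol
EV_TO_KCALMOL = _c.electron_volt * J_TO_KCALMOL

#: speed of light in cm/fs
C_CM_FS = _c.c * 100.0 * 1e-15

#: hc in eV * nm (for wavelength <-> energy conversion)
HC_EV_NM = _c.h * _c.c / _c.electron_volt * 1e9


def omega_to_wavenumber(omega_fs: float) -> float:
    """Angular frequency in fs^-1 -> wavenumber in cm^-1."""
    return omega_fs / (2.0 * math.pi * C_CM_FS)


def wavenumber_to_omega(nu_cm: float) -> float:
    """Wavenumber in cm^-1 -> angular frequency in fs^-1."""
    return nu_cm * 2.0 * math.pi * C_CM_FS


def ev_to_nm(e_ev):
    """Photon energy in eV -> wavelength in nm (elementwise)."""
    return HC_EV_NM / e_ev


def nm_to_ev(lam_nm):
    """Wavelength in nm -> photon energy in eV (elementwise)."""
    return HC_EV_NM / lam_nm
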