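"""Broadened absorption/ECD spectra and Kuhn anisotropy factors.

Vertical excitations (energy, dipole strength D, rotatory strength R) are
convolved with Gaussian lineshapes to give relative extinction eps(E),
circular dichroism delta_eps(E) and the dissymmetry spectrum
g(E) = delta_eps/eps.  Proportionality constants are chosen so that for a
single transition g at the band center equals the per-transition Kuhn
factor g = 4R/D; absolute extinction scales are not meaningful (relative
spectra only, as in simulated-spectrum practice).

Two width conventions are supported and interconverted exactly:

* ``fwhm``       : full width at half maximum f
* ``one_over_e`` : half-width w at 1/e of the maximum,
                   lineshape exp(-(dE/w)^2), with f = 2 sqrt(ln 2) w.

A global blue shift (eV) displaces every band center, mimicking the usual
empirical correction of computed excitation energies to experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from prochir.constants import ev_to_nm

__all__ = [
    "TransitionRecord",
    "BroadeningParams",
    "SpectrumGrid",
    "broaden",
    "kuhn_g",
    "g_spectrum",
    "cpl_differential",
    "fwhm_to_one_over_e",
    "one_over_e_to_fwhm",
]

_LN2 = math.log(2.0)


def fwhm_to_one_over_e(fwhm: float) -> float:
    """FWHM -> half-width at 1/e maximum (exact, Gaussian)."""
    return fwhm / (2.0 * math.sqrt(_LN2))


def one_over_e_to_fwhm(w: float) -> float:
    """Half-width at 1/e maximum -> FWHM (exact, Gaussian)."""
    return 2.0 * math.sqrt(_LN2) * w


@dataclass(frozen=True)
class TransitionRecord:
    """One vertical excitation.

    energy_ev > 0; dipole strength >= 0 (a.u., or oscillator strength via
    ``strength_type`` in :func:`broaden`); rotatory strength in a.u. with
    positive = left-CPL-favoring.
    """

    energy_ev: float
    dipole_strength: float
    rotatory_strength: float
    geometry_id: int | None = None

    def __post_init__(self) -> None:
        if not self.energy_ev > 0:
            raise ValueError("excitation energy must be > 0")
        if self.dipole_strength < 0:
            raise ValueError("dipole strength must be >= 0")


@dataclass(frozen=True)
class BroadeningParams:
    """Gaussian lineshape width, its convention, and a global blue shift."""

    width: float = 0.2
    convention: str = "fwhm"  # fwhm | one_over_e
    blue_shift_ev: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("lineshape width must be > 0")
        if self.convention not in ("fwhm", "one_over_e"):
            raise ValueError("width convention must be 'fwhm' or 'one_over_e'")
        if not math.isfinite(self.blue_shift_ev):
            raise ValueError("blue shift must be finite")

    @property
    def one_over_e_halfwidth(self) -> float:
        if self.convention == "one_over_e":
            return self.width
        return fwhm_to_one_over_e(self.width)


@dataclass
class SpectrumGrid:
    """Spectra on a strictly monotonic energy grid.

    g is NaN (undefined, not zero) wherever eps falls below the floor.
    """

    energy_ev: np.ndarray
    eps: np.ndarray
    deps: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_ev, dtype=float)
        if e.ndim != 1 or len(e) < 2 or not (np.all(np.diff(e) > 0)
                                             or np.all(np.diff(e) < 0)):
            raise ValueError("energy grid must be strictly monotonic")

    @property
    def wavelength_nm(self) -> np.ndarray:
        return ev_to_nm(self.energy_ev)


def broaden(transitions, params: BroadeningParams, grid,
            strength_type: str = "dipole") -> SpectrumGrid:
    """Gaussian-broadened eps and delta_eps on ``grid`` (eV).

    eps bands are weighted by dipole strength (or oscillator strength
    converted as D = f/E), delta_eps bands by 4x rotatory strength, with
    identical centers and widths so that band-shape factors cancel in g.
    """
    transitions = list(transitions)
    if not transitions:
        raise ValueError("need at least one transition")
    if strength_type not in ("dipole", "oscillator"):
        raise ValueError("strength_type must be 'dipole' or 'oscillator'")
    e = np.asarray(grid, dtype=float)
    w = params.one_over_e_halfwidth
    eps = np.zeros_like(e)
    deps = np.zeros_like(e)
    for tr in transitions:
        center = tr.energy_ev + params.blue_shift_ev
        band = np.exp(-((e - center) / w) ** 2)
        d = tr.dipole_strength
        if strength_type == "oscillator":
            d = d / tr.energy_ev
        eps += d * band
        deps += 4.0 * tr.rotatory_strength * band
    return SpectrumGrid(energy_ev=e, eps=eps, deps=deps)


def kuhn_g(dipole_strength: float, rotatory_strength: float) -> float:
    """Per-transition Kuhn dissymmetry factor g = 4R/D."""
    if dipole_strength <= 0:
        raise ValueError("dipole strength must be > 0 for a g factor")
    return 4.0 * rotatory_strength / dipole_strength


def g_spectrum(spec: SpectrumGrid, eps_floor_rel: float = 1e-6) -> np.ndarray:
    """Pointwise dissymmetry g = delta_eps/eps.

    NaN wherever eps < eps_floor_rel * max(eps) (g undefined in regions of
    no absorption).
    """
    floor = eps_floor_rel * np.max(spec.eps)
    g = np.full_like(spec.eps, np.nan)
    ok = spec.eps >= max(floor, 0.0)
    if floor <= 0:
        ok = spec.eps > 0
    g[ok] = spec.deps[ok] / spec.eps[ok]
    return g


def cpl_differential(spec: SpectrumGrid, handedness: str,
                     convention: str = "kinetic") -> np.ndarray:
    """Extinction curve seen by one circular polarization.

    kuhn convention:    eps_r = eps (1 - g/2),  eps_l = eps (1 + g/2)
    kinetic convention: eps_r = eps (1 - g),    eps_l = eps (1 + g)

    Either way eps_r + eps_l = 2 eps identically.  Outside the absorption
    support (g undefined) the unpolarized eps is returned.
    """
    if handedness not in ("r", "l"):
        raise ValueError("handedness must be 'r' or 'l'")
    if convention not in ("kuhn", "kinetic"):
        raise ValueError("convention must be 'kuhn' or 'kinetic'")
    g = g_spectrum(spec)
    g = np.where(np.isnan(g), 0.0, g)
    half = 0.5 if convention == "kuhn" else 1.0
    sign = -1.0 if handedness == "r" else 1.0
    return spec.eps * (1.0 + sign * half * g)


def average_spectra(spectra) -> SpectrumGrid:
    """Uniform arithmetic mean of per-geometry spectra on a shared grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    e0 = spectra[0].energy_ev
    for s in spectra[1:]:
        if not np.array_equal(s.energy_ev, e0):
            raise ValueError("spectra must share the energy grid")
    return SpectrumGrid(
        energy_ev=e0.copy(),
        eps=np.mean([s.eps for s in spectra], axis=0),
        deps=np.mean([s.deps for s in spectra], axis=0),
    )
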