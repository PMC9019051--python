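"""Photostationary-state kinetics of DHP formation under CPL.

Five-species linear scheme {M, P, T, RR, SS}: the M and P helical
enantiomers of the cis isomer photoisomerize to the achiral trans species
T (rate k_ct) or photocyclize to the chiral dihydro products R,R-DHP /
S,S-DHP (rate k_cD); the DHP enantiomers photorevert (k_Dc); T reverts
symmetrically to both helices (k_tc/2 each); M and P interconvert
thermally on the ground state (k_rac both ways).

Circular polarization enters through the anisotropy (g) factors: under
r-CPL the rates out of M and of R,R-DHP are scaled by (1 + g) and those
out of P and of S,S-DHP by (1 - g) (``convention='kinetic'``).  This is
the unique convention under which the scheme's asymptotic steady states
reproduce the closed-form photostationary enantiomeric excess

    ee = |k_ct (g_D - g_s g_D) + 2 k_rac (g_D - g_s)|
         / [k_ct (1 - g_s) + 2 k_rac (1 - g_s g_D)]

whose limits are |g_D| (photoisomerization much faster than ground-state
racemization) and |g_D - g_s| / (1 - g_s g_D) (racemization much faster).
The physically motivated half-asymmetry variant (1 +- g/2) is available
as ``convention='kuhn'`` for sensitivity analysis.

At intermediate rate ratios the five-species scheme and the closed form
differ at O(g^2); both are exposed so the residual can be inspected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "SPECIES",
    "RateConstants",
    "AnisotropyPair",
    "SpeciesState",
    "EEResult",
    "build_rate_matrix",
    "photostationary_state",
    "ee_from_state",
    "ee_closed_form",
    "ee_limits",
    "wavelength_scan",
    "DegenerateSchemeError",
]

SPECIES = ("M", "P", "T", "RR", "SS")


class DegenerateSchemeError(RuntimeError):
    """The kinetic scheme has no unique steady state."""


@dataclass(frozen=True)
class RateConstants:
    """Effective first-order rate constants (arbitrary inverse time).

    Only unprimed rates are stored; the CPL-primed partners of the scheme
    are derived from these and the anisotropy pair in
    :func:`build_rate_matrix`.  The default branching k_cD/k_ct = 4/52
    follows the photoproduct ratio of the cis isomer (it does not affect
    the ee in either asymptotic limit).
    """

    k_ct: float = 1.0
    k_cD: float = 4.0 / 52.0
    k_Dc: float = 1.0
    k_tc: float = 1.0
    k_rac: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_ct", "k_cD", "k_Dc", "k_tc", "k_rac"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class AnisotropyPair:
    """g factors of the cis isomer and of DHP; open interval (-1, 1)."""

    g_stil: float
    g_DHP: float

    def __post_init__(self) -> None:
        for name in ("g_stil", "g_DHP"):
            v = getattr(self, name)
            if not (math.isfinite(v) and -1.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly inside (-1, 1)")


@dataclass
class SpeciesState:
    """Concentrations [M, P, T, RR, SS] (arbitrary units, all >= 0)."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape != (5,):
            raise ValueError("state must have 5 species")
        if np.any(self.c < -1e-12):
            raise ValueError("concentrations must be >= 0")
        self.c = np.clip(self.c, 0.0, None)

    @property
    def total(self) -> float:
        return float(self.c.sum())

    def as_dict(self) -> dict:
        return dict(zip(SPECIES, self.c))


@dataclass
class EEResult:
    """Photostationary enantiomeric excess, with provenance."""

    ee: float
    regime: str
    wavelength_nm: float | None = None

    @property
    def ee_percent(self) -> float:
        return 100.0 * self.ee


def build_rate_matrix(rc: RateConstants, aniso: AnisotropyPair,
                      convention: str = "kinetic") -> np.ndarray:
    """Generator K of dc/dt = K c over [M, P, T, RR, SS] under r-CPL.

    Columns sum to zero (mass conservation).  Switching the light
    handedness is equivalent to negating both g factors.
    """
    if convention not in ("kinetic", "kuhn"):
        raise ValueError("convention must be 'kinetic' or 'kuhn'")
    half = 1.0 if convention == "kinetic" else 0.5
    gs = half * aniso.g_stil
    gd = half * aniso.g_DHP
    up_s, dn_s = 1.0 + gs, 1.0 - gs
    up_d, dn_d = 1.0 + gd, 1.0 - gd
    for v in (up_s, dn_s, up_d, dn_d):
        if v < 0:
            raise ValueError("effective rate would be negative: |g| too large")

    K = np.zeros((5, 5))
    M, P, T, RR, SS = range(5)

    def flow(src, dst, rate):
        K[dst, src] += rate

    flow(M, T, rc.k_ct * up_s)
    flow(M, RR, rc.k_cD * up_s)
    flow(P, T, rc.k_ct * dn_s)
    flow(P, SS, rc.k_cD * dn_s)
    flow(RR, M, rc.k_Dc * up_d)
    flow(SS, P, rc.k_Dc * dn_d)
    flow(T, M, 0.5 * rc.k_tc)
    flow(T, P, 0.5 * rc.k_tc)
    flow(M, P, rc.k_rac)
    flow(P, M, rc.k_rac)
    # diagonal as the exact negative of each column's outflow; the second
    # pass absorbs the last rounding residual so column sums vanish exactly
    for j in range(5):
        K[j, j] = -math.fsum(K[:, j])
        K[j, j] -= math.fsum(K[:, j])
    return K


def photostationary_state(K: np.ndarray, init: SpeciesState,
                          method: str = "nullspace") -> SpeciesState:
    """Steady state of the scheme with the same total as ``init``.

    ``nullspace`` solves K c = 0 directly; ``ode`` integrates the stiff
    linear system to stationarity.  The two agree to ~1e-9 relative.
    Raises :class:`DegenerateSchemeError` when the steady state is not
    unique (e.g. absorbing DHP states with k_Dc = 0).
    """
    K = np.asarray(K, dtype=float)
    total = init.total
    if not total > 0:
        raise ValueError("initial total concentration must be > 0")
    if method == "nullspace":
        ns = linalg.null_space(K, rcond=1e-10)
        if ns.shape[1] != 1:
            raise DegenerateSchemeError(
                f"steady state is not unique (nullspace dim {ns.shape[1]})"
            )
        v = ns[:, 0]
        if v.sum() < 0:
            v = -v
        if np.any(v < -1e-8 * np.abs(v).max()):
            raise DegenerateSchemeError("nullspace vector is not sign-definite")
        v = np.clip(v, 0.0, None)
        return SpeciesState(v / v.sum() * total)
    if method == "ode":
        # exact propagation of the stiff linear system by matrix
        # exponentials with time doubling until the residual vanishes
        rate_scale = np.abs(K).max()
        if rate_scale == 0:
            raise DegenerateSchemeError("all rates vanish")
        c = init.c.astype(float)
        t_step = 1.0 / rate_scale
        E = linalg.expm(K * t_step)
        for _ in range(200):
            c = E @ c
            if np.linalg.norm(K @ c, np.inf) < 1e-13 * rate_scale * total:
                break
            E = E @ E  # double the propagation time
        else:
            raise DegenerateSchemeError("ODE route did not reach stationarity")
        return SpeciesState(np.clip(c, 0.0, None) / c.sum() * total)
    raise ValueError("method must be 'ode' or 'nullspace'")


def ee_from_state(state: SpeciesState) -> float:
    """ee = |[SS] - [RR]| / ([SS] + [RR])."""
    rr, ss = state.c[3], state.c[4]
    tot = rr + ss
    if tot <= 0:
        raise ValueError("no DHP formed; ee undefined")
    return abs(ss - rr) / tot


def scheme_ee(rc: RateConstants, aniso: AnisotropyPair) -> float:
    """Closed-form steady-state ee of the five-species scheme itself.

    ee = [k_ct g_D (1-g_s^2) + 2 k_rac (g_D-g_s)]
         / [k_ct (1-g_s^2) + 2 k_rac (1-g_s g_D)]

    Differs from :func:`ee_closed_form` at O(g^2); used as an independent
    cross-check of the numerical steady state.
    """
    gs, gd = aniso.g_stil, aniso.g_DHP
    num = rc.k_ct * gd * (1 - gs * gs) + 2 * rc.k_rac * (gd - gs)
    den = rc.k_ct * (1 - gs * gs) + 2 * rc.k_rac * (1 - gs * gd)
    return abs(num) / den


def ee_closed_form(k_ct: float, k_rac: float, g_stil: float, g_DHP: float,
                   wavelength_nm: float | None = None) -> EEResult:
    """Closed-form photostationary enantiomeric excess.

    ee = |k_ct (g_D - g_s g_D) + 2 k_rac (g_D - g_s)|
         / [k_ct (1 - g_s) + 2 k_rac (1 - g_s g_D)]
    """
    num = abs(k_ct * (g_DHP - g_stil * g_DHP) + 2.0 * k_rac * (g_DHP - g_stil))
    den = k_ct * (1.0 - g_stil) + 2.0 * k_rac * (1.0 - g_stil * g_DHP)
    if den <= 0:
        raise ValueError("denominator must be positive")
    return EEResult(ee=num / den, regime="closed_form", wavelength_nm=wavelength_nm)


def ee_limits(g_stil: float, g_DHP: float,
              wavelength_nm: float | None = None) -> dict:
    """The three limiting regimes of the closed form (algebraic limits).

    fast_isomerization (k_ct >> k_rac): ee -> |g_D|
    fast_racemization  (k_rac >> k_ct): ee -> |g_D - g_s| / (1 - g_s g_D)
    comparable         (k_ct = k_rac):  closed form at equal rates
    """
    fast_iso = EEResult(abs(g_DHP), "fast_isomerization", wavelength_nm)
    fast_rac = EEResult(
        abs(g_DHP - g_stil) / (1.0 - g_stil * g_DHP),
        "fast_racemization",
        wavelength_nm,
    )
    comp = ee_closed_form(1.0, 1.0, g_stil, g_DHP, wavelength_nm)
    comp.regime = "comparable"
    return {
        "fast_isomerization": fast_iso,
        "fast_racemization": fast_rac,
        "comparable": comp,
    }


def wavelength_scan(wavelength_nm, g_stil_curve, g_DHP_curve,
                    regime: str = "fast_isomerization",
                    window: tuple = (230.0, 350.0)) -> dict:
    """Pointwise photostationary ee over a wavelength window.

    Curves must share the grid.  Points where either g is undefined (NaN)
    are skipped and reported.  Returns the ee(lambda) curve, the argmax
    (lambda*, ee_max) over the window, and the skipped-point count.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    gs = np.asarray(g_stil_curve, dtype=float)
    gd = np.asarray(g_DHP_curve, dtype=float)
    if not (lam.shape == gs.shape == gd.shape):
        raise ValueError("curves must share the wavelength grid")
    sel = (lam >= window[0]) & (lam <= window[1])
    if not np.any(sel):
        raise ValueError("empty overlap between curves and window")
    lam_w, gs_w, gd_w = lam[sel], gs[sel], gd[sel]
    defined = np.isfinite(gs_w) & np.isfinite(gd_w)
    ee = np.full(lam_w.shape, np.nan)
    for i in np.nonzero(defined)[0]:
        if regime == "comparable":
            ee[i] = ee_closed_form(1.0, 1.0, gs_w[i], gd_w[i]).ee
        else:
            ee[i] = ee_limits(gs_w[i], gd_w[i])[regime].ee
    if not np.any(np.isfinite(ee)):
        raise ValueError("g undefined at every point of the window")
    imax = int(np.nanargmax(ee))
    return {
        "wavelength_nm": lam_w,
        "ee": ee,
        "regime": regime,
        "lambda_max_nm": float(lam_w[imax]),
        "ee_max": float(ee[imax]),
        "n_skipped": int((~defined).sum()),
    }
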