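"""Analytic two-state model surface in reduced coordinates (tau, phi).

The surface is a stand-in for the ab initio S0/S1 landscape of helically
twisted alkenes (cis-stilbene, cis-stiff-stilbene).  It encodes, exactly and
by construction, the topography that makes these molecules *electronically
prochiral*:

* two mirror-image S0 wells (P at +tau0, M at -tau0) separated by a low
  helical-inversion barrier whose saddle is reached by phi (``phenyl
  rotation``),
* an S1 sheet that is sloped from the Franck-Condon point toward the
  S1/S0 degeneracies at tau = +-pi/2, with a *high* planar (tau = 0)
  inversion saddle, so P and M cannot interconvert while excited,
* isolated conical intersections at (tau, phi) = (+-pi/2, +-pi/2) where the
  adiabatic gap vanishes.

Functional form (2x2 diabatic matrix, angles in rad, energies kcal/mol)::

    H11 = A1 sin^2(tau) + B1 cos^2(phi) - c1 sin(tau) sin(phi)
    H22 = C2 + A2 cos^2(tau) + B2 cos^2(phi)
    H12 = k cos(tau) [G(tau - pi/2) + G(tau + pi/2)],   G = Gaussian(width w)

With phi0 = pi/2 and B2 = B1 the calibration is closed-form:

    A2 = barrier_S1                      (planar S1 saddle height, exact)
    A1 = (dE_vert - A2 cos^2 tau0) / (1 - sin tau0)^2
    c1 = 2 A1 sin tau0                   (places the P well at (tau0, pi/2))
    B1 = barrier_S0 - A1 sin^2 tau0      (S0 inversion saddle at (0, 0))
    C2 = A1 - c1                         (degeneracy exactly at the CI)

The cos(tau) factor in H12 makes the coupling vanish *linearly* at
tau = +-pi/2, so the degeneracies are true isolated conical intersections
(gap zero only there) rather than avoided-crossing seams.  The adiabatic
coupling diverges at the CI and is therefore capped at ``nacv_cap``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy import optimize

from prochir.constants import AMU_AA2

__all__ = [
    "ReducedCoords",
    "SurfaceParams",
    "SurfaceEval",
    "CriticalPoint",
    "CriticalPointReport",
    "TwoStateSurface",
    "LinearCrossingSurface",
    "evaluate_surface",
    "characterize_surface",
    "preset",
    "PRESETS",
    "wrap_angle",
]

HALF_PI = math.pi / 2.0


def wrap_angle(x: float) -> float:
    """Wrap an angle to (-pi, pi]; in-range values pass through unchanged."""
    if -math.pi < x <= math.pi:
        return x
    y = math.fmod(x + math.pi, 2.0 * math.pi)
    if y <= 0.0:
        y += 2.0 * math.pi
    return y - math.pi


class InvalidParameterError(ValueError):
    """Raised when surface parameters are non-finite or inconsistent."""


@dataclass
class ReducedCoords:
    """Phase-space point on the reduced 2D surface.

    tau : ethylenic twist angle (rad), wrapped to (-pi, pi]
    phi : helicity coordinate (rad), wrapped to (-pi, pi]
    p_tau, p_phi : conjugate momenta (kcal/mol * fs / rad)
    """

    tau: float
    phi: float
    p_tau: float = 0.0
    p_phi: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p_tau) and math.isfinite(self.p_phi)):
            raise ValueError("momenta must be finite")
        if not (math.isfinite(self.tau) and math.isfinite(self.phi)):
            raise ValueError("angles must be finite")
        self.tau = wrap_angle(self.tau)
        self.phi = wrap_angle(self.phi)

    def mirrored(self) -> "ReducedCoords":
        """Mirror image: (tau, phi, p) -> (-tau, -phi, -p)."""
        return ReducedCoords(-self.tau, -self.phi, -self.p_tau, -self.p_phi)


@dataclass(frozen=True)
class SurfaceParams:
    """Calibration parameters of the two-state model surface.

    Energies in kcal/mol, angles in rad, inertias in kcal/mol * fs^2.
    ``barrier_S0``/``barrier_S1`` are calibration *targets*: the surface is
    built so that :func:`characterize_surface` reproduces them.
    """

    dE_vert: float = 70.0
    barrier_S0: float = 1.6
    barrier_S1: float = 19.0
    tau_ci: float = HALF_PI
    tau0: float = math.radians(8.0)
    phi0: float = HALF_PI
    coupling_width: float = 0.18
    coupling_strength: float = 2.0
    I_tau: float = 167.0 * AMU_AA2
    I_phi: float = 167.0 * AMU_AA2
    nacv_cap: float = 50.0
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        for name in (
            "dE_vert",
            "barrier_S0",
            "barrier_S1",
            "tau0",
            "phi0",
            "coupling_width",
            "coupling_strength",
            "I_tau",
            "I_phi",
            "nacv_cap",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if self.barrier_S0 <= 0 or self.barrier_S1 <= 0:
            raise InvalidParameterError("barriers must be > 0")
        if not (0.0 < self.tau0 < HALF_PI):
            raise InvalidParameterError("tau0 must lie in (0, pi/2)")
        if self.I_tau <= 0 or self.I_phi <= 0:
            raise InvalidParameterError("inertias must be > 0")
        if self.coupling_width <= 0:
            raise InvalidParameterError("coupling_width must be > 0")
        # closed-form feasibility: the S0 well depth along tau must stay
        # below the requested inversion barrier
        a1 = self._a1()
        if self.barrier_S0 - a1 * math.sin(self.tau0) ** 2 <= 0:
            raise InvalidParameterError(
                "infeasible calibration: barrier_S0 <= A1 sin^2(tau0); "
                "decrease tau0 or dE_vert"
            )

    def _a1(self) -> float:
        a2 = self.barrier_S1
        return (self.dE_vert - a2 * math.cos(self.tau0) ** 2) / (
            1.0 - math.sin(self.tau0)
        ) ** 2

    def to_dict(self) -> dict:
        return {
            "dE_vert": self.dE_vert,
            "barrier_S0": self.barrier_S0,
            "barrier_S1": self.barrier_S1,
            "tau_ci": self.tau_ci,
            "tau0": self.tau0,
            "phi0": self.phi0,
            "coupling_width": self.coupling_width,
            "coupling_strength": self.coupling_strength,
            "I_tau": self.I_tau,
            "I_phi": self.I_phi,
            "nacv_cap": self.nacv_cap,
            "preset_name": self.preset_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidParameterError(f"unknown surface keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SurfaceEval:
    """Adiabatic energies/gradients/coupling at one geometry.

    e : (2,) adiabatic energies, e[0] <= e[1] (kcal/mol)
    grad : (2, 2) per-state gradient wrt (tau, phi)
    nacv : (2,) nonadiabatic coupling vector d12 (capped near the CI)
    gap : e[1] - e[0]
    """

    e: np.ndarray
    grad: np.ndarray
    nacv: np.ndarray
    gap: float


class TwoStateSurface:
    """Callable evaluator compiled from :class:`SurfaceParams`."""

    def __init__(self, params: SurfaceParams):
        self.params = params
        t0 = params.tau0
        self.A2 = params.barrier_S1
        self.A1 = params._a1()
        self.c1 = 2.0 * self.A1 * math.sin(t0)
        self.B1 = params.barrier_S0 - self.A1 * math.sin(t0) ** 2
        self.B2 = self.B1
        self.C2 = self.A1 - self.c1
        self.k = params.coupling_strength
        self.w2 = params.coupling_width ** 2
        self.I_tau = params.I_tau
        self.I_phi = params.I_phi
        self.nacv_cap = params.nacv_cap
        #: energy of the S0 enantiomer wells (for barrier bookkeeping)
        self.e_well = -self.A1 * math.sin(t0) ** 2

    # -- raw float interface used by the propagator ----------------------
    def eval_raw(self, tau: float, phi: float):
        """Return (e0, e1, g0t, g0p, g1t, g1p, d_t, d_p, gap) as floats."""
        st = math.sin(tau)
        ct = math.cos(tau)
        sp = math.sin(phi)
        cp = math.cos(phi)

        h11 = self.A1 * st * st + self.B1 * cp * cp - self.c1 * st * sp
        h22 = self.C2 + self.A2 * ct * ct + self.B2 * cp * cp
        d11t = ct * (2.0 * self.A1 * st - self.c1 * sp)
        d11p = -2.0 * self.B1 * cp * sp - self.c1 * st * cp
        d22t = -2.0 * self.A2 * ct * st
        d22p = -2.0 * self.B2 * cp * sp

        xm = tau - HALF_PI
        xp = tau + HALF_PI
        ga = math.exp(-xm * xm / (2.0 * self.w2))
        gb = math.exp(-xp * xp / (2.0 * self.w2))
        h12 = self.k * ct * (ga + gb)
        d12t = self.k * (
            -st * (ga + gb) + ct * (-(xm / self.w2) * ga - (xp / self.w2) * gb)
        )
        d12p = 0.0

        delta = h11 - h22
        ddt = d11t - d22t
        ddp = d11p - d22p
        r2 = delta * delta + 4.0 * h12 * h12
        r = math.sqrt(r2)
        mean_t = 0.5 * (d11t + d22t)
        mean_p = 0.5 * (d11p + d22p)
        if r > 1e-12:
            q_t = (delta * ddt + 4.0 * h12 * d12t) / (2.0 * r)
            q_p = (delta * ddp + 4.0 * h12 * d12p) / (2.0 * r)
        else:
            q_t = q_p = 0.0
        e0 = 0.5 * (h11 + h22) - 0.5 * r
        e1 = 0.5 * (h11 + h22) + 0.5 * r
        g0t = mean_t - q_t
        g0p = mean_p - q_p
        g1t = mean_t + q_t
        g1p = mean_p + q_p

        if r2 > 1e-300:
            nt = (delta * d12t - h12 * ddt) / r2
            npv = (delta * d12p - h12 * ddp) / r2
        else:
            nt = npv = 0.0
        nrm = math.hypot(nt, npv)
        if nrm > self.nacv_cap:
            s = self.nacv_cap / nrm
            nt *= s
            npv *= s
        return e0, e1, g0t, g0p, g1t, g1p, nt, npv, r


class LinearCrossingSurface:
    """Linear diabatic crossing with constant coupling.

    The linear-crossing limit of the two-state family: H11 = f1*(tau-tau_c),
    H22 = -f2*(tau-tau_c), H12 = k.  Used to validate surface hopping
    against the closed-form single-passage transition probability
    P = 1 - exp(-2 pi k^2 / (hbar v |f1 + f2|)).
    """

    def __init__(self, f1: float = 5.0, f2: float = 5.0, k: float = 2.0,
                 tau_c: float = 0.0, I_tau: float = 1000.0, I_phi: float = 1000.0):
        self.f1, self.f2, self.k, self.tau_c = f1, f2, k, tau_c
        self.I_tau, self.I_phi = I_tau, I_phi
        self.nacv_cap = float("inf")

    def eval_raw(self, tau: float, phi: float):
        x = tau - self.tau_c
        h11 = self.f1 * x
        h22 = -self.f2 * x
        h12 = self.k
        delta = h11 - h22
        ddt = self.f1 + self.f2
        r2 = delta * delta + 4.0 * h12 * h12
        r = math.sqrt(r2)
        e0 = 0.5 * (h11 + h22) - 0.5 * r
        e1 = 0.5 * (h11 + h22) + 0.5 * r
        mean_t = 0.5 * (self.f1 - self.f2)
        q_t = delta * ddt / (2.0 * r)
        nt = -h12 * ddt / r2
        return e0, e1, mean_t - q_t, 0.0, mean_t + q_t, 0.0, nt, 0.0, r

    @property
    def slope_sum(self) -> float:
        return abs(self.f1 + self.f2)


def evaluate_surface(coords: ReducedCoords, params: SurfaceParams) -> SurfaceEval:
    """Adiabatic energies, gradients and coupling at ``coords``.

    Exactly mirror-symmetric: energies at (tau, phi) and (-tau, -phi) are
    identical and gradients/coupling map by a sign flip of both coordinates.
    """
    surf = params if isinstance(params, TwoStateSurface) else TwoStateSurface(params)
    e0, e1, g0t, g0p, g1t, g1p, nt, npv, gap = surf.eval_raw(coords.tau, coords.phi)
    return SurfaceEval(
        e=np.array([e0, e1]),
        grad=np.array([[g0t, g0p], [g1t, g1p]]),
        nacv=np.array([nt, npv]),
        gap=gap,
    )


@dataclass
class CriticalPoint:
    tau: float
    phi: float
    energy: float


@dataclass
class CriticalPointReport:
    """Numerically located critical points and barrier heights."""

    well_P: CriticalPoint
    well_M: CriticalPoint
    s0_saddle: CriticalPoint
    s1_min: CriticalPoint
    s1_saddle: CriticalPoint
    min_gap_point: CriticalPoint
    min_gap: float
    barrier_S0: float
    barrier_S1: float

    def rows(self) -> list[dict]:
        out = []
        for name in ("well_P", "well_M", "s0_saddle", "s1_min", "s1_saddle",
                     "min_gap_point"):
            cp = getattr(self, name)
            out.append(
                {
                    "point": name,
                    "tau_deg": math.degrees(cp.tau),
                    "phi_deg": math.degrees(cp.phi),
                    "energy_kcal_mol": cp.energy,
                }
            )
        return out


class OptimizerError(RuntimeError):
    """Numerical search for a critical point failed; carries last iterate."""

    def __init__(self, msg: str, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


def _state_energy(surf: TwoStateSurface, state: int):
    def f(x):
        out = surf.eval_raw(x[0], x[1])
        return out[state]

    return f


def _state_grad(surf: TwoStateSurface, state: int):
    def g(x):
        out = surf.eval_raw(x[0], x[1])
        if state == 0:
            return np.array([out[2], out[3]])
        return np.array([out[4], out[5]])

    return g


def _find_saddle(surf: TwoStateSurface, state: int, x0) -> CriticalPoint:
    grad = _state_grad(surf, state)
    sol = optimize.root(grad, x0, method="hybr", tol=1e-13)
    if not sol.success:
        raise OptimizerError(f"saddle search failed: {sol.message}", sol.x)
    # verify index-1 signature by central finite differences
    h = 1e-5
    x = sol.x
    hess = np.zeros((2, 2))
    for i in range(2):
        dx = np.zeros(2)
        dx[i] = h
        hess[:, i] = (grad(x + dx) - grad(x - dx)) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    ev = np.linalg.eigvalsh(hess)
    if not (ev[0] < 0 < ev[1]):
        raise OptimizerError(f"stationary point at {x} is not index-1: {ev}", x)
    return CriticalPoint(x[0], x[1], _state_energy(surf, state)(x))


def characterize_surface(params: SurfaceParams) -> CriticalPointReport:
    """Locate wells, saddles and the minimum-gap point by numerical search.

    Barrier heights are reported relative to the corresponding minima:
    ``barrier_S0`` is the helical-inversion saddle (near the origin, reached
    by phi) above the enantiomer wells; ``barrier_S1`` is the planar
    (tau = 0) saddle of the upper adiabat above the S1 minimum at the CI.
    """
    surf = TwoStateSurface(params)
    p = params

    res = optimize.minimize(
        _state_energy(surf, 0),
        x0=[p.tau0, p.phi0],
        jac=_state_grad(surf, 0),
        method="L-BFGS-B",
        options={"gtol": 1e-12, "ftol": 1e-15},
    )
    if not res.success and np.linalg.norm(_state_grad(surf, 0)(res.x)) > 1e-8:
        raise OptimizerError(f"P-well search failed: {res.message}", res.x)
    well_p = CriticalPoint(res.x[0], res.x[1], res.fun)
    well_m = CriticalPoint(-res.x[0], -res.x[1], res.fun)

    s0_saddle = _find_saddle(surf, 0, [0.0, 0.0])

    # S1 minimum sits at the conical intersection where the upper sheet is
    # non-smooth; Nelder-Mead tolerates the cusp.
    res1 = optimize.minimize(
        _state_energy(surf, 1),
        x0=[HALF_PI - 0.05, HALF_PI - 0.05],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    s1_min = CriticalPoint(res1.x[0], res1.x[1], res1.fun)

    s1_saddle = _find_saddle(surf, 1, [0.0, HALF_PI])

    def gap2(x):
        return surf.eval_raw(x[0], x[1])[8] ** 2

    resg = optimize.minimize(
        gap2,
        x0=[HALF_PI - 0.03, HALF_PI - 0.03],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-24, "maxiter": 4000},
    )
    gap_val = math.sqrt(max(resg.fun, 0.0))
    min_gap_point = CriticalPoint(resg.x[0], resg.x[1], _state_energy(surf, 0)(resg.x))

    return CriticalPointReport(
        well_P=well_p,
        well_M=well_m,
        s0_saddle=s0_saddle,
        s1_min=s1_min,
        s1_saddle=s1_saddle,
        min_gap_point=min_gap_point,
        min_gap=gap_val,
        barrier_S0=s0_saddle.energy - well_p.energy,
        barrier_S1=s1_saddle.energy - s1_min.energy,
    )


PRESETS: dict[str, dict] = {
    # S0/S1 helical-inversion barriers are the published calibration
    # targets; tau0, dE_vert and the inertias are model choices (see the
    # methods note).
    "stilbene": dict(
        barrier_S0=1.6,
        barrier_S1=19.0,
        tau0=math.radians(8.0),
        dE_vert=70.0,
        I_tau=167.0 * AMU_AA2,
        I_phi=167.0 * AMU_AA2,
    ),
    "stiff_stilbene": dict(
        barrier_S0=4.9,
        barrier_S1=13.0,
        tau0=math.radians(12.0),
        dE_vert=70.0,
        I_tau=250.0 * AMU_AA2,
        I_phi=250.0 * AMU_AA2,
    ),
}


def preset(name: str) -> SurfaceParams:
    """Named parameter sets calibrated to the published inversion barriers."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {sorted(PRESETS)}"
        )
    return SurfaceParams(preset_name=name, **PRESETS[name])
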