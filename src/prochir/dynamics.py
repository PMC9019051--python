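"""Fewest-switches surface hopping (FSSH) on the reduced model surface.

Classical nuclei (velocity Verlet in the (tau, phi) plane with inertias
I_tau, I_phi) carry a two-state electronic wavefunction integrated along
the path.  Stochastic hops follow the fewest-switches prescription with
momentum rescaling along the nonadiabatic coupling vector; energetically
forbidden (frustrated) hops are ignored or velocity-reflected per policy.

The electronic amplitudes are propagated in phase-factored form
``c_k = a_k exp(-i Theta_k)`` with the dynamical phases integrated exactly
for linearly interpolated energies, so the electronic norm is conserved to
machine precision away from the coupling region.  Near small gaps
(< ``substep_gap``) the electronic integration is substepped 10x.

A trajectory swarm started from a Wigner ensemble in the P well expresses
the designed unidirectionality of the surface: essentially every
trajectory reaches the +90 deg intersection (clockwise rotation) and none
inverts helicity while on S1.
"""

from __future__ import annotations

import cmath
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from prochir.constants import HBAR
from prochir.pes import (
    HALF_PI,
    LinearCrossingSurface,
    ReducedCoords,
    SurfaceParams,
    TwoStateSurface,
)

__all__ = [
    "FSSHParams",
    "Trajectory",
    "TrajectoryEnsemble",
    "hop_probability",
    "propagate",
    "run_swarm",
    "hop_fraction_from_probs",
    "landau_zener_probability",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FSSHParams:
    """Propagation controls.

    dt in fs; ``energy_drift_tol`` in kcal/mol per ps of hop-free
    propagation; ``stop_tau`` is the |tau| beyond which a ground-state
    trajectory is considered to have left the photochemically active
    region.  ``hops='off'`` disables stochastic switching but still
    records per-substep hop probabilities (used for the analytic
    Landau-Zener validation).
    """

    dt: float = 0.05
    n_steps: int = 28000  # 1.4 ps at the default step: the passage is
    # sub-ps but rare ridge-bounce stragglers need the extra margin
    initial_state: int = 1
    seed: int = 0
    frustrated: str = "ignore"  # ignore | reflect
    decoherence: str = "none"  # none | energy-based
    energy_drift_tol: float = 1.0
    stop_tau: float = HALF_PI
    substep_gap: float = 1.0
    substeps: int = 10
    hops: str = "stochastic"  # stochastic | off
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.frustrated not in ("ignore", "reflect"):
            raise ValueError("frustrated policy must be 'ignore' or 'reflect'")
        if self.decoherence not in ("none", "energy-based"):
            raise ValueError("decoherence must be 'none' or 'energy-based'")
        if self.hops not in ("stochastic", "off"):
            raise ValueError("hops must be 'stochastic' or 'off'")


@dataclass
class Trajectory:
    """Time series of one surface-hopping trajectory.

    ``tau`` is recorded *unwrapped* (continuous, no 2 pi jumps) so that
    directionality analysis can follow the rotation sense.  ``pop`` holds
    |c_0|^2, |c_1|^2; ``e_total`` is kinetic + active-state potential.
    """

    t: np.ndarray
    tau: np.ndarray
    phi: np.ndarray
    p_tau: np.ndarray
    p_phi: np.ndarray
    state: np.ndarray
    pop: np.ndarray
    e_total: np.ndarray
    hops: list = field(default_factory=list)
    n_frustrated: int = 0
    valid: bool = True
    invalid_reason: str = ""
    norm_err_max: float = 0.0
    seed: int = 0
    stopped_early: bool = False
    hop_probs: np.ndarray | None = None

    @property
    def final_state(self) -> int:
        return int(self.state[-1])


@dataclass
class TrajectoryEnsemble:
    """Swarm of trajectories sharing surface and FSSH parameters."""

    trajectories: list
    surface: SurfaceParams | object
    params: FSSHParams
    seeds: list

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def valid(self) -> list:
        return [tr for tr in self.trajectories if tr.valid]


def hop_probability(
    amplitudes, coupling_dot_velocity: float, dt: float, from_state: int
) -> float:
    """Fewest-switches hop probability out of ``from_state``.

    max(0, 2 Re(c_from conj(c_to) * coupling_dot_velocity) * dt
    / |c_from|^2), clamped to [0, 1].  ``coupling_dot_velocity`` is
    v . d_(from,to) in fs^-1.
    """
    c_from = amplitudes[from_state]
    c_to = amplitudes[1 - from_state]
    pop = abs(c_from) ** 2
    if pop < 1e-12:
        logger.warning("hop_probability: vanishing active population")
        return 0.0
    raw = 2.0 * (c_from * c_to.conjugate() * coupling_dot_velocity).real * dt / pop
    return min(max(raw, 0.0), 1.0)


def landau_zener_probability(h12: float, v: float, slope_sum: float) -> float:
    """Closed-form single-passage transition probability for a linear
    crossing: 1 - exp(-2 pi H12^2 / (hbar v |d(H11-H22)/dtau|))."""
    return 1.0 - math.exp(-2.0 * math.pi * h12 * h12 / (HBAR * v * slope_sum))


def _as_surface(surface):
    if isinstance(surface, SurfaceParams):
        return TwoStateSurface(surface)
    return surface


def propagate(ic: ReducedCoords, surface, params: FSSHParams) -> Trajectory:
    """Propagate one FSSH trajectory from ``ic`` on the declared state.

    Terminates at ``n_steps`` or when the active state is S0 with
    |tau| >= stop_tau.  Trajectories whose total energy drifts beyond
    tolerance between hops are flagged invalid rather than silently kept.
    """
    surf = _as_surface(surface)
    dt = params.dt
    I_t, I_p = surf.I_tau, surf.I_phi
    rng = np.random.default_rng(params.seed)

    tau = float(ic.tau)
    phi = float(ic.phi)
    p_t = float(ic.p_tau)
    p_p = float(ic.p_phi)
    state = params.initial_state

    n = params.n_steps
    T = np.empty(n + 1)
    TA = np.empty(n + 1)
    PH = np.empty(n + 1)
    PT = np.empty(n + 1)
    PP = np.empty(n + 1)
    ST = np.empty(n + 1, dtype=np.int8)
    POP = np.empty((n + 1, 2))
    ET = np.empty(n + 1)
    record_probs = params.hops == "off"
    probs: list = [] if record_probs else None

    ev = surf.eval_raw(tau, phi)
    a = [0j, 0j]
    a[state] = 1.0 + 0j
    theta01 = 0.0  # Theta_0 - Theta_1 accumulated phase difference

    def ke(pt, pp):
        return 0.5 * (pt * pt / I_t + pp * pp / I_p)

    e_seg_ref = ke(p_t, p_p) + ev[state]
    t_seg_ref = 0.0
    hops: list = []
    n_frustrated = 0
    norm_err_max = 0.0
    valid = True
    invalid_reason = ""
    stopped = False

    T[0] = 0.0
    TA[0], PH[0], PT[0], PP[0] = tau, phi, p_t, p_p
    ST[0] = state
    POP[0] = (abs(a[0]) ** 2, abs(a[1]) ** 2)
    ET[0] = e_seg_ref

    n_done = 0
    for istep in range(1, n + 1):
        gi = 2 + 2 * state  # gradient index for active state
        f_t = -ev[gi]
        f_p = -ev[gi + 1]
        p_t += 0.5 * dt * f_t
        p_p += 0.5 * dt * f_p
        tau += dt * p_t / I_t
        phi += dt * p_p / I_p
        ev_new = surf.eval_raw(tau, phi)
        gi = 2 + 2 * state
        p_t += 0.5 * dt * (-ev_new[gi])
        p_p += 0.5 * dt * (-ev_new[gi + 1])

        # electronic propagation across this nuclear step -----------------
        gap0, gap1 = ev[8], ev_new[8]
        cdv0 = (PT[istep - 1] / I_t) * ev[6] + (PP[istep - 1] / I_p) * ev[7]
        cdv1 = (p_t / I_t) * ev_new[6] + (p_p / I_p) * ev_new[7]
        m = params.substeps if min(gap0, gap1) < params.substep_gap else 1
        h = dt / m
        hop_now = False
        dgap = (gap1 - gap0) / dt
        dcdv = (cdv1 - cdv0) / dt
        for j in range(m):
            s0 = j * h
            # linear interpolation of gap and v.d01 over the step
            g_a = gap0 + dgap * s0
            g_b = gap0 + dgap * (s0 + 0.5 * h)
            g_c = gap0 + dgap * (s0 + h)
            c_a = cdv0 + dcdv * s0
            c_b = cdv0 + dcdv * (s0 + 0.5 * h)
            c_c = cdv0 + dcdv * (s0 + h)
            # theta01 = Theta_0 - Theta_1 decreases at rate gap/hbar;
            # the increments below are exact for the linear gap interpolant
            ph_a = theta01
            ph_b = theta01 - (g_a + g_b) * 0.25 * h / HBAR
            ph_c = theta01 - (g_a + 2.0 * g_b + g_c) * 0.25 * h / HBAR
            e_a = cmath.exp(1j * ph_a)
            e_b = cmath.exp(1j * ph_b)
            e_c = cmath.exp(1j * ph_c)
            a0, a1 = a[0], a[1]
            k1_0 = -c_a * a1 * e_a
            k1_1 = c_a * a0 * e_a.conjugate()
            x0 = a0 + 0.5 * h * k1_0
            x1 = a1 + 0.5 * h * k1_1
            k2_0 = -c_b * x1 * e_b
            k2_1 = c_b * x0 * e_b.conjugate()
            x0 = a0 + 0.5 * h * k2_0
            x1 = a1 + 0.5 * h * k2_1
            k3_0 = -c_b * x1 * e_b
            k3_1 = c_b * x0 * e_b.conjugate()
            x0 = a0 + h * k3_0
            x1 = a1 + h * k3_1
            k4_0 = -c_c * x1 * e_c
            k4_1 = c_c * x0 * e_c.conjugate()
            a[0] = a0 + h / 6.0 * (k1_0 + 2 * k2_0 + 2 * k3_0 + k4_0)
            a[1] = a1 + h / 6.0 * (k1_1 + 2 * k2_1 + 2 * k3_1 + k4_1)
            theta01 = ph_c

            # fewest-switches draw over this substep
            cf = a[state]
            ct = a[1 - state]
            popf = abs(cf) ** 2
            if popf < 1e-12:
                p_hop = 0.0
            else:
                # c_from conj(c_to) including the dynamical phase factor
                if state == 1:
                    cross = cf * ct.conjugate() * cmath.exp(1j * theta01)
                    cdv_ft = -c_c  # v.d_(1,0) = -v.d01
                else:
                    cross = cf * ct.conjugate() * cmath.exp(-1j * theta01)
                    cdv_ft = c_c
                p_hop = min(max(2.0 * (cross * cdv_ft).real * h / popf, 0.0), 1.0)
            if record_probs:
                probs.append(p_hop)
            elif p_hop > 0.0 and rng.random() < p_hop:
                hop_now = True
                break

        if params.decoherence == "energy-based" and not hop_now:
            ekin = ke(p_t, p_p)
            tau_d = HBAR / max(ev_new[8], 1e-8) * (1.0 + 62.75 / max(ekin, 1e-8))
            damp = math.exp(-dt / tau_d)
            other = 1 - state
            a[other] *= damp
            pa = abs(a[state]) ** 2
            po = abs(a[other]) ** 2
            if pa > 0:
                a[state] *= math.sqrt(max(1.0 - po, 0.0) / pa)

        if hop_now:
            new_state = 1 - state
            d_t, d_p = ev_new[6], ev_new[7]
            a_coef = 0.5 * (d_t * d_t / I_t + d_p * d_p / I_p)
            b_coef = p_t * d_t / I_t + p_p * d_p / I_p
            dE = ev_new[new_state] - ev_new[state]
            disc = b_coef * b_coef - 4.0 * a_coef * dE
            if a_coef > 0 and disc >= 0:
                e_before = ke(p_t, p_p) + ev_new[state]
                sq = math.sqrt(disc)
                g1 = (b_coef + sq) / (2.0 * a_coef)
                g2 = (b_coef - sq) / (2.0 * a_coef)
                gamma = g2 if abs(g2) < abs(g1) else g1
                p_t -= gamma * d_t
                p_p -= gamma * d_p
                state = new_state
                hops.append(
                    {
                        "t": istep * dt,
                        "tau": tau,
                        "phi": phi,
                        "to": state,
                        "e_before": e_before,
                        "e_after": ke(p_t, p_p) + ev_new[state],
                    }
                )
                e_seg_ref = ke(p_t, p_p) + ev_new[state]
                t_seg_ref = istep * dt
            else:
                n_frustrated += 1
                if params.frustrated == "reflect" and a_coef > 0:
                    gamma = b_coef / a_coef
                    p_t -= gamma * d_t
                    p_p -= gamma * d_p

        norm = abs(a[0]) ** 2 + abs(a[1]) ** 2
        norm_err_max = max(norm_err_max, abs(norm - 1.0))
        etot = ke(p_t, p_p) + ev_new[state]
        seg_ps = (istep * dt - t_seg_ref) / 1000.0
        if abs(etot - e_seg_ref) > params.energy_drift_tol * (seg_ps + 0.02):
            valid = False
            invalid_reason = (
                f"energy drift {etot - e_seg_ref:.3e} kcal/mol at t={istep * dt} fs"
            )

        T[istep] = istep * dt
        TA[istep], PH[istep], PT[istep], PP[istep] = tau, phi, p_t, p_p
        ST[istep] = state
        POP[istep] = (abs(a[0]) ** 2, abs(a[1]) ** 2)
        ET[istep] = etot
        ev = ev_new
        n_done = istep
        if state == 0 and abs(tau) >= params.stop_tau:
            stopped = True
            break
        if not valid:
            break

    sl = slice(0, n_done + 1)
    return Trajectory(
        t=T[sl].copy(),
        tau=TA[sl].copy(),
        phi=PH[sl].copy(),
        p_tau=PT[sl].copy(),
        p_phi=PP[sl].copy(),
        state=ST[sl].copy(),
        pop=POP[sl].copy(),
        e_total=ET[sl].copy(),
        hops=hops,
        n_frustrated=n_frustrated,
        valid=valid,
        invalid_reason=invalid_reason,
        norm_err_max=norm_err_max,
        seed=params.seed,
        stopped_early=stopped,
        hop_probs=np.asarray(probs) if record_probs else None,
    )


def run_swarm(ensemble, surface, params: FSSHParams, seed_base: int) -> TrajectoryEnsemble:
    """Propagate every ensemble member with seed = seed_base + index.

    Deterministic given ``seed_base``.  Raises if every trajectory is
    flagged invalid.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must be nonempty")
    trajs = []
    seeds = []
    for i in range(len(ensemble)):
        pos, mom = ensemble[i]
        ic = ReducedCoords(pos[0], pos[1], mom[0], mom[1])
        seed = seed_base + i
        trajs.append(propagate(ic, surface, replace(params, seed=seed)))
        seeds.append(seed)
    out = TrajectoryEnsemble(trajs, surface, params, seeds)
    if not out.valid:
        raise RuntimeError("all trajectories in the swarm are invalid")
    return out


def landau_zener_validation(n_traj: int, seed: int, k: float = 1.0,
                            slope: float = 10.0, v0: float = 1.0,
                            inertia: float = 1000.0, dt: float = 0.008) -> dict:
    """Single-passage surface-switch statistics vs the LZ closed form.

    Propagates ``n_traj`` FSSH trajectories through a linear diabatic
    crossing (constant coupling ``k``, diabatic slopes +-``slope``) at
    velocity ~``v0`` and counts the fraction that end on the lower
    adiabat.  For a passage begun on the upper adiabat this equals the
    diabatic-passage probability exp(-2 pi Gamma); its complement -- the
    fraction switching diabats -- is the textbook 1 - exp(-2 pi Gamma)
    with Gamma = k^2/(hbar v |d(H11-H22)/dtau|), v measured at the
    crossing.  Returns fractions, the closed form and the Monte-Carlo
    sigma.
    """
    surf = LinearCrossingSurface(f1=slope, f2=slope, k=k, I_tau=inertia)
    ic = ReducedCoords(-2.0, 0.0, inertia * v0, 0.0)
    # run well past the crossing: the adiabatic-basis coherence relaxes
    # over about one more length unit, and the back-hops it drives are
    # part of the fewest-switches balance
    n_steps = int(5.0 / v0 / dt)
    base = FSSHParams(dt=dt, n_steps=n_steps, seed=0, stop_tau=1e9)
    # deterministic reference passage for the crossing velocity
    ref = propagate(ic, surf, replace(base, hops="off", seed=1))
    i_c = int(np.argmin(np.abs(ref.tau)))
    v_c = ref.p_tau[i_c] / inertia
    p_lz = math.exp(-2.0 * math.pi * k * k / (HBAR * v_c * 2.0 * slope))
    traj_seeds = np.random.default_rng(seed).integers(2**31 - 1, size=n_traj)
    n_lower = 0
    for s in traj_seeds:
        tr = propagate(ic, surf, replace(base, seed=int(s)))
        n_lower += tr.final_state == 0
    frac = n_lower / n_traj
    sigma = math.sqrt(p_lz * (1.0 - p_lz) / n_traj)
    return {
        "hop_fraction": frac,
        "diabatic_switch_fraction": 1.0 - frac,
        "lz_hop": p_lz,
        "lz_switch": 1.0 - p_lz,
        "sigma_mc": sigma,
        "deviation_sigma": (frac - p_lz) / sigma,
        "v_crossing": v_c,
        "quantum_transfer": 1.0 - ref.pop[-1, 1],
    }


def hop_fraction_from_probs(probs: np.ndarray, n: int, seed: int) -> float:
    """Monte-Carlo fraction of RNG streams that hop at least once.

    For identical initial conditions the pre-hop dynamics of every
    trajectory coincide, so the swarm statistic reduces to sampling the
    per-substep fewest-switches draws ``n`` times over the recorded
    probability sequence.
    """
    probs = np.asarray(probs)
    rng = np.random.default_rng(seed)
    hopped = 0
    # chunk to bound memory at large n
    chunk = max(1, int(2e7 // max(len(probs), 1)))
    done = 0
    while done < n:
        m = min(chunk, n - done)
        u = rng.random((m, len(probs)))
        hopped += int(np.any(u < probs[None, :], axis=1).sum())
        done += m
    return hopped / n
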