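"""Chirality-aware geometric analysis of trajectories.

Twist angle tau (circular mean of the two dihedrals spanning the central
C=C bond), P/M helicity labels, clockwise/anticlockwise directionality of
photoisomerization swarms, and photoproduct classification.  Works both on
reduced-coordinate model trajectories and on Cartesian XYZ trajectories
given a :class:`TwistSpec`.

Sign conventions: dihedrals follow the IUPAC convention (clockwise
rotation of the front bond onto the back bond, viewed from atom 2 toward
atom 3, is positive); tau > 0 is the P (right-handed) helix and evolves
toward +90 deg on S1, tau < 0 is M and evolves toward -90 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from prochir.pes import HALF_PI

__all__ = [
    "TwistSpec",
    "DirectionalitySummary",
    "dihedral",
    "twist_angle",
    "assign_helicity",
    "classify_photoproduct",
    "summarize",
    "UndefinedDihedralError",
]

#: |tau| below which helicity is reported as undetermined (deg)
HELICITY_DEAD_ZONE_DEG = 1.0
#: photoproduct thresholds, symmetric about the 90 deg intersection (deg)
CIS_MAX_DEG = 60.0
TRANS_MIN_DEG = 120.0
#: C4a-C4b distance below which a Cartesian frame counts as cyclized (A)
DHP_BOND_MAX_AA = 1.8


class UndefinedDihedralError(ValueError):
    """Collinear atoms leave the dihedral undefined."""


@dataclass(frozen=True)
class TwistSpec:
    """Two dihedral definitions (0-based atom indices) sharing the central
    C=C bond: both quadruples must have the same two middle atoms."""

    dihedral1: tuple
    dihedral2: tuple

    def __post_init__(self) -> None:
        d1, d2 = tuple(self.dihedral1), tuple(self.dihedral2)
        for d in (d1, d2):
            if len(d) != 4 or len(set(d)) != 4:
                raise ValueError(f"dihedral must be 4 distinct indices, got {d}")
        if (d1[1], d1[2]) != (d2[1], d2[2]):
            raise ValueError(
                "both dihedrals must span the same central bond (middle atoms)"
            )


@dataclass
class DirectionalitySummary:
    """Swarm-level rotation statistics.

    fraction_cw + fraction_acw <= 1 (unresolved trajectories allowed);
    product counts sum to n_valid.
    """

    n_total: int
    n_valid: int
    fraction_cw: float
    fraction_acw: float
    helicity_inversion_count: int
    products: dict = field(default_factory=dict)
    mean_time_to_ci_fs: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_valid": self.n_valid,
            "fraction_cw": self.fraction_cw,
            "fraction_acw": self.fraction_acw,
            "helicity_inversion_count": self.helicity_inversion_count,
            "products": dict(self.products),
            "mean_time_to_ci_fs": self.mean_time_to_ci_fs,
        }


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (-180, 180].

    Raises :class:`UndefinedDihedralError` when either bonded triple is
    collinear (or p2 == p3), which leaves a plane undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise UndefinedDihedralError("central atoms coincide")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    scale = max(np.linalg.norm(b0), 1.0) * 1e-9
    if nv < scale or nw < max(np.linalg.norm(b2), 1.0) * 1e-9:
        raise UndefinedDihedralError("collinear atoms: dihedral undefined")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def twist_angle(coords: np.ndarray, spec: TwistSpec) -> float:
    """Twist angle tau in degrees: circular mean of the two dihedrals.

    Averaging on the unit circle avoids the +-180 wrap artifact: dihedrals
    of 179 and -179 deg give tau = 180, not 0.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    for d in (spec.dihedral1, spec.dihedral2):
        if max(d) >= n or min(d) < 0:
            raise IndexError(f"dihedral indices {d} out of range for {n} atoms")
    d1 = dihedral(*(coords[i] for i in spec.dihedral1))
    d2 = dihedral(*(coords[i] for i in spec.dihedral2))
    r1, r2 = math.radians(d1), math.radians(d2)
    ang = math.degrees(
        math.atan2(0.5 * (math.sin(r1) + math.sin(r2)),
                   0.5 * (math.cos(r1) + math.cos(r2)))
    )
    if ang <= -180.0:
        ang += 360.0
    return ang


def assign_helicity(tau_deg: float, dead_zone_deg: float = HELICITY_DEAD_ZONE_DEG) -> str:
    """P for tau > 0, M for tau < 0, 'undetermined' inside the dead zone."""
    if abs(tau_deg) <= dead_zone_deg:
        return "undetermined"
    return "P" if tau_deg > 0 else "M"


def classify_photoproduct(tau_final_deg: float, dhp_flag: bool = False,
                          rotation_sense: str | None = None) -> str:
    """Classify the S0 photoproduct of a terminated trajectory.

    |tau| < 60 -> cis; |tau| > 120 -> trans; in between -> 'unresolved'.
    If ``dhp_flag`` marks cyclization the stereochemical label follows the
    rotation sense: CW (from P) gives the S,S product, ACW (from M) the
    R,R product.
    """
    if dhp_flag:
        if rotation_sense == "CW":
            return "DHP_SS"
        if rotation_sense == "ACW":
            return "DHP_RR"
        raise ValueError("DHP flag requires rotation_sense 'CW' or 'ACW'")
    a = abs(tau_final_deg)
    if a < CIS_MAX_DEG:
        return "cis"
    if a > TRANS_MIN_DEG:
        return "trans"
    return "unresolved"


def _first_crossing(tau: np.ndarray, threshold: float) -> tuple:
    """Index of first |tau| >= threshold and the sign reached, else (None, 0)."""
    hits = np.nonzero(np.abs(tau) >= threshold)[0]
    if len(hits) == 0:
        return None, 0
    i = int(hits[0])
    return i, (1 if tau[i] > 0 else -1)


def summarize(ensemble, ci_threshold: float = HALF_PI) -> DirectionalitySummary:
    """Directionality statistics of a model-trajectory swarm.

    CW = trajectory whose (unwrapped) tau first reaches +90 deg, ACW =
    first reaches -90 deg.  A helicity inversion is any sign change of the
    phi-well membership while the trajectory is on S1.  Deterministic and
    permutation-invariant.
    """
    trajs = [tr for tr in ensemble if tr.valid]
    n_total = len(list(ensemble))
    n_cw = n_acw = 0
    inversions = 0
    t_ci = []
    products: dict = {}
    for tr in trajs:
        idx, sign = _first_crossing(tr.tau, ci_threshold)
        if idx is not None:
            if sign > 0:
                n_cw += 1
            else:
                n_acw += 1
            t_ci.append(tr.t[idx])
        on_s1 = tr.state == 1
        sgn_phi = np.sign(tr.phi[on_s1])
        sgn_phi = sgn_phi[sgn_phi != 0]
        if len(sgn_phi) and np.any(sgn_phi[1:] != sgn_phi[:-1]):
            inversions += 1
        if tr.state[-1] == 0:
            sense = "CW" if sign > 0 else ("ACW" if sign < 0 else None)
            label = classify_photoproduct(
                math.degrees(tr.tau[-1]), dhp_flag=False, rotation_sense=sense
            )
        else:
            label = "excited"
        products[label] = products.get(label, 0) + 1
    n_valid = len(trajs)
    return DirectionalitySummary(
        n_total=n_total,
        n_valid=n_valid,
        fraction_cw=n_cw / n_valid if n_valid else 0.0,
        fraction_acw=n_acw / n_valid if n_valid else 0.0,
        helicity_inversion_count=inversions,
        products=products,
        mean_time_to_ci_fs=float(np.mean(t_ci)) if t_ci else float("nan"),
    )


def twist_series(frames, spec: TwistSpec) -> np.ndarray:
    """Twist angle (deg) for each frame of a Cartesian trajectory."""
    return np.array([twist_angle(f.coords if hasattr(f, "coords") else f, spec)
                     for f in frames])


def dhp_distance_flag(coords: np.ndarray, i: int, j: int,
                      d_max: float = DHP_BOND_MAX_AA) -> bool:
    """Cyclization detector for Cartesian frames: C4a-C4b bond formed when
    the distance drops below ``d_max`` Angstrom.  Provided for external
    trajectories; not exercised by the model surface (which has no
    cyclization coordinate)."""
    coords = np.asarray(coords, dtype=float)
    return bool(np.linalg.norm(coords[i] - coords[j]) < d_max)
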