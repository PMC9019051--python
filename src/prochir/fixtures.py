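"""Deterministic synthetic fixtures for every pipeline stage.

The fixture set stands in for deposited data: mirror-pair transition
tables (equal dipole strengths, opposite rotatory strengths), anisotropy
curves bounded by |g| < 0.01 with a DHP-like sign change inside the
230-350 nm window, toy Hessians with known spectra, hand-built geometries
with known dihedrals, and the P/M well pair of the model surface.
Everything is regenerable from a seed and checksummed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from prochir.chiroptics import BroadeningParams, SpectrumGrid, TransitionRecord, broaden, g_spectrum
from prochir.constants import nm_to_ev
from prochir.pes import SurfaceParams, preset

__all__ = ["FixtureSet", "make_fixtures"]


@dataclass
class FixtureSet:
    seed: int
    surface: SurfaceParams
    transitions_P: list
    transitions_M: list
    transitions_dhp: list
    wavelength_nm: np.ndarray
    g_stil: np.ndarray
    g_dhp: np.ndarray
    diatomic: dict
    triatomic: dict
    twist_geometry: np.ndarray
    twist_indices: dict = field(default_factory=dict)

    def checksum(self) -> str:
        h = hashlib.sha256()
        payload = {
            "seed": self.seed,
            "surface": self.surface.to_dict(),
            "transitions_P": [
                (t.energy_ev, t.dipole_strength, t.rotatory_strength)
                for t in self.transitions_P
            ],
            "transitions_dhp": [
                (t.energy_ev, t.dipole_strength, t.rotatory_strength)
                for t in self.transitions_dhp
            ],
        }
        h.update(json.dumps(payload, sort_keys=True).encode())
        for a in (self.wavelength_nm, self.g_stil, self.g_dhp, self.twist_geometry):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


def _twist_geometry(d1_deg: float = 10.0, d2_deg: float = 20.0) -> np.ndarray:
    """Six-point scaffold whose two central-bond dihedrals are d1 and d2.

    Atoms: [a1, b1, b2, c1, a2, c2]; dihedral(a1,b1,b2,c1) = d1 and
    dihedral(a2,b1,b2,c2) = d2, axis along z.
    """
    b1 = np.zeros(3)
    b2 = np.array([0.0, 0.0, 1.4])

    def on_ring(azimuth_deg, z):
        a = math.radians(azimuth_deg)
        return np.array([math.cos(a), math.sin(a), z])

    a1 = on_ring(0.0, -0.5)
    c1 = on_ring(d1_deg, 1.9)
    a2 = on_ring(180.0, -0.5)
    c2 = on_ring(180.0 + d2_deg, 1.9)
    return np.array([a1, b1, b2, c1, a2, c2])


def _toy_triatomic() -> dict:
    """Bent 3-atom system with three planted vibrational frequencies."""
    symbols = ["O", "H", "H"]
    masses = np.array([15.999, 1.008, 1.008])
    coords = np.array(
        [[0.0, 0.0, 0.0], [0.9578, 0.0, 0.0], [-0.2399, 0.9273, 0.0]]
    )
    planted_cm = np.array([1650.0, 3650.0, 3750.0])
    # build a Hessian with exactly these modes: pick orthonormal internal
    # vectors in the mass-weighted space orthogonal to rigid-body motions
    from prochir.wigner import MolecularGeometry, _rigid_body_projectors
    from prochir.constants import wavenumber_to_omega, AMU_AA2

    geom = MolecularGeometry(symbols, masses, coords)
    proj = _rigid_body_projectors(geom)
    # complete the basis; the 3 orthogonal complements carry the modes
    rnd = np.random.default_rng(2024).standard_normal((9, 3))
    basis = np.hstack([proj, rnd])
    q, _ = np.linalg.qr(basis)
    internal = q[:, proj.shape[1]: proj.shape[1] + 3]
    lam = (np.array([wavenumber_to_omega(nu) for nu in planted_cm])) ** 2
    Hmw = internal @ np.diag(lam) @ internal.T
    sq = np.sqrt(np.repeat(masses, 3) * AMU_AA2)
    H = Hmw * np.outer(sq, sq)
    return {
        "geometry": geom,
        "hessian": H,
        "planted_frequencies_cm": planted_cm,
    }


def make_fixtures(seed: int = 0) -> FixtureSet:
    """Build the deterministic fixture set for a seed."""
    rng = np.random.default_rng(seed)

    # mirror-pair transition tables for the helical enantiomers: two bands,
    # equal dipole strengths, opposite-signed rotatory strengths; Kuhn
    # factors kept below the |g| < 0.01 bound typical of small organics
    e1 = 4.30 + 0.02 * rng.standard_normal()
    e2 = 5.60 + 0.02 * rng.standard_normal()
    d1, d2 = 1.0, 0.65
    g1, g2 = 0.0052, -0.0074
    trans_p = [
        TransitionRecord(e1, d1, 0.25 * g1 * d1),
        TransitionRecord(e2, d2, 0.25 * g2 * d2),
    ]
    trans_m = [
        TransitionRecord(t.energy_ev, t.dipole_strength, -t.rotatory_strength)
        for t in trans_p
    ]
    # DHP-like pair: overlapping bands with opposite R so that g changes
    # sign inside the 230-350 nm scan window
    ed1 = 4.10 + 0.02 * rng.standard_normal()   # ~302 nm band
    ed2 = 4.96 + 0.02 * rng.standard_normal()   # ~250 nm band
    gd1, gd2 = 0.0061, -0.0085
    trans_d = [
        TransitionRecord(ed1, 0.9, 0.25 * gd1 * 0.9),
        TransitionRecord(ed2, 1.1, 0.25 * gd2 * 1.1),
    ]

    lam = np.linspace(200.0, 400.0, 401)
    grid = nm_to_ev(lam)[::-1]  # increasing energy
    bp = BroadeningParams(width=0.35, convention="fwhm")
    g_stil = g_spectrum(broaden(trans_p, bp, grid))[::-1]
    g_dhp = g_spectrum(broaden(trans_d, bp, grid))[::-1]

    diatomic = {
        "symbols": ["C", "O"],
        "masses": np.array([12.011, 15.999]),
        "force_constant": 620.0,  # kcal/mol/A^2
        "bond_length": 1.13,
        "reduced_mass": 12.011 * 15.999 / (12.011 + 15.999),
    }

    return FixtureSet(
        seed=seed,
        surface=preset("stilbene"),
        transitions_P=trans_p,
        transitions_M=trans_m,
        transitions_dhp=trans_d,
        wavelength_nm=lam,
        g_stil=g_stil,
        g_dhp=g_dhp,
        diatomic=diatomic,
        triatomic=_toy_triatomic(),
        twist_geometry=_twist_geometry(),
        twist_indices={"dihedral1": (0, 1, 2, 3), "dihedral2": (4, 1, 2, 5)},
    )
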