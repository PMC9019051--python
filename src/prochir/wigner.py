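"""0 K harmonic Wigner phase-space sampling.

Normal-mode analysis (mass-weighting, Eckart rigid-body projection,
diagonalization) plus sampling of the ground-vibrational-state Wigner
function: per retained mode the mass-weighted coordinate and momentum are
independent zero-mean Gaussians with

    Var(Q) = hbar / (2 omega),      Var(P) = hbar omega / 2,

the minimum-uncertainty distribution (sigma_Q sigma_P = hbar/2).

Works for full Cartesian molecules given a Hessian (kcal/mol/A^2, amu
masses) and for the 2D reduced-coordinate model wells (masses = inertias).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from prochir.constants import AMU_AA2, HBAR, omega_to_wavenumber

__all__ = [
    "MolecularGeometry",
    "NormalModeSet",
    "PhaseSpaceEnsemble",
    "build_normal_modes",
    "sample_wigner",
    "subselect",
    "NotAMinimumError",
]

#: modes with |wavenumber| below this are treated as rigid-body remnants
ZERO_MODE_TOL_CM = 5.0


class NotAMinimumError(ValueError):
    """Hessian has a retained imaginary frequency beyond tolerance."""


@dataclass
class MolecularGeometry:
    """Elements, masses (amu) and Cartesian coordinates (Angstrom)."""

    symbols: list[str]
    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.symbols)
        if self.masses.shape != (n,):
            raise ValueError("masses shape inconsistent with atom count")
        if self.coords.shape != (n, 3):
            raise ValueError("coords shape inconsistent with atom count")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be > 0")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


@dataclass
class NormalModeSet:
    """Retained positive-frequency normal modes.

    frequencies : wavenumbers in cm^-1 (all > 0)
    omega : angular frequencies in fs^-1 (internal energy units)
    modes : (n_modes, n_dof) orthonormal mass-weighted displacement vectors
    masses_dof : per-degree-of-freedom masses used for mass weighting
        (amu repeated 3x per atom for Cartesian input; inertias for the
        2D model)
    reference : flattened reference coordinates (minimum)
    n_projected : number of rigid-body modes projected out
    """

    frequencies: np.ndarray
    omega: np.ndarray
    modes: np.ndarray
    masses_dof: np.ndarray
    reference: np.ndarray
    n_projected: int = 0
    geometry: MolecularGeometry | None = None

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for a in (self.frequencies, self.modes, self.masses_dof, self.reference):
            h.update(np.ascontiguousarray(a, dtype=float).tobytes())
        return h.hexdigest()[:16]


@dataclass
class PhaseSpaceEnsemble:
    """List of sampled (positions, momenta) pairs with provenance.

    positions/momenta have shape (n, n_dof) in the original (non
    mass-weighted) coordinates; momenta in mass * coordinate / fs units.
    """

    positions: np.ndarray
    momenta: np.ndarray
    seed: int
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int):
        return self.positions[i], self.momenta[i]


def _rigid_body_projectors(geometry: MolecularGeometry) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (Eckart)."""
    m = geometry.masses
    x = geometry.coords - np.average(geometry.coords, axis=0, weights=m)
    n = geometry.n_atoms
    sq = np.sqrt(m)
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sq
        vecs.append(v.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        v = (np.cross(x, e[None, :] * np.ones((n, 3))) * sq[:, None]).ravel()
        vecs.append(v)
    V = np.array(vecs).T  # (3N, 6)
    # orthonormalize, dropping null rotations (linear molecules)
    q, r = np.linalg.qr(V)
    keep = np.abs(np.diag(r)) > 1e-8 * np.max(np.abs(np.diag(r)))
    return q[:, keep]


def build_normal_modes(
    geometry: MolecularGeometry | None,
    hessian: np.ndarray,
    masses: np.ndarray | None = None,
) -> NormalModeSet:
    """Harmonic analysis of a symmetric Hessian.

    For Cartesian input (``geometry`` given) the Hessian is in
    kcal/mol/A^2, is mass-weighted with amu masses, and the 5/6 rigid-body
    modes are projected out before diagonalization.  For reduced-coordinate
    wells pass ``geometry=None`` and ``masses`` = the inertias
    (kcal/mol fs^2); no projection is applied.

    Raises :class:`NotAMinimumError` if a retained frequency is imaginary
    beyond the 5 cm^-1 zero-mode tolerance.
    """
    H = np.asarray(hessian, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("hessian must be square")
    if not np.allclose(H, H.T, atol=1e-8 * max(1.0, np.abs(H).max())):
        raise ValueError("hessian must be symmetric")

    if geometry is not None:
        n_dof = 3 * geometry.n_atoms
        if H.shape[0] != n_dof:
            raise ValueError("hessian dimension must be 3N")
        masses_dof = np.repeat(geometry.masses, 3) * AMU_AA2
        reference = geometry.coords.ravel().copy()
        proj = _rigid_body_projectors(geometry)
    else:
        if masses is None:
            raise ValueError("masses required when no geometry is given")
        masses_dof = np.asarray(masses, dtype=float)
        if masses_dof.shape != (H.shape[0],):
            raise ValueError("masses shape must match hessian")
        reference = np.zeros(H.shape[0])
        proj = None

    sq = np.sqrt(masses_dof)
    Hmw = H / np.outer(sq, sq)

    if proj is not None:
        P = np.eye(len(masses_dof)) - proj @ proj.T
        Hmw = P @ Hmw @ P
        n_projected = proj.shape[1]
    else:
        n_projected = 0

    evals, evecs = np.linalg.eigh(0.5 * (Hmw + Hmw.T))
    omega = np.sign(evals) * np.sqrt(np.abs(evals))  # fs^-1 (signed)
    nu = np.array([omega_to_wavenumber(w) for w in omega])

    zero = np.abs(nu) < ZERO_MODE_TOL_CM
    if proj is not None and zero.sum() < n_projected:
        # rigid-body projection should have produced that many null modes
        raise NotAMinimumError(
            f"expected {n_projected} zero modes, found {zero.sum()}"
        )
    retained = ~zero
    if np.any(nu[retained] < 0):
        bad = nu[retained][nu[retained] < 0]
        raise NotAMinimumError(
            f"imaginary retained frequencies (cm^-1): {np.round(bad, 2)}"
        )

    order = np.argsort(nu[retained])
    return NormalModeSet(
        frequencies=nu[retained][order],
        omega=omega[retained][order],
        modes=evecs[:, retained][:, order].T.copy(),
        masses_dof=masses_dof,
        reference=reference,
        n_projected=n_projected,
        geometry=geometry,
    )


def sample_wigner(modes: NormalModeSet, n: int, seed: int) -> PhaseSpaceEnsemble:
    """Draw ``n`` phase-space points from the 0 K harmonic Wigner function.

    Pure function of (modes, n, seed); reproducible bit-for-bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if np.any(modes.omega <= 0):
        raise ValueError("all retained frequencies must be positive")
    rng = np.random.default_rng(seed)
    nm = modes.n_modes
    sig_q = np.sqrt(HBAR / (2.0 * modes.omega))
    sig_p = np.sqrt(HBAR * modes.omega / 2.0)
    Q = rng.standard_normal((n, nm)) * sig_q
    P = rng.standard_normal((n, nm)) * sig_p
    sq = np.sqrt(modes.masses_dof)
    # back-transform: x = x_ref + M^-1/2 L Q ; p = M^1/2 L P
    disp = (Q @ modes.modes) / sq
    mom = (P @ modes.modes) * sq
    return PhaseSpaceEnsemble(
        positions=modes.reference + disp,
        momenta=mom,
        seed=seed,
        provenance={"mode_set": modes.fingerprint(), "n": n, "kind": "wigner0K"},
    )


def model_well_modes(params, well: str = "P") -> NormalModeSet:
    """Normal modes of the S0 enantiomer well of the reduced model surface.

    Central-difference Hessian of the lower adiabat at the P (+tau0,
    +phi0) or M (-tau0, -phi0) minimum, mass-weighted with the reduced
    inertias; the returned mode set carries the well position as its
    reference so Wigner samples land around the correct enantiomer.
    """
    from prochir.pes import TwoStateSurface

    if well not in ("P", "M"):
        raise ValueError("well must be 'P' or 'M'")
    surf = TwoStateSurface(params) if not hasattr(params, "eval_raw") else params
    sgn = 1.0 if well == "P" else -1.0
    x0 = np.array([sgn * surf.params.tau0, sgn * surf.params.phi0])

    def e0(x):
        return surf.eval_raw(x[0], x[1])[0]

    h = 1e-4
    H = np.zeros((2, 2))
    e_c = e0(x0)
    for i in range(2):
        ei = np.eye(2)[i] * h
        H[i, i] = (e0(x0 + ei) - 2 * e_c + e0(x0 - ei)) / h**2
    ei, ej = np.eye(2) * h
    H[0, 1] = H[1, 0] = (
        e0(x0 + ei + ej) - e0(x0 + ei - ej) - e0(x0 - ei + ej) + e0(x0 - ei - ej)
    ) / (4 * h**2)
    modes = build_normal_modes(None, H, masses=np.array([surf.I_tau, surf.I_phi]))
    modes.reference = x0
    return modes


def subselect(ensemble: PhaseSpaceEnsemble, k: int, seed: int) -> PhaseSpaceEnsemble:
    """Uniform random subset of ``k`` members without replacement.

    Members keep their original relative order.  With ``k == len`` this is
    the identity (same members, same order).
    """
    if k > len(ensemble):
        raise ValueError(f"cannot select {k} from {len(ensemble)} samples")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(ensemble), size=k, replace=False))
    return PhaseSpaceEnsemble(
        positions=ensemble.positions[idx].copy(),
        momenta=ensemble.momenta[idx].copy(),
        seed=seed,
        provenance={
            **ensemble.provenance,
            "parent_seed": ensemble.seed,
            "selection_seed": seed,
            "selected": k,
        },
    )
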