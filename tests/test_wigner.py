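import math

import numpy as np
import pytest
from scipy import constants as sc

from prochir.constants import HBAR
from prochir.wigner import (
    MolecularGeometry,
    NotAMinimumError,
    build_normal_modes,
    model_well_modes,
    sample_wigner,
    subselect,
)


def diatomic_hessian(k, axis=np.array([0.0, 0.0, 1.0])):
    """3D Hessian of a harmonic bond along ``axis``: k (u u^T) blocks."""
    P = k * np.outer(axis, axis)
    H = np.zeros((6, 6))
    H[:3, :3] = P
    H[3:, 3:] = P
    H[:3, 3:] = -P
    H[3:, :3] = -P
    return H


@pytest.fixture()
def co_modes():
    m1, m2 = 12.011, 15.999
    geom = MolecularGeometry(
        ["C", "O"], np.array([m1, m2]),
        np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.13]]),
    )
    return build_normal_modes(geom, diatomic_hessian(620.0)), m1 * m2 / (m1 + m2)


class TestNormalModes:
    def test_diatomic_frequency_closed_form(self, co_modes):
        modes, mu = co_modes
        assert modes.n_modes == 1  # linear molecule: 3N - 5
        # independent oracle: omega = sqrt(k/mu) in SI -> cm^-1
        k_si = 620.0 * 4184.0 / sc.Avogadro / 1e-20  # J/m^2
        omega_si = math.sqrt(k_si / (mu * sc.atomic_mass))
        nu_cm = omega_si / (2 * math.pi * sc.c * 100.0)
        assert modes.frequencies[0] == pytest.approx(nu_cm, rel=1e-10)

    def test_triatomic_planted_spectrum(self, fixture_set):
        toy = fixture_set.triatomic
        modes = build_normal_modes(toy["geometry"], toy["hessian"])
        assert modes.n_modes == 3  # nonlinear: 3N - 6
        np.testing.assert_allclose(
            modes.frequencies, sorted(toy["planted_frequencies_cm"]), rtol=1e-8
        )

    def test_mode_vectors_orthonormal(self, fixture_set):
        toy = fixture_set.triatomic
        modes = build_normal_modes(toy["geometry"], toy["hessian"])
        gram = modes.modes @ modes.modes.T
        np.testing.assert_allclose(gram, np.eye(modes.n_modes), atol=1e-10)

    def test_imaginary_frequency_raises(self, fixture_set):
        toy = fixture_set.triatomic
        with pytest.raises(NotAMinimumError):
            build_normal_modes(toy["geometry"], -toy["hessian"])

    def test_asymmetric_hessian_rejected(self, fixture_set):
        toy = fixture_set.triatomic
        H = toy["hessian"].copy()
        H[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            build_normal_modes(toy["geometry"], H)

    def test_model_well_modes_are_2d(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        assert modes.n_modes == 2
        assert modes.n_projected == 0
        assert np.all(modes.frequencies > 0)
        np.testing.assert_allclose(
            modes.reference, [stilbene.tau0, stilbene.phi0], atol=1e-12
        )


N_BIG = 100_000


@pytest.fixture(scope="module")
def big_sample(stilbene):
    modes = model_well_modes(stilbene, "P")
    return modes, sample_wigner(modes, N_BIG, seed=11)


class TestWignerSampling:
    N = N_BIG

    def test_variances_match_wigner_widths(self, big_sample):
        modes, ens = big_sample
        # project back onto each mass-weighted mode and check Var(Q), Var(P)
        sq = np.sqrt(modes.masses_dof)
        dq = (ens.positions - modes.reference) * sq
        dp = ens.momenta / sq
        for i, w in enumerate(modes.omega):
            Q = dq @ modes.modes[i]
            P = dp @ modes.modes[i]
            var_q_exp = HBAR / (2 * w)
            var_p_exp = HBAR * w / 2
            se_q = var_q_exp * math.sqrt(2 / self.N)
            se_p = var_p_exp * math.sqrt(2 / self.N)
            assert abs(Q.var() - var_q_exp) < 3 * se_q
            assert abs(P.var() - var_p_exp) < 3 * se_p
            # minimum-uncertainty product
            prod = Q.std() * P.std()
            assert prod == pytest.approx(HBAR / 2, rel=5 * math.sqrt(2 / self.N))

    def test_mean_energy_per_mode_is_zero_point(self, big_sample):
        modes, ens = big_sample
        sq = np.sqrt(modes.masses_dof)
        dq = (ens.positions - modes.reference) * sq
        dp = ens.momenta / sq
        for i, w in enumerate(modes.omega):
            Q = dq @ modes.modes[i]
            P = dp @ modes.modes[i]
            e = 0.5 * (P**2).mean() + 0.5 * w**2 * (Q**2).mean()
            se = (HBAR * w / 2) * math.sqrt(2 / self.N)
            assert abs(e - HBAR * w / 2) < 3 * se

    def test_mean_geometry_unbiased(self, big_sample):
        modes, ens = big_sample
        for j in range(2):
            se = ens.positions[:, j].std() / math.sqrt(self.N)
            assert abs(ens.positions[:, j].mean() - modes.reference[j]) < 3 * se

    def test_seeded_reproducibility_bitwise(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        a = sample_wigner(modes, 50, seed=5)
        b = sample_wigner(modes, 50, seed=5)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.momenta, b.momenta)

    def test_sampling_does_not_mutate_modes(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        fp = modes.fingerprint()
        sample_wigner(modes, 10, seed=1)
        assert modes.fingerprint() == fp

    def test_invalid_n_rejected(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        with pytest.raises(ValueError):
            sample_wigner(modes, 0, seed=1)


class TestSubselect:
    def test_identity_when_k_equals_size(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        ens = sample_wigner(modes, 20, seed=2)
        sub = subselect(ens, 20, seed=3)
        assert np.array_equal(sub.positions, ens.positions)

    def test_thirty_of_five_hundred_unique(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        ens = sample_wigner(modes, 500, seed=2)
        sub = subselect(ens, 30, seed=3)
        assert len(sub) == 30
        assert len(np.unique(sub.positions, axis=0)) == 30
        assert sub.provenance["parent_seed"] == 2

    def test_fixed_seeds_identical_subsets(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        ens = sample_wigner(modes, 100, seed=2)
        a = subselect(ens, 10, seed=9)
        b = subselect(ens, 10, seed=9)
        assert np.array_equal(a.positions, b.positions)

    def test_oversized_selection_rejected(self, stilbene):
        modes = model_well_modes(stilbene, "P")
        ens = sample_wigner(modes, 10, seed=2)
        with pytest.raises(ValueError):
            subselect(ens, 11, seed=0)
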