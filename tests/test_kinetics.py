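import math

import numpy as np
import pytest
from scipy import integrate

from prochir.kinetics import (
    SPECIES,
    AnisotropyPair,
    DegenerateSchemeError,
    RateConstants,
    SpeciesState,
    build_rate_matrix,
    ee_closed_form,
    ee_from_state,
    ee_limits,
    photostationary_state,
    scheme_ee,
    wavelength_scan,
)

INIT = SpeciesState([1.0, 1.0, 0.0, 0.0, 0.0])

#: permutation swapping M<->P and RR<->SS (enantiomer relabeling)
SWAP = np.array([1, 0, 2, 4, 3])


def random_rates(rng):
    return RateConstants(*rng.uniform(0.05, 5.0, 5))


class TestGenerator:
    def test_achiral_light_symmetric_under_enantiomer_swap(self):
        K = build_rate_matrix(RateConstants(), AnisotropyPair(0.0, 0.0))
        np.testing.assert_array_equal(K, K[np.ix_(SWAP, SWAP)])

    def test_columns_sum_to_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            K = build_rate_matrix(
                random_rates(rng), AnisotropyPair(*rng.uniform(-0.5, 0.5, 2))
            )
            assert np.abs(K.sum(axis=0)).max() < 1e-14 * max(np.abs(K).max(), 1.0)

    def test_negating_g_equals_enantiomer_swap(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            rc = random_rates(rng)
            gs, gd = rng.uniform(-0.3, 0.3, 2)
            K = build_rate_matrix(rc, AnisotropyPair(gs, gd))
            K_neg = build_rate_matrix(rc, AnisotropyPair(-gs, -gd))
            np.testing.assert_allclose(K_neg, K[np.ix_(SWAP, SWAP)], atol=1e-15)

    def test_kuhn_convention_halves_the_asymmetry(self):
        rc = RateConstants()
        g = AnisotropyPair(0.2, 0.0)
        K_kin = build_rate_matrix(rc, g, convention="kinetic")
        K_kuhn = build_rate_matrix(rc, g, convention="kuhn")
        # outflow from M scales with 1+g vs 1+g/2
        assert K_kin[2, 0] / K_kuhn[2, 0] == pytest.approx(1.2 / 1.1, rel=1e-12)

    def test_excessive_g_rejected(self):
        with pytest.raises(ValueError):
            AnisotropyPair(1.0, 0.0)


class TestPhotostationaryState:
    def test_achiral_light_gives_racemic_dhp(self):
        K = build_rate_matrix(RateConstants(), AnisotropyPair(0.0, 0.0))
        s = photostationary_state(K, INIT)
        assert s.c[3] == pytest.approx(s.c[4], rel=1e-12)
        assert ee_from_state(s) < 1e-12

    def test_total_concentration_preserved(self):
        K = build_rate_matrix(RateConstants(), AnisotropyPair(0.01, -0.02))
        for method in ("nullspace", "ode"):
            s = photostationary_state(K, INIT, method)
            assert s.total == pytest.approx(INIT.total, rel=1e-10)

    def test_ode_and_nullspace_agree(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            K = build_rate_matrix(
                random_rates(rng), AnisotropyPair(*rng.uniform(-0.05, 0.05, 2))
            )
            a = photostationary_state(K, INIT, "nullspace")
            b = photostationary_state(K, INIT, "ode")
            np.testing.assert_allclose(a.c, b.c, rtol=1e-9, atol=1e-9 * INIT.total)

    def test_matches_scheme_closed_form(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            rc = random_rates(rng)
            an = AnisotropyPair(*rng.uniform(-0.05, 0.05, 2))
            s = photostationary_state(build_rate_matrix(rc, an), INIT)
            assert ee_from_state(s) == pytest.approx(scheme_ee(rc, an), abs=1e-10)

    def test_fast_isomerization_steady_state(self):
        rc = RateConstants(k_ct=1e6, k_cD=4 / 52 * 1e6, k_Dc=1.0, k_tc=1.0, k_rac=1.0)
        s = photostationary_state(build_rate_matrix(rc, AnisotropyPair(0.001, 0.0023)), INIT)
        assert ee_from_state(s) == pytest.approx(0.0023, abs=1e-6)

    def test_fast_racemization_steady_state(self):
        rc = RateConstants(k_ct=1.0, k_rac=1e6)
        s = photostationary_state(build_rate_matrix(rc, AnisotropyPair(0.01, 0.02)), INIT)
        expected = (0.02 - 0.01) / (1 - 0.0002)
        assert ee_from_state(s) == pytest.approx(expected, abs=1e-6)

    def test_absorbing_dhp_detected_as_degenerate(self):
        rc = RateConstants(k_Dc=0.0)
        K = build_rate_matrix(rc, AnisotropyPair(0.01, 0.0))
        with pytest.raises(DegenerateSchemeError):
            photostationary_state(K, INIT, "nullspace")

    def test_handedness_switch_preserves_ee_and_swaps_excess(self):
        rc = RateConstants()
        an = AnisotropyPair(0.01, 0.02)
        s1 = photostationary_state(build_rate_matrix(rc, an), INIT)
        s2 = photostationary_state(
            build_rate_matrix(rc, AnisotropyPair(-0.01, -0.02)), INIT
        )
        assert ee_from_state(s1) == pytest.approx(ee_from_state(s2), rel=1e-9)
        assert (s1.c[4] - s1.c[3]) == pytest.approx(-(s2.c[4] - s2.c[3]), rel=1e-9)

    def test_zero_initial_total_rejected(self):
        K = build_rate_matrix(RateConstants(), AnisotropyPair(0.0, 0.0))
        with pytest.raises(ValueError):
            photostationary_state(K, SpeciesState(np.zeros(5)))


class TestClosedForm:
    def test_zero_g_gives_zero(self):
        assert ee_closed_form(1.0, 1.0, 0.0, 0.0).ee == 0.0

    def test_direct_substitution(self):
        # 0.0398 / 2.9896
        res = ee_closed_form(1.0, 1.0, 0.01, 0.02)
        assert res.ee == pytest.approx(0.0398 / 2.9896, rel=1e-12)

    def test_no_racemization_reduces_to_g_dhp(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            gs, gd = rng.uniform(-0.5, 0.5, 2)
            kct = rng.uniform(1e-3, 1e3)
            assert ee_closed_form(kct, 0.0, gs, gd).ee == pytest.approx(
                abs(gd), abs=1e-12
            )

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ee_closed_form(0.0, 0.0, 0.0, 0.0)


class TestLimits:
    def test_three_regimes(self):
        lims = ee_limits(0.01, 0.02)
        assert lims["fast_isomerization"].ee == 0.02
        assert lims["fast_racemization"].ee == pytest.approx(
            0.01 / (1 - 0.0002), rel=1e-12
        )
        assert lims["comparable"].ee == ee_closed_form(1.0, 1.0, 0.01, 0.02).ee

    def test_equal_g_kills_fast_racemization_ee(self):
        assert ee_limits(0.007, 0.007)["fast_racemization"].ee == 0.0

    def test_full_scheme_approaches_limits(self):
        an = AnisotropyPair(0.004, -0.006)
        for ratio, regime in ((1e8, "fast_isomerization"), (1e-8, "fast_racemization")):
            rc = RateConstants(k_ct=ratio, k_cD=4 / 52 * ratio, k_rac=1.0)
            s = photostationary_state(build_rate_matrix(rc, an), INIT)
            assert ee_from_state(s) == pytest.approx(
                ee_limits(an.g_stil, an.g_DHP)[regime].ee, abs=1e-6
            )

    def test_first_order_consistency_with_scheme(self):
        """For |g| <= 1e-3 the closed form and the five-species scheme
        agree to O(g^2) at intermediate rate ratios."""
        rng = np.random.default_rng(9)
        for _ in range(40):
            gs, gd = rng.uniform(-1e-3, 1e-3, 2)
            rc = random_rates(rng)
            s = photostationary_state(build_rate_matrix(rc, AnisotropyPair(gs, gd)), INIT)
            full = ee_from_state(s)
            eq = ee_closed_form(rc.k_ct, rc.k_rac, gs, gd).ee
            g2 = max(abs(gs), abs(gd)) ** 2
            assert abs(full - eq) < 10 * g2

    def test_branching_ratio_does_not_move_asymptotic_ee(self):
        an = AnisotropyPair(0.005, 0.011)
        for kcd in (0.01, 4 / 52, 0.5):
            rc = RateConstants(k_ct=1e8, k_cD=kcd * 1e8, k_rac=1.0)
            s = photostationary_state(build_rate_matrix(rc, an), INIT)
            assert ee_from_state(s) == pytest.approx(0.011, abs=1e-6)


class TestConservation:
    def test_total_constant_along_ode(self):
        K = build_rate_matrix(RateConstants(), AnisotropyPair(0.01, -0.02))
        sol = integrate.solve_ivp(
            lambda t, y: K @ y, (0, 50.0), INIT.c, method="Radau",
            jac=lambda t, y: K, rtol=1e-12, atol=1e-14,
        )
        totals = sol.y.sum(axis=0)
        assert np.abs(totals - INIT.total).max() < 1e-10 * INIT.total


class TestWavelengthScan:
    def test_constant_curves_give_regime_value(self):
        lam = np.linspace(230, 350, 121)
        res = wavelength_scan(lam, np.full_like(lam, 0.001),
                              np.full_like(lam, 0.002))
        assert np.allclose(res["ee"], 0.002)
        assert res["ee_max"] == pytest.approx(0.002)

    def test_sign_change_maximum_matches_grid_search(self, fixture_set):
        lam, gs, gd = fixture_set.wavelength_nm, fixture_set.g_stil, fixture_set.g_dhp
        for regime in ("fast_isomerization", "fast_racemization", "comparable"):
            res = wavelength_scan(lam, gs, gd, regime=regime)
            # exhaustive oracle over the window
            best = -1.0
            for l, a, b in zip(lam, gs, gd):
                if not (230 <= l <= 350) or math.isnan(a) or math.isnan(b):
                    continue
                if regime == "fast_isomerization":
                    v = abs(b)
                elif regime == "fast_racemization":
                    v = abs(b - a) / (1 - a * b)
                else:
                    v = ee_closed_form(1.0, 1.0, a, b).ee
                if v > best:
                    best, lbest = v, l
            assert res["ee_max"] == pytest.approx(best, rel=1e-12)
            assert res["lambda_max_nm"] == lbest

    def test_dhp_g_changes_sign_inside_window(self, fixture_set):
        sel = (fixture_set.wavelength_nm >= 230) & (fixture_set.wavelength_nm <= 350)
        g = fixture_set.g_dhp[sel]
        g = g[np.isfinite(g)]
        assert g.min() < 0 < g.max()

    def test_empty_window_rejected(self):
        lam = np.linspace(230, 350, 12)
        with pytest.raises(ValueError):
            wavelength_scan(lam, lam * 0, lam * 0, window=(500, 600))

    def test_undefined_points_skipped_and_reported(self):
        lam = np.linspace(230, 350, 13)
        gs = np.full_like(lam, 0.001)
        gd = np.full_like(lam, 0.002)
        gs[3] = np.nan
        res = wavelength_scan(lam, gs, gd)
        assert res["n_skipped"] == 1
        assert np.isnan(res["ee"][3])
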