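import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from canopyrue.structure import (
    AMAX_CEILING,
    LIA_MEANS_DEG,
    amax_from_sln,
    beta_normalizer,
    calibrate_lia,
    cumulative_lai,
    leaf_area_profile,
    lia_class_frequencies,
    lia_density,
    nitrogen_distribution_family,
    nitrogen_profile,
)

shape_params = st.floats(min_value=0.5, max_value=15.0)


class TestBetaNormalizer:
    def test_uniform_case(self):
        assert beta_normalizer(1, 1) == pytest.approx(1.0)

    def test_gamma_arithmetic(self):
        assert beta_normalizer(2, 2) == pytest.approx(1.0 / 6.0)

    def test_symmetry(self):
        assert beta_normalizer(3, 5) == pytest.approx(beta_normalizer(5, 3))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            beta_normalizer(0, 1)


class TestLiaDensity:
    def test_uniform_density(self):
        b = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(lia_density(b, 1, 1), 1.0)

    def test_integrates_to_one(self):
        total, _ = quad(lambda b: lia_density(b, 4, 7), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_mean_matches_closed_form(self):
        # mean of b under f(b) = (1-b)^(mu-1) b^(nu-1) / B is nu/(mu+nu)
        mean, _ = quad(lambda b: b * lia_density(b, 4, 7), 0, 1)
        assert mean == pytest.approx(7.0 / 11.0, abs=1e-8)

    def test_rejects_boundary_b(self):
        with pytest.raises(ValueError):
            lia_density(0.0, 2, 2)


class TestClassFrequencies:
    def test_uniform_gives_equal_classes(self):
        np.testing.assert_allclose(lia_class_frequencies(1, 1), 1.0 / 9.0)

    @given(mu=shape_params, nu=shape_params)
    @settings(max_examples=30, deadline=None)
    def test_total_probability(self, mu, nu):
        assert lia_class_frequencies(mu, nu).sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("mu,nu", [(4.0, 7.0), (1.5, 1.5), (9.0, 2.0)])
    def test_matches_adaptive_quadrature(self, mu, nu):
        f_a = lia_class_frequencies(mu, nu)
        edges = np.linspace(0, 1, 10)
        for a in range(9):
            expected, _ = quad(lambda b: lia_density(b, mu, nu), edges[a], edges[a + 1])
            assert f_a[a] == pytest.approx(expected, abs=1e-8)


class TestCalibrateLia:
    def test_symmetric_at_45(self):
        d = calibrate_lia(45.0)
        assert d.mu == pytest.approx(d.nu)

    @pytest.mark.parametrize("mean", [13.30, 76.70])
    def test_candidate_extremes_self_consistent(self, mean):
        d = calibrate_lia(mean)
        realized, _ = quad(lambda b: 90.0 * b * lia_density(b, d.mu, d.nu), 0, 1)
        assert realized == pytest.approx(mean, abs=0.01)

    @pytest.mark.parametrize("mean", list(range(5, 90, 10)))
    def test_left_inverse_of_density_mean(self, mean):
        assert calibrate_lia(float(mean)).mean_angle == pytest.approx(mean, abs=0.01)

    def test_discretized_mean_within_half_class(self):
        for mean in LIA_MEANS_DEG:
            d = calibrate_lia(mean)
            disc = float(d.f_a @ np.arange(5.0, 90.0, 10.0))
            assert abs(disc - mean) < 5.0

    def test_rejects_out_of_range_mean(self):
        with pytest.raises(ValueError):
            calibrate_lia(95.0)


class TestLeafAreaProfile:
    def test_boundary_values(self):
        p = leaf_area_profile(5.0, 0.5)
        assert p.clai[0] == 0.0
        assert p.clai[-1] == pytest.approx(5.0)

    def test_closed_form_midpoint(self):
        # LAI 5, peak depth 0.5, z 0.5: 5 * 2 * 0.25 = 2.5
        assert cumulative_lai(0.5, 5.0, 0.5) == pytest.approx(2.5)

    def test_layer_areas_sum_and_sign(self):
        for zm in [0.3, 0.5, 0.7]:
            p = leaf_area_profile(4.0, zm)
            assert p.lap.sum() == pytest.approx(4.0, abs=1e-9)
            assert np.all(p.lap >= 0)

    def test_peak_layer_tracks_zm(self):
        assert leaf_area_profile(5.0, 0.3).modal_layer < leaf_area_profile(5.0, 0.7).modal_layer

    def test_rejects_degenerate_zm(self):
        with pytest.raises(ValueError):
            leaf_area_profile(5.0, 1.0)


class TestAmaxFromSln:
    def test_zero_at_logistic_midpoint(self):
        assert amax_from_sln(0.25) == 0.0

    def test_asymptote(self):
        assert amax_from_sln(100.0) == pytest.approx(AMAX_CEILING)
        assert AMAX_CEILING == pytest.approx(46.458, abs=1e-3)

    def test_worked_value(self):
        assert amax_from_sln(1.0) == pytest.approx(43.85, abs=0.01)

    def test_monotone_and_bounded(self):
        sln = np.linspace(0.0, 5.0, 200)
        a = amax_from_sln(sln)
        assert np.all(np.diff(a) >= 0) and np.all(a <= AMAX_CEILING) and np.all(a >= 0)

    def test_clamped_below_operating_range(self):
        assert np.all(amax_from_sln(np.array([0.0, 0.1, 0.2])) == 0.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            amax_from_sln(-0.1)


class TestNitrogenProfile:
    def test_uniform_everything_gives_constant_sln(self):
        p = leaf_area_profile(5.0, 0.5)
        # synthetic uniform-layer profile: equal LAP by construction
        import dataclasses
        uniform = dataclasses.replace(
            p, clai=np.linspace(0, 5, 11), lap=np.full(10, 0.5)
        )
        n = nitrogen_profile(np.full(10, 0.1), 900.0, uniform, rho=6.5)
        np.testing.assert_allclose(n.sln, n.sln[0])

    def test_layer_arithmetic(self):
        # LAP 0.5, rho 6.5, fraction 0.1 of 900 mg: LA = 0.07692 m2, SLN = 1.17 g/m2
        import dataclasses
        p = leaf_area_profile(5.0, 0.5)
        uniform = dataclasses.replace(p, clai=np.linspace(0, 5, 11), lap=np.full(10, 0.5))
        n = nitrogen_profile(np.full(10, 0.1), 900.0, uniform, rho=6.5)
        assert n.la_m2[0] == pytest.approx(0.076923, abs=1e-6)
        assert n.sln[0] == pytest.approx(1.17, abs=1e-6)

    def test_nitrogen_conserved(self):
        p = leaf_area_profile(3.0, 0.4)
        fracs = nitrogen_distribution_family()[12]
        n = nitrogen_profile(fracs, 900.0, p, rho=6.5)
        assert n.lnc_mg.sum() == pytest.approx(900.0, abs=1e-6)

    def test_rejects_nitrogen_without_leaf_area(self):
        import dataclasses
        p = leaf_area_profile(5.0, 0.5)
        degenerate = dataclasses.replace(
            p, lap=np.r_[0.0, np.full(9, 5.0 / 9.0)],
            clai=np.r_[0.0, np.cumsum(np.r_[0.0, np.full(9, 5.0 / 9.0)])][:11],
        )
        with pytest.raises(ValueError):
            nitrogen_profile(np.full(10, 0.1), 900.0, degenerate)


class TestNitrogenFamily:
    def test_each_member_sums_to_one(self):
        for fracs in nitrogen_distribution_family():
            assert fracs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_modal_layers_move_top_to_bottom(self):
        family = nitrogen_distribution_family()
        modal = [int(np.argmax(f)) for f in family]
        assert modal == sorted(modal)
        assert modal[0] < 4 and modal[-1] > 6

    def test_mode_positions_strictly_increasing(self):
        family = nitrogen_distribution_family(n_layers=200)
        argmax = np.array([int(np.argmax(f)) for f in family])
        assert np.all(np.diff(argmax) > 0)

    def test_matched_member_replicates_leaf_area_pattern(self):
        # N14 (mode 0.5) and the leaf-area profile peaking at 0.5 share one
        # beta shape, so their per-layer fractions coincide exactly
        fracs = nitrogen_distribution_family()[13]
        p = leaf_area_profile(5.0, 0.5)
        np.testing.assert_allclose(fracs, p.lap / p.lai, atol=1e-12)

    def test_fixed_concentration_variant(self):
        family = nitrogen_distribution_family(concentration=8.0)
        for fracs in family:
            assert fracs.sum() == pytest.approx(1.0, abs=1e-9)
        modal = [int(np.argmax(f)) for f in family]
        assert modal == sorted(modal)
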