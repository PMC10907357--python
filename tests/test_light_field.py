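"""Attenuation, red:far-red and PAR-absorption arithmetic."""

import numpy as np
import pytest

from canopylight.light_field import (
    CANONICAL_DEPTHS_M,
    ParProfile,
    SpectralField,
    SpectralScan,
    average_replicates,
    fraction_absorbed,
    kd_regression,
    kd_two_point,
    light_level_depth,
    red_farred,
    rfr_profile,
)

WL = np.linspace(400.0, 750.0, 36)


def make_field(kd, depths=CANONICAL_DEPTHS_M, ed0=100.0):
    """Noiseless single-exponential field Ed(λ,z) = Ed0·exp(−Kd(λ)·z)."""
    kd = np.broadcast_to(np.asarray(kd, float), WL.shape)
    scans = [SpectralScan(z, WL, ed0 * np.exp(-kd * z)) for z in depths]
    return SpectralField(scans)


class TestAverageReplicates:
    def test_identical_scans_are_a_fixed_point(self):
        scan = SpectralScan(0.3, WL, np.linspace(1, 5, WL.size))
        out = average_replicates([scan, scan, scan])
        np.testing.assert_allclose(out.ed, scan.ed, rtol=1e-12)
        assert out.depth_m == 0.3

    def test_elementwise_mean(self):
        scans = [SpectralScan(0.1, WL, np.full(WL.size, v)) for v in (1.0, 2.0, 3.0)]
        np.testing.assert_allclose(average_replicates(scans).ed, 2.0)

    @pytest.mark.parametrize(
        "other", [SpectralScan(0.2, WL, np.ones(WL.size)),
                  SpectralScan(0.1, WL + 1.0, np.ones(WL.size))],
        ids=["depth mismatch", "grid mismatch"],
    )
    def test_mismatched_replicates_rejected(self, other):
        base = SpectralScan(0.1, WL, np.ones(WL.size))
        with pytest.raises(ValueError, match="replicates"):
            average_replicates([base, other])

    def test_noise_averages_out_at_clt_rate(self):
        # 25 replicates with additive zero-mean sigma=0.1: the mean sits
        # within 3·sigma/sqrt(25) of truth in ~99.7% of draws
        truth = np.ones(WL.size)
        bound = 3 * 0.1 / np.sqrt(25)
        rng = np.random.default_rng(42)
        devs = []
        for _ in range(100):
            scans = [
                SpectralScan(0.1, WL, truth + 0.1 * rng.standard_normal(WL.size))
                for _ in range(25)
            ]
            devs.append(np.abs(average_replicates(scans).ed - truth))
        within = np.concatenate(devs) < bound
        assert within.mean() > 0.99  # 3-sigma coverage ≈ 99.7%


class TestKdTwoPoint:
    def test_no_attenuation_gives_zero(self):
        assert kd_two_point(100.0, 100.0, 0.5) == 0.0

    def test_e_fold_over_half_metre(self):
        assert kd_two_point(100.0, 36.788, 0.5) == pytest.approx(2.000, abs=1e-3)

    def test_brightening_with_depth_is_negative(self):
        assert kd_two_point(100.0, 200.0, 1.0) == pytest.approx(-0.693, abs=1e-3)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(0)
        up, lo = rng.uniform(1, 100, 50), rng.uniform(1, 100, 50)
        np.testing.assert_allclose(
            kd_two_point(up, lo, 0.4), -kd_two_point(lo, up, 0.4), rtol=1e-12
        )

    def test_nonpositive_irradiance_marked_missing(self):
        out = kd_two_point(np.array([100.0, 0.0]), np.array([50.0, 10.0]), 0.5)
        assert np.isfinite(out[0]) and np.isnan(out[1])

    def test_bad_dz_rejected(self):
        with pytest.raises(ValueError, match="dz_m"):
            kd_two_point(10.0, 5.0, 0.0)


class TestKdRegression:
    def test_recovers_exponential_coefficient_exactly(self):
        ks = kd_regression(make_field(2.0))
        np.testing.assert_allclose(ks.kd, 2.0, atol=1e-9)
        assert ks.n_depths_used == 9

    @pytest.mark.parametrize("subset", [(0, 1), (0, 4, 8), (2, 3, 5, 7)])
    def test_any_depth_subset_gives_same_answer(self, subset):
        depths = [CANONICAL_DEPTHS_M[i] for i in subset]
        ks = kd_regression(make_field(1.37, depths=depths))
        np.testing.assert_allclose(ks.kd, 1.37, atol=1e-9)

    def test_two_depths_reduce_to_two_point_formula(self):
        f = make_field(0.9, depths=(0.1, 0.7))
        ks = kd_regression(f)
        expected = kd_two_point(f.scans[0].ed, f.scans[1].ed, 0.6)
        np.testing.assert_allclose(ks.kd, expected, atol=1e-12)

    def test_layer_argument_restricts_depths(self):
        ks = kd_regression(make_field(2.0), layer=(0.3, 0.9))
        assert ks.n_depths_used == 4
        np.testing.assert_allclose(ks.kd, 2.0, atol=1e-9)

    def test_dark_wavelengths_become_missing(self):
        f = make_field(2.0)
        ed_dark = f.scans[-1].ed.copy()
        scans = list(f.scans)
        dark = np.array([s.ed for s in scans])
        dark[1:, 0] = 0.0  # only the surface scan sees this wavelength
        scans = [SpectralScan(s.depth_m, WL, dark[i]) for i, s in enumerate(scans)]
        ks = kd_regression(SpectralField(scans))
        assert np.isnan(ks.kd[0]) and np.all(np.isfinite(ks.kd[1:]))
        del ed_dark

    def test_single_depth_rejected(self):
        with pytest.raises(ValueError, match=">= 2 depths"):
            kd_regression(make_field(1.0, depths=(0.5,)), layer=(0.0, 1.0))


class TestRedFarred:
    def test_flat_spectrum_gives_unity(self):
        assert red_farred(SpectralScan(0.0, WL, np.ones(WL.size))) == pytest.approx(1.0)

    def test_direct_ratio(self):
        ed = np.where(WL <= 700, 98.0, 100.0)
        assert red_farred(SpectralScan(0.0, WL, ed)) == pytest.approx(0.98)

    def test_interpolates_between_bracketing_points(self):
        wl = np.array([640.0, 660.0, 740.0, 760.0])
        scan = SpectralScan(0.0, wl, np.array([80.0, 120.0, 50.0, 150.0]))
        assert red_farred(scan) == pytest.approx(100.0 / 100.0)

    def test_zero_farred_is_missing(self):
        ed = np.where(WL < 700, 10.0, 0.0)
        assert np.isnan(red_farred(SpectralScan(0.0, WL, ed)))

    def test_grey_water_leaves_ratio_constant_in_depth(self):
        # wavelength-independent Kd cancels in the ratio at every depth
        _, ratios = rfr_profile(make_field(1.3))
        np.testing.assert_allclose(ratios, ratios[0], atol=1e-12)


class TestParSummaries:
    def exp_profile(self, kd, depths=np.linspace(0.0, 1.5, 9), p0=100.0):
        return ParProfile(depths, p0 * np.exp(-kd * depths))

    def test_two_thirds_lost_when_light_drops_to_a_third(self):
        prof = ParProfile(np.array([0.0, 0.1]), np.array([100.0, 33.33]))
        assert fraction_absorbed(prof, 0.0, 0.1) == pytest.approx(66.7, abs=0.05)

    def test_constant_light_absorbs_nothing(self):
        prof = ParProfile(np.linspace(0, 1, 5), np.full(5, 42.0))
        assert fraction_absorbed(prof, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_lost_over_sixty_centimetres(self):
        prof = ParProfile(np.array([0.0, 0.6]), np.array([100.0, 50.0]))
        assert fraction_absorbed(prof, 0.0, 0.6) == pytest.approx(50.0, abs=1e-9)

    def test_absorption_composes_multiplicatively(self):
        prof = self.exp_profile(1.7)
        f13 = fraction_absorbed(prof, 0.1, 1.3)
        f12 = fraction_absorbed(prof, 0.1, 0.7)
        f23 = fraction_absorbed(prof, 0.7, 1.3)
        assert 1 - f13 / 100 == pytest.approx((1 - f12 / 100) * (1 - f23 / 100), rel=1e-9)

    def test_half_light_depth_of_exponential(self):
        prof = self.exp_profile(np.log(2) / 0.5)
        assert light_level_depth(prof, 0.5) == pytest.approx(0.500, abs=1e-9)

    def test_unreached_level_flagged(self):
        # 1% depth of a Kd=2 profile is ln(100)/2 = 2.30 m, beyond 1.5 m
        assert np.isnan(light_level_depth(self.exp_profile(2.0), 0.01))

    @pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5])
    def test_fraction_bounds_enforced(self, fraction):
        with pytest.raises(ValueError, match="fraction"):
            light_level_depth(self.exp_profile(1.0), fraction)
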