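"""The generator's calibrated optics and plant truth, and its round trips."""

import numpy as np
import pytest

from canopylight.fluorometry import process_trace
from canopylight.light_field import (
    fraction_absorbed,
    kd_regression,
    light_level_depth,
    red_farred,
)
from canopylight.synthetic import (
    Scenario,
    canopy_kd,
    generate_field,
    generate_plant,
    plant_truth,
    simulate_induction,
    water_kd,
)


class TestWaterOptics:
    def test_open_water_half_light_depth(self, open_water_field):
        z_half = light_level_depth(open_water_field.par, 0.5)
        assert z_half == pytest.approx(0.60, abs=1e-6)

    def test_red_farred_step_of_water(self, wavelengths):
        kw = water_kd(wavelengths)
        delta = np.interp(650, wavelengths, kw) - np.interp(750, wavelengths, kw)
        assert delta == pytest.approx(0.0404, abs=2e-4)

    def test_water_kd_nonnegative_and_bimodal(self, wavelengths):
        kw = water_kd(wavelengths)
        assert np.all(kw >= 0)
        # local maxima in both the blue (400–500) and red (600–700) bands
        blue = kw[(wavelengths >= 400) & (wavelengths <= 500)]
        mid = kw[(wavelengths > 500) & (wavelengths < 600)]
        red = kw[(wavelengths >= 600) & (wavelengths <= 700)]
        assert blue.max() > mid.min() and red.max() > mid.min()


class TestCanopy:
    def test_open_water_adds_nothing(self, wavelengths):
        layers = canopy_kd("open_water", wavelengths)
        assert all(np.all(add == 0) for _, _, add in layers)

    def test_unknown_class_rejected(self, wavelengths):
        with pytest.raises(ValueError, match="density class"):
            canopy_kd("jungle", wavelengths)

    def test_moderate_peak_after_regression_round_trip(self, moderate_field, wavelengths):
        ks = kd_regression(moderate_field.field)
        band = (wavelengths >= 450) & (wavelengths <= 650)
        assert np.nanmax(ks.kd[band]) == pytest.approx(3.0, abs=0.01)

    def test_high_density_shifts_red_farred_at_half_metre(self, high_field):
        scan = [s for s in high_field.field.scans if s.depth_m == 0.5][0]
        assert red_farred(scan) == pytest.approx(0.46, abs=0.005)

    def test_denser_canopy_absorbs_more_at_every_band_wavelength(
        self, open_water_field, low_field, moderate_field, high_field, wavelengths
    ):
        # estimated over the top layer, where every canopy is present
        kds = [
            kd_regression(fb.field, layer=(0.0, 0.1)).kd
            for fb in (open_water_field, low_field, moderate_field, high_field)
        ]
        band = (wavelengths >= 450) & (wavelengths <= 650)
        for sparse, dense in zip(kds, kds[1:]):
            assert np.all(sparse[band] <= dense[band] + 1e-9)


class TestFieldGeneration:
    def test_zero_noise_regression_recovers_water_kd(self, open_water_field, wavelengths):
        ks = kd_regression(open_water_field.field)
        np.testing.assert_allclose(ks.kd, water_kd(wavelengths), atol=1e-9)

    def test_same_seed_reproduces_bit_exactly(self):
        sc = Scenario(density_class="moderate", seed=31, spectral_sigma=0.08)
        a, b = generate_field(sc), generate_field(sc)
        np.testing.assert_array_equal(a.field.ed_matrix, b.field.ed_matrix)
        np.testing.assert_array_equal(a.par.par, b.par.par)

    def test_different_seeds_differ_under_noise(self):
        a = generate_field(Scenario(seed=1, spectral_sigma=0.08))
        b = generate_field(Scenario(seed=2, spectral_sigma=0.08))
        assert not np.array_equal(a.field.ed_matrix, b.field.ed_matrix)

    def test_dense_patch_absorbs_two_thirds_in_top_decimetre(self, high_field):
        assert fraction_absorbed(high_field.par, 0.0, 0.1) == pytest.approx(
            66.7, abs=0.05
        )

    def test_replicate_scans_emitted_per_depth(self, moderate_field):
        assert all(len(reps) == 3 for reps in moderate_field.replicates)


class TestPlantTruth:
    def test_mean_saturation_intensity_calibration(self, truth_levels):
        assert truth_levels["i_k"].mean() == pytest.approx(160.0, abs=1e-9)
        ratio = truth_levels["i_k"].iloc[-1] / truth_levels["i_k"].iloc[0]
        assert ratio == pytest.approx(0.70, abs=1e-9)

    def test_etrmax_declines_27_percent(self, truth_levels):
        ratio = truth_levels["etr_max"].iloc[-1] / truth_levels["etr_max"].iloc[0]
        assert ratio == pytest.approx(0.73, abs=1e-9)

    def test_apical_assimilation_share(self):
        assert plant_truth().apical_share_percent == pytest.approx(55.98, abs=0.01)

    def test_ik_is_etrmax_over_alpha(self, truth_levels):
        np.testing.assert_allclose(
            truth_levels["i_k"], truth_levels["etr_max"] / truth_levels["alpha"]
        )

    def test_pigment_gradients(self, truth_levels):
        chl = truth_levels["total_chl_ug_cm2"]
        # ×2.5 reached at 60 cm relative to the extrapolated surface value
        assert chl.iloc[4] == pytest.approx(2.5 * 16.0, abs=1e-9)
        assert (chl.iloc[4:] == chl.iloc[4]).all()  # flat below 60 cm
        ab = truth_levels["chl_ab_ratio"]
        assert ab.iloc[-1] / ab.iloc[0] == pytest.approx(0.75, abs=1e-9)
        car = truth_levels["chl_car_ratio"]
        assert car.iloc[-1] / car.iloc[0] == pytest.approx(1.56, abs=1e-9)

    def test_leaf_shape_valid(self, truth_levels):
        assert truth_levels["circularity"].between(0, 1).all()
        assert truth_levels["circularity"].is_monotonic_decreasing


class TestInductionSimulation:
    def test_zero_noise_inverts_exactly(self):
        for em, al in [(50.0, 0.30), (36.5, 0.28), (70.0, 0.20)]:
            _, fit = process_trace(simulate_induction(em, al))
            assert fit.etr_max == pytest.approx(em, rel=1e-6)
            assert fit.alpha == pytest.approx(al, rel=1e-6)

    def test_same_seed_gives_identical_trace(self):
        mk = lambda: simulate_induction(
            50, 0.3, fluoro_sigma=0.05, rng=np.random.default_rng(77)
        )
        a, b = mk(), mk()
        assert all(
            s1.fs == s2.fs and s1.fm_prime == s2.fm_prime
            for s1, s2 in zip(a.steps, b.steps)
        )

    def test_unreachable_yield_names_the_step(self):
        with pytest.raises(ValueError, match="step 1"):
            simulate_induction(50.0, 3.0)  # alpha demands yield > 1 at I=5

    def test_noisy_recovery_median_error(self):
        errs = []
        for seed in range(200):
            tr = simulate_induction(
                50.0, 0.30, fluoro_sigma=0.05, rng=np.random.default_rng(seed)
            )
            _, fit = process_trace(tr)
            errs.append(abs(fit.etr_max - 50.0) / 50.0)
        assert np.median(errs) < 0.05


class TestPlantGeneration:
    def test_zero_noise_tables_reproduce_truth(self):
        sc = Scenario(seed=3, n_plants=2).noiseless()
        pb = generate_plant(sc)
        lt = pb.leaf_truth.groupby("depth_cm")[["etr_max", "alpha", "la_cm2"]].mean()
        truth = pb.truth.levels.set_index("depth_cm")
        np.testing.assert_allclose(lt["etr_max"], truth["etr_max"], rtol=1e-12)
        np.testing.assert_allclose(lt["la_cm2"], truth["la_cm2"], rtol=1e-12)

    def test_trait_noise_hits_requested_cv(self):
        # lognormal trait noise calibrated so CV ≈ trait_sigma = 0.25
        sc = Scenario(seed=5, n_plants=150, trait_sigma=0.25)
        pb = generate_plant(sc)
        cvs = (
            pb.leaf_truth.groupby("depth_cm")["etr_max"]
            .agg(lambda v: v.std(ddof=1) / v.mean())
            .to_numpy()
        )
        assert np.median(cvs) == pytest.approx(0.25, abs=0.04)

    def test_same_seed_bit_identical(self):
        sc = Scenario(seed=9, n_plants=2)
        a, b = generate_plant(sc), generate_plant(sc)
        assert a.fluoro.equals(b.fluoro)
        assert a.pigments.equals(b.pigments)
        assert a.biomass.equals(b.biomass)

    def test_biomass_anchors_by_density(self):
        low = generate_plant(Scenario(density_class="low", seed=1).noiseless())
        high = generate_plant(Scenario(density_class="high", seed=1).noiseless())
        low_density = low.biomass["total_dry_g"] / 0.25 / (
            (low.biomass["layer_bottom_cm"] - low.biomass["layer_top_cm"]) / 100
        )
        np.testing.assert_allclose(low_density, 270.0, rtol=1e-9)
        surf = high.biomass[high.biomass["layer_top_cm"] == 0].iloc[0]
        assert surf["leaf_dry_g"] / surf["total_dry_g"] == pytest.approx(0.30, abs=1e-9)
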