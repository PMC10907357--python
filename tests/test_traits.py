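"""Assimilation distribution, trait variability, correlation and PCA."""

import numpy as np
import pandas as pd
import pytest

from canopylight.traits import (
    CANONICAL_LEAF_LEVELS_CM,
    apical_share,
    correlate_traits,
    pca_traits,
    potential_assimilation,
    significance_stars,
    trait_cv,
)


class TestAssimilation:
    def test_direct_normalisation(self):
        out = potential_assimilation([10, 50], [8.0, 11.0], [7.0, 4.0])
        np.testing.assert_allclose(out["percent"], [56.0, 44.0])

    def test_single_level_takes_all(self):
        out = potential_assimilation([20], [50.0], [10.0])
        assert out["percent"].iloc[0] == 100.0

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = rng.integers(2, 12)
            out = potential_assimilation(
                np.sort(rng.choice(200, n, replace=False)),
                rng.uniform(10, 60, n),
                rng.uniform(0, 20, n),
            )
            assert out["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_products_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            potential_assimilation([10, 50], [5.0, 5.0], [0.0, 0.0])

    def test_uniform_products_split_by_level_count(self):
        out = potential_assimilation(
            CANONICAL_LEAF_LEVELS_CM, np.ones(9), np.ones(9)
        )
        assert apical_share(out, 40) == pytest.approx(100 * 4 / 9, abs=1e-9)

    def test_apical_and_basal_shares_are_complementary(self):
        out = potential_assimilation([1, 40, 80, 140], [5, 4, 3, 2], [3, 1, 2, 4])
        top = apical_share(out, 40)
        bottom = out.loc[out["depth_cm"] > 40, "percent"].sum()
        assert top + bottom == pytest.approx(100.0, abs=1e-9)

    def test_concentrated_leaf_area_takes_all(self):
        out = potential_assimilation([1, 60, 140], [5.0, 9.0, 9.0], [12.0, 0.0, 0.0])
        assert apical_share(out, 40) == pytest.approx(100.0)


class TestTraitCV:
    def matrix(self):
        return pd.DataFrame(
            {"depth_cm": [5, 5, 5, 40, 40, 40], "t": [1.0, 2.0, 3.0, 4.0, 4.0, 4.0]}
        )

    def test_sample_cv_of_small_group(self):
        out = trait_cv(self.matrix(), traits=["t"])
        assert out.loc[out["depth_cm"] == 5, "cv"].iloc[0] == pytest.approx(0.5)
        assert out.loc[out["depth_cm"] == 40, "cv"].iloc[0] == pytest.approx(0.0)

    def test_cv_invariant_to_positive_rescaling(self):
        m = self.matrix()
        scaled = m.assign(t=m["t"] * 17.3)
        pd.testing.assert_series_equal(
            trait_cv(m, traits=["t"])["cv"], trait_cv(scaled, traits=["t"])["cv"]
        )

    def test_single_replicate_undefined(self):
        m = pd.DataFrame({"depth_cm": [5], "t": [3.0]})
        assert np.isnan(trait_cv(m, traits=["t"])["cv"].iloc[0])


class TestCorrelations:
    def test_perfect_linear_association(self):
        m = pd.DataFrame({"x": np.arange(9.0), "depth_cm": 2 * np.arange(9.0) + 1})
        out = correlate_traits(m, traits=["x"], env_cols=("depth_cm",))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-6
        assert out["significance"].iloc[0] == "***"

    def test_perfect_anticorrelation(self):
        m = pd.DataFrame({"x": np.arange(9.0), "depth_cm": -np.arange(9.0)})
        out = correlate_traits(m, traits=["x"], env_cols=("depth_cm",))
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_r_invariant_to_affine_transforms(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        base = correlate_traits(
            pd.DataFrame({"x": x, "depth_cm": y}), ["x"], ("depth_cm",)
        )["r"].iloc[0]
        moved = correlate_traits(
            pd.DataFrame({"x": 3 * x + 7, "depth_cm": -2 * y + 1}), ["x"], ("depth_cm",)
        )["r"].iloc[0]
        assert moved == pytest.approx(-base, rel=1e-12)

    def test_zero_variance_is_missing(self):
        m = pd.DataFrame({"x": np.ones(10), "depth_cm": np.arange(10.0)})
        out = correlate_traits(m, traits=["x"], env_cols=("depth_cm",))
        assert np.isnan(out["r"].iloc[0])

    def test_critical_value_coverage_at_n40(self):
        # independent normals, n=40: |r| stays below the 5% critical
        # value 0.312 in ≈95% of draws
        rng = np.random.default_rng(123)
        inside = 0
        for _ in range(1000):
            m = pd.DataFrame(
                {"x": rng.standard_normal(40), "depth_cm": rng.standard_normal(40)}
            )
            r = correlate_traits(m, ["x"], ("depth_cm",))["r"].iloc[0]
            inside += abs(r) <= 0.312
        assert 930 <= inside <= 970

    def test_star_thresholds(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""


class TestPCA:
    def test_perfectly_correlated_traits_load_on_one_axis(self):
        x = np.arange(12.0)
        m = pd.DataFrame({"a": x, "b": 3 * x + 1})
        _, _, pct = pca_traits(m, traits=["a", "b"])
        assert pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_variance_percentages_conserved(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.standard_normal((30, 6)), columns=list("abcdef"))
        _, _, pct = pca_traits(m, traits=list("abcdef"))
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_isotropic_cloud_splits_variance_evenly(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.standard_normal((5000, 3)), columns=list("abc"))
        _, _, pct = pca_traits(m, traits=list("abc"))
        np.testing.assert_allclose(pct, 100 / 3, atol=2.0)

    def test_reconstruction_from_all_axes(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.standard_normal((15, 4)), columns=list("abcd"))
        scores, loadings, _ = pca_traits(m, traits=list("abcd"))
        x = m.to_numpy()
        z = (x - x.mean(0)) / x.std(0)
        np.testing.assert_allclose(
            scores.to_numpy() @ loadings.to_numpy().T, z, atol=1e-9
        )

    def test_loadings_orthonormal_with_positive_lead(self):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
        _, loadings, _ = pca_traits(m, traits=list("abcd"))
        L = loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-9)
        for a in range(4):
            assert L[np.argmax(np.abs(L[:, a])), a] > 0

    def test_constant_column_dropped_with_warning(self):
        m = pd.DataFrame({"a": np.arange(9.0), "b": np.ones(9), "c": np.arange(9.0) ** 2})
        with pytest.warns(UserWarning, match="constant"):
            _, loadings, _ = pca_traits(m, traits=["a", "b", "c"])
        assert "b" not in loadings.index
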