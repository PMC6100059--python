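"""PCA correctness against the covariance eigendecomposition, score images
and effective-wavelength selection."""

import numpy as np
import pytest

from seedhsi.io import HyperCube, make_spectra_table
from seedhsi.pca import (
    EwSet,
    PcaModel,
    achievable_components,
    fit_pixel_pca,
    restrict_to_ews,
    score_images,
    select_ews,
)


def _sign_fix(vectors):
    out = vectors.copy()
    for j in range(out.shape[1]):
        if out[np.argmax(np.abs(out[:, j])), j] < 0:
            out[:, j] = -out[:, j]
    return out


class TestFitPixelPca:
    def test_rank_one_data_explains_everything_with_pc1(self):
        base = np.linspace(0.2, 0.8, 30)
        spectra = np.outer(np.linspace(1, 3, 12), base)
        model = fit_pixel_pca(spectra, 1)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self, rng):
        """Loadings/variances agree with eigh of the sample covariance to 1e-8."""
        X = rng.normal(size=(300, 40))
        model = fit_pixel_pca(X, 5)
        cov = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], _sign_fix(evecs[:, order])
        np.testing.assert_allclose(np.abs(model.loadings), np.abs(evecs[:, :5]), atol=1e-8)
        np.testing.assert_allclose(model.loadings, evecs[:, :5], atol=1e-8)
        np.testing.assert_allclose(
            model.explained_variance_fraction, evals[:5] / evals.sum(), atol=1e-10
        )

    def test_variance_fractions_sum_to_one_over_full_rank(self, rng):
        X = rng.normal(size=(50, 8))
        model = fit_pixel_pca(X, 8)
        assert model.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(model.explained_variance_fraction) <= 1e-12).all()

    def test_loadings_orthonormal(self, rng):
        model = fit_pixel_pca(rng.normal(size=(100, 20)), 6)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_rank_deficient_request_rejected_and_clipped(self):
        spectra = np.vstack([np.full(10, 0.1)] * 5 + [np.full(10, 0.9)] * 5)
        with pytest.raises(ValueError, match="rank"):
            fit_pixel_pca(spectra, 3)
        assert achievable_components(spectra, 3) == 1

    def test_subsampling_is_seeded(self, rng):
        X = rng.normal(size=(500, 10)) + np.linspace(0, 1, 10)
        a = fit_pixel_pca(X, 3, subsample_cap=200, rng_seed=9)
        b = fit_pixel_pca(X, 3, subsample_cap=200, rng_seed=9)
        np.testing.assert_array_equal(a.loadings, b.loadings)


class TestScoreImages:
    def test_background_zero_and_projection_oracle(self, corrected_small):
        cube, truth = corrected_small
        mask = truth.label_map.labels > 0
        rows, cols = np.nonzero(mask)
        model = fit_pixel_pca(cube.values[rows, cols, :].astype(float), 4)
        scores = score_images(model, cube, mask)
        assert (scores[:, ~mask] == 0).all()
        r, c = rows[7], cols[7]
        expected = (cube.values[r, c, :] - model.mean_spectrum) @ model.loadings
        np.testing.assert_allclose(scores[:, r, c], expected, rtol=1e-10)

    def test_class_three_separates_on_pc1(self, corrected_small):
        """Mean PC1 score of the well-separated class differs in sign from classes 1/2."""
        cube, truth = corrected_small
        mask = truth.label_map.labels > 0
        rows, cols = np.nonzero(mask)
        model = fit_pixel_pca(cube.values[rows, cols, :].astype(float), 2)
        scores = score_images(model, cube, mask)
        class_img = truth.class_image()
        m1 = scores[0][class_img == 1].mean()
        m2 = scores[0][class_img == 2].mean()
        m3 = scores[0][class_img == 3].mean()
        assert np.sign(m3) != np.sign(m1)
        assert np.sign(m3) != np.sign(m2)

    def test_band_mismatch_rejected(self, corrected_small, rng):
        cube, truth = corrected_small
        model = fit_pixel_pca(rng.normal(size=(50, 10)), 2)
        with pytest.raises(ValueError, match="bands"):
            score_images(model, cube, truth.label_map.labels > 0)


def _model_from_loadings(loadings, variance=None):
    loadings = np.asarray(loadings, dtype=float)
    k = loadings.shape[1]
    return PcaModel(
        mean_spectrum=np.zeros(loadings.shape[0]),
        loadings=loadings,
        explained_variance_fraction=np.asarray(variance if variance is not None else np.ones(k) / k),
        n_components=k,
    )


class TestSelectEws:
    wl = np.linspace(1000, 1600, 121)  # 5 nm spacing

    def test_single_gaussian_bump_yields_one_ew_at_center(self):
        curve = np.exp(-0.5 * ((self.wl - 1300) / 30) ** 2)
        ews = select_ews(_model_from_loadings(curve[:, None]), self.wl)
        assert len(ews) == 1
        assert ews.wavelengths_nm[0] == pytest.approx(1300.0)
        assert ews.extremum_kind == ["peak"]

    def test_monotonic_curve_yields_no_ews(self):
        curve = np.linspace(-1, 1, self.wl.size)
        with pytest.warns(UserWarning, match="no effective wavelengths"):
            ews = select_ews(_model_from_loadings(curve[:, None]), self.wl)
        assert len(ews) == 0

    def test_close_extrema_from_two_components_deduplicated(self):
        """Extrema one band apart collapse to the stronger candidate."""
        c1 = np.exp(-0.5 * ((self.wl - 1300) / 30) ** 2)
        c2 = 0.5 * np.exp(-0.5 * ((self.wl - 1305) / 30) ** 2)
        ews = select_ews(_model_from_loadings(np.column_stack([c1, c2]), [0.5, 0.5]), self.wl, dedup_window_nm=10)
        assert len(ews) == 1
        assert ews.wavelengths_nm[0] == pytest.approx(1300.0)
        assert ews.source_component[0] == 1

    def test_variance_weighting_prefers_dominant_component(self):
        c1 = 0.6 * np.exp(-0.5 * ((self.wl - 1300) / 30) ** 2)  # dominant component
        c2 = 1.0 * np.exp(-0.5 * ((self.wl - 1306) / 30) ** 2)  # minor, larger raw loading
        model = _model_from_loadings(np.column_stack([c1, c2]), [0.95, 0.001])
        ews = select_ews(model, self.wl, dedup_window_nm=10)
        assert ews.source_component[0] == 1
        raw_rank = select_ews(model, self.wl, dedup_window_nm=10, dedup_rank="loading")
        assert raw_rank.source_component[0] == 2

    def test_separated_extrema_all_kept_sorted(self):
        c = np.exp(-0.5 * ((self.wl - 1100) / 25) ** 2) - np.exp(
            -0.5 * ((self.wl - 1450) / 25) ** 2
        )
        ews = select_ews(_model_from_loadings(c[:, None]), self.wl)
        assert len(ews) == 2
        np.testing.assert_allclose(ews.wavelengths_nm, [1100, 1450])
        assert ews.extremum_kind == ["peak", "valley"]


class TestRestrictToEws:
    def _table(self, rng):
        wl = np.linspace(1000, 1199, 200)
        return make_spectra_table(rng.random((4, 200)), wl, classes=[1, 2, 3, 1]), wl

    def test_restricts_to_ten_columns(self, rng):
        table, wl = self._table(rng)
        pick = wl[[5, 20, 40, 60, 80, 100, 120, 140, 160, 180]]
        ews = EwSet(pick, np.arange(10), np.ones(10, dtype=int), ["peak"] * 10)
        out = restrict_to_ews(table, ews)
        assert out.shape == (4, 2 + 10)
        # matches a brute-force column filter
        expect = table[["roi_label", "class"] + [f"{w:.2f}" for w in pick]]
        assert out.equals(expect)

    def test_empty_ew_set_rejected(self, rng):
        table, _ = self._table(rng)
        empty = EwSet(np.array([]), np.array([], dtype=int), np.array([], dtype=int), [])
        with pytest.raises(ValueError, match="empty"):
            restrict_to_ews(table, empty)

    def test_unknown_wavelength_rejected(self, rng):
        table, _ = self._table(rng)
        ews = EwSet(np.array([1500.0]), np.array([0]), np.array([1]), ["peak"])
        with pytest.raises(ValueError, match="not present"):
            restrict_to_ews(table, ews)
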