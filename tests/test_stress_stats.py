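"""NDSI, point-biserial r, Welch t-tests, ratio maps — against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

import hyperscanner as hs
from hyperscanner.errors import DegenerateSpectrumError
from hyperscanner.segmentation import PixelSet, TreatmentSample

from conftest import make_mini_scene, tray_samples


def _sample(values, treatment="a"):
    values = np.asarray(values, dtype=float)
    wl = np.linspace(500, 900, values.shape[1])
    return TreatmentSample(values=values, wavelengths=wl, treatment=treatment)


def welch_oracle(a, b):
    """From-scratch Welch t, df and p for two 1-D samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestVectorNormalize:
    def test_three_four_five_triangle(self):
        out = hs.vector_normalize(_sample([[3.0, 4.0]]))
        np.testing.assert_allclose(out.values, [[0.6, 0.8]])

    def test_idempotent_on_unit_rows(self):
        s = hs.vector_normalize(_sample([[1.0, 2.0, 2.0], [5.0, 1.0, 3.0]]))
        again = hs.vector_normalize(s)
        np.testing.assert_allclose(again.values, s.values)

    def test_rows_unit_norm(self, rng):
        s = hs.vector_normalize(_sample(rng.uniform(0.01, 1, (20, 7))))
        np.testing.assert_allclose(np.linalg.norm(s.values, axis=1), 1.0, atol=1e-12)

    def test_zero_row_raises_with_pixel_named(self):
        with pytest.raises(DegenerateSpectrumError, match="pixel 1"):
            hs.vector_normalize(_sample([[1.0, 1.0], [0.0, 0.0]]))


class TestNdsiAllPairs:
    def test_equal_bands_give_zero(self):
        m = hs.ndsi_all_pairs(_sample([[0.5, 0.5]]))
        np.testing.assert_allclose(m.values, 0.0)

    def test_direct_arithmetic(self):
        m = hs.ndsi_all_pairs(_sample([[0.8, 0.4]]))
        assert m.values[0, 1] == pytest.approx((0.8 - 0.4) / (0.8 + 0.4))

    def test_matches_double_loop_oracle(self, rng):
        x = rng.uniform(0.05, 0.95, (5, 4))
        m, stack = hs.ndsi_all_pairs(_sample(x), keep_pixel_ndsi=True)
        for i in range(4):
            for j in range(4):
                per_pixel = [(x[p, i] - x[p, j]) / (x[p, i] + x[p, j]) for p in range(5)]
                assert m.values[i, j] == pytest.approx(np.mean(per_pixel), abs=1e-12)
                np.testing.assert_allclose(stack[:, i, j], per_pixel, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(hnp.arrays(float, st.tuples(st.integers(1, 6), st.integers(2, 5)),
                      elements=st.floats(1e-3, 1.0)))
    def test_bounds_and_antisymmetry_property(self, x):
        m = hs.ndsi_all_pairs(_sample(x))
        assert np.all(m.values <= 1.0 + 1e-12) and np.all(m.values >= -1.0 - 1e-12)
        np.testing.assert_allclose(m.values, -m.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m.values), 0.0)


class TestNdsiTreatmentR:
    def test_identical_samples_give_zero_r(self, rng):
        x = rng.uniform(0.1, 0.9, (10, 4))
        r = hs.ndsi_treatment_r(_sample(x, "a"), _sample(x.copy(), "b"))
        np.testing.assert_allclose(r.values, 0.0, atol=1e-10)

    def test_matches_pooled_corrcoef_oracle(self, rng):
        a = rng.uniform(0.1, 0.9, (8, 3))
        b = rng.uniform(0.1, 0.9, (12, 3))
        r = hs.ndsi_treatment_r(_sample(a, "a"), _sample(b, "b"))
        ind = np.r_[np.zeros(8), np.ones(12)]
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                nd_a = (a[:, i] - a[:, j]) / (a[:, i] + a[:, j])
                nd_b = (b[:, i] - b[:, j]) / (b[:, i] + b[:, j])
                expect = np.corrcoef(np.r_[nd_a, nd_b], ind)[0, 1]
                assert r.values[i, j] == pytest.approx(expect, abs=1e-10)

    def test_sign_antisymmetry(self, rng):
        a = rng.uniform(0.1, 0.9, (9, 5))
        b = rng.uniform(0.1, 0.9, (9, 5))
        r = hs.ndsi_treatment_r(_sample(a, "a"), _sample(b, "b"))
        np.testing.assert_allclose(r.values, -r.values.T, atol=1e-10)

    def test_r_t_identity(self, rng):
        """Point-biserial r and pooled t satisfy r^2 = t^2/(t^2+df) exactly."""
        a = rng.uniform(0.1, 0.9, (15, 4))
        b = rng.uniform(0.1, 0.9, (11, 4)) * 1.1
        r = hs.ndsi_treatment_r(_sample(a, "a"), _sample(b, "b"))
        off = ~np.eye(4, dtype=bool)
        lhs = r.values[off] ** 2
        rhs = r.t[off] ** 2 / (r.t[off] ** 2 + r.df)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_perfect_separation_matches_closed_form(self):
        # group constants per band pair -> |r| has the two-point closed form
        a = np.tile([0.2, 0.8], (4, 1))
        b = np.tile([0.8, 0.2], (6, 1))
        r = hs.ndsi_treatment_r(_sample(a, "a"), _sample(b, "b"))
        nd_a = (0.2 - 0.8) / 1.0
        nd_b = (0.8 - 0.2) / 1.0
        pooled = np.r_[np.full(4, nd_a), np.full(6, nd_b)]
        expect = np.corrcoef(pooled, np.r_[np.zeros(4), np.ones(6)])[0, 1]
        assert r.values[0, 1] == pytest.approx(expect, abs=1e-12)
        assert abs(expect) == pytest.approx(1.0)


class TestWavelengthTTests:
    def test_matches_welch_oracle(self, rng):
        a = rng.normal(0.5, 0.05, (30, 6))
        b = rng.normal(0.5, 0.08, (25, 6))
        spec = hs.wavelength_ttests(_sample(a, "a"), _sample(b, "b"))
        for k in range(6):
            t, df, p = welch_oracle(a[:, k], b[:, k])
            assert spec.t[k] == pytest.approx(t, rel=1e-10)
            assert spec.df[k] == pytest.approx(df, rel=1e-10)
            assert spec.p[k] == pytest.approx(p, rel=1e-10)

    def test_matches_scipy(self, rng):
        a = rng.normal(0.4, 0.05, (20, 5))
        b = rng.normal(0.45, 0.05, (22, 5))
        spec = hs.wavelength_ttests(_sample(a, "a"), _sample(b, "b"))
        ref = stats.ttest_ind(a, b, equal_var=False, axis=0)
        np.testing.assert_allclose(spec.t, ref.statistic, rtol=1e-12)
        np.testing.assert_allclose(spec.p, ref.pvalue, rtol=1e-10)

    def test_single_shifted_band_is_argmin_p(self, rng):
        a = rng.normal(0.5, 0.01, (200, 8))
        b = a + rng.normal(0, 0.01, a.shape)
        b[:, 5] += 0.3  # large shift at exactly one band
        spec = hs.wavelength_ttests(_sample(a, "a"), _sample(b, "b"))
        assert int(np.argmin(spec.p)) == 5
        assert spec.significant[5]

    def test_degenerate_zero_variance_equal_means(self):
        a = np.full((3, 2), 0.5)
        spec = hs.wavelength_ttests(_sample(a, "a"), _sample(a.copy(), "b"))
        np.testing.assert_allclose(spec.p, 1.0)
        assert np.all(spec.log10_p <= 0)

    def test_p_in_unit_interval_and_log_nonpositive(self, rng):
        a = rng.normal(0.5, 0.02, (15, 10))
        b = rng.normal(0.52, 0.02, (15, 10))
        spec = hs.wavelength_ttests(_sample(a, "a"), _sample(b, "b"))
        assert np.all((spec.p > 0) & (spec.p <= 1))
        assert np.all(spec.log10_p <= 0)


class TestRatioMap:
    def _refl(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(0.1, 0.9, (6, 6, 4))
        return hs.ReflectanceCube(data, np.array([544.0, 676.0, 743.0, 782.0]))

    def test_direct_ratio(self):
        refl = self._refl()
        refl.data[2, 3, 3] = 0.5   # 782 nm
        refl.data[2, 3, 0] = 0.25  # 544 nm
        m = hs.ratio_map(refl, PixelSet(np.array([[2, 3]])), 782, 544)
        assert m.values[2, 3] == pytest.approx(2.0)
        assert m.mean == pytest.approx(2.0)

    def test_same_wavelength_gives_unit_ratio(self):
        refl = self._refl()
        px = PixelSet(np.argwhere(np.ones((6, 6), dtype=bool)))
        m = hs.ratio_map(refl, px, 743, 743)
        np.testing.assert_allclose(m.values, 1.0)

    def test_nonplant_pixels_masked(self):
        refl = self._refl()
        m = hs.ratio_map(refl, PixelSet(np.array([[0, 0]])), 782, 544)
        assert np.isfinite(m.values[0, 0])
        assert np.isnan(m.values).sum() == 35

    def test_nonpositive_denominator_masked_and_counted(self):
        refl = self._refl()
        refl.data[1, 1, 0] = 0.0
        m = hs.ratio_map(refl, PixelSet(np.array([[1, 1], [2, 2]])), 782, 544)
        assert m.n_masked == 1 and np.isnan(m.values[1, 1])


class TestTrendSeries:
    def test_single_day_equals_map_summary(self):
        refl = hs.ReflectanceCube(np.full((3, 3, 2), 0.5), np.array([544.0, 782.0]))
        px = PixelSet(np.argwhere(np.ones((3, 3), dtype=bool)))
        m = hs.ratio_map(refl, px, 782, 544, day=20, treatment="drought")
        table = hs.trend_series([m])
        assert len(table) == 1
        assert table.loc[0, "mean"] == pytest.approx(m.mean)

    def test_means_match_bruteforce_recomputation(self):
        maps = []
        for day in (20, 21, 22):
            cube, truth = make_mini_scene(seed=day, effects_by_tray=(None, None))
            white = hs.select_white_line(cube, truth.panel_columns)
            refl = hs.to_reflectance(cube, white)
            px = hs.extract_plant_pixels(refl, panel_columns=truth.panel_columns)
            maps.append(hs.ratio_map(refl, px, 782, 544, day=day, treatment="control"))
        table = hs.trend_series(maps)
        for m in maps:
            vals = m.values[np.isfinite(m.values)]
            row = table[table.day == m.day].iloc[0]
            assert row["mean"] == pytest.approx(vals.mean())
            assert row["sd"] == pytest.approx(vals.std(ddof=1))

    def test_mixed_ratio_definitions_rejected(self):
        refl = hs.ReflectanceCube(np.full((2, 2, 2), 0.5), np.array([544.0, 782.0]))
        px = PixelSet(np.array([[0, 0]]))
        m1 = hs.ratio_map(refl, px, 782, 544)
        m2 = hs.ratio_map(refl, px, 544, 782)
        with pytest.raises(ValueError):
            hs.trend_series([m1, m2])


class TestPipelineLevelEffects:
    """Scaled-down treatment comparisons on paired mini scenes."""

    def test_injected_drought_bands_recovered(self):
        cube, truth = make_mini_scene((None, hs.drought_effect()), seed=101)
        (ctrl, drt), mask = tray_samples(cube, truth, names=("control", "drought"))
        spec = hs.wavelength_ttests(ctrl, drt)
        inj = hs.drought_effect().affected(ctrl.wavelengths)
        assert spec.significant[inj].mean() >= 0.9
        assert spec.significant[~inj].mean() <= 0.1

    def test_shared_effect_bands_null_in_cross_comparison(self):
        cube, truth = make_mini_scene(
            (hs.drought_effect(), hs.saline_effect()), seed=102)
        (drt, sal), _ = tray_samples(cube, truth, names=("drought", "saline"))
        spec = hs.wavelength_ttests(drt, sal)
        wl = drt.wavelengths
        inj_d = hs.drought_effect().affected(wl)
        inj_s = hs.saline_effect().affected(wl)
        only = inj_d ^ inj_s
        shared = inj_d & inj_s
        assert spec.significant[only].mean() >= 0.9
        assert spec.significant[shared].mean() <= 0.1
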