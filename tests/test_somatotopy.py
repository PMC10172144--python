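"""Somatotopy: axis projection, WTA, Gaussian peak fits, F-test, LOWESS."""

import numpy as np
import pytest

from scanmap import somatotopy as st
from scanmap import synthetic as syn


def _profile(y, mask=None):
    y = np.asarray(y, dtype=float)
    if mask is None:
        mask = np.ones(y.size, dtype=bool)
    return st.AxisProfile(positions=np.arange(y.size), activation=y, fit_mask=mask)


class TestProjectToAxis:
    def test_coincident_vertex(self):
        axis = np.column_stack([np.zeros(10), np.arange(10.0)])
        assert st.project_to_axis(axis[7][None, :], axis)[0] == 7

    def test_equidistant_tie_goes_to_lower_index(self):
        axis = np.column_stack([np.zeros(10), np.arange(10.0)])
        v = np.array([[1.0, 3.5]])  # equidistant between 3 and 4
        assert st.project_to_axis(v, axis)[0] == 3

    def test_matches_exhaustive_scan(self, rng):
        axis = rng.standard_normal((30, 2))
        verts = rng.standard_normal((100, 2))
        got = st.project_to_axis(verts, axis)
        for i in range(100):
            d = np.sqrt(((verts[i] - axis) ** 2).sum(axis=1))
            assert got[i] == int(np.argmin(d))

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            st.project_to_axis(np.zeros((1, 2)), np.zeros((0, 2)))


class TestWinnerTakeAll:
    def test_argmax_winner(self):
        wta = st.winner_take_all({"toe": np.array([2.0]), "hand": np.array([3.0])})
        assert wta.winner[0] == "hand"

    def test_exact_tie_flagged_lowest_condition(self):
        wta = st.winner_take_all({"toe": np.array([3.0]), "hand": np.array([3.0])})
        assert wta.winner[0] == "toe"
        assert bool(wta.tie[0])

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            st.winner_take_all({"toe": np.zeros(3)})

    def test_bands_follow_injected_centers(self):
        x = np.arange(120.0)
        maps = {
            "a": syn.gaussian_profile(x, ((3.0, 20.0, 6.0),)),
            "b": syn.gaussian_profile(x, ((3.0, 60.0, 6.0),)),
            "c": syn.gaussian_profile(x, ((3.0, 100.0, 6.0),)),
        }
        wta = st.winner_take_all(maps)
        med = {m: np.median(np.flatnonzero(wta.winner == m)) for m in maps}
        assert med["a"] < med["b"] < med["c"]

    def test_top_percent_display_mask(self, rng):
        maps = {"a": rng.standard_normal(1000), "b": rng.standard_normal(1000)}
        wta = st.winner_take_all(maps, top_percent=1.0)
        assert wta.display_mask.sum() == 10


class TestFitPeakModels:
    def test_noiseless_single_peak_exact_recovery(self):
        x = np.arange(60.0)
        y = syn.gaussian_profile(x, ((3.0, 30.0, 5.0),))
        fit1, fit2 = st.fit_peak_models(_profile(y))
        np.testing.assert_allclose(fit1.params, [3.0, 30.0, 5.0], atol=1e-6)
        assert fit1.sse == pytest.approx(0.0, abs=1e-10)
        assert fit1.df == 57 and fit2.df == 54

    def test_noiseless_two_peak_separates_models(self):
        x = np.arange(80.0)
        y = syn.gaussian_profile(x, ((2.0, 25.0, 5.0), (3.0, 55.0, 5.0)))
        fit1, fit2 = st.fit_peak_models(_profile(y))
        assert fit2.sse == pytest.approx(0.0, abs=1e-8)
        assert fit1.sse > 1.0
        assert fit2.params[1] == pytest.approx(25.0, abs=1e-4)
        assert fit2.params[4] == pytest.approx(55.0, abs=1e-4)
        assert fit2.params[1] <= fit2.params[4]  # canonical ordering

    def test_all_zero_profile_boundary_fit(self):
        fit1, fit2 = st.fit_peak_models(_profile(np.zeros(20)))
        assert fit1.sse == pytest.approx(0.0, abs=1e-6)
        assert fit1.params[0] == pytest.approx(0.0, abs=1e-3)

    def test_two_peak_sse_never_exceeds_one_peak(self, rng):
        for _ in range(10):
            y = syn.gaussian_profile(np.arange(40.0), ((2.0, 20.0, 6.0),))
            y = y + rng.standard_normal(40)
            fit1, fit2 = st.fit_peak_models(_profile(y))
            assert fit2.sse <= fit1.sse + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            st.fit_peak_models(_profile(np.zeros(6)))

    def test_amplitudes_nonnegative_and_widths_bounded(self, rng):
        y = rng.standard_normal(30)
        _, fit2 = st.fit_peak_models(_profile(y))
        assert fit2.params[0] >= 0 and fit2.params[3] >= 0
        assert fit2.params[2] >= st.MIN_WIDTH and fit2.params[5] >= st.MIN_WIDTH


class TestCompareModelsF:
    def _fit(self, n_peaks, sse, df):
        return st.PeakFit(n_peaks=n_peaks, params=np.zeros(3 * n_peaks), sse=sse,
                          df=df, converged=True)

    def test_printed_formula_example(self):
        comp = st.compare_models_f(self._fit(1, 10.0, 97), self._fit(2, 5.0, 94))
        assert comp.f_stat == pytest.approx((5.0 / 3.0) / (5.0 / 94.0))
        assert comp.f_stat == pytest.approx(31.3333, abs=1e-3)
        assert comp.df_num == 3 and comp.df_den == 94

    def test_equal_sse_gives_f_zero_p_one(self):
        comp = st.compare_models_f(self._fit(1, 5.0, 57), self._fit(2, 5.0, 54))
        assert comp.f_stat == 0.0
        assert comp.p_value == pytest.approx(1.0)
        assert comp.preferred == 1

    def test_zero_sse2_convention(self):
        comp = st.compare_models_f(self._fit(1, 5.0, 57), self._fit(2, 0.0, 54))
        assert np.isinf(comp.f_stat) and comp.p_value == 0.0 and comp.preferred == 2

    def test_invalid_dfs_rejected(self):
        with pytest.raises(ValueError):
            st.compare_models_f(self._fit(1, 5.0, 54), self._fit(2, 4.0, 57))

    def test_invariant_to_peak_order_in_two_peak_fit(self, rng):
        """Canonicalized fits give the same F whichever peak came first."""
        x = np.arange(60.0)
        y = syn.gaussian_profile(x, ((2.0, 15.0, 5.0), (3.0, 45.0, 5.0)))
        y = y + 0.3 * rng.standard_normal(60)
        fit1, fit2 = st.fit_peak_models(_profile(y))
        comp_a = st.compare_models_f(fit1, fit2)
        swapped = st.PeakFit(
            n_peaks=2,
            params=np.concatenate([fit2.params[3:], fit2.params[:3]]),
            sse=fit2.sse, df=fit2.df, converged=True,
        )
        comp_b = st.compare_models_f(fit1, swapped)
        assert comp_a.f_stat == pytest.approx(comp_b.f_stat, abs=1e-12)


class TestSelectivityAndCoactivation:
    def test_selectivity_best_minus_second(self):
        maps = {k: np.array([v]) for k, v in zip("abcdef", [4.0, 1, 1, 1, 1, 1])}
        assert st.movement_selectivity(maps)[0] == pytest.approx(3.0)

    def test_selectivity_all_equal_zero(self):
        maps = {k: np.array([2.0]) for k in "abcdef"}
        assert st.movement_selectivity(maps)[0] == 0.0

    def test_selectivity_needs_two_conditions(self):
        with pytest.raises(ValueError):
            st.movement_selectivity({"a": np.zeros(3)})

    def test_identical_profiles_correlate_perfectly(self):
        labels = np.array(["r1"] * 3 + ["r2"] * 3)
        maps = {m: np.concatenate([np.full(3, v), np.full(3, v)])
                for m, v in zip("abcd", [1.0, 3.0, 2.0, 5.0])}
        out = st.coactivation_profiles(maps, labels, ["r1", "r2"])
        assert out.loc["r1", "r2"] == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        labels = np.array(["r1", "r2"])
        maps = {"a": np.array([1.0, -1.0]), "b": np.array([2.0, -2.0]), "c": np.array([3.0, -3.0])}
        out = st.coactivation_profiles(maps, labels, ["r1", "r2"])
        assert out.loc["r1", "r2"] == pytest.approx(-1.0)

    def test_constant_profile_masked(self):
        labels = np.array(["r1", "r2"])
        maps = {"a": np.array([1.0, 0.0]), "b": np.array([1.0, 1.0]), "c": np.array([1.0, 2.0])}
        out = st.coactivation_profiles(maps, labels, ["r1", "r2"])
        assert np.isnan(out.loc["r1", "r2"])

    def test_too_few_movements_rejected(self):
        labels = np.array(["r1"])
        maps = {"a": np.zeros(1), "b": np.zeros(1)}
        with pytest.raises(ValueError):
            st.coactivation_profiles(maps, labels, ["r1"])


class TestLowess:
    def test_linear_data_reproduced(self):
        x = np.arange(50.0)
        y = 2.0 * x + 1.0
        out = st.lowess_profile(y, x, span=0.5)
        np.testing.assert_allclose(out, y, atol=1e-8)

    def test_full_span_flat_data_constant(self):
        out = st.lowess_profile(np.full(30, 2.5), span=1.0)
        np.testing.assert_allclose(out, 2.5, atol=1e-10)

    def test_noisy_two_peak_curve_peaks_recovered(self, rng):
        x = np.arange(120.0)
        y = syn.gaussian_profile(x, ((3.0, 30.0, 8.0), (3.0, 90.0, 8.0)))
        y = y + 0.4 * rng.standard_normal(120)
        sm = st.lowess_profile(y, x, span=0.25)
        left = int(np.argmax(sm[:60]))
        right = 60 + int(np.argmax(sm[60:]))
        assert abs(left - 30) <= 2 and abs(right - 90) <= 2

    def test_span_too_small_rejected(self):
        with pytest.raises(ValueError):
            st.lowess_profile(np.zeros(20), span=0.05)
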