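"""Selection criteria against definition oracles, and model ranking."""

import numpy as np
import pytest

from lactofit.catalogue import get_model
from lactofit.fitting import fit_series, sweep
from lactofit.io import ComponentSeries
from lactofit.selection import (
    adjusted_r2, information_criteria, loocv_mmse, mspe, overfit_ratio,
    rank_models,
)


class TestAdjustedR2:
    @pytest.mark.parametrize("r2,n,k,expected", [
        (1.0, 10, 3, 1.0),
        (0.5, 10, 3, 0.25),
        (0.0, 10, 3, -0.5),
    ])
    def test_hand_values(self, r2, n, k, expected):
        assert adjusted_r2(r2, n, k) == pytest.approx(expected)

    def test_undefined_for_tiny_n(self):
        assert np.isnan(adjusted_r2(0.5, 4, 3))

    def test_never_exceeds_r2(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            r2 = rng.uniform(0, 1)
            n = int(rng.integers(6, 40))
            k = int(rng.integers(1, n - 2))
            assert adjusted_r2(r2, n, k) <= r2 + 1e-12


class TestOverfitRatio:
    @pytest.mark.parametrize("adj,r2,ratio,flag", [
        (0.25, 0.5, 0.5, False),
        (0.1, 0.5, 0.2, True),
        (0.5, 0.5, 1.0, False),
    ])
    def test_hand_values(self, adj, r2, ratio, flag):
        got, got_flag = overfit_ratio(adj, r2)
        assert got == pytest.approx(ratio)
        assert got_flag is flag

    def test_zero_r2_is_missing(self):
        got, flag = overfit_ratio(0.0, 0.0)
        assert np.isnan(got) and not flag


class TestInformationCriteria:
    def test_hand_values(self):
        aic, aicc, bic = information_criteria(10.0, 10, 3)
        assert aic == pytest.approx(6.0)
        assert aicc == pytest.approx(10.0)
        assert bic == pytest.approx(3 * np.log(10))

    def test_halving_rss_lowers_aic_by_n_ln2(self):
        a1, _, _ = information_criteria(8.0, 20, 3)
        a2, _, _ = information_criteria(4.0, 20, 3)
        assert a1 - a2 == pytest.approx(20 * np.log(2))

    def test_aicc_approaches_aic_for_large_samples(self):
        aic, aicc, _ = information_criteria(50.0, 400, 3)
        assert aicc - aic == pytest.approx(2 * 3 * 4 / 396)
        assert aicc - aic < 0.1

    def test_exact_fit_sentinel(self):
        aic, aicc, bic = information_criteria(0.0, 10, 2)
        assert aic == -np.inf and aicc == -np.inf and bic == -np.inf


class TestMSPE:
    def test_definition(self):
        t = np.arange(10.0, 110.0, 10.0)
        fit = fit_series((t, 2 + 0.01 * t), "SIMLIN")
        assert mspe(fit) == pytest.approx(fit.rss / fit.n)
        assert mspe(fit) == pytest.approx(0.0, abs=1e-16)


class TestLOOCV:
    def test_exact_interpolation_gives_zero(self):
        t = np.arange(10.0, 130.0, 10.0)
        mmse, dropped = loocv_mmse((t, 2 + 0.01 * t), "SIMLIN")
        assert mmse == pytest.approx(0.0, abs=1e-16)
        assert dropped == 0

    def test_matches_brute_force_refit_loop(self):
        rng = np.random.default_rng(9)
        t = np.linspace(10, 200, 12)
        y = 3 + 0.005 * t + 0.1 * rng.standard_normal(12)
        mmse, _ = loocv_mmse((t, y), "QUADRT")
        # independent oracle: explicit per-fold closed-form LS refit
        errs = []
        for i in range(len(t)):
            mask = np.ones(len(t), bool)
            mask[i] = False
            X = np.column_stack([np.ones(mask.sum()), t[mask], t[mask]**2])
            b = np.linalg.lstsq(X, y[mask], rcond=None)[0]
            pred = b[0] + b[1] * t[i] + b[2] * t[i]**2
            errs.append((y[i] - pred) ** 2)
        assert mmse == pytest.approx(float(np.mean(errs)), rel=1e-8)

    def test_pure_noise_point_raises_mmse(self):
        rng = np.random.default_rng(4)
        t = np.linspace(10, 190, 10)
        y = 3 + 0.005 * t + 0.02 * rng.standard_normal(10)
        base, _ = loocv_mmse((t, y), "SIMLIN")
        t2 = np.append(t, 200.0)
        y2 = np.append(y, 3 + 0.005 * 200 + 2.0)  # gross outlier
        worse, _ = loocv_mmse((t2, y2), "SIMLIN")
        assert worse > base

    def test_too_short_series_missing(self):
        t = np.arange(10.0, 50.0, 10.0)
        mmse, _ = loocv_mmse((t, 2 + 0.01 * t), "QUADRT")
        assert np.isnan(mmse)


class TestRanking:
    def _herd(self, code, n_goats, noise, seed, n=14):
        spec = get_model(code)
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n_goats):
            t = np.linspace(6, 208, n)
            b = spec.typical(4.0) * (1 + 0.05 * rng.standard_normal(
                spec.n_params))
            y = spec(b, t) * (1 + noise * rng.standard_normal(n))
            out.append(ComponentSeries(f"g{i}", "protein", t, np.abs(y)))
        return out

    def test_single_model_ranks_first(self):
        series = self._herd("SIMLIN", 4, 0.05, 0)
        rep = rank_models(sweep(series, ["SIMLIN"]))
        assert rep["rank"].tolist() == [1]

    def test_generating_model_beats_straight_line(self):
        wins = 0
        for seed in range(8):
            series = self._herd("ALISCH", 25, 0.141, 100 + seed)
            rep = rank_models(sweep(series, ["ALISCH", "SIMLIN"]))
            wins += rep.index[0] == "ALISCH"
        assert wins >= 7

    def test_unfittable_model_ranks_last_with_missing_criteria(self):
        series = [ComponentSeries("g", "protein",
                                  t=np.linspace(10, 100, 4),
                                  y=np.array([4.0, 4.1, 3.9, 4.0]))]
        rep = rank_models(sweep(series, ["SIMLIN", "ALISCH"]))
        assert rep.index[-1] == "ALISCH"
        assert rep.loc["ALISCH", "percent_fitted"] == 0.0
        assert np.isnan(rep.loc["ALISCH", "mean_adj_r2"])

    def test_adj_r2_definition_equivalence(self):
        rng = np.random.default_rng(2)
        t = np.linspace(8, 205, 15)
        y = 4 + 0.003 * t + 0.1 * rng.standard_normal(15)
        fit = fit_series((t, y), "QUADRT")
        tss = float(np.sum((y - y.mean()) ** 2))
        direct = 1 - (fit.rss / tss) * (fit.n - 1) / (fit.n - fit.k - 1)
        assert adjusted_r2(fit.r2, fit.n, fit.k) == pytest.approx(
            direct, rel=1e-12)

    def test_aic_and_bic_rankings_coincide_at_equal_k(self):
        series = self._herd("QUADRT", 10, 0.1, 3)
        rep = rank_models(sweep(series, ["QUADRT", "PARYLDENS", "DAVE"]))
        assert (rep["k"] == 3).all()
        by_aic = rep["mean_aic"].sort_values().index.tolist()
        by_bic = rep["mean_bic"].sort_values().index.tolist()
        assert by_aic == by_bic

    def test_adj_r2_spread_shrinks_with_noise(self):
        sds = []
        for noise in (0.15, 0.02):
            series = self._herd("WOOD", 20, noise, 5)
            rep = rank_models(sweep(series, ["WOOD"]))
            sds.append(rep.loc["WOOD", "sd_adj_r2"])
        assert sds[1] < sds[0]
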