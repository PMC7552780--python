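"""JZS Bayes factors against an independent dense-quadrature oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special
from scipy.integrate import simpson

from lactofit.bayes import (
    DEFAULT_SCALE, bayes_pearson, complexity_anova, evidence_label,
    jzs_anova, jzs_bf10,
)


def oracle_bf10(groups, scale=DEFAULT_SCALE, n_grid=4001):
    """Brute-force JZS ANOVA Bayes factor: dense N x N matrix algebra and
    Simpson quadrature on the substituted g = u/(1-u) axis.  Kept free of
    the package's Woodbury/adaptive-quadrature path."""
    vals = np.concatenate(groups)
    labels = np.concatenate([np.full(len(g), i)
                             for i, g in enumerate(groups)]).astype(int)
    n, p = len(vals), len(groups)
    centering = np.eye(p) - np.ones((p, p)) / p
    w, V = np.linalg.eigh(centering)
    Q = V[:, w > 0.5]
    X = Q[labels, :]
    one = np.ones(n)
    ss0 = vals @ vals - vals.sum() ** 2 / n
    r2 = scale**2
    us = np.linspace(1e-9, 1 - 1e-9, n_grid)
    f = np.empty_like(us)
    for i, u in enumerate(us):
        g = u / (1 - u)
        sigma = np.eye(n) + g * X @ X.T
        si = np.linalg.inv(sigma)
        _, logdet = np.linalg.slogdet(sigma)
        ssg = vals @ si @ vals - (one @ si @ vals) ** 2 / (one @ si @ one)
        lr = (-0.5 * logdet - 0.5 * math.log((one @ si @ one) / n)
              - 0.5 * (n - 1) * math.log(ssg / ss0))
        lp = (0.5 * math.log(r2 / 2) - special.gammaln(0.5)
              - 1.5 * math.log(g) - r2 / (2 * g))
        f[i] = math.exp(lr + lp) / (1 - u) ** 2
    return float(simpson(f, x=us))


def _fixed_datasets(n_sets=20):
    rng = np.random.default_rng(20200918)
    out = []
    for _ in range(n_sets):
        k = int(rng.integers(2, 5))
        out.append([rng.normal(rng.normal(0, 0.8), 1.0,
                               int(rng.integers(5, 12))) for _ in range(k)])
    return out


class TestJZSAnova:
    def test_matches_quadrature_oracle(self):
        for groups in _fixed_datasets(20):
            mine = jzs_bf10(groups)
            ref = oracle_bf10(groups)
            assert mine == pytest.approx(ref, rel=1e-4)

    def test_scale_invariance_of_bf(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)]
        base = jzs_bf10(groups)
        assert jzs_bf10([10.0 * g for g in groups]) == pytest.approx(
            base, rel=1e-6)
        assert jzs_bf10([g + 100.0 for g in groups]) == pytest.approx(
            base, rel=1e-6)

    def test_bf10_times_bf01_is_one(self):
        rng = np.random.default_rng(2)
        res = jzs_anova([rng.normal(0, 1, 20), rng.normal(1, 1, 20)])
        assert res.bf10 * res.bf01 == pytest.approx(1.0, rel=1e-12)

    def test_null_data_mostly_favors_null(self):
        rng = np.random.default_rng(3)
        below = sum(
            jzs_bf10([rng.normal(0, 1, 50), rng.normal(0, 1, 50)]) < 1
            for _ in range(200))
        assert below >= 0.9 * 200

    def test_large_separation_reaches_extreme_band(self):
        rng = np.random.default_rng(4)
        res = jzs_anova([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        assert res.bf10 > 100
        assert res.evidence == "extreme H1"

    def test_posterior_means_shrink_toward_grand_mean(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 25)
        b = rng.normal(1.2, 1, 25)
        res = jzs_anova({"a": a, "b": b}, seed=0)
        grand = np.concatenate([a, b]).mean()
        for name, sample in (("a", a), ("b", b)):
            post = res.posterior_means[name]
            lo_, hi_ = sorted((sample.mean(), grand))
            assert lo_ - 0.05 <= post <= hi_ + 0.05
            lo, hi = res.credible_intervals[name]
            assert lo <= post <= hi

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            jzs_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            jzs_anova([[1.0, 1.0], [1.0, 1.0]])


class TestEvidenceLabels:
    @pytest.mark.parametrize("bf,label", [
        (1.0, "no evidence"),
        (8.367, "moderate H1"),
        (2.173, "anecdotal H1"),
        (0.451, "anecdotal H0"),
        (45.0, "very strong H1"),
        (250.0, "extreme H1"),
        (1 / 40.0, "very strong H0"),
    ])
    def test_bands(self, bf, label):
        assert evidence_label(bf) == label

    def test_invalid_bf_rejected(self):
        with pytest.raises(ValueError):
            evidence_label(0.0)


class TestBayesPearson:
    def test_perfect_correlation_concentrates_near_one(self):
        x = np.linspace(0, 1, 50)
        post = bayes_pearson(x, 2 * x + 1)
        assert post.mean > 0.95
        assert post.ci95[0] > 0.9
        assert post.bf10 > 1e6

    def test_density_normalized(self):
        rng = np.random.default_rng(6)
        post = bayes_pearson(rng.normal(0, 1, 60), rng.normal(0, 1, 60))
        assert np.trapezoid(post.density, post.rho_grid) == pytest.approx(
            1.0, abs=1e-6)

    def test_interval_calibration_under_independence(self):
        rng = np.random.default_rng(7)
        covered = 0
        reps = 300
        for _ in range(reps):
            post = bayes_pearson(rng.standard_normal(200),
                                 rng.standard_normal(200), grid_size=801)
            covered += post.ci95[0] <= 0.0 <= post.ci95[1]
        assert covered / reps == pytest.approx(0.95, abs=0.04)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bayes_pearson(np.ones(10), np.arange(10.0))


class TestComplexityAnova:
    @staticmethod
    def _table(adj_by_class, aic_exchangeable, seed=0, per_class=6):
        rng = np.random.default_rng(seed)
        rows = []
        for cls in (2, 3, 4, 5):
            for _ in range(per_class):
                rows.append({
                    "regressor_count": cls,
                    "mean_adj_r2": adj_by_class[cls]
                    + 0.02 * rng.standard_normal(),
                    "mean_aic": (100.0 if aic_exchangeable
                                 else 100.0 - 10 * cls)
                    + 5.0 * rng.standard_normal(),
                })
        return pd.DataFrame(rows)

    def test_graded_adj_r2_flagged_but_exchangeable_aic_not(self):
        table = self._table({2: 0.20, 3: 0.31, 4: 0.35, 5: 0.45},
                            aic_exchangeable=True, seed=1)
        out = complexity_anova(table, criteria=("mean_adj_r2", "mean_aic"),
                               seed=0)
        assert out["mean_adj_r2"].flagged
        assert not out["mean_aic"].flagged

    def test_identical_criterion_values_favor_null(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({
            "regressor_count": np.repeat([2, 3, 4, 5], 6),
            "mean_adj_r2": 0.3 + 1e-6 * rng.standard_normal(24),
        })
        out = complexity_anova(table, criteria=("mean_adj_r2",), seed=0)
        assert out["mean_adj_r2"].bf10 < 1
        means = list(out["mean_adj_r2"].posterior_means.values())
        assert np.ptp(means) < 1e-3

    def test_single_class_warns_and_skips(self):
        table = pd.DataFrame({"regressor_count": [3, 3, 3],
                              "mean_adj_r2": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning):
            out = complexity_anova(table, criteria=("mean_adj_r2",))
        assert out == {}
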