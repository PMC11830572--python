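import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln

from portal5hmc.io import CountMatrix, GenomicRegion
from portal5hmc.differential import (call_dhmrs, estimate_dispersion,
                                     nb_wald_test, size_factors, welch_t,
                                     wilcoxon_rank_sum, ALPHA_MIN)
from portal5hmc.synthetic import SimulationConfig, simulate_counts


def cm_from(array, samples=None):
    array = np.asarray(array)
    samples = samples or [f"s{i+1}" for i in range(array.shape[1])]
    df = pd.DataFrame(array, index=[f"r{i+1}" for i in range(array.shape[0])],
                      columns=samples)
    return CountMatrix(df, df.sum(axis=0).clip(lower=1).astype(np.int64))


def dummy_regions(n):
    return [GenomicRegion("chr1", i * 1000, i * 1000 + 500, f"hmr_{i:06d}")
            for i in range(n)]


def nb_nll_oracle(y, x, s, alpha):
    """Independent NB log-likelihood, maximized numerically."""
    r = 1.0 / alpha

    def nll(b):
        mu = np.exp(b[0] + b[1] * x) * s
        return -np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                       + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))

    best = minimize(nll, [np.log(y.mean() + 1), 0.0], method="Nelder-Mead",
                    options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return best.x


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = cm_from(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_column_ratio(self):
        a = np.array([[10, 20], [30, 60], [7, 14]])
        sf = size_factors(cm_from(a))
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert sf.iloc[1] == pytest.approx(np.sqrt(2))

    def test_matches_brute_force_median_of_ratios(self):
        rng = np.random.default_rng(21)
        mat = rng.poisson(30, size=(50, 6)) + 1
        sf = size_factors(cm_from(mat)).to_numpy()
        geo = np.exp(np.mean(np.log(mat), axis=1))
        oracle = np.array([np.median(mat[:, j] / geo) for j in range(6)])
        assert np.allclose(sf, oracle)

    def test_no_all_positive_region_errors_with_advice(self):
        mat = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="fallback"):
            size_factors(cm_from(mat))
        sf = size_factors(cm_from(mat), fallback=True)
        assert np.all(sf > 0)


class TestDispersion:
    def test_constant_counts_floor(self):
        cm = cm_from(np.full((3, 8), 50))
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cm.counts.columns)
        disp = estimate_dispersion(cm, size_factors(cm), groups)
        assert np.allclose(disp, ALPHA_MIN)

    def test_poisson_data_small_alpha(self):
        cfg = SimulationConfig(seed=31, frac_differential=0.0,
                               dispersion_range=(1e-8, 1e-8), libsize_log_sd=0.0,
                               group_sizes={"PC": 200, "MLM": 200})
        cm, _ = simulate_counts(cfg, dummy_regions(200))
        groups = pd.Series([s.split("_")[0] for s in cm.sample_ids],
                           index=cm.sample_ids)
        disp = estimate_dispersion(cm, size_factors(cm), groups)
        assert (disp <= 0.01).mean() >= 0.95


class TestNbWald:
    def run_test(self, cm, contrast=("PC", "MLM")):
        groups = pd.Series([s.split("_")[0] for s in cm.sample_ids],
                           index=cm.sample_ids)
        sf = size_factors(cm, fallback=True)
        disp = estimate_dispersion(cm, sf, groups)
        return nb_wald_test(cm, sf, groups, disp, contrast=contrast), sf, disp

    def test_swapping_groups_negates_log2fc(self):
        cfg = SimulationConfig(seed=41, frac_differential=0.3,
                               group_sizes={"PC": 6, "MLM": 6})
        cm, _ = simulate_counts(cfg, dummy_regions(40))
        a, _, _ = self.run_test(cm, ("PC", "MLM"))
        b, _, _ = self.run_test(cm, ("MLM", "PC"))
        assert np.allclose(a.log2fc, -b.log2fc, atol=1e-6)
        assert np.allclose(a.pvalue, b.pvalue, atol=1e-8)

    def test_closed_form_limit_fourfold(self):
        # equal size factors, tiny dispersion, huge n: log2fc -> 2
        rng = np.random.default_rng(7)
        n = 2000
        y = np.concatenate([rng.poisson(100, n), rng.poisson(400, n)])
        cm = cm_from(y[None, :],
                     samples=[f"PC_{i:04d}" for i in range(n)]
                     + [f"MLM_{i:04d}" for i in range(n)])
        groups = pd.Series([s.split("_")[0] for s in cm.sample_ids],
                           index=cm.sample_ids)
        sf = pd.Series(1.0, index=cm.counts.columns)
        disp = pd.Series(1e-8, index=cm.counts.index)
        res = nb_wald_test(cm, sf, groups, disp, contrast=("PC", "MLM"))
        assert res.log2fc.iloc[0] == pytest.approx(2.0, abs=0.02)

    def test_matches_likelihood_oracle_on_small_fixtures(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            y = rng.integers(1, 120, size=6).astype(float)
            s = rng.uniform(0.6, 1.6, size=6)
            alpha = float(rng.uniform(0.05, 0.3))
            x = np.array([0, 0, 0, 1, 1, 1], dtype=float)
            cm = cm_from(y[None, :].astype(int),
                         samples=["PC_1", "PC_2", "PC_3", "MLM_1", "MLM_2", "MLM_3"])
            groups = pd.Series([c.split("_")[0] for c in cm.counts.columns],
                               index=cm.counts.columns)
            res = nb_wald_test(cm, pd.Series(s, index=cm.counts.columns), groups,
                               pd.Series([alpha], index=cm.counts.index),
                               contrast=("PC", "MLM"))
            oracle = nb_nll_oracle(y, x, s, alpha)
            assert res.log2fc.iloc[0] * np.log(2) == pytest.approx(oracle[1], abs=1e-6)

    def test_all_zero_region_flagged(self):
        mat = np.vstack([np.zeros(8, dtype=int), np.full(8, 30)])
        cm = cm_from(mat, samples=[f"PC_{i}" for i in range(4)]
                     + [f"MLM_{i}" for i in range(4)])
        res, _, _ = self.run_test(cm)
        assert res.allzero.iloc[0]
        assert res.pvalue.iloc[0] == 1.0 and res.log2fc.iloc[0] == 0.0
        assert res.pvalue.iloc[1] > 0  # other region unaffected

    def test_pvalue_consistent_with_z(self):
        cfg = SimulationConfig(seed=43, group_sizes={"PC": 10, "MLM": 10})
        cm, _ = simulate_counts(cfg, dummy_regions(50))
        res, _, _ = self.run_test(cm)
        expected = 2 * stats.norm.sf(np.abs(res.wald_z))
        assert np.allclose(res.pvalue, expected)


class TestCallDhmrs:
    def make_results(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "pvalue"],
                            index=[f"r{i}" for i in range(len(rows))])

    def test_infinite_threshold_empties(self):
        res = self.make_results([(3.0, 1e-5), (-2.0, 1e-6)])
        up, down = call_dhmrs(res, np.inf, 0.01)
        assert up == [] and down == []

    @pytest.mark.parametrize("lfc,p,in_up", [
        (0.5, 0.009, True),    # boundary lfc inclusive
        (0.49, 0.009, False),
        (0.5, 0.01, False),    # boundary p strict
        (0.5, 0.0099, True),
    ])
    def test_boundary_semantics(self, lfc, p, in_up):
        res = self.make_results([(lfc, p)])
        up, down = call_dhmrs(res, 0.5, 0.01)
        assert ("r0" in up) is in_up

    def test_down_side_symmetric(self):
        res = self.make_results([(-0.5, 0.001), (-0.4, 0.001), (0.6, 0.5)])
        up, down = call_dhmrs(res, 0.5, 0.01)
        assert down == ["r0"] and up == []


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_antisymmetric_in_arguments(self):
        x, y = [1.0, 2.0, 5.0], [2.0, 4.0, 6.0, 8.0]
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        t_exp = (x.mean() - y.mean()) / np.sqrt(sx2 / nx + sy2 / ny)
        df_exp = (sx2 / nx + sy2 / ny) ** 2 / (
            (sx2 / nx) ** 2 / (nx - 1) + (sy2 / ny) ** 2 / (ny - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        t, df, p = welch_t(x, y)
        assert t == pytest.approx(t_exp)
        assert df == pytest.approx(df_exp)
        assert p == pytest.approx(p_exp)

    def test_zero_variance_both_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_t([2.0, 2.0], [3.0, 3.0])


class TestWilcoxon:
    def test_complete_separation(self):
        u, _ = wilcoxon_rank_sum([10, 11, 12], [1, 2])
        assert u == 6  # nx * ny

    def test_identical_multisets_half(self):
        u, _ = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # nx*ny/2

    def test_brute_force_pair_count(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = rng.normal(size=9)
        u, _ = wilcoxon_rank_sum(x, y)
        oracle = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        assert u == pytest.approx(oracle)


class TestNullCalibrationQuick:
    def test_null_pvalues_roughly_uniform(self):
        cfg = SimulationConfig(seed=61, frac_differential=0.0,
                               group_sizes={"PC": 20, "MLM": 20})
        cm, _ = simulate_counts(cfg, dummy_regions(2000))
        groups = pd.Series([s.split("_")[0] for s in cm.sample_ids],
                           index=cm.sample_ids)
        sf = size_factors(cm)
        disp = estimate_dispersion(cm, sf, groups)
        res = nb_wald_test(cm, sf, groups, disp, contrast=("PC", "MLM"))
        ks = stats.kstest(res.pvalue, "uniform").statistic
        assert ks < 0.05
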