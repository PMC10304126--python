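"""Joint ANOVA, AMMI decomposition, axis tests and the GE partition."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metstab import (cell_means, fit_ammi, fit_ammi_from_dataset,
                     ge_signal_noise, generate_met, ipca_tests, joint_anova,
                     predict_ammi)
from metstab.ammi import AnovaTable

from conftest import dataset_from_array


def brute_force_anova(y):
    """Every sum of squares by definition sums over plots."""
    g, e, r = y.shape
    grand = y.mean()
    gen_m = {i: y[i].mean() for i in range(g)}
    env_m = {j: y[:, j].mean() for j in range(e)}
    cell = {(i, j): y[i, j].mean() for i in range(g) for j in range(e)}
    blk = {(j, k): y[:, j, k].mean() for j in range(e) for k in range(r)}
    ss = dict.fromkeys(["ENV", "REP(ENV)", "GEN", "GEN:ENV", "Residual",
                        "Total"], 0.0)
    for i, j, k in itertools.product(range(g), range(e), range(r)):
        v = y[i, j, k]
        ss["Total"] += (v - grand) ** 2
        ss["ENV"] += (env_m[j] - grand) ** 2
        ss["REP(ENV)"] += (blk[j, k] - env_m[j]) ** 2
        ss["GEN"] += (gen_m[i] - grand) ** 2
        ss["GEN:ENV"] += (cell[i, j] - gen_m[i] - env_m[j] + grand) ** 2
        ss["Residual"] += (v - cell[i, j] - blk[j, k] + env_m[j]) ** 2
    return ss


class TestJointAnova:
    @pytest.mark.parametrize("shape,seed", [((2, 2, 2), 0), ((5, 4, 3), 1)])
    def test_matches_brute_force_enumeration(self, shape, seed):
        rng = np.random.default_rng(seed)
        y = 3.0 + rng.normal(0, 1, shape) ** 2
        data = dataset_from_array(y)
        an = joint_anova(data)
        brute = brute_force_anova(y)
        for src, val in brute.items():
            assert an.table.loc[src, "SS"] == pytest.approx(
                val, rel=1e-8, abs=1e-10), src

    def test_ss_and_df_conservation(self, small_met):
        an = joint_anova(small_met)
        parts = an.table.drop(index="Total")
        assert parts["SS"].sum() == pytest.approx(
            an.table.loc["Total", "SS"], rel=1e-8)
        assert parts["df"].sum() == an.table.loc["Total", "df"]
        assert np.allclose(parts["MS"], parts["SS"] / parts["df"])

    def test_no_genotype_differences(self):
        rng = np.random.default_rng(7)
        env = rng.normal(0, 1, 4)
        y = np.tile(3.0 + env[None, :, None], (3, 1, 2))
        an = joint_anova(dataset_from_array(y))
        assert an.table.loc["GEN", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_environment_dominant_share_recovered(self):
        # generator target: E share ~0.9 of G+E+GE
        shares = []
        for seed in range(5):
            d, _ = generate_met(10, 20, 3, mu=3.0, sigma2_g=0.03,
                                sigma2_e=0.9, lambdas=(1.5,),
                                sigma2_block=0.01, sigma2_res=0.08,
                                seed=seed)
            shares.append(joint_anova(d).shares["E"])
        assert np.mean(shares) == pytest.approx(0.9, abs=0.05)


class TestFitAmmi:
    def test_additive_table_rank_zero(self):
        a = np.array([0.0, 1.0, -1.0])
        b = np.array([0.5, -0.5, 1.0, -1.0])
        tab = pd.DataFrame(3.0 + a[:, None] + b[None, :])
        fit = fit_ammi(tab, r=3, residual_ms=0.1)
        assert np.allclose(fit.singular_values, 0.0)

    def test_rank_one_interaction(self):
        u = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        v = np.array([1.0, -2.0, 1.0]) / np.sqrt(6)
        tab = pd.DataFrame(2.0 + 1.5 * np.outer(u, v))
        fit = fit_ammi(tab, r=3, residual_ms=0.1)
        assert fit.singular_values[0] == pytest.approx(1.5, rel=1e-10)
        assert fit.singular_values[1] == pytest.approx(0.0, abs=1e-10)
        assert fit.explained[0] == pytest.approx(1.0)

    def test_lambda_squared_sums_to_interaction_ss(self):
        rng = np.random.default_rng(11)
        tab = pd.DataFrame(rng.normal(3, 1, (5, 4)))
        fit = fit_ammi(tab, r=2, residual_ms=0.1)
        y = tab.to_numpy()
        z = (y - y.mean(axis=1, keepdims=True)
             - y.mean(axis=0, keepdims=True) + y.mean())
        assert (fit.singular_values ** 2).sum() == pytest.approx(
            (z ** 2).sum(), rel=1e-10)
        # Frobenius reconstruction from all axes
        u = fit.genotype_vectors.to_numpy()
        v = fit.environment_vectors.to_numpy()
        assert np.allclose((u * fit.singular_values) @ v.T, z, atol=1e-10)

    def test_effects_center_and_vectors_orthonormal(self, small_met):
        fit = fit_ammi_from_dataset(small_met)
        assert fit.genotype_effects.sum() == pytest.approx(0.0, abs=1e-10)
        assert fit.environment_effects.sum() == pytest.approx(0.0, abs=1e-10)
        for vec in (fit.genotype_vectors, fit.environment_vectors):
            gram = vec.to_numpy().T @ vec.to_numpy()
            assert np.allclose(gram, np.eye(fit.p), atol=1e-10)
        assert np.all(np.diff(fit.explained) <= 1e-12)
        assert fit.explained.sum() == pytest.approx(1.0)

    def test_permutation_equivariance(self, small_met):
        fit = fit_ammi_from_dataset(small_met)
        rng = np.random.default_rng(4)
        y = small_met.to_array()
        pg, pe = rng.permutation(5), rng.permutation(4)
        permuted = dataset_from_array(
            y[np.ix_(pg, pe)],
            gen=[small_met.genotypes[i] for i in pg],
            env=[small_met.environments[j] for j in pe])
        fit2 = fit_ammi_from_dataset(permuted)
        assert np.allclose(fit.singular_values, fit2.singular_values)
        pd.testing.assert_series_equal(
            fit.genotype_effects.sort_index(),
            fit2.genotype_effects.sort_index(), atol=1e-10)


class TestIpcaTests:
    def test_gollob_df_formula(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(rng.normal(3, 1, (12, 28)))
        fit = fit_ammi(tab, r=3, residual_ms=0.1, residual_df=616)
        tests = ipca_tests(fit)
        assert tests.loc["IPCA1", "df"] == 37
        assert list(tests["df"]) == [12 + 28 - 1 - 2 * k
                                     for k in range(1, 12)]

    def test_zero_axis_f_zero_p_one(self):
        a = np.array([0.0, 1.0, -1.0])
        tab = pd.DataFrame(3.0 + a[:, None] + np.zeros((3, 4)))
        fit = fit_ammi(tab, r=3, residual_ms=0.1, residual_df=24)
        tests = ipca_tests(fit)
        assert (tests["F"] == 0).all() and (tests["p"] == 1).all()

    def test_planted_axes_detected(self):
        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            d, _ = generate_met(10, 15, 3, mu=3.0, sigma2_g=0.05,
                                sigma2_e=0.5, lambdas=(2.5, 1.8),
                                sigma2_block=0.01, sigma2_res=0.09,
                                seed=seed)
            p = ipca_tests(fit_ammi_from_dataset(d))["p"]
            detected += bool(p.iloc[0] < 0.05 and p.iloc[1] < 0.05)
        assert detected >= 0.9 * n_seeds

    def test_cumulative_percent(self, small_met):
        tests = ipca_tests(fit_ammi_from_dataset(small_met))
        assert tests["cumulative_pct"].iloc[-1] == pytest.approx(100.0)
        assert tests["cumulative_pct"].is_monotonic_increasing


class TestGeSignalNoise:
    def test_direct_formula(self):
        tab = pd.DataFrame(
            {"df": [20, 40], "SS": [100.0, 100.0], "MS": [5.0, 2.5],
             "F": [np.nan] * 2, "p": [np.nan] * 2},
            index=["GEN:ENV", "Residual"])
        part = ge_signal_noise(AnovaTable(tab, {}, 3, 4, 3))
        assert part.noise == 50.0 and part.signal == 50.0
        assert part.signal_fraction == 0.5

    def test_zero_residual_all_signal(self, small_met):
        an = joint_anova(small_met)
        forced = AnovaTable(an.table.copy(), an.shares, an.g, an.e, an.r)
        forced.table.loc["Residual", "MS"] = 0.0
        assert ge_signal_noise(forced).signal_fraction == 1.0

    def test_pure_noise_fraction_near_zero(self):
        fracs = []
        for seed in range(10):
            d, _ = generate_met(8, 10, 3, mu=3.0, sigma2_g=0.05,
                                sigma2_e=0.4, lambdas=(), sigma2_block=0.0,
                                sigma2_res=0.25, seed=seed)
            fracs.append(ge_signal_noise(joint_anova(d)).signal_fraction)
        assert np.mean(fracs) == pytest.approx(0.0, abs=0.1)


class TestPredictAmmi:
    def test_k_zero_is_additive(self, small_met):
        fit = fit_ammi_from_dataset(small_met)
        pred = predict_ammi(fit, 0)
        expect = (fit.grand_mean
                  + fit.genotype_effects.to_numpy()[:, None]
                  + fit.environment_effects.to_numpy()[None, :])
        assert np.allclose(pred.to_numpy(), expect)

    def test_full_rank_reproduces_cell_means(self, small_met):
        fit = fit_ammi_from_dataset(small_met)
        pred = predict_ammi(fit, fit.p)
        assert np.allclose(pred.to_numpy(), cell_means(small_met).to_numpy(),
                           atol=1e-10)

    def test_rank_one_recovered_exactly_at_k1(self):
        u = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        v = np.array([1.0, -2.0, 1.0]) / np.sqrt(6)
        tab = pd.DataFrame(2.0 + 1.5 * np.outer(u, v))
        fit = fit_ammi(tab, r=3, residual_ms=0.1)
        assert np.allclose(predict_ammi(fit, 1).to_numpy(), tab.to_numpy(),
                           atol=1e-10)

    def test_rss_nonincreasing_in_k(self, small_met):
        fit = fit_ammi_from_dataset(small_met)
        obs = cell_means(small_met).to_numpy()
        rss = [((predict_ammi(fit, k).to_numpy() - obs) ** 2).sum()
               for k in range(fit.p + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(rss, rss[1:]))

    def test_k_out_of_range(self, small_met):
        fit = fit_ammi_from_dataset(small_met)
        with pytest.raises(Exception):
            predict_ammi(fit, fit.p + 1)
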