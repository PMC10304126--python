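"""Variance components, BLUP shrinkage, and the mixed-model oracle."""

import numpy as np
import pandas as pd
import pytest

from metstab import (blup_ge_matrix, cell_means, fit_blup, generate_met,
                     genotype_blups, joint_anova, variance_components)
from metstab.blup import VarianceComponents

from conftest import dataset_from_array


def henderson_solve(data, vc):
    """Direct mixed-model-equations BLUP of genotype and GE effects.

    Fixed: intercept, environments, blocks within environments; random:
    genotypes and GE with the given variance components.  Solved by
    pseudo-inverse of the (singular in the fixed part, unique in the
    random part) Henderson system.
    """
    rec = data.records
    n = len(rec)
    gi = {g: i for i, g in enumerate(data.genotypes)}
    ei = {e: i for i, e in enumerate(data.environments)}
    X = [np.ones(n)]
    X += [(rec["environment"] == e).to_numpy(float)
          for e in data.environments]
    X += [((rec["environment"] == e) & (rec["replicate"] == r)
           ).to_numpy(float)
          for e in data.environments for r in data.replicates]
    X = np.column_stack(X)
    Zg = np.zeros((n, data.g))
    Zge = np.zeros((n, data.g * data.e))
    for i, (gg, ee) in enumerate(zip(rec["genotype"], rec["environment"])):
        Zg[i, gi[gg]] = 1.0
        Zge[i, gi[gg] * data.e + ei[ee]] = 1.0
    Z = np.hstack([Zg, Zge])
    Dinv = np.diag([vc.sigma2_res / vc.sigma2_g] * data.g
                   + [vc.sigma2_res / vc.sigma2_ge] * (data.g * data.e))
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + Dinv]])
    yv = rec["yield"].to_numpy()
    sol = np.linalg.pinv(C) @ np.concatenate([X.T @ yv, Z.T @ yv])
    u = sol[X.shape[1]:]
    return u[:data.g], u[data.g:].reshape(data.g, data.e)


@pytest.fixture(scope="module")
def vc_fixture():
    data, _ = generate_met(5, 4, 3, mu=3.0, sigma2_g=0.5, sigma2_e=0.3,
                           lambdas=(1.5,), sigma2_ge=0.1,
                           sigma2_block=0.02, sigma2_res=0.1, seed=11)
    return data, variance_components(data)


class TestVarianceComponents:
    def test_hand_enumerated_two_by_two(self, toy222):
        an = joint_anova(toy222)
        ms_g = an.table.loc["GEN", "MS"]
        ms_ge = an.table.loc["GEN:ENV", "MS"]
        ms_res = an.residual_ms
        vc = variance_components(toy222)
        assert vc.sigma2_res == pytest.approx(ms_res)
        assert vc.sigma2_ge == pytest.approx(max((ms_ge - ms_res) / 2, 0.0))
        assert vc.sigma2_g == pytest.approx(max((ms_g - ms_ge) / 4, 0.0))

    def test_pure_noise_components_near_zero(self):
        ests = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            d = dataset_from_array(3.0 + rng.normal(0, 0.3, (6, 5, 3)))
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    vc = variance_components(d)
            ests.append([vc.sigma2_g, vc.sigma2_ge])
        mean = np.mean(ests, axis=0)
        assert mean[0] == pytest.approx(0.0, abs=0.01)
        assert mean[1] == pytest.approx(0.0, abs=0.01)

    def test_parameter_recovery_within_ten_percent(self):
        truth = dict(sigma2_g=0.25, sigma2_ge=0.10, sigma2_res=0.30)
        ests = []
        for seed in range(200):
            d, _ = generate_met(10, 8, 3, mu=4.0, sigma2_e=0.4,
                                lambdas=(), sigma2_block=0.01, seed=seed,
                                **truth)
            vc = variance_components(d)
            ests.append([vc.sigma2_g, vc.sigma2_ge, vc.sigma2_res])
        mean = np.mean(ests, axis=0)
        for got, want in zip(mean, truth.values()):
            assert got == pytest.approx(want, rel=0.10)

    def test_all_nonnegative(self, vc_fixture):
        _, vc = vc_fixture
        assert min(vc.sigma2_g, vc.sigma2_ge, vc.sigma2_res) >= 0


class TestGenotypeBlups:
    def test_no_nongenetic_variance_returns_raw_means(self, small_met):
        vc = VarianceComponents(sigma2_g=0.4, sigma2_ge=0.0, sigma2_res=0.0)
        blups = genotype_blups(small_met, vc)
        raw = cell_means(small_met).mean(axis=1)
        pd.testing.assert_series_equal(blups, raw, atol=1e-12,
                                       check_names=False)

    def test_zero_genetic_variance_collapses_to_grand_mean(self, small_met):
        vc = VarianceComponents(sigma2_g=0.0, sigma2_ge=0.1, sigma2_res=0.2)
        blups = genotype_blups(small_met, vc)
        mu = cell_means(small_met).to_numpy().mean()
        assert np.allclose(blups, mu)

    def test_matches_mixed_model_equations(self, vc_fixture):
        data, vc = vc_fixture
        u_g, _ = henderson_solve(data, vc)
        blups = genotype_blups(data, vc)
        mu = cell_means(data).to_numpy().mean()
        assert np.allclose(blups.to_numpy() - mu, u_g, atol=1e-8)

    def test_shrinkage_bound(self, vc_fixture):
        data, vc = vc_fixture
        blups = genotype_blups(data, vc)
        tab = cell_means(data)
        mu = tab.to_numpy().mean()
        raw_dev = (tab.mean(axis=1) - mu).abs()
        assert ((blups - mu).abs() <= raw_dev + 1e-12).all()

    def test_ranking_preserved_on_balanced_data(self, vc_fixture):
        # shrinkage is common to all genotypes, so order cannot change
        data, vc = vc_fixture
        blups = genotype_blups(data, vc)
        raw = cell_means(data).mean(axis=1)
        assert list(blups.sort_values().index) == \
            list(raw.sort_values().index)


class TestBlupGEMatrix:
    def test_no_residual_keeps_raw_interaction(self, small_met):
        vc = VarianceComponents(sigma2_g=0.1, sigma2_ge=0.3, sigma2_res=0.0)
        ge = blup_ge_matrix(small_met, vc).to_numpy()
        y = cell_means(small_met).to_numpy()
        z = (y - y.mean(axis=1, keepdims=True)
             - y.mean(axis=0, keepdims=True) + y.mean())
        assert np.allclose(ge, z)

    def test_zero_interaction_variance_gives_zero_matrix(self, small_met):
        vc = VarianceComponents(sigma2_g=0.1, sigma2_ge=0.0, sigma2_res=0.2)
        assert np.allclose(blup_ge_matrix(small_met, vc).to_numpy(), 0.0)

    def test_doubly_centered_and_contractive(self, vc_fixture):
        data, vc = vc_fixture
        ge = blup_ge_matrix(data, vc).to_numpy()
        assert np.allclose(ge.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(ge.sum(axis=1), 0.0, atol=1e-10)
        y = cell_means(data).to_numpy()
        z = (y - y.mean(axis=1, keepdims=True)
             - y.mean(axis=0, keepdims=True) + y.mean())
        assert np.linalg.norm(ge) <= np.linalg.norm(z) + 1e-12

    def test_shrinkage_contractive_over_random_components(self, small_met):
        rng = np.random.default_rng(6)
        y = cell_means(small_met).to_numpy()
        z = (y - y.mean(axis=1, keepdims=True)
             - y.mean(axis=0, keepdims=True) + y.mean())
        for _ in range(20):
            vc = VarianceComponents(sigma2_g=rng.uniform(0, 1),
                                    sigma2_ge=rng.uniform(0, 1),
                                    sigma2_res=rng.uniform(0, 1))
            ge = blup_ge_matrix(small_met, vc).to_numpy()
            assert np.linalg.norm(ge) <= np.linalg.norm(z) + 1e-12


def test_accuracy_improves_with_trial_size():
    """Correlation with true genotype effects grows with g*e*r."""
    cors = []
    for (g, e) in ((6, 4), (12, 16)):
        run = []
        for seed in range(25):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d, truth = generate_met(g, e, 3, mu=3.0, sigma2_g=0.05,
                                        sigma2_e=0.4, lambdas=(),
                                        sigma2_ge=0.05, sigma2_block=0.01,
                                        sigma2_res=0.2, seed=seed)
                fit = fit_blup(d)
                with np.errstate(invalid="ignore"):
                    c = np.corrcoef(fit.genotype_means.to_numpy(),
                                    truth.genotype_effects.to_numpy())[0, 1]
            # a truncated-to-zero genetic variance predicts a constant:
            # no information, correlation counted as 0
            run.append(0.0 if np.isnan(c) else c)
        cors.append(np.mean(run))
    assert cors[1] >= cors[0]
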