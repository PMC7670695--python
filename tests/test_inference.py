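"""PC priors, the collapsed sampler, the MME oracle and DIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from spatialbv import (McmcConfig, ModelSpec, PCPrior, RelationshipMatrix,
                       blup_given_variances, build_model_data, dic, fit,
                       pc_prior_range, pc_prior_sd)

# ---------------------------------------------------------------------------
# synthetic model-matched data


def synth_data(n=120, n_pred=20, n_herds=40, seed=0, hypers=None,
               beta0=0.2):
    """Data drawn exactly from the evaluation model, with a random PSD K."""
    hypers = hypers or dict(sigma2_a=0.3, sigma2_h=0.2, sigma2_s=0.25,
                            rho=0.3, sigma2_e=0.2)
    rng = np.random.default_rng(seed)
    m = n + n_pred
    B = rng.standard_normal((m, m // 2)) / np.sqrt(m // 2)
    K = B @ B.T + 0.3 * np.eye(m)
    coords = rng.random((n_herds, 2))
    hidx = np.concatenate([np.arange(n_herds),
                           rng.integers(0, n_herds, n - n_herds)])
    from spatialbv.spatial import MaternParams, sample_grf

    a = np.linalg.cholesky(K) @ rng.standard_normal(m) * np.sqrt(hypers["sigma2_a"])
    h = rng.standard_normal(n_herds) * np.sqrt(hypers["sigma2_h"])
    s = sample_grf(coords, MaternParams(hypers["sigma2_s"], hypers["rho"]), rng) \
        if hypers["sigma2_s"] > 0 else np.zeros(n_herds)
    e = rng.standard_normal(n) * np.sqrt(hypers["sigma2_e"])
    y = beta0 + a[:n] + h[hidx] + s[hidx] + e

    records = pd.DataFrame({"id": np.arange(1, n + 1), "herd": hidx + 1, "y": y})
    Kmat = RelationshipMatrix(kind="genomic_G", ids=np.arange(1, m + 1), matrix=K)
    data = build_model_data(records, coords, Kmat,
                            pred_ids=np.arange(n + 1, m + 1))
    return data, hypers, dict(a=a, h=h, s=s)


# ---------------------------------------------------------------------------
# penalised complexity priors


class TestPCPriors:
    def test_sd_rate_identity(self):
        p = pc_prior_sd(0.25, 0.5)
        assert p.lam == pytest.approx(np.log(2) / 0.25)    # 2.7726
        assert p.median == pytest.approx(0.25)

    def test_sd_tail_probability_by_integration(self):
        p = pc_prior_sd(0.3, 0.5)
        tail, _ = integrate.quad(lambda x: np.exp(p.logpdf(x)), 0.3, np.inf)
        assert tail == pytest.approx(0.5, abs=1e-8)

    def test_additive_prior_median_from_study_settings(self):
        p = pc_prior_sd(0.10, 0.50)     # the additive-sd prior of every model
        assert p.median == pytest.approx(0.10)
        assert p.median ** 2 == pytest.approx(0.01)

    def test_range_tail_probability_by_integration(self):
        p = pc_prior_range(0.60, 0.95)
        mass, _ = integrate.quad(lambda x: np.exp(p.logpdf(x)), 0, 0.60)
        assert mass == pytest.approx(0.95, abs=1e-6)

    @pytest.mark.parametrize("u, alpha", [(0.2, 0.3), (1.5, 0.8)])
    def test_range_cdf_matches_alpha_anywhere(self, u, alpha):
        p = pc_prior_range(u, alpha)
        assert p.cdf(u) == pytest.approx(alpha)

    def test_sampler_quantiles_match_inverse_cdf(self, rng):
        p = pc_prior_range(0.6, 0.95)
        draws = p.sample(rng, size=50_000)
        for q in (0.1, 0.5, 0.9):
            assert np.quantile(draws, q) == pytest.approx(p.ppf(q), rel=0.05)

    def test_degenerate_alpha_rejected(self):
        for alpha in (0.0, 1.0):
            with pytest.raises(ValueError):
                PCPrior(u=0.1, alpha=alpha)


# ---------------------------------------------------------------------------
# sampler against exact conditional results


class TestFitFixedHypers:
    def test_single_animal_shrinkage(self):
        """One record, known variances: E[a|y] = y sigma_a^2/(sigma_a^2+sigma_e^2)."""
        y = 1.7
        records = pd.DataFrame({"id": [1], "herd": [1], "y": [y]})
        K = RelationshipMatrix("genomic_G", np.array([1]), np.eye(1))
        data = build_model_data(records, np.array([[0.5, 0.5]]), K, [])
        spec = ModelSpec.named("G")
        spec.prior_beta_variance = 1e-12        # pin the intercept at zero
        summ = fit(data, spec, McmcConfig(n_iter=4000, burn_in=0, thin=1),
                   seed=1, fixed_hypers=dict(sigma2_a=0.3, sigma2_e=0.2))
        expected = y * 0.3 / 0.5
        se = summ.bv_sd[0] / np.sqrt(summ.bv_samples.shape[0])
        assert summ.bv_mean[0] == pytest.approx(expected, abs=4 * se)

    def test_posterior_mean_matches_mme_oracle(self):
        """Fixed hypers: the sampler's mean equals the Henderson solution."""
        data, hypers, _ = synth_data(n=120, n_pred=20, seed=3)
        spec = ModelSpec.named("GHS")
        sol = blup_given_variances(data, spec, hypers)
        summ = fit(data, spec, McmcConfig(n_iter=600, burn_in=0, thin=1),
                   seed=4, fixed_hypers=hypers)
        se = summ.bv_sd / np.sqrt(summ.bv_samples.shape[0])
        z = (summ.bv_mean - sol["a"]) / se
        assert np.abs(z).max() < 4.5
        assert np.abs(z.mean()) < 0.5
        assert np.corrcoef(summ.bv_mean, sol["a"])[0, 1] > 0.999

    def test_record_order_is_immaterial(self, rng):
        data, hypers, _ = synth_data(n=40, n_pred=5, n_herds=15, seed=5)
        records = pd.DataFrame({"id": np.arange(1, 41),
                                "herd": data.herd_index + 1, "y": data.y})
        shuffled = records.sample(frac=1.0, random_state=7)
        K = RelationshipMatrix("genomic_G", data.K.ids, data.K.matrix)
        d2 = build_model_data(shuffled, data.herd_coords, K,
                              pred_ids=np.arange(41, 46))
        spec = ModelSpec.named("GHS")
        mc = McmcConfig(n_iter=50, burn_in=0, thin=1)
        a = fit(data, spec, mc, seed=8, fixed_hypers=hypers)
        b = fit(d2, spec, mc, seed=8, fixed_hypers=hypers)
        np.testing.assert_allclose(a.bv_mean, b.bv_mean)

    def test_missing_fixed_hyper_rejected(self):
        data, _, _ = synth_data(n=30, n_pred=2, n_herds=10, seed=9)
        with pytest.raises(ValueError, match="missing"):
            fit(data, ModelSpec.named("GHS"), seed=1,
                fixed_hypers=dict(sigma2_a=0.1))


class TestBlupOracle:
    def test_zero_genetic_variance_zero_ebv(self):
        data, hypers, _ = synth_data(n=50, n_pred=5, n_herds=20, seed=11)
        sol = blup_given_variances(data, ModelSpec.named("GHS"),
                                   {**hypers, "sigma2_a": 0.0})
        np.testing.assert_array_equal(sol["a"], 0.0)

    def test_ghs_reduces_to_gs_without_herd_variance(self):
        data, hypers, _ = synth_data(n=60, n_pred=5, n_herds=20, seed=12)
        hy = {**hypers, "sigma2_h": 0.0}
        a_ghs = blup_given_variances(data, ModelSpec.named("GHS"), hy)["a"]
        a_gs = blup_given_variances(data, ModelSpec.named("GS"),
                                    {k: v for k, v in hy.items()
                                     if k != "sigma2_h"})["a"]
        np.testing.assert_allclose(a_ghs, a_gs, atol=1e-8)

    def test_balanced_one_way_shrinkage_closed_form(self, rng):
        """Single random effect: h_j = k sigma_h^2/(k sigma_h^2+sigma_e^2) ybar_j."""
        n_herds, k = 25, 4
        hidx = np.repeat(np.arange(n_herds), k)
        y = rng.standard_normal(n_herds * k)
        records = pd.DataFrame({"id": np.arange(1, y.size + 1),
                                "herd": hidx + 1, "y": y})
        K = RelationshipMatrix("genomic_G", np.arange(1, y.size + 1),
                               np.eye(y.size))
        data = build_model_data(records, rng.random((n_herds, 2)), K, [])
        spec = ModelSpec(name="GH", use_herd=True, prior_beta_variance=1e-12)
        sig_h, sig_e = 0.5, 0.3
        sol = blup_given_variances(
            data, spec, dict(sigma2_a=0.0, sigma2_h=sig_h, sigma2_e=sig_e))
        ybar = records.groupby("herd")["y"].mean().to_numpy()
        expected = k * sig_h / (k * sig_h + sig_e) * ybar
        np.testing.assert_allclose(sol["h"], expected, atol=1e-6)


# ---------------------------------------------------------------------------
# full sampling: recovery and model comparison


class TestSampling:
    def test_variance_components_recovered_with_nominal_coverage(self):
        """50% intervals should bracket the truth in a fair share of replicates."""
        truth = dict(sigma2_a=0.1, sigma2_h=0.25, sigma2_s=0.4, rho=0.3,
                     sigma2_e=0.25)
        hits = {k: 0 for k in ("sigma2_a", "sigma2_h", "sigma2_s", "sigma2_e")}
        n_rep = 10
        for rep in range(n_rep):
            data, _, _ = synth_data(n=400, n_pred=5, n_herds=100,
                                    seed=100 + rep, hypers=truth)
            summ = fit(data, ModelSpec.named("GHS"),
                       McmcConfig(n_iter=800, burn_in=300, thin=5),
                       seed=200 + rep)
            q = summ.hyper_samples.quantile([0.25, 0.75])
            for k in hits:
                if q.loc[0.25, k] <= truth[k] <= q.loc[0.75, k]:
                    hits[k] += 1
        for k, n_hit in hits.items():
            assert n_hit >= 3, f"{k}: {n_hit}/{n_rep} coverage"

    def test_diagnostics_reported(self):
        data, _, _ = synth_data(n=60, n_pred=5, n_herds=20, seed=13)
        summ = fit(data, ModelSpec.named("GH"),
                   McmcConfig(n_iter=400, burn_in=150, thin=5), seed=14)
        assert 0.05 <= summ.diagnostics["acceptance_rate"] <= 0.95
        assert set(summ.diagnostics["ess"]) == {"sigma2_a", "sigma2_h", "sigma2_e"}
        assert summ.bv_samples.shape[0] == summ.diagnostics["n_samples"]
        assert np.all(summ.bv_sd >= 0)


class TestDic:
    def test_degenerate_posterior_has_no_effective_parameters(self):
        devs = np.full(50, 123.4)
        assert dic(devs, 123.4) == pytest.approx(123.4)

    def test_hand_computed_two_sample_case(self):
        devs = np.array([10.0, 14.0])       # mean 12; p_D = 12 - 9 = 3
        assert dic(devs, 9.0) == pytest.approx(15.0)

    def test_herd_model_preferred_on_herd_structured_data(self):
        data, _, _ = synth_data(n=150, n_pred=5, n_herds=50, seed=15,
                                hypers=dict(sigma2_a=0.1, sigma2_h=0.6,
                                            sigma2_s=0.0, rho=0.3,
                                            sigma2_e=0.2))
        mc = McmcConfig(n_iter=700, burn_in=250, thin=5)
        dic_g = fit(data, ModelSpec.named("G"), mc, seed=16).dic
        dic_gh = fit(data, ModelSpec.named("GH"), mc, seed=17).dic
        assert dic_gh <= dic_g + 5.0
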