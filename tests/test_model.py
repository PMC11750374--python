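import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wingallometry.model import (
    ModelParameters, PriorConfig, SamplerConfig, _LogPosterior, _ModelData,
    _empirical_bayes, beta_hat, fit, linear_predictor, log_joint_density, rhat,
)
from wingallometry.nuts import sample_nuts
from wingallometry.simulate import SimulationConfig, simulate_dataset

from _oracles import log_joint_oracle, random_model_instance
from conftest import covariate_table_from_dict


def instance_to_frames(params, rows, g_dict):
    data = pd.DataFrame(rows, columns=["species", "year", "sex_code", "z", "w"])
    table = covariate_table_from_dict(g_dict, params.columns)
    return data, table


class TestLinearPredictor:
    @pytest.mark.parametrize("args,expected", [
        ((0.5, 0.2, 0.1, -0.05, 1.0, 1), 0.75),
        ((0.3, 0.7, 0.2, 0.4, 0.0, 0), 0.3),
        ((0.5, 0.2, 0.1, -0.05, 2.0, 0), 0.9),
    ])
    def test_examples(self, args, expected):
        assert linear_predictor(*args) == pytest.approx(expected)

    def test_vectorized(self):
        z = np.array([0.0, 1.0, -1.0])
        out = linear_predictor(1.0, 0.5, 0.2, 0.1, z, np.array([0, 1, 1]))
        np.testing.assert_allclose(out, [1.0, 1.8, 0.6])


class TestBetaHat:
    def test_examples(self):
        assert beta_hat([0.47, 0.18], [1.0, 1.5]) == pytest.approx(0.74)
        assert beta_hat([0.3, 0.1, -0.2], [1, 0, 0]) == pytest.approx(0.3)
        assert beta_hat([0.0, 0.0], [1.0, 2.0]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            beta_hat([1.0], [1.0, 2.0])


class TestLogJointDensity:
    def test_matches_scipy_oracle_on_random_instances(self, rng):
        """Hand-rolled log joint equals an independently coded
        scipy.stats sum on random tiny instances within 1e-8."""
        for _ in range(100):
            params, rows, g_dict = random_model_instance(rng)
            data, table = instance_to_frames(params, rows, g_dict)
            got = log_joint_density(params, data, table)
            want = log_joint_oracle(params, rows, g_dict)
            assert got == pytest.approx(want, abs=1e-8)

    def test_zero_scale_is_out_of_support(self, rng):
        params, rows, g_dict = random_model_instance(rng)
        data, table = instance_to_frames(params, rows, g_dict)
        params.tau0 = 0.0
        assert log_joint_density(params, data, table) == -math.inf

    def test_translation_leaves_observation_term_unchanged(self, rng):
        """Adding a constant to every w and to the constant-column effects
        (shifting beta0 alike) leaves the observation residuals identical."""
        params, rows, g_dict = random_model_instance(rng)
        data, table = instance_to_frames(params, rows, g_dict)
        base = log_joint_density(params, data, table)

        shift = 0.75
        params2 = ModelParameters(**{**params.__dict__})
        params2.beta0 = params.beta0 + shift
        data2 = data.assign(w=data["w"] + shift)
        shifted = log_joint_density(params2, data2, table)
        # only the beta0-level term changed; remove both analytically
        from scipy import stats
        sp_index = {s: i for i, s in enumerate(params.species)}

        def beta_level(p):
            tot = 0.0
            for j, (sp, y) in enumerate(p.cells):
                g = np.asarray(g_dict[(sp, y)])
                tot += stats.norm.logpdf(
                    p.beta0[j], float(np.dot(p.I0[sp_index[sp]], g)), p.tau0)
            return tot

        assert base - beta_level(params) == pytest.approx(
            shifted - beta_level(params2), abs=1e-9)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        """Every parameterization combination has an exact gradient."""
        cfg = SimulationConfig(n_species=3, year_start=2000, year_end=2004,
                               n_per_species_year=8, seed=3)
        ds = simulate_dataset(cfg)
        md = _ModelData(ds.model_data(), ds.G)
        eb = _empirical_bayes(md)
        rng = np.random.default_rng(0)
        for cb, ci, cn in itertools.product((False, True), repeat=3):
            post = _LogPosterior(md, PriorConfig(),
                                 centered={"beta": cb, "I": ci, "n": cn},
                                 eb=eb)
            q = post.initial_point(rng)
            lp, grad = post.logp_and_grad(q)
            assert np.isfinite(lp)
            idx = rng.choice(post.dim, size=25, replace=False)
            for i in idx:
                qp, qm = q.copy(), q.copy()
                qp[i] += 1e-6
                qm[i] -= 1e-6
                fd = (post.logp_and_grad(qp)[0]
                      - post.logp_and_grad(qm)[0]) / 2e-6
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestCompiledKernel:
    def test_kernel_matches_numpy_reference(self):
        """The compiled gradient kernel and the numpy reference agree on
        every parameterization combination, with and without the
        observation term."""
        from wingallometry._kernels import HAVE_NUMBA

        if not HAVE_NUMBA:
            pytest.skip("numba not installed; numpy path is the only path")
        cfg = SimulationConfig(n_species=3, year_start=2000, year_end=2004,
                               n_per_species_year=8, seed=14)
        ds = simulate_dataset(cfg)
        md = _ModelData(ds.model_data(), ds.G)
        eb = _empirical_bayes(md)
        rng = np.random.default_rng(2)
        for cb, ci, cn in itertools.product((False, True), repeat=3):
            for prior_only in (False, True):
                post = _LogPosterior(
                    md, PriorConfig(), prior_only=prior_only,
                    centered={"beta": cb, "I": ci, "n": cn}, eb=eb)
                q = post.initial_point(rng)
                lp_k, g_k = post.logp_and_grad(q)
                lp_n, g_n = post.logp_and_grad_numpy(q)
                assert lp_k == pytest.approx(lp_n, abs=1e-9)
                np.testing.assert_allclose(g_k, g_n, atol=1e-9)


class TestRhat:
    def test_iid_chains_near_one(self, rng):
        draws = rng.standard_normal((4, 1000))
        assert 1.0 <= rhat(draws) < 1.02

    def test_offset_chains_flagged(self, rng):
        draws = rng.standard_normal((2, 500))
        draws[1] += 10
        assert rhat(draws) > 1.5

    def test_constant_chains_give_inf(self):
        assert rhat(np.ones((3, 100))) == math.inf

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        draws = np.cumsum(rng.standard_normal((4, 400)), axis=1) * 0.01 \
            + rng.standard_normal((4, 400))
        ours = rhat(draws)
        theirs = float(az.rhat(az.convert_to_dataset(draws))["x"].values)
        # arviz uses rank-normalized split-Rhat; agreement is approximate
        assert ours == pytest.approx(theirs, abs=0.05)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))
        with pytest.raises(ValueError):
            rhat(np.ones((2, 2)))


class TestNutsSampler:
    def test_standard_normal_moments(self):
        def logp(q):
            return -0.5 * float(q @ q), -q

        rng = np.random.default_rng(1)
        res = sample_nuts(logp, rng.standard_normal(20),
                          n_iterations=1500, n_warmup=500, rng=rng)
        assert abs(res.samples.mean()) < 0.05
        assert res.samples.var() == pytest.approx(1.0, abs=0.1)
        assert res.n_divergent == 0

    def test_anisotropic_gaussian_adapts_mass(self):
        sd = np.geomspace(0.05, 2.0, 10)

        def logp(q):
            return -0.5 * float(np.sum((q / sd) ** 2)), -q / sd ** 2

        rng = np.random.default_rng(2)
        res = sample_nuts(logp, 0.1 * sd, n_iterations=1200, n_warmup=600,
                          rng=rng)
        ratio = res.samples.std(axis=0) / sd
        assert np.all(ratio > 0.8) and np.all(ratio < 1.25)

    def test_rejects_nonfinite_start(self):
        def logp(q):
            return -math.inf, np.zeros_like(q)

        with pytest.raises(ValueError, match="non-finite"):
            sample_nuts(logp, np.zeros(3), n_iterations=10, n_warmup=5,
                        rng=np.random.default_rng(0))


class TestFit:
    def test_seeded_determinism(self, tiny_dataset):
        cfg = tiny_dataset.config
        sc = SamplerConfig(n_chains=2, n_iterations=120, n_warmup=60, seed=9)
        a = fit(tiny_dataset.model_data(), tiny_dataset.G, cfg.model_spec(), sc)
        b = fit(tiny_dataset.model_data(), tiny_dataset.G, cfg.model_spec(), sc)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_scale_draws_positive(self, tiny_draws):
        for name in ("tau0", "tau1", "sigma_w", "s_n0", "s_n1"):
            assert (tiny_draws.pooled(name) > 0).all()
        assert (tiny_draws.pooled("sigma0") > 0).all()
        assert (tiny_draws.pooled("sigma1") > 0).all()

    def test_draw_counts(self, tiny_draws):
        cfg = tiny_draws.config
        kept = cfg.n_iterations - cfg.n_warmup
        assert tiny_draws.get("mu0").shape[:2] == (cfg.n_chains, kept)
        assert tiny_draws.n_kept == cfg.n_chains * kept

    def test_mismatched_cells_dropped_with_warning(self, tiny_dataset, caplog):
        data = tiny_dataset.model_data()
        extra = data.iloc[:2].copy()
        extra["year"] = 1800
        with caplog.at_level("WARNING"):
            draws = fit(pd.concat([data, extra]), tiny_dataset.G,
                        tiny_dataset.config.model_spec(),
                        SamplerConfig(n_chains=2, n_iterations=60,
                                      n_warmup=30, seed=1))
        assert "dropped" in caplog.text
        assert all(y != 1800 for _, y in draws.cells)

    def test_prior_only_recovers_mu_margin(self):
        """With the observation term removed, the mu margins revert to their
        Normal(0, 2) prior (KS test on thinned pooled draws)."""
        from scipy import stats

        cfg = SimulationConfig(n_species=2, year_start=2010, year_end=2012,
                               n_per_species_year=5, seed=21, covariates=[])
        ds = simulate_dataset(cfg)
        draws = fit(ds.model_data(), ds.G, cfg.model_spec(),
                    SamplerConfig(n_chains=4, n_iterations=1500,
                                  n_warmup=500, seed=17),
                    prior_only=True)
        pooled = draws.pooled("mu0")[:, 0]
        thinned = pooled[::4]
        ks = stats.kstest(thinned, "norm", args=(0, 2))
        assert ks.pvalue > 0.01

    def test_sampler_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_chains=1)
        with pytest.raises(ValueError):
            SamplerConfig(n_warmup=4000, n_iterations=4000)
        with pytest.raises(ValueError):
            SamplerConfig(target_accept=1.5)

    def test_bad_parameterization_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="parameterization"):
            fit(tiny_dataset.model_data(), tiny_dataset.G,
                tiny_dataset.config.model_spec(),
                SamplerConfig(n_chains=2, n_iterations=20, n_warmup=10),
                parameterization="bogus")
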