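"""Sampler building blocks: weighting, tempering, resampling, MH kernel."""

import numpy as np
import pytest
from scipy import optimize, stats

import dipsmc
from dipsmc import (
    DipoleConfig,
    Model,
    MomentPrior,
    NoiseModel,
    SamplerSettings,
    SourcePrior,
    ess,
    initialize_particles,
    mcmc_move,
    next_exponent,
    resample,
    reweight,
    run_smc,
)
from dipsmc.sampler import ConvergenceError, Particle, ParticleSet

from conftest import make_tiny_model, make_recovery_problem


def make_particle_set(logmls, weights=None, gamma=0.0):
    I = len(logmls)
    w = np.full(I, 1.0 / I) if weights is None else np.asarray(weights, float)
    parts = [
        Particle(DipoleConfig(()), 1.0, float(np.log(wi)) if wi > 0 else -np.inf, float(l))
        for wi, l in zip(w, logmls)
    ]
    ps = ParticleSet(parts, gamma=gamma)
    return ps


class TestEss:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            (np.full(100, 0.01), 100.0),
            (np.array([1.0, 0.0, 0.0]), 1.0),
            (np.array([0.5, 0.5, 0.0, 0.0]), 2.0),
        ],
    )
    def test_closed_forms(self, weights, expected):
        assert ess(weights) == pytest.approx(expected)


class TestInitialization:
    def test_seeded_reproducibility(self, tiny_model):
        model, _ = tiny_model
        s = SamplerSettings(n_particles=50, seed=11)
        a = initialize_particles(s, model, np.random.default_rng(11))
        b = initialize_particles(s, model, np.random.default_rng(11))
        assert [p.config for p in a.particles] == [p.config for p in b.particles]
        assert [p.sigma_q for p in a.particles] == [p.sigma_q for p in b.particles]

    def test_prior_frequency_of_empty_config(self, tiny_model):
        model, _ = tiny_model
        rng = np.random.default_rng(42)
        n = 10_000
        draws = [model.source_prior.sample_config(rng).n_dipoles for _ in range(n)]
        p0 = model.source_prior.n_prior_pmf[0]
        freq = np.mean(np.array(draws) == 0)
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(freq - p0) <= 3 * se

    def test_one_hot_vertex_weights_pin_all_dipoles(self):
        model, _ = make_tiny_model(seed=2)
        w = np.zeros(model.n_vertices)
        w[4] = 1.0
        prior = SourcePrior(n_vertices=model.n_vertices, n_max=1, vertex_weights=w)
        rng = np.random.default_rng(0)
        for _ in range(200):
            cfg = prior.sample_config(rng)
            assert all(v == 4 for v in cfg.vertices)

    def test_initial_gamma_and_weights(self, tiny_model):
        model, _ = tiny_model
        ps = initialize_particles(SamplerSettings(n_particles=40), model, np.random.default_rng(1))
        assert ps.gamma == 0.0
        np.testing.assert_allclose(ps.weights, 1 / 40, atol=1e-15)
        # cached marginal likelihood consistent with a fresh recomputation
        p = ps.particles[0]
        assert p.cached_logml == pytest.approx(
            dipsmc.log_marginal_likelihood(
                p.config, p.sigma_q, model.data, model.leadfield, model.noise
            ),
            abs=1e-9,
        )


class TestNextExponent:
    def test_identical_likelihoods_jump_to_one(self):
        ps = make_particle_set([5.0] * 10)
        assert next_exponent(ps, SamplerSettings()) == 1.0

    def test_root_condition_satisfied(self):
        rng = np.random.default_rng(3)
        ps = make_particle_set(rng.normal(0, 40, size=200))
        s = SamplerSettings()
        g = next_exponent(ps, s)
        assert 0 < g <= 1
        if g < 1:
            w = ps.weights * np.exp(g * ps.logml)
            w /= w.sum()
            assert abs(ess(w) - s.ess_decay_target * ps.ess()) <= 0.1

    def test_two_particle_increment_matches_scalar_root(self):
        d = 30.0
        ps = make_particle_set([0.0, d])
        s = SamplerSettings()
        g = next_exponent(ps, s)
        target = s.ess_decay_target * 2.0

        def f(delta):
            w = np.array([0.5, 0.5 * np.exp(delta * d)])
            w /= w.sum()
            return ess(w) - target

        root = optimize.brentq(f, 1e-12, 1.0)
        assert g == pytest.approx(root, abs=1e-5)

    def test_usage_error_at_gamma_one(self):
        ps = make_particle_set([0.0, 1.0], gamma=1.0)
        with pytest.raises(ValueError):
            next_exponent(ps, SamplerSettings())


class TestReweight:
    def test_identity_when_gamma_unchanged(self):
        ps = make_particle_set([1.0, 2.0, 3.0], gamma=0.3)
        before = ps.weights.copy()
        reweight(ps, 0.3)
        np.testing.assert_allclose(ps.weights, before, atol=1e-15)

    def test_closed_form_two_particles(self):
        ps = make_particle_set([np.log(3.0), 0.0])
        reweight(ps, 1.0)
        np.testing.assert_allclose(ps.weights, [0.75, 0.25], atol=1e-12)

    def test_normalization(self):
        rng = np.random.default_rng(4)
        ps = make_particle_set(rng.normal(size=64), gamma=0.2)
        reweight(ps, 0.7)
        assert abs(ps.weights.sum() - 1.0) <= 1e-12


class TestResample:
    def test_degenerate_weight_duplicates_winner(self):
        ps = make_particle_set([0.0] * 8, weights=[1.0] + [0.0] * 7)
        out = resample(ps, np.random.default_rng(0))
        assert all(p.config == ps.particles[0].config for p in out.particles)
        np.testing.assert_allclose(out.weights, 1 / 8, atol=1e-15)

    def test_equal_weights_keep_every_particle_once(self):
        logml = np.arange(6.0)
        ps = make_particle_set(logml)
        out = resample(ps, np.random.default_rng(9))
        assert sorted(p.cached_logml for p in out.particles) == sorted(logml)

    def test_expected_copy_counts_unbiased(self):
        w = np.array([0.5, 0.3, 0.15, 0.05])
        I = len(w)
        n_rep = 10_000
        rng = np.random.default_rng(7)
        counts = np.zeros(I)
        cum = np.cumsum(w)
        for _ in range(n_rep):
            pos = (rng.random() + np.arange(I)) / I
            idx = np.searchsorted(cum, pos, side="right")
            counts += np.bincount(idx, minlength=I)
        mean_counts = counts / n_rep
        # systematic resampling: copy count varies by at most 1, so the SE
        # is bounded by that of a Bernoulli on the fractional part
        for i in range(I):
            frac = I * w[i] - np.floor(I * w[i])
            se = max(np.sqrt(frac * (1 - frac) / n_rep), 1e-12)
            assert abs(mean_counts[i] - I * w[i]) <= 3 * se + 1e-9


class TestMcmcMove:
    def test_birth_beyond_n_max_always_rejected(self):
        model, _ = make_tiny_model(seed=1, n_max=1)
        rng = np.random.default_rng(0)
        p = Particle(DipoleConfig((0,)), 1e-8, 0.0, model.log_marginal(DipoleConfig((0,)), 1e-8))
        s = SamplerSettings(move_probabilities=(1.0, 0.0, 0.0))
        for _ in range(100):
            new, move, accepted = mcmc_move(p, 0.5, model, s, rng)
            assert move == "birth" and not accepted
            assert new.config == p.config

    def test_prior_is_stationary_at_gamma_zero(self):
        """At gamma = 0 the chain must leave the prior over N invariant."""
        model, _ = make_tiny_model(seed=4)
        rng = np.random.default_rng(123)
        n = 10_000
        before, after = [], []
        s = SamplerSettings()
        for _ in range(n):
            cfg = model.source_prior.sample_config(rng)
            sq = model.moment_prior.sample_sigma_q(rng)
            p = Particle(cfg, sq, 0.0, model.log_marginal(cfg, sq))
            before.append(p.config.n_dipoles)
            for _ in range(3):
                p, _, _ = mcmc_move(p, 0.0, model, s, rng)
            after.append(p.config.n_dipoles)
        table = np.array(
            [np.bincount(before, minlength=3), np.bincount(after, minlength=3)]
        )
        table = table[:, table.sum(axis=0) > 0]
        _, pval, _, _ = stats.chi2_contingency(table)
        assert pval > 0.01

    def test_stationary_distribution_matches_enumeration(self):
        """Long MH run at gamma = 1 on a 5-vertex space reproduces the exact posterior."""
        model, _ = make_tiny_model(seed=6, n_max=1)
        # restrict to 5 vertices via prior weights
        w = np.zeros(model.n_vertices)
        w[:5] = 1.0
        prior = SourcePrior(n_vertices=model.n_vertices, n_max=1, vertex_weights=w)
        model = Model(
            model.leadfield, model.data, model.noise, prior,
            model.moment_prior, model.source_space,
        )
        exact = dipsmc.enumerate_posterior(model)
        rng = np.random.default_rng(5)
        cfg = prior.sample_config(rng)
        sq = model.moment_prior.sample_sigma_q(rng)
        p = Particle(cfg, sq, 0.0, model.log_marginal(cfg, sq))
        n_steps, burn = 20_000, 1_000
        counts_n = np.zeros(2)
        counts_v = np.zeros(model.n_vertices)
        s = SamplerSettings()
        for step in range(n_steps + burn):
            p, _, _ = mcmc_move(p, 1.0, model, s, rng)
            if step >= burn:
                counts_n[p.config.n_dipoles] += 1
                for v in p.config.vertices:
                    counts_v[v] += 1
        freq_n = counts_n / n_steps
        # correlated samples: use a conservative effective n
        n_eff = n_steps / 10
        for k in range(2):
            se = max(np.sqrt(exact.n_pmf[k] * (1 - exact.n_pmf[k]) / n_eff), 1e-4)
            assert abs(freq_n[k] - exact.n_pmf[k]) <= 3 * se
        if exact.n_pmf[1] > 0.2:
            freq_v = counts_v / counts_n[1]
            emap = exact.conditional_maps[1]
            for v in range(5):
                se = max(np.sqrt(emap[v] * (1 - emap[v]) / n_eff), 1e-4)
                assert abs(freq_v[v] - emap[v]) <= 3 * se

    def test_rejection_keeps_state(self, tiny_model):
        model, _ = tiny_model
        rng = np.random.default_rng(2)
        cfg = DipoleConfig((0,))
        p = Particle(cfg, 1e-8, -0.5, model.log_marginal(cfg, 1e-8))
        s = SamplerSettings()
        for _ in range(50):
            new, _, accepted = mcmc_move(p, 0.9, model, s, rng)
            if not accepted:
                assert new is p
            p = new


class TestRunSmc:
    def test_same_seed_bitwise_identical(self):
        model, _ = make_tiny_model(seed=8, mode="hyper")
        s = SamplerSettings(n_particles=60, seed=21)
        a, log_a = run_smc(model, s)
        b, log_b = run_smc(model, s)
        assert a.gamma == b.gamma == 1.0
        assert [p.config for p in a.particles] == [p.config for p in b.particles]
        assert [p.sigma_q for p in a.particles] == [p.sigma_q for p in b.particles]
        np.testing.assert_array_equal(a.weights, b.weights)
        assert [r["gamma"] for r in log_a] == [r["gamma"] for r in log_b]

    def test_gamma_schedule_monotone_and_logged(self):
        model, _ = make_tiny_model(seed=9)
        ps, log = run_smc(model, SamplerSettings(n_particles=50, seed=2))
        gammas = [r["gamma"] for r in log]
        assert all(b >= a for a, b in zip(gammas, gammas[1:]))
        assert gammas[-1] == 1.0
        assert all(set(r) >= {"iteration", "gamma", "ess", "acceptance"} for r in log)
        assert abs(ps.weights.sum() - 1.0) <= 1e-12

    def test_null_data_recovers_zero_sources(self):
        model, _ = make_recovery_problem(seed=1, n_dipoles=0, n_vertices=60)
        ps, _ = run_smc(model, SamplerSettings(n_particles=100, seed=3))
        pmf = dipsmc.source_number_posterior(ps, model.source_prior.n_max)
        assert int(np.argmax(pmf)) == 0

    def test_two_dipole_recovery(self):
        model, true_cfg = make_recovery_problem(seed=2, n_vertices=120)
        ps, _ = run_smc(model, SamplerSettings(n_particles=100, seed=4))
        pmf = dipsmc.source_number_posterior(ps, model.source_prior.n_max)
        assert int(np.argmax(pmf)) == 2

    def test_max_iterations_raises_with_partial_state(self):
        model, _ = make_recovery_problem(seed=3, n_vertices=80)
        with pytest.raises(ConvergenceError) as err:
            run_smc(model, SamplerSettings(n_particles=50, seed=5, max_iterations=3))
        assert err.value.particles.gamma < 1.0
        assert len(err.value.log) == 3
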