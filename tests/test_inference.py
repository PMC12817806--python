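import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from mcspace import (Hyperparameters, InferenceConfig, StudyDesign,
                     ParticleCountMatrix, SimulationConfig, simulate_particles,
                     normalize_for_encoder, kmeans_ilr_init, anneal_xi,
                     elbo, fit)
from mcspace.inference import (VariationalPosterior, encode, gaussian_kl,
                               bernoulli_kl)

from oracles import particle_log_marginal_enum


def _pcm(counts):
    counts = np.asarray(counts)
    L, O = counts.shape
    return ParticleCountMatrix(
        counts=counts, particle_ids=[f"p{i}" for i in range(L)],
        otu_ids=[f"OTU{j+1}" for j in range(O)],
        subjects=["S0"] * L, times=[0.0] * L)


class TestNormalize:
    @pytest.mark.parametrize("row,expected", [([2, 2], [0.5, 0.5]),
                                              ([3, 1], [0.75, 0.25])])
    def test_values(self, row, expected):
        assert np.allclose(normalize_for_encoder(_pcm([row]))[0], expected)

    def test_scale_invariance(self):
        a = normalize_for_encoder(_pcm([[3, 1], [1, 7]]))
        b = normalize_for_encoder(_pcm([[30, 10], [10, 70]]))
        assert np.allclose(a, b)

    def test_zero_read_particle_is_error(self):
        with pytest.raises(Exception, match="zero-read"):
            normalize_for_encoder(_pcm([[0, 0]]))


class TestEncoder:
    def _weights(self, O, H, K, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "W1": rng.normal(size=(O, H)), "b1": rng.normal(size=H),
            "W2": rng.normal(size=(H, H)), "b2": rng.normal(size=H),
            "Wmu": rng.normal(size=(H, K)), "bmu": rng.normal(size=K),
            "Wsd": rng.normal(size=(H, K)), "bsd": rng.normal(size=K),
        }

    def test_particle_order_invariance(self):
        rng = np.random.default_rng(1)
        rhat = rng.dirichlet(np.ones(4), size=10)
        w = self._weights(4, 6, 3)
        mu1, sd1 = encode(rhat, w)
        mu2, sd2 = encode(rhat[::-1], w)
        assert np.allclose(mu1, mu2) and np.allclose(sd1, sd2)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(2)
        rhat = rng.dirichlet(np.ones(4), size=7)
        w = self._weights(4, 6, 3)
        mu1, _ = encode(rhat, w)
        mu2, _ = encode(np.vstack([rhat, rhat]), w)
        assert np.allclose(mu1, mu2)

    def test_zero_weight_heads_return_biases(self):
        rng = np.random.default_rng(3)
        rhat = rng.dirichlet(np.ones(4), size=5)
        w = self._weights(4, 6, 3)
        w["Wmu"] = np.zeros_like(w["Wmu"])
        w["Wsd"] = np.zeros_like(w["Wsd"])
        mu, logsd = encode(rhat, w)
        assert np.allclose(mu[0], w["bmu"]) and np.allclose(logsd[0], w["bsd"])

    def test_group_pooling_is_per_sample(self):
        rng = np.random.default_rng(4)
        rhat = rng.dirichlet(np.ones(4), size=6)
        w = self._weights(4, 6, 3)
        groups = np.array([0, 0, 0, 1, 1, 1])
        mu, _ = encode(rhat, w, groups, 2)
        mu0, _ = encode(rhat[:3], w)
        assert np.allclose(mu[0], mu0[0])


class TestKmeansIlrInit:
    def test_separable_point_masses(self):
        counts = [[50, 0, 0]] * 8 + [[0, 0, 50]] * 8
        theta = kmeans_ilr_init(_pcm(counts), K=2, seed=0)
        assert theta.shape == (2, 3)
        assert np.allclose(theta.sum(axis=1), 1.0)
        tops = sorted(np.argmax(theta, axis=1))
        assert tops == [0, 2]
        # centers equal the zero-replaced compositions: delta = 1/9 smooths
        # a point mass to (7/9, 1/9, 1/9)
        assert theta.max(axis=1).min() == pytest.approx(7 / 9, abs=1e-6)

    def test_uniform_composition_at_ilr_origin(self):
        from skbio.stats.composition import ilr
        assert np.allclose(ilr(np.full(5, 0.2)), 0.0)

    def test_k_exceeding_distinct_particles_is_error(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_ilr_init(_pcm([[1, 1], [1, 1]]), K=2)


class TestAnnealXi:
    @pytest.mark.parametrize("epoch,expected", [(5, 1.0), (95, 50.0), (50, 25.5)])
    def test_schedule(self, epoch, expected):
        assert anneal_xi(epoch, 100, 50.0) == pytest.approx(expected)

    def test_final_value_below_one_is_error(self):
        with pytest.raises(ValueError):
            anneal_xi(0, 100, 0.5)

    def test_monotone_non_decreasing(self):
        vals = [anneal_xi(e, 200, 30.0) for e in range(200)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestKlTerms:
    def test_gaussian_kl_zero_at_prior(self):
        assert gaussian_kl(1.5, np.log(2.0), 1.5, 4.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("mq,sq,mp,vp", [(0.3, 0.5, 0.0, 1.0),
                                             (-1.0, 2.0, 0.5, 9.0)])
    def test_gaussian_kl_matches_quadrature(self, mq, sq, mp, vp):
        q = norm(mq, sq)
        p = norm(mp, np.sqrt(vp))
        integrand = lambda x: q.pdf(x) * (q.logpdf(x) - p.logpdf(x))
        want, _ = integrate.quad(integrand, mq - 12 * sq, mq + 12 * sq)
        assert np.isclose(gaussian_kl(mq, np.log(sq), mp, vp), want, atol=1e-6)

    def test_bernoulli_kl_zero_at_prior(self):
        assert bernoulli_kl(0.2, np.log(0.2), np.log(0.8)) == pytest.approx(0.0)

    def test_bernoulli_kl_closed_form(self):
        q, p = 0.9, 0.1
        want = q * np.log(q / p) + (1 - q) * np.log((1 - q) / (1 - p))
        assert bernoulli_kl(q, np.log(p), np.log1p(-p)) == pytest.approx(want)

    def test_bernoulli_kl_finite_for_extreme_prior(self):
        val = bernoulli_kl(0.5, -5000.0, -np.exp(-5000.0))
        assert np.isfinite(val) and val > 0


@pytest.fixture(scope="module")
def small_fit():
    theta = np.array([
        [0.7, 0.1, 0.1, 0.05, 0.05, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.05, 0.05, 0.1, 0.1, 0.7, 0.0, 0.0],
        [0.0, 0.1, 0.0, 0.0, 0.3, 0.0, 0.0, 0.0, 0.3, 0.3],
    ])
    beta = np.array([0.5, 0.3, 0.2])
    cfg = SimulationConfig(n_particles=600, read_depth=500,
                           contamination=0.01, seed=0)
    m, truth = simulate_particles(theta, beta, cfg)
    design = StudyDesign(timepoints=np.array([0.0]))
    vp = fit(m, design, Hyperparameters(K=8),
             InferenceConfig(epochs=800, n_restarts=1, seed=5,
                             early_stop_patience=200))
    return m, design, truth, vp


class TestFit:
    def test_recovers_three_separated_assemblages(self, small_fit):
        _, _, truth, vp = small_fit
        assert vp.n_active(0.95) == 3

    def test_smoothed_loss_decreases(self, small_fit):
        _, _, _, vp = small_fit
        loss = vp.loss_history
        assert np.mean(loss[-50:]) < np.mean(loss[:50])

    def test_recovered_frequencies_close(self, small_fit):
        from mcspace import assemblage_recovery_error
        _, _, truth, vp = small_fit
        res = assemblage_recovery_error(vp.theta[vp.active_indices()], truth.theta)
        assert res.error < 0.1

    def test_posterior_round_trip(self, small_fit, tmp_path):
        _, _, _, vp = small_fit
        vp.save(tmp_path / "post.npz")
        back = VariationalPosterior.load(tmp_path / "post.npz")
        assert np.allclose(back.theta, vp.theta)
        assert np.allclose(back.q_gamma, vp.q_gamma)
        assert back.hp.K == vp.hp.K

    def test_elbo_of_fit_is_finite(self, small_fit):
        m, design, _, vp = small_fit
        val = elbo(m, vp, vp.hp, design, seed=0)
        assert np.isfinite(val)


def test_fit_deterministic_under_seed():
    rng = np.random.default_rng(3)
    theta = rng.dirichlet(np.full(5, 0.4), size=2)
    m, _ = simulate_particles(theta, np.array([0.6, 0.4]),
                              SimulationConfig(n_particles=120, read_depth=200,
                                               contamination=0.0, seed=1))
    design = StudyDesign(timepoints=np.array([0.0]))
    cfg = InferenceConfig(epochs=120, n_restarts=2, seed=9)
    vp1 = fit(m, design, Hyperparameters(K=4), cfg)
    vp2 = fit(m, design, Hyperparameters(K=4), cfg)
    assert np.array_equal(vp1.q_gamma, vp2.q_gamma)
    assert np.array_equal(vp1.theta, vp2.theta)
    assert np.array_equal(vp1.mu_x, vp2.mu_x)


def test_minibatch_likelihood_estimator_is_unbiased():
    """The reweighted per-group mini-batch objective matches the full-batch
    objective in expectation (same reparameterization noise, random batches)."""
    from mcspace.inference import (_Prepared, _init_params, _draw_noise,
                                   _draw_batch, _negative_elbo)

    rng = np.random.default_rng(0)
    theta = rng.dirichlet(np.full(6, 0.5), size=2)
    m, _ = simulate_particles(theta, np.array([0.6, 0.4]),
                              SimulationConfig(n_particles=120, read_depth=150,
                                               contamination=0.0, seed=2))
    design = StudyDesign(timepoints=np.array([0.0]))
    prep = _Prepared(m, design)
    hp = Hyperparameters(K=3, xi=1.0)
    cfg = InferenceConfig(epochs=10, n_restarts=1)
    params = _init_params(prep, hp, cfg, rng.dirichlet(np.ones(6), size=3), rng)
    noise = _draw_noise(prep, hp.K, rng)
    full = float(_negative_elbo(params, prep, hp, 1.0, noise, 0.5))
    draws = []
    for _ in range(300):
        noise_b = dict(noise)
        noise_b["batch"] = _draw_batch(prep, 40, rng)
        draws.append(float(_negative_elbo(params, prep, hp, 1.0, noise_b, 0.5)))
    draws = np.asarray(draws)
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - full) < 4 * se


def test_minibatch_fit_runs_and_selects_assemblages():
    rng = np.random.default_rng(1)
    theta = np.array([[0.9, 0.1, 0.0, 0.0], [0.0, 0.0, 0.1, 0.9]])
    m, _ = simulate_particles(theta, np.array([0.5, 0.5]),
                              SimulationConfig(n_particles=300, read_depth=300,
                                               contamination=0.0, seed=3))
    design = StudyDesign(timepoints=np.array([0.0]))
    vp = fit(m, design, Hyperparameters(K=4),
             InferenceConfig(epochs=400, n_restarts=1, seed=4, batch_size=100))
    assert vp.n_active(0.95) == 2


def test_elbo_bounded_by_monte_carlo_marginal():
    """Averaged single-sample ELBO stays below the log marginal likelihood
    estimated by exhaustive prior Monte Carlo on a tiny instance."""
    rng = np.random.default_rng(11)
    O, K = 3, 2
    counts = np.array([[2, 1, 0], [0, 2, 1], [1, 0, 2]])
    m = ParticleCountMatrix(counts, ["a", "b", "c"], ["O1", "O2", "O3"],
                            ["S0"] * 3, [0.0] * 3)
    design = StudyDesign(timepoints=np.array([0.0]))
    hp = Hyperparameters(K=K, xi=1.0)
    theta = rng.dirichlet(np.ones(O), size=K)
    from mcspace import compute_contamination_profile
    G = compute_contamination_profile(m)
    # q_gamma close to one keeps hard evaluation samples non-empty (an empty
    # assemblage set has zero likelihood under the exact model)
    vp = VariationalPosterior(
        mu_x=rng.normal(size=(1, 1, K)) * 0.5,
        logsd_x=np.full((1, 1, K), -0.5),
        q_gamma=np.array([0.95, 0.9]), q_c=np.zeros((K, 0)),
        theta=theta, nu2_mean=np.array([0.0]), nu2_logsd=np.array([0.0]),
        delta_mean=np.zeros((K, 0)), delta_logsd=np.zeros((K, 0)),
        pig_mean=np.array([norm.ppf(0.05)]), pig_logsd=np.array([-1.0]),
        G=G, otu_ids=m.otu_ids, subjects=np.array(["S0"], dtype=object),
        timepoints=np.array([0.0]), perturbation_names=[], xi=1.0, hp=hp)

    elbos = np.array([elbo(m, vp, hp, design, seed=s) for s in range(400)])
    se_elbo = elbos.std(ddof=1) / np.sqrt(len(elbos))

    # prior Monte Carlo of p(data | theta, G): x ~ N(0,1), gamma ~ Bern(pi),
    # logit pi_G ~ N(mu_pi, rho2_pi); empty-gamma draws have zero likelihood
    M = 200_000
    pg = (0.5 / K) ** 1.0
    xs = rng.normal(size=(M, K))
    gammas = (rng.random((M, K)) < pg).astype(float)
    pigs = 1 / (1 + np.exp(-rng.normal(hp.mu_pi, np.sqrt(hp.rho2_pi), M)))
    w = gammas * np.exp(xs - xs.max(axis=1, keepdims=True))
    nonempty = w.sum(axis=1) > 0
    beta = np.where(nonempty[:, None], w / np.where(nonempty, w.sum(axis=1), 1.0)[:, None], 0.0)
    # mixed per-OTU probabilities per draw and assemblage: (M, K, O)
    mix = (1 - pigs)[:, None, None] * theta[None] + pigs[:, None, None] * G[0][None, None]
    ll_k = np.einsum("lo,mko->mlk", counts, np.log(mix))  # (M, L, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = ll_k + np.log(beta)[:, None, :]
        mxk = inner.max(axis=2, keepdims=True)
        loglik = np.where(
            nonempty,
            np.squeeze(mxk, 2).sum(axis=1)
            + np.log(np.nan_to_num(np.exp(inner - mxk), nan=0.0).sum(axis=2)).sum(axis=1),
            -np.inf,
        )
    finite = np.isfinite(loglik)
    mx = loglik[finite].max()
    log_z = mx + np.log(np.exp(loglik[finite] - mx).sum() / M)
    assert elbos.mean() + 3 * se_elbo <= log_z + 0.05
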