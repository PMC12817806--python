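import numpy as np
import pytest

from mcspace import (Hyperparameters, bayes_factor, summarize_beta,
                     perturbed_assemblages, association_score,
                     association_matrix, coassociation_probability,
                     association_map, select_anchor_taxa)
from mcspace.inference import VariationalPosterior
from mcspace.posterior import PosteriorEnsemble


class TestBayesFactor:
    def test_posterior_equal_prior_is_one(self):
        assert bayes_factor(0.3, 0.3) == pytest.approx(1.0)

    def test_formula_arithmetic(self):
        assert bayes_factor(0.95, 0.005) == pytest.approx(19 * 199)

    def test_zero_odds(self):
        assert bayes_factor(0.0, 0.1) == 0.0

    def test_certain_posterior_is_infinite(self):
        assert np.isinf(bayes_factor(1.0, 0.1))

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(0.5, 0.0)

    def test_monotone_in_q_and_prior(self):
        qs = np.linspace(0.01, 0.99, 25)
        bfs = bayes_factor(qs, 0.05)
        assert (np.diff(bfs) > 0).all()
        assert bayes_factor(0.5, 0.01) > bayes_factor(0.5, 0.1)


def _vp(mu_x, q_gamma, theta, q_c=None, logsd=-3.0, pi_c=0.05):
    mu_x = np.asarray(mu_x, dtype=float)
    S, T, K = mu_x.shape
    P = 0 if q_c is None else np.asarray(q_c).shape[1]
    hp = Hyperparameters(K=K, pi_c=pi_c, xi=1.0)
    return VariationalPosterior(
        mu_x=mu_x, logsd_x=np.full((S, T, K), logsd),
        q_gamma=np.asarray(q_gamma, dtype=float),
        q_c=np.asarray(q_c, dtype=float) if q_c is not None else np.zeros((K, 0)),
        theta=np.asarray(theta, dtype=float),
        nu2_mean=np.zeros(S), nu2_logsd=np.zeros(S),
        delta_mean=np.zeros((K, P)), delta_logsd=np.zeros((K, P)),
        pig_mean=np.full(T, -3.0), pig_logsd=np.full(T, -2.0),
        G=np.full((T, theta.shape[1]), 1.0 / theta.shape[1]),
        otu_ids=np.array([f"OTU{j+1}" for j in range(theta.shape[1])], dtype=object),
        subjects=np.array(["S0"], dtype=object) if S == 1 else
        np.array([f"S{i}" for i in range(S)], dtype=object),
        timepoints=np.arange(float(T)), perturbation_names=[f"P{j}" for j in range(P)],
        xi=1.0, hp=hp)


class TestSummarizeBeta:
    def test_degenerate_posterior_is_softmax_of_mean(self):
        mu = np.array([[[1.0, 0.0, -1.0]]])
        theta = np.full((3, 4), 0.25)
        vp = _vp(mu, [1.0, 1.0, 1.0], theta, logsd=-20.0)
        ens = summarize_beta(vp, n=50, seed=0)
        want = np.exp(mu[0, 0]) / np.exp(mu[0, 0]).sum()
        assert np.allclose(ens.beta_mean[0, 0], want, atol=1e-6)

    def test_low_probability_assemblage_masked_and_renormalized(self):
        mu = np.array([[[0.0, 0.0, 0.0]]])
        theta = np.full((3, 4), 0.25)
        vp = _vp(mu, [1.0, 0.5, 1.0], theta, logsd=-20.0)
        ens = summarize_beta(vp, n=20, seed=0)
        assert list(ens.retained) == [0, 2]
        assert np.allclose(ens.beta_mean[0, 0], [0.5, 0.5])

    def test_samples_on_simplex(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(2, 3, 4))
        theta = rng.dirichlet(np.ones(5), size=4)
        vp = _vp(mu, [1, 1, 1, 1], theta, logsd=0.0)
        ens = summarize_beta(vp, n=100, seed=1)
        assert np.allclose(ens.beta_samples.sum(axis=-1), 1.0)
        assert np.allclose(ens.beta_mean.sum(axis=-1), 1.0)

    def test_no_assemblage_passing_threshold_is_error(self):
        vp = _vp(np.zeros((1, 1, 2)), [0.5, 0.4], np.full((2, 3), 1 / 3))
        with pytest.raises(ValueError, match="q_gamma"):
            summarize_beta(vp)

    def test_bayes_factors_from_qc(self):
        vp = _vp(np.zeros((1, 1, 2)), [1.0, 1.0], np.full((2, 3), 1 / 3),
                 q_c=np.array([[0.95], [0.05]]), pi_c=0.005)
        ens = summarize_beta(vp, n=10, seed=0)
        assert ens.bf[0, 0] == pytest.approx(19 * 199)


class TestPerturbedAssemblages:
    def _ens(self, bfs):
        K = len(bfs)
        return PosteriorEnsemble(
            beta_samples=np.full((5, 1, 1, K), 1.0 / K),
            theta=np.full((K, 3), 1 / 3), retained=np.arange(K),
            q_gamma=np.ones(K), bf=np.asarray(bfs, dtype=float).reshape(K, 1),
            bf_infinite=np.zeros((K, 1), dtype=bool),
            otu_ids=np.array(["OTU1", "OTU2", "OTU3"], dtype=object),
            subjects=np.array(["S0"], dtype=object),
            timepoints=np.array([0.0]), perturbation_names=["P0"])

    def test_all_unit_bf_gives_empty(self):
        assert perturbed_assemblages(self._ens([1.0, 1.0])) == []

    def test_threshold_nesting_and_sorting(self):
        ens = self._ens([5.0, 50.0, 12.0])
        low = perturbed_assemblages(ens, bf_threshold=3.1)
        high = perturbed_assemblages(ens, bf_threshold=10)
        assert {h[0] for h in high} <= {h[0] for h in low}
        assert [h[2] for h in high] == sorted([h[2] for h in high], reverse=True)


class TestAssociationScore:
    def test_single_assemblage_half(self):
        theta = np.array([[0.5, 0.5]])
        assert association_score(np.array([1.0]), theta, 0, 1) == pytest.approx(0.5)

    def test_absent_taxon_zero(self):
        theta = np.array([[0.0, 1.0]])
        assert association_score(np.array([1.0]), theta, 0, 1) == 0.0

    def test_self_association_ceiling(self):
        theta = np.array([[1.0, 0.0]])
        assert association_score(np.array([1.0]), theta, 0, 0) == pytest.approx(1.0)

    def test_matrix_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        theta = rng.dirichlet(np.ones(6), size=4)
        beta = rng.dirichlet(np.ones(4))
        alpha = association_matrix(beta, theta)
        assert np.allclose(alpha, alpha.T)
        assert (alpha >= 0).all() and (alpha <= 1 + 1e-12).all()

    def test_invariant_to_assemblage_relabeling(self):
        rng = np.random.default_rng(3)
        theta = rng.dirichlet(np.ones(5), size=3)
        beta = rng.dirichlet(np.ones(3))
        perm = np.array([2, 0, 1])
        a1 = association_matrix(beta, theta)
        a2 = association_matrix(beta[perm], theta[perm])
        assert np.allclose(a1, a2)


class TestCoassociation:
    def _ens(self, beta, theta):
        beta = np.asarray(beta, dtype=float)
        K = len(beta)
        return PosteriorEnsemble(
            beta_samples=np.tile(beta, (4, 1, 1, 1)),
            theta=np.asarray(theta, dtype=float), retained=np.arange(K),
            q_gamma=np.ones(K), bf=np.zeros((K, 0)),
            bf_infinite=np.zeros((K, 0), dtype=bool),
            otu_ids=np.array([f"OTU{j+1}" for j in range(np.shape(theta)[1])],
                             dtype=object),
            subjects=np.array(["S0"], dtype=object),
            timepoints=np.array([0.0]), perturbation_names=[])

    def test_single_covering_assemblage(self):
        theta = np.array([[0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
        p = coassociation_probability(self._ens([0.6, 0.4], theta))
        assert p[0, 1] == pytest.approx(0.6)

    def test_no_shared_assemblage_zero(self):
        theta = np.array([[1.0, 0.0], [0.0, 1.0]])
        p = coassociation_probability(self._ens([0.7, 0.3], theta))
        assert p[0, 1] == 0.0

    def test_every_assemblage_shared_is_one(self):
        theta = np.array([[0.5, 0.5], [0.4, 0.6]])
        p = coassociation_probability(self._ens([0.7, 0.3], theta))
        assert p[0, 1] == pytest.approx(1.0)

    def test_tau_zero_counts_any_mass(self):
        theta = np.array([[0.5, 0.5, 0.0], [0.2, 0.0, 0.8]])
        ens = self._ens([0.6, 0.4], theta)
        p = coassociation_probability(ens, tau=0.0)
        assert p[0, 1] == pytest.approx(0.6)
        assert p[0, 2] == pytest.approx(0.4)


class TestAssociationMap:
    def _ens(self):
        theta = np.array([
            [0.6, 0.4, 0.0, 0.0],
            [0.3, 0.0, 0.4, 0.3],
        ])
        beta = np.array([[[[0.5, 0.5]], [[0.9, 0.1]]]])  # S=1, T=2, K=2
        beta = beta.reshape(1, 2, 2)
        return PosteriorEnsemble(
            beta_samples=np.tile(beta, (3, 1, 1, 1)),
            theta=theta, retained=np.arange(2), q_gamma=np.ones(2),
            bf=np.zeros((2, 0)), bf_infinite=np.zeros((2, 0), dtype=bool),
            otu_ids=np.array(["OTU1", "OTU2", "OTU3", "OTU4"], dtype=object),
            subjects=np.array(["S0"], dtype=object),
            timepoints=np.array([0.0, 1.0]), perturbation_names=[])

    def test_min_edge_zero_lists_all_partners(self):
        edges = association_map(self._ens(), "OTU1", min_edge=0.0)
        assert len(edges) == 3

    def test_raising_min_edge_never_adds(self):
        ens = self._ens()
        lo = association_map(ens, "OTU1", min_edge=0.01)
        hi = association_map(ens, "OTU1", min_edge=0.2)
        assert set(hi.partner) <= set(lo.partner)

    def test_condition_average_is_mean_of_daily_scores(self):
        ens = self._ens()
        both = association_map(ens, "OTU1", min_edge=0.0, times=[0.0, 1.0])
        d0 = association_map(ens, "OTU1", min_edge=0.0, times=[0.0])
        d1 = association_map(ens, "OTU1", min_edge=0.0, times=[1.0])
        for p in both.partner:
            a = float(both[both.partner == p].alpha.iloc[0])
            a0 = float(d0[d0.partner == p].alpha.iloc[0])
            a1 = float(d1[d1.partner == p].alpha.iloc[0])
            assert a == pytest.approx(0.5 * (a0 + a1))

    def test_unknown_anchor_is_error(self):
        with pytest.raises(KeyError):
            association_map(self._ens(), "OTU99")


def test_select_anchor_taxa_threshold_rule():
    theta = np.array([[0.8, 0.2, 0.0], [0.0, 0.1, 0.9]])
    beta = np.zeros((1, 4, 2))
    beta[0, :2] = [1.0, 0.0]   # period 1: only assemblage 1
    beta[0, 2:] = [0.0, 1.0]   # period 2: only assemblage 2
    ens = PosteriorEnsemble(
        beta_samples=np.tile(beta, (2, 1, 1, 1)), theta=theta,
        retained=np.arange(2), q_gamma=np.ones(2), bf=np.zeros((2, 0)),
        bf_infinite=np.zeros((2, 0), dtype=bool),
        otu_ids=np.array(["OTU1", "OTU2", "OTU3"], dtype=object),
        subjects=np.array(["S0"], dtype=object),
        timepoints=np.array([0.0, 1.0, 2.0, 3.0]), perturbation_names=[])
    anchors = select_anchor_taxa(ens, periods=[[0.0, 1.0], [2.0, 3.0]],
                                 min_abund=0.05, min_periods=2)
    assert anchors == ["OTU2"]  # only OTU2 is >= 5% in both periods
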