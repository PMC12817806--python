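"""Stochastic variational inference for the assemblage mixture model.

The posterior over latent variables is approximated with:

* ``x`` (untransformed assemblage weights per subject/time) — Gaussian, with
  parameters *amortized* by an encoder network: normalized particle reads are
  passed through a two-layer softplus MLP, mean-pooled over the particles of
  each (subject, time) sample, and mapped by linear heads to a mean and log
  standard deviation per assemblage.
* ``nu2`` (pre-softplus process variance), ``delta`` (perturbation
  magnitudes), ``logit pi_G`` (contamination weights) — free-form Gaussians.
* ``gamma`` (assemblage indicators), ``c`` (perturbation indicators) —
  Bernoulli with global logit parameters, realized through a binary
  Gumbel-Softmax (concrete) relaxation during training and hard samples at
  evaluation.
* ``theta`` (assemblage OTU frequencies) — point estimates via row softmax of
  unconstrained logits, initialized from k-means on ILR-transformed particle
  compositions.

KL terms are analytic (Gaussian/Gaussian and Bernoulli/Bernoulli) for all
latents except ``x``, whose contribution uses a single-sample estimator; the
per-particle assemblage assignment ``z`` and the per-read contamination flags
are marginalized exactly inside the likelihood.  The sparsity exponent ``xi``
is annealed from 1 to its final value over the middle 80% of training epochs.
Training uses Adam with multiple restarts; the restart with the lowest mean
loss over its final 10% of epochs is returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from autograd import numpy as anp
from autograd import value_and_grad
from autograd.misc import flatten
from autograd.scipy.special import logsumexp as a_logsumexp
from scipy.special import expit
from sklearn.cluster import KMeans
from skbio.stats.composition import ilr, ilr_inv, multi_replace

from .data import ParticleCountMatrix, StudyDesign
from .model import Hyperparameters, compute_contamination_profile

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "VariationalPosterior",
    "normalize_for_encoder",
    "encode",
    "kmeans_ilr_init",
    "anneal_xi",
    "gaussian_kl",
    "bernoulli_kl",
    "elbo",
    "fit",
]


@dataclass
class InferenceConfig:
    """Optimization settings.

    ``epochs`` defaults to 10,000 with early stopping once the sparsity
    anneal has finished (plateau patience in epochs); smaller values are
    appropriate for small simulated datasets.

    ``batch_size`` switches the likelihood to per-epoch particle mini-batches
    (sampled per sample group, reweighted to stay unbiased); the encoder still
    pools the full dataset, which is a fixed summary.  Default is full batch.
    """

    hidden_width: int = 50
    learning_rate: float = 0.005
    indicator_lr_mult: float = 10.0  # step multiplier for gamma/c logits
    epochs: int = 10_000
    n_restarts: int = 10
    anneal_fracs: tuple = (0.10, 0.90)
    gumbel_temperature: float = 0.5
    early_stop_patience: int = 500
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.anneal_fracs
        if not (0 < lo < hi <= 1):
            raise ValueError("anneal_fracs must satisfy 0 < start < end <= 1")
        if self.epochs < 10:
            raise ValueError("epochs must be >= 10")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")


@dataclass
class VariationalPosterior:
    """Fitted variational parameters plus everything needed downstream."""

    mu_x: np.ndarray          # (S, T, K)
    logsd_x: np.ndarray       # (S, T, K)
    q_gamma: np.ndarray       # (K,)
    q_c: np.ndarray           # (K, P)
    theta: np.ndarray         # (K, O) row-stochastic
    nu2_mean: np.ndarray      # (S,)
    nu2_logsd: np.ndarray
    delta_mean: np.ndarray    # (K, P)
    delta_logsd: np.ndarray
    pig_mean: np.ndarray      # (T,)
    pig_logsd: np.ndarray
    G: np.ndarray             # (T, O)
    otu_ids: np.ndarray
    subjects: np.ndarray      # ordered subject labels (S,)
    timepoints: np.ndarray    # (T,)
    perturbation_names: list
    xi: float
    hp: Hyperparameters
    encoder_weights: dict = field(default_factory=dict, repr=False)
    loss_history: np.ndarray | None = None
    seed: int = 0

    @property
    def pi_G(self) -> np.ndarray:
        """Posterior-mean contamination weight per time point."""
        return expit(self.pig_mean)

    def n_active(self, threshold: float = 0.95) -> int:
        """Number of assemblages with posterior presence probability >= threshold."""
        return int((self.q_gamma >= threshold).sum())

    def active_indices(self, threshold: float = 0.95) -> np.ndarray:
        return np.flatnonzero(self.q_gamma >= threshold)

    def save(self, path) -> None:
        path = Path(path)
        arrays = {
            k: getattr(self, k)
            for k in (
                "mu_x", "logsd_x", "q_gamma", "q_c", "theta", "nu2_mean",
                "nu2_logsd", "delta_mean", "delta_logsd", "pig_mean",
                "pig_logsd", "G",
            )
        }
        arrays["otu_ids"] = np.asarray(self.otu_ids, dtype=str)
        arrays["subjects"] = np.asarray(self.subjects, dtype=str)
        arrays["timepoints"] = np.asarray(self.timepoints, dtype=float)
        arrays["perturbation_names"] = np.asarray(self.perturbation_names, dtype=str)
        arrays["xi"] = np.array(self.xi)
        arrays["seed"] = np.array(self.seed)
        if self.loss_history is not None:
            arrays["loss_history"] = self.loss_history
        for k, v in self.encoder_weights.items():
            arrays[f"enc__{k}"] = v
        np.savez(path, **arrays)
        hp_path = path.with_suffix(".hyperparams.json")
        self.hp.to_json(hp_path)

    @classmethod
    def load(cls, path) -> "VariationalPosterior":
        path = Path(path)
        with np.load(path, allow_pickle=False) as z:
            enc = {k[5:]: z[k] for k in z.files if k.startswith("enc__")}
            kw = {k: z[k] for k in z.files if not k.startswith("enc__")}
        hp = Hyperparameters.from_json(path.with_suffix(".hyperparams.json"))
        loss = kw.pop("loss_history", None)
        return cls(
            mu_x=kw["mu_x"], logsd_x=kw["logsd_x"], q_gamma=kw["q_gamma"],
            q_c=kw["q_c"], theta=kw["theta"], nu2_mean=kw["nu2_mean"],
            nu2_logsd=kw["nu2_logsd"], delta_mean=kw["delta_mean"],
            delta_logsd=kw["delta_logsd"], pig_mean=kw["pig_mean"],
            pig_logsd=kw["pig_logsd"], G=kw["G"],
            otu_ids=kw["otu_ids"].astype(object),
            subjects=kw["subjects"].astype(object),
            timepoints=kw["timepoints"],
            perturbation_names=list(kw["perturbation_names"].astype(str)),
            xi=float(kw["xi"]), hp=hp, encoder_weights=enc,
            loss_history=loss, seed=int(kw["seed"]),
        )


# ---------------------------------------------------------------------------
# building blocks


def normalize_for_encoder(m: ParticleCountMatrix) -> np.ndarray:
    """Per-particle relative abundances (rows sum to one)."""
    return m.relative_abundances()


def _softplus(x):
    return anp.logaddexp(0.0, x)


def encode(rhat, weights: dict, group_of_particle=None, n_groups: int | None = None):
    """Apply the encoder: per-particle MLP, mean pooling per sample, linear heads.

    ``group_of_particle`` assigns each particle to a (subject, time) sample;
    by default all particles form one group.  Returns (mu, log_sd), each of
    shape (n_groups, K).  Deterministic given the weights, and invariant to
    particle order and duplication within a group.
    """
    rhat = anp.asarray(rhat)
    if group_of_particle is None:
        group_of_particle = np.zeros(rhat.shape[0], dtype=int)
        n_groups = 1
    if n_groups is None:
        n_groups = int(np.max(group_of_particle)) + 1
    pool = np.zeros((n_groups, rhat.shape[0]))
    pool[group_of_particle, np.arange(rhat.shape[0])] = 1.0
    pool /= pool.sum(axis=1, keepdims=True)
    h1 = _softplus(rhat @ weights["W1"] + weights["b1"])
    h2 = _softplus(h1 @ weights["W2"] + weights["b2"])
    pooled = pool @ h2
    mu = pooled @ weights["Wmu"] + weights["bmu"]
    logsd = pooled @ weights["Wsd"] + weights["bsd"]
    return mu, logsd


def kmeans_ilr_init(m: ParticleCountMatrix, K: int, seed: int = 0) -> np.ndarray:
    """Assemblage initialization: k-means in ILR coordinates.

    Particle relative abundances undergo multiplicative zero replacement
    (delta = 1/O^2), the isometric log-ratio transform, k-means with K
    centers, and the inverse transform of the centers back to the simplex.
    """
    rel = m.relative_abundances()
    n_distinct = len(np.unique(rel.round(12), axis=0))
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct particle compositions")
    O = m.n_otus
    comp = multi_replace(rel, delta=1.0 / O**2)
    z = ilr(comp)
    km = KMeans(n_clusters=K, random_state=seed, n_init=10).fit(z)
    return np.asarray(ilr_inv(km.cluster_centers_))


def anneal_xi(epoch: int, total_epochs: int, xi_final: float,
              frac_start: float = 0.10, frac_end: float = 0.90) -> float:
    """Sparsity-exponent schedule: 1, then linear ramp, then xi_final.

    Held at 1 for the first ``frac_start`` of epochs, increased linearly to
    ``xi_final`` at ``frac_end``, then held constant.
    """
    if xi_final < 1:
        raise ValueError("xi_final must be >= 1")
    if not 0 <= epoch < total_epochs:
        raise ValueError("epoch out of range")
    e0 = frac_start * total_epochs
    e1 = frac_end * total_epochs
    if epoch < e0:
        return 1.0
    if epoch >= e1:
        return float(xi_final)
    return float(1.0 + (xi_final - 1.0) * (epoch - e0) / (e1 - e0))


def gaussian_kl(mu_q, logsd_q, mu_p, var_p):
    """Analytic KL( N(mu_q, exp(logsd_q)^2) || N(mu_p, var_p) ), elementwise sum."""
    var_q = anp.exp(2.0 * logsd_q)
    return anp.sum(
        0.5 * anp.log(var_p) - logsd_q + (var_q + (mu_q - mu_p) ** 2) / (2.0 * var_p) - 0.5
    )


def bernoulli_kl(q, log_p1, log_p0):
    """Analytic KL( Bern(q) || Bern(p) ) with the prior given in log space.

    ``log_p1`` = log p and ``log_p0`` = log(1-p); passing logs keeps the term
    finite for the extremely small sparsity priors (p = (0.5/K)^xi).
    """
    q = anp.clip(q, 1e-12, 1.0 - 1e-12)
    return anp.sum(q * (anp.log(q) - log_p1) + (1.0 - q) * (anp.log1p(-q) - log_p0))


def _log1m_exp(log_p):
    """log(1 - exp(log_p)) for log_p < 0, stable for very negative log_p."""
    if log_p > -30:
        return float(np.log1p(-np.exp(log_p)))
    return float(-np.exp(log_p))


def _sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


# ---------------------------------------------------------------------------
# data preparation


class _Prepared:
    """Static tensors shared by every ELBO evaluation of one dataset."""

    def __init__(self, m: ParticleCountMatrix, design: StudyDesign):
        self.timepoints = np.asarray(design.timepoints, dtype=float)
        extra = set(m.timepoints) - set(self.timepoints)
        if extra:
            raise ValueError(f"data contain time points {sorted(extra)} not in design")
        self.subjects = np.unique(m.subjects.astype(str))
        self.S = len(self.subjects)
        self.T = len(self.timepoints)
        self.R = m.counts.astype(float)
        self.rhat = normalize_for_encoder(m)
        self.total_reads = float(self.R.sum())
        s_idx = np.searchsorted(self.subjects, m.subjects.astype(str))
        t_idx = np.searchsorted(self.timepoints, m.times)
        self.group_of_particle = s_idx * self.T + t_idx  # s-major ordering
        self.n_groups = self.S * self.T
        present = np.bincount(self.group_of_particle, minlength=self.n_groups)
        if (present == 0).any():
            raise ValueError("every (subject, time) sample must contain particles")
        self.t_of_particle = t_idx
        self.particles_at_t = [np.flatnonzero(t_idx == i) for i in range(self.T)]
        self.G = compute_contamination_profile(m)
        self.delta_t = design.delta_t
        self.signs = design.transition_signs()  # (T, P)
        self.P = self.signs.shape[1]
        self.pert_names = design.perturbation_names


def _init_params(prep: _Prepared, hp: Hyperparameters, config: InferenceConfig,
                 theta_init: np.ndarray, rng: np.random.Generator) -> dict:
    O, K, H = prep.R.shape[1], hp.K, config.hidden_width
    def g(*shape, scale=1.0):
        return scale * rng.standard_normal(shape)
    params = {
        "W1": g(O, H, scale=1.0 / np.sqrt(O)),
        "b1": np.zeros(H),
        "W2": g(H, H, scale=1.0 / np.sqrt(H)),
        "b2": np.zeros(H),
        "Wmu": g(H, K, scale=1.0 / np.sqrt(H)),
        "bmu": g(K),
        "Wsd": g(H, K, scale=0.01 / np.sqrt(H)),
        "bsd": np.full(K, -2.0),
        # start the random walk stiff (process variance ~1%, the prior's
        # intent) so coordinated jumps are attributed to perturbation effects
        # first and drift variance loosens only as the data demand it
        "nu2_mean": np.full(prep.S, np.log(np.expm1(0.01))) + 0.1 * g(prep.S),
        "nu2_logsd": np.full(prep.S, -2.0),
        "pig_mean": g(prep.T),
        "pig_logsd": np.full(prep.T, -2.0),
        "gamma_logit": g(K),
        "theta_logits": np.log(np.clip(theta_init, 1e-12, None)),
    }
    if prep.P > 0:
        params["delta_mean"] = g(K, prep.P)
        params["delta_logsd"] = np.full((K, prep.P), -2.0)
        params["c_logit"] = g(K, prep.P)
    return params


def _draw_noise(prep: _Prepared, K: int, rng: np.random.Generator) -> dict:
    u_g = rng.uniform(1e-8, 1 - 1e-8, K)
    noise = {
        "x": rng.standard_normal((prep.n_groups, K)),
        "nu2": rng.standard_normal(prep.S),
        "pig": rng.standard_normal(prep.T),
        "eps_gamma": np.log(u_g) - np.log1p(-u_g),  # logistic noise
    }
    if prep.P > 0:
        noise["delta"] = rng.standard_normal((K, prep.P))
        u_c = rng.uniform(1e-8, 1 - 1e-8, (K, prep.P))
        noise["eps_c"] = np.log(u_c) - np.log1p(-u_c)
    return noise


def _draw_batch(prep: _Prepared, batch_size: int, rng: np.random.Generator) -> dict:
    """Sample a per-group particle mini-batch with inverse-inclusion weights.

    Each (subject, time) group contributes a share of the batch proportional
    to its size (at least one particle), and its sampled particles carry the
    weight L_g / n_g so the mini-batch log likelihood is unbiased.
    """
    L = prep.R.shape[0]
    weight = np.zeros(L)
    at_t = []
    chosen_all = []
    for g in range(prep.n_groups):
        members = np.flatnonzero(prep.group_of_particle == g)
        n_g = max(1, int(round(batch_size * len(members) / L)))
        n_g = min(n_g, len(members))
        chosen = rng.choice(members, size=n_g, replace=False)
        weight[chosen] = len(members) / n_g
        chosen_all.append(chosen)
    chosen_all = np.concatenate(chosen_all)
    for i in range(prep.T):
        at_t.append(chosen_all[prep.t_of_particle[chosen_all] == i])
    return {"at_t": at_t, "weight": weight}


_MASK = 1e6  # additive log-mask for hard-off assemblages at evaluation


def _negative_elbo(params, prep: _Prepared, hp: Hyperparameters, xi: float,
                   noise: dict, temperature: float, training: bool = True):
    """Single-sample negative ELBO; autograd-differentiable in ``params``.

    Training realizes the binary indicators through the Gumbel-Softmax
    (binary concrete) relaxation and couples gamma to the likelihood as an
    unnormalized thinning of the softmax proportions,
    ``w_k = gamma_k softmax(x)_k``: mass on switched-off assemblages is lost
    rather than renormalized away, which is what makes the sparsity
    indicators identifiable under the relaxation (a renormalized masked
    softmax is invariant to scaling all gammas, so the indicators would feel
    only their KL term).  As gamma hardens to {0,1} and the softmax mass
    concentrates on the active set, this coincides with the exact model's
    renormalized proportions, which evaluation mode (hard Bernoulli samples,
    masked renormalized softmax) uses directly.
    """
    K = hp.K
    if "mu_x_free" in params:   # evaluating a stored posterior
        mu_x, logsd_x = params["mu_x_free"], params["logsd_x_free"]
    else:
        mu_x, logsd_x = encode(prep.rhat, params, prep.group_of_particle, prep.n_groups)
    sd_x = anp.exp(logsd_x)
    x = mu_x + sd_x * noise["x"]                        # (n_groups, K)

    nu2 = params["nu2_mean"] + anp.exp(params["nu2_logsd"]) * noise["nu2"]
    sigma2_w = _softplus(nu2)                           # (S,)
    pig_hat = params["pig_mean"] + anp.exp(params["pig_logsd"]) * noise["pig"]
    pi_G = _sigmoid(pig_hat)                            # (T,)

    if training:
        # relaxed gamma with its log-mask scaled by xi: the effective prior on
        # an indicator is pi^xi, so scaling the mass-loss penalty identically
        # preserves the exact model's prior-vs-likelihood odds (see methods)
        log_gamma = -xi * _softplus(-(params["gamma_logit"] + noise["eps_gamma"])
                                    / temperature)     # xi * log(relaxed gamma)
    else:
        # evaluation: hard Bernoulli samples (logit + logistic noise > 0)
        hard_gamma = (params["gamma_logit"] + noise["eps_gamma"] > 0).astype(float)
        if hard_gamma.sum() == 0:
            hard_gamma[int(np.argmax(params["gamma_logit"] + noise["eps_gamma"]))] = 1.0
        log_gamma = -_MASK * (1.0 - hard_gamma)
    if prep.P > 0:
        delta = params["delta_mean"] + anp.exp(params["delta_logsd"]) * noise["delta"]
        if training:
            c = _sigmoid((params["c_logit"] + noise["eps_c"]) / temperature)
        else:
            c = (params["c_logit"] + noise["eps_c"] > 0).astype(float)

    theta = anp.exp(params["theta_logits"]
                    - a_logsumexp(params["theta_logits"], axis=1, keepdims=True))

    # assemblage proportions per (subject, time) sample
    logw = x - a_logsumexp(x, axis=1, keepdims=True) + log_gamma[None, :]
    if training:
        logbeta = logw          # unnormalized thinned mass (see docstring)
    else:
        logbeta = logw - a_logsumexp(logw, axis=1, keepdims=True)

    # expected log likelihood, z and contamination flags marginalized exactly;
    # an optional particle mini-batch reweights each group's contribution so
    # the estimator stays unbiased for the full-data likelihood
    batch = noise.get("batch")
    loglik = 0.0
    for i in range(prep.T):
        idx = prep.particles_at_t[i] if batch is None else batch["at_t"][i]
        if len(idx) == 0:
            continue
        mix = (1.0 - pi_G[i]) * theta + pi_G[i] * prep.G[i][None, :]
        logmix = anp.log(mix)
        ll = prep.R[idx] @ logmix.T + logbeta[prep.group_of_particle[idx]]
        lse = a_logsumexp(ll, axis=1)
        if batch is None:
            loglik = loglik + anp.sum(lse)
        else:
            loglik = loglik + anp.sum(batch["weight"][idx] * lse)

    # stochastic KL for x: log q(x~) - log p(x~ | chain)
    log_q_x = anp.sum(-0.5 * np.log(2 * np.pi) - logsd_x
                      - 0.5 * ((x - mu_x) / sd_x) ** 2)
    x_st = anp.reshape(x, (prep.S, prep.T, K))
    log_p_x = anp.sum(-0.5 * np.log(2 * np.pi) - 0.5 * x_st[:, 0, :] ** 2)
    for i in range(1, prep.T):
        if prep.P > 0:
            step = (c * delta) @ prep.signs[i]          # (K,)
        else:
            step = 0.0
        eta = x_st[:, i - 1, :] + step
        var = sigma2_w[:, None] * prep.delta_t[i - 1]
        log_p_x = log_p_x + anp.sum(
            -0.5 * anp.log(2 * np.pi * var) - (x_st[:, i, :] - eta) ** 2 / (2 * var)
        )
    kl = log_q_x - log_p_x

    kl = kl + gaussian_kl(params["nu2_mean"], params["nu2_logsd"], hp.mu_w, hp.rho2_w)
    kl = kl + gaussian_kl(params["pig_mean"], params["pig_logsd"], hp.mu_pi, hp.rho2_pi)
    log_pg = hp.log_pi_gamma(xi)
    kl = kl + bernoulli_kl(_sigmoid(params["gamma_logit"]), log_pg, _log1m_exp(log_pg))
    if prep.P > 0:
        kl = kl + gaussian_kl(params["delta_mean"], params["delta_logsd"],
                              hp.mu_delta, hp.rho2_delta)
        kl = kl + bernoulli_kl(_sigmoid(params["c_logit"]),
                               float(np.log(hp.pi_c)), float(np.log1p(-hp.pi_c)))
    return -(loglik - kl)


def elbo(m: ParticleCountMatrix, vp: VariationalPosterior, hp: Hyperparameters,
         design: StudyDesign, seed: int = 0, xi: float | None = None) -> float:
    """Single-sample ELBO of a fitted posterior on a dataset.

    Binary indicators are realized as hard samples (evaluation mode).  The
    value is a lower bound on the log marginal likelihood of the model, up to
    the omitted multinomial constants.
    """
    prep = _Prepared(m, design)
    params = _params_from_posterior(vp, prep)
    noise = _draw_noise(prep, hp.K, np.random.default_rng(seed))
    xi = vp.xi if xi is None else xi
    val = _negative_elbo(params, prep, hp, xi, noise, temperature=0.5, training=False)
    if not np.isfinite(val):
        raise FloatingPointError("non-finite ELBO; check the likelihood terms")
    return float(-val)


def _params_from_posterior(vp: VariationalPosterior, prep: _Prepared) -> dict:
    """Rebuild a parameter dict (free-form x in place of the encoder) for
    evaluating the ELBO of a stored posterior."""
    K = vp.mu_x.shape[-1]
    params = {
        "mu_x_free": vp.mu_x.reshape(prep.n_groups, K),
        "logsd_x_free": vp.logsd_x.reshape(prep.n_groups, K),
    }
    with np.errstate(divide="ignore"):
        params.update({
            "nu2_mean": vp.nu2_mean, "nu2_logsd": vp.nu2_logsd,
            "pig_mean": vp.pig_mean, "pig_logsd": vp.pig_logsd,
            "gamma_logit": np.log(np.clip(vp.q_gamma, 1e-12, 1 - 1e-12))
            - np.log1p(-np.clip(vp.q_gamma, 1e-12, 1 - 1e-12)),
            "theta_logits": np.log(np.clip(vp.theta, 1e-300, None)),
        })
    if prep.P > 0:
        qc = np.clip(vp.q_c, 1e-12, 1 - 1e-12)
        params.update({
            "delta_mean": vp.delta_mean, "delta_logsd": vp.delta_logsd,
            "c_logit": np.log(qc) - np.log1p(-qc),
        })
    return params


# ---------------------------------------------------------------------------
# training


def _run_restart(prep: _Prepared, hp: Hyperparameters, config: InferenceConfig,
                 xi_final: float, restart_seed: int):
    rng = np.random.default_rng(restart_seed)
    theta_init = kmeans_ilr_init_from_rel(prep.rhat, hp.K, seed=restart_seed)
    params = _init_params(prep, hp, config, theta_init, rng)
    flat, unflatten = flatten(params)
    # per-parameter learning rates: binary-indicator logits move faster so
    # selection resolves within the annealing schedule
    lr_map = {k: np.full(np.shape(v), config.learning_rate) for k, v in params.items()}
    for k in ("gamma_logit", "c_logit"):
        if k in lr_map:
            lr_map[k] *= config.indicator_lr_mult
    lr, _ = flatten(lr_map)
    m_adam = np.zeros_like(flat)
    v_adam = np.zeros_like(flat)
    b1, b2, eps = 0.9, 0.999, 1e-8
    losses = []
    vag = value_and_grad(_negative_elbo)
    anneal_end = int(config.anneal_fracs[1] * config.epochs)
    best = np.inf
    since_best = 0
    window = 50
    for epoch in range(config.epochs):
        xi = anneal_xi(epoch, config.epochs, xi_final, *config.anneal_fracs)
        noise = _draw_noise(prep, hp.K, rng)
        if config.batch_size is not None and config.batch_size < prep.R.shape[0]:
            noise["batch"] = _draw_batch(prep, config.batch_size, rng)
        params = unflatten(flat)
        loss, grads = vag(params, prep, hp, xi, noise, config.gumbel_temperature, True)
        if not np.isfinite(loss):
            warnings.warn(f"restart seed {restart_seed}: non-finite loss, discarded")
            return None
        losses.append(float(loss))
        gflat, _ = flatten(grads)
        m_adam = b1 * m_adam + (1 - b1) * gflat
        v_adam = b2 * v_adam + (1 - b2) * gflat**2
        t = epoch + 1
        flat = flat - lr * (m_adam / (1 - b1**t)) / (np.sqrt(v_adam / (1 - b2**t)) + eps)
        # plateau-based early stop, only once the sparsity anneal is finished
        if epoch >= anneal_end and len(losses) >= window:
            sm = float(np.mean(losses[-window:]))
            if sm < best - 1e-6 * abs(best):
                best = sm
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break
    return unflatten(flat), np.asarray(losses)


def kmeans_ilr_init_from_rel(rel: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """k-means/ILR initialization from a precomputed relative-abundance matrix."""
    O = rel.shape[1]
    n_distinct = len(np.unique(rel.round(12), axis=0))
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct particle compositions")
    comp = multi_replace(rel, delta=1.0 / O**2)
    z = ilr(comp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        km = KMeans(n_clusters=K, random_state=seed % (2**32), n_init=4).fit(z)
    return np.asarray(ilr_inv(km.cluster_centers_))


def fit(m: ParticleCountMatrix, design: StudyDesign,
        hp: Hyperparameters | None = None,
        config: InferenceConfig | None = None) -> VariationalPosterior:
    """Fit the model by multi-restart stochastic variational inference.

    Runs ``config.n_restarts`` independent Adam optimizations from distinct
    seeds (theta from k-means in ILR coordinates, other parameters from
    scaled normal draws) and returns the restart with the lowest mean loss
    over its final 10% of epochs.  Restarts that diverge (NaN loss) are
    discarded with a warning.
    """
    hp = hp if hp is not None else Hyperparameters()
    config = config if config is not None else InferenceConfig()
    prep = _Prepared(m, design)
    xi_final = hp.resolve_xi(int(prep.total_reads))
    results = []
    for r in range(config.n_restarts):
        out = _run_restart(prep, hp, config, xi_final, config.seed + r)
        if out is None:
            continue
        params, losses = out
        tail = losses[-max(1, len(losses) // 10):]
        results.append((float(np.mean(tail)), params, losses))
        logger.info("restart %d: tail loss %.2f (%d epochs)", r, results[-1][0], len(losses))
    if not results:
        raise RuntimeError("all restarts diverged")
    score, params, losses = min(results, key=lambda t: t[0])
    mu, logsd = encode(prep.rhat, params, prep.group_of_particle, prep.n_groups)
    K = hp.K
    enc = {k: params[k] for k in ("W1", "b1", "W2", "b2", "Wmu", "bmu", "Wsd", "bsd")}
    theta = np.exp(params["theta_logits"]
                   - np.logaddexp.reduce(params["theta_logits"], axis=1)[:, None])
    return VariationalPosterior(
        mu_x=mu.reshape(prep.S, prep.T, K),
        logsd_x=logsd.reshape(prep.S, prep.T, K),
        q_gamma=expit(params["gamma_logit"]),
        q_c=expit(params["c_logit"]) if prep.P > 0 else np.zeros((K, 0)),
        theta=theta,
        nu2_mean=params["nu2_mean"], nu2_logsd=params["nu2_logsd"],
        delta_mean=params.get("delta_mean", np.zeros((K, 0))),
        delta_logsd=params.get("delta_logsd", np.zeros((K, 0))),
        pig_mean=params["pig_mean"], pig_logsd=params["pig_logsd"],
        G=prep.G, otu_ids=m.otu_ids, subjects=prep.subjects,
        timepoints=prep.timepoints, perturbation_names=prep.pert_names,
        xi=xi_final, hp=hp, encoder_weights=enc,
        loss_history=losses, seed=config.seed,
    )
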