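"""Generative model core: priors, dynamics, contamination, and likelihood.

The model explains particle-level OTU read counts through K latent
*assemblages*, each a frequency distribution theta_k over OTUs.  Per subject
and time point, assemblage proportions beta are a softmax of untransformed
weights x that follow a Gaussian random walk over time (variance scaled by the
time gap), with optional step changes at perturbation on/off transitions.
Binary indicators gamma_k (assemblage present) and c_kp (perturbation p
affects assemblage k) carry sparsity-inducing Bernoulli priors.  Each read in
a particle is generated either from the particle's assemblage or from a
per-time-point contamination profile G (unencapsulated DNA), chosen with
probability pi_G.

Generative process, for capacity K, subjects S, time grid t_0..t_{T-1}:

1. x_ks(0) ~ Normal(0, 1)
2. sigma2_w,s = softplus(nu2_s),  nu2_s ~ Normal(mu_w, rho2_w)
3. c_kp ~ Bernoulli(pi_c),  delta_kp ~ Normal(0, rho2_delta)
4. x_ks(t_i) ~ Normal(eta_ks(t_i), sigma2_w,s * dt_i) with
   eta = x(t_{i-1}) + c*delta at an "on" transition,
   eta = x(t_{i-1}) - c*delta at an "off" transition,
   eta = x(t_{i-1}) otherwise (pure drift)
5. gamma_k ~ Bernoulli(pi_gamma),  pi_gamma = (0.5/K)^xi
6. beta_ks(t) = gamma_k exp(x_ks(t)) / sum_j gamma_j exp(x_js(t))
7. logit pi_G,t ~ Normal(mu_pi, rho2_pi)
8. per particle: z ~ Categorical(beta); per read: a ~ Bernoulli(pi_G,t),
   OTU ~ Categorical(theta_z) if a=0 else Categorical(G_t)

The per-particle likelihood marginalizes z and the per-read contamination
flags exactly; it is a multinomial kernel (the combinatorial constant is
omitted, which is irrelevant to inference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .data import ParticleCountMatrix, StudyDesign

__all__ = [
    "Hyperparameters",
    "GenerativeState",
    "compute_contamination_profile",
    "perturbed_means",
    "assemblage_weights",
    "particle_log_marginal",
    "log_prior",
    "sample_state",
    "sample_counts",
]


@dataclass
class Hyperparameters:
    """Prior settings.  Defaults encode diffuse priors except the sparsity
    terms (pi_c, pi_gamma), which are set for parsimony.

    The sparsity exponent xi scales the assemblage-presence prior
    pi_gamma = (0.5/K)^xi with the dataset size; by default
    xi = xi_rate * (total reads), i.e. a prior strength of 0.5% of the data.
    ``mu_w`` is the prior location of the *pre-softplus* process variance
    parameter nu2 (see docs/methods.md for the scale caveat).
    """

    K: int = 100
    mu_w: float = 0.01
    rho2_w: float = 10.0
    pi_c: float | None = None  # default 0.5/K
    mu_delta: float = 0.0
    rho2_delta: float = 100.0
    mu_pi: float = float(logit(0.05))
    rho2_pi: float = 10.0
    xi_rate: float = 0.005
    xi: float | None = None  # set explicitly or via resolve_xi

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for name in ("rho2_w", "rho2_delta", "rho2_pi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pi_c is None:
            self.pi_c = 0.5 / self.K
        if not 0 < self.pi_c < 1:
            raise ValueError("pi_c must lie in (0,1)")
        if self.xi is not None and self.xi < 1:
            raise ValueError("xi must be >= 1")

    @property
    def pi_gamma_base(self) -> float:
        return 0.5 / self.K

    def resolve_xi(self, total_reads: int) -> float:
        """xi = xi_rate * total reads, rounded, floored at 1."""
        if self.xi is not None:
            return float(self.xi)
        return float(max(1, round(self.xi_rate * total_reads)))

    def log_pi_gamma(self, xi: float) -> float:
        """log pi_gamma = xi * log(0.5/K); kept in log space for stability."""
        return float(xi) * np.log(self.pi_gamma_base)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {k: getattr(self, k) for k in (
                "K", "mu_w", "rho2_w", "pi_c", "mu_delta", "rho2_delta",
                "mu_pi", "rho2_pi", "xi_rate", "xi")},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "Hyperparameters":
        return cls(**json.loads(Path(path).read_text()))


def softplus(x):
    return np.logaddexp(0.0, x)


@dataclass
class GenerativeState:
    """One full configuration of the latent variables.

    Shapes: x (K,S,T); nu2 (S,); c, delta (K,P); gamma (K,); theta (K,O);
    pi_G (T,); G (T,O).  sigma2_w is derived as softplus(nu2).
    """

    x: np.ndarray
    nu2: np.ndarray
    c: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    pi_G: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("theta rows must sum to 1")
        if not np.allclose(self.G.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("G rows must sum to 1")
        if ((np.asarray(self.pi_G) <= 0) | (np.asarray(self.pi_G) >= 1)).any():
            raise ValueError("pi_G must lie in (0,1)")

    @property
    def sigma2_w(self) -> np.ndarray:
        return softplus(np.asarray(self.nu2, dtype=float))

    @property
    def n_assemblages(self) -> int:
        return self.x.shape[0]

    def save(self, path) -> None:
        np.savez(
            path, x=self.x, nu2=self.nu2, c=self.c, delta=self.delta,
            gamma=self.gamma, theta=self.theta, pi_G=self.pi_G, G=self.G,
        )

    @classmethod
    def load(cls, path) -> "GenerativeState":
        with np.load(path) as z:
            return cls(**{k: z[k] for k in z.files})


def compute_contamination_profile(m: ParticleCountMatrix) -> np.ndarray:
    """Per-time-point OTU profile of pooled reads (T x O, rows sum to 1).

    Contamination is modeled as unencapsulated DNA occurring at frequencies
    proportional to the total DNA in the sample:
    G_to = sum_{s,l} r_lsot / sum_{s,l,j} r_lsjt.
    """
    times = m.timepoints
    G = np.zeros((len(times), m.n_otus))
    for i, t in enumerate(times):
        pooled = m.counts[m.times == t].sum(axis=0).astype(float)
        tot = pooled.sum()
        if tot == 0:
            raise ValueError(f"time point {t} has zero total reads")
        G[i] = pooled / tot
    return G


def perturbed_means(x_prev, c, delta, transition: str):
    """Mean of the random-walk step: add/subtract c*delta at on/off transitions."""
    x_prev = np.asarray(x_prev, dtype=float)
    if transition == "on":
        return x_prev + np.asarray(c) * np.asarray(delta)
    if transition == "off":
        return x_prev - np.asarray(c) * np.asarray(delta)
    if transition == "none":
        return x_prev.copy()
    raise ValueError(f"unknown transition {transition!r}")


def assemblage_weights(x, gamma):
    """Masked softmax: beta_k = gamma_k exp(x_k) / sum_j gamma_j exp(x_j)."""
    x = np.asarray(x, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if not (gamma > 0).any():
        raise ValueError("all assemblage indicators are zero (empty model)")
    w = gamma * np.exp(x - x[gamma > 0].max())
    return w / w.sum()


def particle_log_marginal(reads, beta, theta, G_t, pi_G: float) -> float:
    """Exact log marginal of one particle's count vector.

    log sum_k beta_k prod_o [(1-pi_G) theta_ko + pi_G G_to]^{r_o}, i.e. the
    assemblage assignment z and the per-read contamination flags are summed
    out analytically.  Returns -inf when some observed OTU has zero mixed
    probability in every assemblage with positive weight.
    """
    reads = np.asarray(reads, dtype=float)
    beta = np.asarray(beta, dtype=float)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    G_t = np.asarray(G_t, dtype=float)
    mix = (1.0 - pi_G) * theta + pi_G * G_t[None, :]
    with np.errstate(divide="ignore"):
        logmix = np.log(mix)
        logbeta = np.log(beta)
    obs = reads > 0
    ll_k = np.where(
        np.isneginf(logmix[:, obs]).any(axis=1) & (reads[obs] > 0).any(),
        -np.inf,
        (reads[obs] * np.where(np.isneginf(logmix[:, obs]), 0.0, logmix[:, obs])).sum(axis=1),
    )
    # assemblages with beta=0 contribute nothing
    tot = logbeta + ll_k
    finite = ~np.isneginf(tot)
    if not finite.any():
        return -np.inf
    mx = tot[finite].max()
    return float(mx + np.log(np.exp(tot[finite] - mx).sum()))


def log_prior(
    state: GenerativeState, hp: Hyperparameters, design: StudyDesign, xi: float | None = None
) -> float:
    """Log prior density of a full latent configuration.

    Sums the log densities of steps 1-5 and 7 of the generative process; the
    Bernoulli prior on gamma uses pi_gamma = (0.5/K)^xi evaluated in log
    space.  Requires strictly positive time gaps.
    """
    if (design.delta_t <= 0).any():
        raise ValueError("time gaps must be positive")
    K, S, T = state.x.shape
    if xi is None:
        xi = 1.0 if hp.xi is None else hp.xi
    lp = norm.logpdf(state.x[:, :, 0], 0.0, 1.0).sum()
    lp += norm.logpdf(state.nu2, hp.mu_w, np.sqrt(hp.rho2_w)).sum()
    c = np.asarray(state.c, dtype=float)
    lp += (c * np.log(hp.pi_c) + (1 - c) * np.log1p(-hp.pi_c)).sum()
    lp += norm.logpdf(state.delta, hp.mu_delta, np.sqrt(hp.rho2_delta)).sum()
    signs = design.transition_signs()  # (T, P)
    s2 = state.sigma2_w  # (S,)
    for i in range(1, T):
        step = state.c * state.delta @ signs[i]  # (K,)
        eta = state.x[:, :, i - 1] + step[:, None]
        sd = np.sqrt(s2 * design.delta_t[i - 1])  # (S,)
        lp += norm.logpdf(state.x[:, :, i], eta, sd[None, :]).sum()
    log_pg = hp.log_pi_gamma(xi)
    log_1mpg = np.log1p(-np.exp(log_pg)) if log_pg > -30 else -np.exp(log_pg)
    g = np.asarray(state.gamma, dtype=float)
    lp += (g * log_pg + (1 - g) * log_1mpg).sum()
    lp += norm.logpdf(logit(state.pi_G), hp.mu_pi, np.sqrt(hp.rho2_pi)).sum()
    # change of variables is not applied: the prior is placed on logit pi_G,
    # and pi_G is reported as a deterministic transform of it
    return float(lp)


def sample_state(
    hp: Hyperparameters,
    design: StudyDesign,
    n_subjects: int,
    theta: np.ndarray,
    G: np.ndarray,
    rng: np.random.Generator,
    xi: float | None = None,
) -> GenerativeState:
    """Draw one latent configuration from the prior (theta and G are given,
    matching their treatment as non-stochastic parameters)."""
    K, O = np.atleast_2d(theta).shape
    if K != hp.K:
        raise ValueError("theta rows must equal hp.K")
    T = design.n_timepoints
    P = len(design.perturbations)
    S = n_subjects
    if xi is None:
        xi = 1.0 if hp.xi is None else hp.xi
    nu2 = rng.normal(hp.mu_w, np.sqrt(hp.rho2_w), size=S)
    s2 = softplus(nu2)
    c = (rng.random((K, P)) < hp.pi_c).astype(float)
    delta = rng.normal(hp.mu_delta, np.sqrt(hp.rho2_delta), size=(K, P))
    x = np.zeros((K, S, T))
    x[:, :, 0] = rng.normal(0.0, 1.0, size=(K, S))
    signs = design.transition_signs()
    for i in range(1, T):
        step = (c * delta) @ signs[i]
        eta = x[:, :, i - 1] + step[:, None]
        sd = np.sqrt(s2 * design.delta_t[i - 1])
        x[:, :, i] = rng.normal(eta, sd[None, :])
    pi_gamma = np.exp(hp.log_pi_gamma(xi))
    gamma = (rng.random(K) < pi_gamma).astype(float)
    if not gamma.any():
        gamma[rng.integers(K)] = 1.0  # keep the model non-empty
    pi_G = expit(rng.normal(hp.mu_pi, np.sqrt(hp.rho2_pi), size=T))
    return GenerativeState(
        x=x, nu2=nu2, c=c, delta=delta, gamma=gamma,
        theta=np.atleast_2d(theta), pi_G=pi_G, G=np.atleast_2d(G),
    )


def sample_counts(
    state: GenerativeState,
    design: StudyDesign,
    n_particles_per_sample: int,
    reads_per_particle: int,
    rng: np.random.Generator,
):
    """Generate counts from a latent state (steps 6-8); used for self-checks.

    Returns (counts L x O, subjects, times, z assignments).
    """
    K, S, T = state.x.shape
    O = state.theta.shape[1]
    counts, subj, times, zs = [], [], [], []
    for s in range(S):
        for i, t in enumerate(design.timepoints):
            beta = assemblage_weights(state.x[:, s, i], state.gamma)
            z = rng.choice(K, size=n_particles_per_sample, p=beta)
            for l in range(n_particles_per_sample):
                mix = (1 - state.pi_G[i]) * state.theta[z[l]] + state.pi_G[i] * state.G[i]
                counts.append(rng.multinomial(reads_per_particle, mix))
                subj.append(f"S{s}")
                times.append(t)
                zs.append(z[l])
    return np.array(counts), np.array(subj, dtype=object), np.array(times), np.array(zs)
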