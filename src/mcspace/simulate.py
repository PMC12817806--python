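"""Semi-synthetic data generation.

Two generators mirror the study conditions of particle co-localization
experiments:

* ``simulate_particles`` — single-time-point data: particle read depths from a
  negative binomial, assemblage assignment from proportions beta, and each
  read drawn from the assemblage's OTU frequencies or, with probability
  pi_G, from a contamination profile G.
* ``simulate_timeseries`` — longitudinal data: initial log-weights from a
  baseline, perturbation indicators/magnitudes sampled per assemblage, a
  Gaussian random walk between time points (variance scaled by the gap), and
  particles generated per (subject, time).

``bootstrap_assemblages`` resamples baseline assemblages with replacement and
permutes each row's OTU labels, producing new ground truths that preserve the
frequency spectra of the baseline.  ``default_baseline`` provides a synthetic
stand-in baseline with realistic dominance structure for when fitted baseline
assemblages are unavailable.

Preset parameters (read-depth negative binomial, particle numbers,
contamination rates) follow values estimated from real human and mouse
SAMPL-seq series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ParticleCountMatrix, StudyDesign

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "HUMAN_PRESET",
    "MOUSE_PRESET",
    "default_baseline",
    "bootstrap_assemblages",
    "simulate_particles",
    "simulate_timeseries",
    "ground_truth_pairs",
]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    The negative binomial is parameterized as (n successes, success
    probability p) with mean n(1-p)/p, matching the convention of the preset
    (n, p) pairs.  ``read_depth`` fixes the per-particle read count instead of
    drawing it from the negative binomial (used when sweeping depth).
    """

    n_particles: int = 1419
    nb_n: float = 2.582442
    nb_p: float = 0.000792
    contamination: float = 0.004
    read_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nb_p < 1:
            raise ValueError("nb_p must lie in (0,1)")
        if self.nb_n <= 0:
            raise ValueError("nb_n must be positive")
        if not 0 <= self.contamination < 1:
            raise ValueError("contamination must lie in [0,1)")

    @property
    def mean_reads(self) -> float:
        if self.read_depth is not None:
            return float(self.read_depth)
        return self.nb_n * (1 - self.nb_p) / self.nb_p


# defaults estimated from the human and mouse series
HUMAN_PRESET = SimulationConfig(
    n_particles=1419, nb_n=2.582442, nb_p=0.000792, contamination=0.004
)
MOUSE_PRESET = SimulationConfig(
    n_particles=2829, nb_n=1.107895, nb_p=0.000726, contamination=0.018
)


@dataclass
class GroundTruth:
    """Everything the generator knows: frequencies, proportions, assignments."""

    theta: np.ndarray                 # (K, O)
    beta: np.ndarray                  # (K,) or (S, T, K)
    z: np.ndarray                     # particle assemblage assignments
    pairwise: np.ndarray              # (O, O) binary association matrix
    c: np.ndarray | None = None       # (K, P)
    delta: np.ndarray | None = None   # (K, P)
    x: np.ndarray | None = None       # (K, S, T) latent walk
    contamination: float = 0.0

    @property
    def n_assemblages(self) -> int:
        return self.theta.shape[0]


def default_baseline(K0: int = 34, O: int = 58, seed: int = 0,
                     alpha: float = 0.08, beta_conc: float = 2.0):
    """Synthetic stand-in baseline assemblages (theta, beta).

    Rows are sparse Dirichlet draws (concentration ``alpha`` per OTU), giving
    each assemblage a few dominant OTUs and a long tail, the dominance
    structure typical of fitted assemblages; proportions are a Dirichlet draw
    with concentration ``beta_conc``.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    theta = rng.dirichlet(np.full(O, alpha), size=K0)
    beta = rng.dirichlet(np.full(K0, beta_conc))
    return theta, beta


def bootstrap_assemblages(baseline_theta: np.ndarray, baseline_beta: np.ndarray,
                          K: int, seed: int = 0):
    """Resample K (theta, beta) pairs with replacement and permute OTU labels.

    Each sampled frequency row has its OTU labels independently permuted, so
    the sorted frequency multiset of every output row equals that of some
    baseline row; proportions are renormalized to sum to one.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    baseline_theta = np.atleast_2d(np.asarray(baseline_theta, dtype=float))
    baseline_beta = np.asarray(baseline_beta, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, baseline_theta.shape[0], size=K)
    theta = baseline_theta[idx].copy()
    beta = baseline_beta[idx].astype(float).copy()
    for k in range(K):
        theta[k] = theta[k, rng.permutation(theta.shape[1])]
    beta /= beta.sum()
    return theta, beta


def _default_contamination_profile(theta: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Proportion-weighted average of assemblage frequencies (simulation G)."""
    return np.asarray(beta, dtype=float) @ np.atleast_2d(theta)


def _draw_particle_counts(theta_z: np.ndarray, G: np.ndarray, pi_G: float,
                          depths: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Counts for a batch of particles with given assemblage rows and depths."""
    L, O = theta_z.shape
    counts = np.zeros((L, O), dtype=np.int64)
    n_contam = rng.binomial(depths, pi_G) if pi_G > 0 else np.zeros(L, dtype=np.int64)
    for l in range(L):
        if depths[l] == 0:
            continue
        if n_contam[l]:
            counts[l] += rng.multinomial(n_contam[l], G)
        kept = depths[l] - n_contam[l]
        if kept:
            counts[l] += rng.multinomial(kept, theta_z[l])
    return counts


def simulate_particles(theta: np.ndarray, beta: np.ndarray,
                       config: SimulationConfig,
                       G: np.ndarray | None = None,
                       time: float = 0.0, subject: str = "S0",
                       rng: np.random.Generator | None = None):
    """Single-time-point generator; returns (ParticleCountMatrix, GroundTruth).

    Per particle: depth R_l ~ NegativeBinomial(nb_n, nb_p) (or the fixed
    ``read_depth``), assemblage z_l ~ Categorical(beta); each read comes from
    the contamination profile with probability ``config.contamination`` and
    from theta_{z_l} otherwise.  Zero-depth particles are emitted (downstream
    read filters remove them).
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    beta = np.asarray(beta, dtype=float)
    K, O = theta.shape
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if G is None:
        G = _default_contamination_profile(theta, beta)
    L = config.n_particles
    if config.read_depth is not None:
        depths = np.full(L, config.read_depth, dtype=np.int64)
    else:
        depths = rng.negative_binomial(config.nb_n, config.nb_p, size=L)
    z = rng.choice(K, size=L, p=beta / beta.sum())
    counts = _draw_particle_counts(theta[z], G, config.contamination, depths, rng)
    m = ParticleCountMatrix(
        counts=counts,
        particle_ids=np.array([f"{subject}_t{time:g}_p{l}" for l in range(L)], dtype=object),
        otu_ids=np.array([f"OTU{o+1}" for o in range(O)], dtype=object),
        subjects=np.full(L, subject, dtype=object),
        times=np.full(L, float(time)),
    )
    truth = GroundTruth(
        theta=theta, beta=beta, z=z,
        pairwise=ground_truth_pairs(theta),
        contamination=config.contamination,
    )
    return m, truth


def simulate_timeseries(baseline_theta: np.ndarray, baseline_beta: np.ndarray,
                        design: StudyDesign, config: SimulationConfig,
                        sigma2_w: float = 0.1, pi_c: float = 0.1,
                        mu_delta: float = 0.0, rho2_delta: float = 4.0,
                        n_subjects: int = 1,
                        G: np.ndarray | None = None,
                        c: np.ndarray | None = None,
                        delta: np.ndarray | None = None):
    """Longitudinal generator with random walk and perturbation effects.

    Initial weights are x(0) = log(baseline beta); per assemblage and
    perturbation, c ~ Bernoulli(pi_c) and delta ~ Normal(mu_delta,
    rho2_delta) unless supplied explicitly (to inject a known effect).  At an
    on (off) transition of perturbation p the walk mean shifts by +c*delta
    (-c*delta); between time points x diffuses with variance sigma2_w * dt.
    Proportions are softmax(x); all baseline assemblages remain present.
    Returns (ParticleCountMatrix over all samples, GroundTruth).
    """
    theta = np.atleast_2d(np.asarray(baseline_theta, dtype=float))
    beta0 = np.asarray(baseline_beta, dtype=float)
    K, O = theta.shape
    T = design.n_timepoints
    P = len(design.perturbations)
    S = n_subjects
    rng = np.random.default_rng(config.seed)
    if G is None:
        G = _default_contamination_profile(theta, beta0)
    if c is None:
        c = (rng.random((K, P)) < pi_c).astype(float)
    if delta is None:
        delta = rng.normal(mu_delta, np.sqrt(rho2_delta), size=(K, P))
    c = np.asarray(c, dtype=float).reshape(K, P)
    delta = np.asarray(delta, dtype=float).reshape(K, P)
    signs = design.transition_signs()
    x = np.zeros((K, S, T))
    x[:, :, 0] = np.log(np.clip(beta0, 1e-12, None))[:, None]
    for i in range(1, T):
        step = (c * delta) @ signs[i]
        eta = x[:, :, i - 1] + step[:, None]
        sd = np.sqrt(sigma2_w * design.delta_t[i - 1])
        x[:, :, i] = eta + sd * rng.standard_normal((K, S))
    beta = np.moveaxis(np.exp(x - x.max(axis=0)), 0, -1)  # (S, T, K)
    beta /= beta.sum(axis=-1, keepdims=True)

    blocks, zs = [], []
    subj_all, time_all, pid_all = [], [], []
    for s in range(S):
        for i, t in enumerate(design.timepoints):
            L = config.n_particles
            if config.read_depth is not None:
                depths = np.full(L, config.read_depth, dtype=np.int64)
            else:
                depths = rng.negative_binomial(config.nb_n, config.nb_p, size=L)
            z = rng.choice(K, size=L, p=beta[s, i])
            counts = _draw_particle_counts(theta[z], G, config.contamination, depths, rng)
            blocks.append(counts)
            zs.append(z)
            subj_all.append(np.full(L, f"S{s}", dtype=object))
            time_all.append(np.full(L, float(t)))
            pid_all.append(np.array([f"S{s}_t{t:g}_p{l}" for l in range(L)], dtype=object))
    m = ParticleCountMatrix(
        counts=np.vstack(blocks),
        particle_ids=np.concatenate(pid_all),
        otu_ids=np.array([f"OTU{o+1}" for o in range(O)], dtype=object),
        subjects=np.concatenate(subj_all),
        times=np.concatenate(time_all),
    )
    truth = GroundTruth(
        theta=theta, beta=beta, z=np.concatenate(zs),
        pairwise=ground_truth_pairs(theta),
        c=c, delta=delta, x=x, contamination=config.contamination,
    )
    return m, truth


def ground_truth_pairs(theta: np.ndarray, tau: float = 0.005) -> np.ndarray:
    """Binary O x O matrix: 1 iff some assemblage holds both OTUs above tau."""
    present = (np.atleast_2d(theta) > tau)
    return (present.T @ present > 0).astype(int)


def independent_presence_matrix(seed: int = 0, n_particles: int = 500,
                                n_otus: int = 10) -> ParticleCountMatrix:
    """Null data with independently occurring OTUs (no co-localization).

    Each OTU appears in each particle independently with its own occupancy
    probability (uniform on [0.3, 0.7]); present OTUs carry enough reads to
    clear the presence threshold.  Used to calibrate pairwise tests: under
    this generator no pair is truly associated, so their p-values should be
    approximately uniform.
    """
    rng = np.random.default_rng(seed)
    p_o = rng.uniform(0.3, 0.7, n_otus)
    pres = rng.random((n_particles, n_otus)) < p_o
    counts = pres * (15 + rng.poisson(50, size=(n_particles, n_otus)))
    empty = counts.sum(axis=1) == 0
    counts[empty, 0] = 20
    return ParticleCountMatrix(
        counts=counts,
        particle_ids=np.array([f"p{i}" for i in range(n_particles)], dtype=object),
        otu_ids=np.array([f"OTU{j+1}" for j in range(n_otus)], dtype=object),
        subjects=np.full(n_particles, "S0", dtype=object),
        times=np.zeros(n_particles),
    )
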