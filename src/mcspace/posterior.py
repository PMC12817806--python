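"""Posterior summaries: Bayes factors, assemblage proportions, associations.

Quantities reported to the user after a fit:

* **Bayes factors** for perturbation effects: posterior-to-prior odds of the
  perturbation indicator, BF = [q/(1-q)] * [(1-pi_c)/pi_c].  Values above 10
  are conventionally read as strong evidence.
* **Assemblage proportions**: assemblages with posterior presence probability
  below a threshold (default 0.95) are removed; the latent weights x are then
  sampled from the fitted Gaussian posterior and softmaxed over the retained
  assemblages, and the arithmetic mean over samples is reported.
* **Association scores** alpha_ij(t): probability of generating a pair of
  reads of OTUs i and j from the same assemblage, normalized by the marginal
  probabilities of generating a read of each.
* **Co-association probabilities**: posterior probability that OTUs i and j
  co-occur in some particle, using a presence threshold tau on assemblage
  frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import StudyDesign
from .inference import VariationalPosterior

__all__ = [
    "PosteriorEnsemble",
    "bayes_factor",
    "summarize_beta",
    "perturbed_assemblages",
    "association_score",
    "association_matrix",
    "coassociation_probability",
    "association_map",
    "select_anchor_taxa",
]

BF_INFINITE_SENTINEL = 1e12


def bayes_factor(q: float, pi_c: float):
    """Posterior-to-prior odds ratio for a Bernoulli indicator.

    BF = [q/(1-q)] * [(1-pi_c)/pi_c].  ``q`` may be an array.  q = 1 yields
    +inf (rendered downstream as a sentinel with a flag).
    """
    if not 0 < pi_c < 1:
        raise ValueError("pi_c must lie in (0,1)")
    q = np.asarray(q, dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q must lie in [0,1]")
    prior_odds = pi_c / (1.0 - pi_c)
    with np.errstate(divide="ignore"):
        post_odds = np.where(q < 1, q / (1.0 - q), np.inf)
    out = post_odds / prior_odds
    return float(out) if out.ndim == 0 else out


@dataclass
class PosteriorEnsemble:
    """Monte-Carlo posterior summary over retained assemblages.

    ``beta_samples`` has shape (n_samples, S, T, K_retained); each sample's
    proportions sum to one over the retained assemblages.
    """

    beta_samples: np.ndarray
    theta: np.ndarray            # (K_retained, O)
    retained: np.ndarray         # indices into the original capacity
    q_gamma: np.ndarray          # (K_retained,)
    bf: np.ndarray               # (K_retained, P)
    bf_infinite: np.ndarray      # flags where BF overflowed
    otu_ids: np.ndarray
    subjects: np.ndarray
    timepoints: np.ndarray
    perturbation_names: list
    seed: int = 0

    @property
    def beta_mean(self) -> np.ndarray:
        """Arithmetic mean of proportions over posterior samples (S, T, K)."""
        return self.beta_samples.mean(axis=0)

    @property
    def n_samples(self) -> int:
        return self.beta_samples.shape[0]

    @property
    def n_assemblages(self) -> int:
        return self.theta.shape[0]

    def beta_at(self, subject=None, time=None) -> np.ndarray:
        """Posterior-mean proportions for one (subject, time) sample."""
        s = 0 if subject is None else list(self.subjects.astype(str)).index(str(subject))
        t = 0 if time is None else list(self.timepoints).index(float(time))
        return self.beta_mean[s, t]

    def bf_table(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_assemblages):
            for j, p in enumerate(self.perturbation_names):
                bf = self.bf[k, j]
                rows.append({
                    "assemblage": int(self.retained[k]),
                    "perturbation": p,
                    "bayes_factor": BF_INFINITE_SENTINEL if np.isinf(bf) else bf,
                    "infinite": bool(self.bf_infinite[k, j]),
                })
        return pd.DataFrame(rows)


def summarize_beta(vp: VariationalPosterior, design: StudyDesign | None = None,
                   gamma_threshold: float = 0.95, n: int = 1000,
                   seed: int = 0) -> PosteriorEnsemble:
    """Monte-Carlo summary of assemblage proportions.

    Assemblages with posterior presence probability below ``gamma_threshold``
    are masked out; x is sampled ``n`` times from its Gaussian posterior and
    softmaxed over the retained assemblages.
    """
    keep = vp.active_indices(gamma_threshold)
    if len(keep) == 0:
        raise ValueError(f"no assemblage has q_gamma >= {gamma_threshold}")
    rng = np.random.default_rng(seed)
    mu = vp.mu_x[:, :, keep]                      # (S, T, Kr)
    sd = np.exp(vp.logsd_x[:, :, keep])
    x = mu[None] + sd[None] * rng.standard_normal((n,) + mu.shape)
    x -= x.max(axis=-1, keepdims=True)
    w = np.exp(x)
    beta = w / w.sum(axis=-1, keepdims=True)
    qc = vp.q_c[keep] if vp.q_c.size else np.zeros((len(keep), 0))
    bf = bayes_factor(qc, vp.hp.pi_c) if qc.size else np.zeros((len(keep), 0))
    bf = np.atleast_2d(bf).reshape(len(keep), -1)
    return PosteriorEnsemble(
        beta_samples=beta,
        theta=vp.theta[keep],
        retained=keep,
        q_gamma=vp.q_gamma[keep],
        bf=bf,
        bf_infinite=np.isinf(bf),
        otu_ids=vp.otu_ids,
        subjects=vp.subjects,
        timepoints=vp.timepoints,
        perturbation_names=list(vp.perturbation_names),
        seed=seed,
    )


def perturbed_assemblages(ens: PosteriorEnsemble, bf_threshold: float = 10.0) -> list:
    """(assemblage, perturbation, BF) triples with BF > threshold, descending."""
    hits = []
    for k in range(ens.n_assemblages):
        for j, p in enumerate(ens.perturbation_names):
            if ens.bf[k, j] > bf_threshold:
                hits.append((int(ens.retained[k]), p, float(ens.bf[k, j])))
    return sorted(hits, key=lambda t: -t[2])


def association_matrix(beta_t: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """All pairwise association scores for one sample's proportions.

    alpha_ij = sum_k beta_k theta_ki theta_kj
               / (0.5 * (sum_k beta_k theta_ki + sum_k beta_k theta_kj)).
    Entries where both marginals vanish are defined as 0.
    """
    beta_t = np.asarray(beta_t, dtype=float)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    num = theta.T @ (beta_t[:, None] * theta)          # (O, O)
    marg = theta.T @ beta_t                            # (O,)
    denom = 0.5 * (marg[:, None] + marg[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = np.where(denom > 0, num / denom, 0.0)
    return alpha


def association_score(beta_t, theta, i: int, j: int) -> float:
    """Association score between OTU indices i and j for one sample."""
    beta_t = np.asarray(beta_t, dtype=float)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    num = float(np.sum(beta_t * theta[:, i] * theta[:, j]))
    denom = 0.5 * float(np.sum(beta_t * theta[:, i]) + np.sum(beta_t * theta[:, j]))
    return num / denom if denom > 0 else 0.0


def coassociation_probability(ens: PosteriorEnsemble, tau: float = 0.005,
                              subject=None, time=None) -> np.ndarray:
    """Posterior probability that each OTU pair co-occurs in some particle.

    Per posterior sample s, p^s_ij = sum_k beta^s_k 1(theta_ki > tau)
    1(theta_kj > tau); the result is the mean over samples (symmetric,
    entries in [0, 1]).
    """
    s = 0 if subject is None else list(ens.subjects.astype(str)).index(str(subject))
    t = 0 if time is None else list(ens.timepoints).index(float(time))
    present = (ens.theta > tau).astype(float)          # (K, O)
    beta = ens.beta_samples[:, s, t, :]                # (n, K)
    # p^s = present.T @ diag(beta^s) @ present, averaged over samples
    weighted = present.T @ (beta.mean(axis=0)[:, None] * present)
    return weighted


def association_map(ens: PosteriorEnsemble, anchor, min_edge: float = 0.01,
                    subject=None, times=None) -> pd.DataFrame:
    """Edges (anchor, partner, alpha) with alpha >= min_edge for an anchor OTU.

    ``times`` selects the time points to average over (a dietary/condition
    interval); scores and node abundances are the means of the per-time
    values over those days.  Returns a tidy frame with partner relative
    abundances for node sizing.
    """
    otus = [str(o) for o in ens.otu_ids]
    if str(anchor) not in otus:
        raise KeyError(f"unknown anchor OTU {anchor!r}")
    a_idx = otus.index(str(anchor))
    s = 0 if subject is None else list(ens.subjects.astype(str)).index(str(subject))
    if times is None:
        times = list(ens.timepoints)
    t_idx = [list(ens.timepoints).index(float(t)) for t in times]
    alphas, abunds = [], []
    for ti in t_idx:
        beta = ens.beta_mean[s, ti]
        alphas.append(association_matrix(beta, ens.theta)[a_idx])
        abunds.append(ens.theta.T @ beta)
    alpha = np.mean(alphas, axis=0)
    abund = np.mean(abunds, axis=0)
    rows = [
        {"anchor": str(anchor), "partner": otus[j], "alpha": float(alpha[j]),
         "partner_abundance": float(abund[j])}
        for j in range(len(otus))
        if j != a_idx and alpha[j] >= min_edge
    ]
    return pd.DataFrame(rows, columns=["anchor", "partner", "alpha", "partner_abundance"])


def select_anchor_taxa(ens: PosteriorEnsemble, periods: list,
                       min_abund: float = 0.05, min_periods: int = 3,
                       subject=None) -> list:
    """Anchor-taxon rule: relative abundance >= min_abund on >= min_periods
    of the given time-point groups (e.g. dietary intervals)."""
    s = 0 if subject is None else list(ens.subjects.astype(str)).index(str(subject))
    counts = np.zeros(len(ens.otu_ids), dtype=int)
    for period in periods:
        t_idx = [list(ens.timepoints).index(float(t)) for t in period]
        abund = np.mean([ens.theta.T @ ens.beta_mean[s, ti] for ti in t_idx], axis=0)
        counts += abund >= min_abund
    return [str(o) for o, c in zip(ens.otu_ids, counts) if c >= min_periods]
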