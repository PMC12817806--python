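"""Evaluation machinery: recovery error, pairwise comparators, cross-validation.

* **Assemblage recovery error** — greedy matching of learned and true
  assemblages by Hellinger distance: repeatedly take the global minimum of
  the pairwise distance matrix, delete its row and column, and accumulate;
  each surplus (unmatched) assemblage adds a penalty of 1.0; the total is
  normalized by the larger set size.  A posterior-aware variant computes the
  metric per posterior sample (keeping assemblages with a sampled indicator
  of 1) and reports the median.
* **Pairwise comparators** — presence/absence is called at per-particle
  relative abundance > tau (default 0.005).  Fisher's exact test (one-sided,
  greater) and a SIM9 checkerboard-swap null model score each OTU pair;
  p-values are Benjamini-Hochberg adjusted.  Detection performance is
  summarized with rank-based AUC over unordered pairs.
* **GMM comparator** — Gaussian mixtures on ILR-transformed compositions
  (multiplicative zero replacement with delta = 1/O^2), AIC model selection
  over a grid of component counts and seeds; cluster means are mapped back to
  the simplex as inferred assemblages.
* **Cross-validation** — five folds holding out 20% of particles per sample;
  held-out particles keep a without-replacement subsample of half their
  reads, and models predict the held-out half; performance is the cosine
  distance between predicted and held-out reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm
from sklearn.metrics import roc_auc_score
from sklearn.mixture import GaussianMixture
from skbio.stats.composition import ilr, ilr_inv, multi_replace
from statsmodels.stats.multitest import multipletests

from .data import ParticleCountMatrix, StudyDesign
from .inference import InferenceConfig, VariationalPosterior, fit
from .model import Hyperparameters

__all__ = [
    "RecoveryResult",
    "CrossValResult",
    "hellinger",
    "hellinger_matrix",
    "assemblage_recovery_error",
    "posterior_recovery_error",
    "binarize",
    "fisher_pairwise",
    "sim9_pairwise",
    "bh_adjust",
    "pairwise_auc",
    "gmm_comparator",
    "cosine_distance",
    "crossval_heldout_reads",
    "make_gmm_runner",
    "make_mcspace_runner",
]


def hellinger(a, b) -> float:
    """Hellinger distance between two discrete distributions, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(0.5 * np.sum((np.sqrt(a) - np.sqrt(b)) ** 2)))


def hellinger_matrix(A, B) -> np.ndarray:
    """Pairwise Hellinger distances between rows of A and rows of B."""
    sA = np.sqrt(np.atleast_2d(A))[:, None, :]
    sB = np.sqrt(np.atleast_2d(B))[None, :, :]
    return np.sqrt(0.5 * np.sum((sA - sB) ** 2, axis=-1))


@dataclass
class RecoveryResult:
    error: float
    matching: list          # (learned index, true index, Hellinger distance)
    n_learned: int
    n_true: int


def assemblage_recovery_error(learned, truth) -> RecoveryResult:
    """Greedy Hellinger matching with unit penalties for surplus assemblages.

    Matching proceeds until one side is exhausted (identical sets score 0);
    each unmatched assemblage on the larger side adds 1.0; the sum is divided
    by max(n_learned, n_true).
    """
    learned = np.atleast_2d(np.asarray(learned, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if learned.size == 0 or truth.size == 0:
        raise ValueError("empty assemblage set")
    if learned.shape[1] != truth.shape[1]:
        raise ValueError("assemblage sets must share the OTU universe")
    D = hellinger_matrix(learned, truth)
    rows = list(range(D.shape[0]))
    cols = list(range(D.shape[1]))
    d = 0.0
    matching = []
    while rows and cols:
        sub = D[np.ix_(rows, cols)]
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        matching.append((rows[i], cols[j], float(sub[i, j])))
        d += float(sub[i, j])
        del rows[i], cols[j]
    d += 1.0 * (len(rows) + len(cols))
    n_max = max(learned.shape[0], truth.shape[0])
    return RecoveryResult(
        error=d / n_max, matching=matching,
        n_learned=learned.shape[0], n_true=truth.shape[0],
    )


def posterior_recovery_error(vp: VariationalPosterior, truth_theta,
                             n_samples: int = 100, seed: int = 0) -> float:
    """Median recovery error over posterior samples of the indicators.

    Per sample, gamma_k ~ Bernoulli(q_gamma); only assemblages with a sampled
    indicator of 1 are scored against the truth.  A sample with no active
    assemblage scores the all-penalty value of 1.
    """
    rng = np.random.default_rng(seed)
    truth_theta = np.atleast_2d(truth_theta)
    errors = []
    for _ in range(n_samples):
        keep = rng.random(len(vp.q_gamma)) < vp.q_gamma
        if not keep.any():
            errors.append(1.0)
            continue
        errors.append(assemblage_recovery_error(vp.theta[keep], truth_theta).error)
    return float(np.median(errors))


# ---------------------------------------------------------------------------
# pairwise comparators


def binarize(m: ParticleCountMatrix, tau: float = 0.005) -> np.ndarray:
    """Presence/absence at per-particle relative abundance > tau."""
    return (m.relative_abundances() > tau)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _upper_pairs(O: int):
    return np.triu_indices(O, k=1)


def fisher_pairwise(m: ParticleCountMatrix, tau: float = 0.005,
                    adjust: bool = True) -> np.ndarray:
    """One-sided Fisher's exact p per OTU pair (O x O symmetric).

    Presence is binarized at tau; the one-sided alternative is co-occurrence
    greater than expected under equiprobable occupancy (hypergeometric tail).
    BH-adjusted across pairs unless ``adjust`` is False.
    """
    B = binarize(m, tau)
    N = B.shape[0]
    pres = B.sum(axis=0)                      # per-OTU prevalence
    C = (B.T.astype(int) @ B.astype(int))     # co-occurrence counts
    iu, ju = _upper_pairs(B.shape[1])
    a = C[iu, ju]
    # P(X >= a), X ~ Hypergeom(N, pres_i, pres_j)
    praw = np.clip(hypergeom.sf(a - 1, N, pres[iu], pres[ju]), 0.0, 1.0)
    p = bh_adjust(praw) if adjust else praw
    out = np.ones((B.shape[1], B.shape[1]))
    out[iu, ju] = p
    out[ju, iu] = p
    return out


def _sim9_swaps(B: np.ndarray, n_swaps: int, rng: np.random.Generator,
                count_successes: bool = False) -> np.ndarray:
    """Randomize a binary matrix by 2x2 checkerboard swaps in place.

    Row and column sums are preserved exactly.  ``n_swaps`` counts attempted
    swaps by default (set ``count_successes`` to count realized swaps).
    """
    B = B.copy()
    L, O = B.shape
    done = 0
    batch = max(1024, n_swaps)
    while done < n_swaps:
        r = rng.integers(0, L, size=(batch, 2))
        c = rng.integers(0, O, size=(batch, 2))
        for (r1, r2), (c1, c2) in zip(r, c):
            if r1 == r2 or c1 == c2:
                if not count_successes:
                    done += 1
                    if done >= n_swaps:
                        break
                continue
            a, b_ = B[r1, c1], B[r1, c2]
            cc, dd = B[r2, c1], B[r2, c2]
            swappable = (a == dd) and (b_ == cc) and (a != b_)
            if swappable:
                B[r1, c1] = b_
                B[r1, c2] = a
                B[r2, c1] = dd
                B[r2, c2] = cc
            if swappable or not count_successes:
                done += 1
                if done >= n_swaps:
                    break
    return B


def sim9_pairwise(m: ParticleCountMatrix, tau: float = 0.005,
                  n_swaps: int = 25_000, n_null: int = 50,
                  seed: int = 0, count_successes: bool = False,
                  adjust: bool = True) -> np.ndarray:
    """One-tailed SIM9 p per OTU pair (O x O symmetric), BH-adjusted by default.

    Generates ``n_null`` randomized communities, each by ``n_swaps``
    checkerboard swaps preserving OTU prevalence and particle diversity, and
    scores each pair's observed co-occurrence count with an upper-tail z-test
    against the null mean and standard deviation.  Pairs whose null never
    varies (sd = 0) receive p = 1.
    """
    rng = np.random.default_rng(seed)
    B = binarize(m, tau)
    O = B.shape[1]
    iu, ju = _upper_pairs(O)
    obs = (B.T.astype(int) @ B.astype(int))[iu, ju]
    null = np.empty((n_null, len(iu)))
    current = B
    for i in range(n_null):
        current = _sim9_swaps(B, n_swaps, rng, count_successes=count_successes)
        null[i] = (current.T.astype(int) @ current.astype(int))[iu, ju]
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
        praw = np.clip(np.where(sd > 0, norm.sf(z), 1.0), 0.0, 1.0)
    p = bh_adjust(praw) if adjust else praw
    out = np.ones((O, O))
    out[iu, ju] = p
    out[ju, iu] = p
    return out


def pairwise_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUC of a symmetric score matrix against binary truth.

    Computed over unordered off-diagonal pairs with midrank tie handling.
    For p-value methods pass ``1 - adjusted p`` as the score.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    iu, ju = _upper_pairs(scores.shape[0])
    y = truth[iu, ju].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("truth has a single class among pairs")
    return float(roc_auc_score(y, scores[iu, ju]))


# ---------------------------------------------------------------------------
# GMM comparator


@dataclass
class GmmResult:
    theta: np.ndarray        # (K_best, O) inverse-ILR cluster means
    weights: np.ndarray      # (K_best,)
    assignments: np.ndarray  # per-particle cluster labels
    n_components: int
    aic_table: pd.DataFrame
    model: GaussianMixture


def _to_ilr(m: ParticleCountMatrix) -> np.ndarray:
    rel = m.relative_abundances()
    return ilr(multi_replace(rel, delta=1.0 / m.n_otus**2))


def gmm_comparator(m: ParticleCountMatrix, K_range=range(2, 101),
                   n_seeds: int = 10, seed: int = 0) -> GmmResult:
    """AIC-selected Gaussian mixture on ILR-transformed compositions."""
    z = _to_ilr(m)
    K_range = [k for k in K_range if k <= z.shape[0]]
    if not K_range:
        raise ValueError("no feasible component count (more components than particles)")
    best = None
    rows = []
    for k in K_range:
        for s in range(n_seeds):
            gm = GaussianMixture(n_components=k, random_state=seed + s)
            try:
                gm.fit(z)
            except ValueError:
                continue
            aic = gm.aic(z)
            rows.append({"n_components": k, "seed": seed + s, "aic": aic})
            if best is None or aic < best[0]:
                best = (aic, gm)
    if best is None:
        raise RuntimeError("no Gaussian mixture fit converged over the grid")
    gm = best[1]
    theta = np.asarray(ilr_inv(gm.means_))
    return GmmResult(
        theta=theta, weights=gm.weights_, assignments=gm.predict(z),
        n_components=gm.n_components, aic_table=pd.DataFrame(rows), model=gm,
    )


def gmm_coassociation(result: GmmResult, tau: float = 0.005) -> np.ndarray:
    """Weight-summed co-presence of pairs across GMM clusters (AUC score)."""
    present = (result.theta > tau).astype(float)
    return present.T @ (result.weights[:, None] * present)


# ---------------------------------------------------------------------------
# cross-validation


def cosine_distance(r, rhat) -> float:
    """d = 1 - r.rhat / (|r| |rhat|); a zero predicted vector scores 1."""
    r = np.asarray(r, dtype=float)
    rhat = np.asarray(rhat, dtype=float)
    nr, nh = np.linalg.norm(r), np.linalg.norm(rhat)
    if nr == 0 or nh == 0:
        return 1.0
    return float(1.0 - r @ rhat / (nr * nh))


@dataclass
class CrossValResult:
    method: str
    distances: np.ndarray    # per held-out particle
    folds: np.ndarray        # fold index per held-out particle

    @property
    def median(self) -> float:
        return float(np.median(self.distances))


def _subsample_reads(row: np.ndarray, frac: float, rng: np.random.Generator):
    """Without-replacement (hypergeometric) split of one particle's reads."""
    total = int(row.sum())
    n_keep = int(round(frac * total))
    kept = rng.multivariate_hypergeometric(row.astype(np.int64), n_keep)
    return kept, row - kept


def crossval_heldout_reads(m: ParticleCountMatrix, design: StudyDesign,
                           model_runners: dict, n_folds: int = 5,
                           heldout_read_frac: float = 0.5, seed: int = 0):
    """Held-out-read prediction benchmark.

    Particles in each (subject, time) sample are partitioned into ``n_folds``
    folds.  Per fold, the training set is all other particles at full depth
    plus the fold's particles with ``heldout_read_frac`` of their reads
    subsampled without replacement; each runner predicts the held-out reads,
    scored by cosine distance.  ``model_runners`` maps a method name to a
    callable ``runner(train_m, design, heldout_mask, target_counts, seed)``
    returning per-held-out-particle distances.  Returns {name:
    CrossValResult}.
    """
    rng = np.random.default_rng(seed)
    groups = {}
    for i in range(m.n_particles):
        groups.setdefault((str(m.subjects[i]), float(m.times[i])), []).append(i)
    fold_of = np.empty(m.n_particles, dtype=int)
    for idx in groups.values():
        idx = np.asarray(idx)
        if len(idx) < n_folds:
            raise ValueError("need at least n_folds particles per sample")
        perm = rng.permutation(len(idx))
        fold_of[idx[perm]] = np.arange(len(idx)) % n_folds
    all_dist = {name: [] for name in model_runners}
    all_fold = {name: [] for name in model_runners}
    for f in range(n_folds):
        held = fold_of == f
        counts = m.counts.copy()
        targets = np.zeros_like(counts)
        for i in np.flatnonzero(held):
            kept, rest = _subsample_reads(m.counts[i], heldout_read_frac, rng)
            counts[i] = kept
            targets[i] = rest
        nonzero = counts.sum(axis=1) > 0
        train = ParticleCountMatrix(
            counts=counts[nonzero], particle_ids=m.particle_ids[nonzero],
            otu_ids=m.otu_ids, subjects=m.subjects[nonzero], times=m.times[nonzero],
        )
        held_in_train = held[nonzero]
        target_counts = targets[nonzero][held_in_train]
        for name, runner in model_runners.items():
            d = runner(train, design, held_in_train, target_counts, seed + f)
            all_dist[name].append(np.asarray(d))
            all_fold[name].append(np.full(len(d), f))
    return {
        name: CrossValResult(
            method=name,
            distances=np.concatenate(all_dist[name]),
            folds=np.concatenate(all_fold[name]),
        )
        for name in model_runners
    }


def make_gmm_runner(K_range=range(2, 101), n_seeds: int = 10):
    """CV runner: AIC-selected GMM; prediction is the maximum-likelihood
    cluster's inverse-ILR composition scaled by the particle's read total."""
    def runner(train, design, held_mask, target_counts, seed):
        res = gmm_comparator(train, K_range=K_range, n_seeds=n_seeds, seed=seed)
        z = _to_ilr(train)[held_mask]
        labels = res.model.predict(z)
        totals = train.counts[held_mask].sum(axis=1) + target_counts.sum(axis=1)
        preds = res.theta[labels] * totals[:, None]
        return np.array([
            cosine_distance(t, p) for t, p in zip(target_counts, preds)
        ])
    return runner


def make_mcspace_runner(hp: Hyperparameters | None = None,
                        config: InferenceConfig | None = None,
                        n_posterior_samples: int = 1000):
    """CV runner for the assemblage model.

    For each held-out particle, posterior samples of the assemblage
    proportions give a posterior over its assignment given the observed
    (downsampled) reads; per sample, an assignment is drawn and the predicted
    read distribution is the assemblage/contamination mixture.  The particle's
    score is the median cosine distance over posterior samples.
    """
    def runner(train, design, held_mask, target_counts, seed):
        hp_ = hp if hp is not None else Hyperparameters(K=30)
        cfg = config if config is not None else InferenceConfig(
            epochs=1000, n_restarts=1, seed=seed)
        vp = fit(train, design, hp_, cfg)
        rng = np.random.default_rng(seed)
        subjects = list(vp.subjects.astype(str))
        times = list(vp.timepoints)
        keep = vp.active_indices(0.95)
        if len(keep) == 0:
            keep = np.array([int(np.argmax(vp.q_gamma))])
        theta = vp.theta[keep]
        held_idx = np.flatnonzero(held_mask)
        dists = np.empty(len(held_idx))
        with np.errstate(divide="ignore"):
            log_theta_mix = {}
        for out_i, i in enumerate(held_idx):
            s = subjects.index(str(train.subjects[i]))
            t = times.index(float(train.times[i]))
            if t not in log_theta_mix:
                mix = (1 - vp.pi_G[t]) * theta + vp.pi_G[t] * vp.G[t][None, :]
                log_theta_mix[t] = (mix, np.log(np.clip(mix, 1e-300, None)))
            mix, logmix = log_theta_mix[t]
            r_obs = train.counts[i].astype(float)
            mu = vp.mu_x[s, t, keep]
            sd = np.exp(vp.logsd_x[s, t, keep])
            x = mu + sd * rng.standard_normal((n_posterior_samples, len(keep)))
            logbeta = x - np.logaddexp.reduce(x, axis=1)[:, None]
            logpost = logbeta + (logmix @ r_obs)[None, :]
            logpost -= np.logaddexp.reduce(logpost, axis=1)[:, None]
            post = np.exp(logpost)
            zs = np.array([
                rng.choice(len(keep), p=post[n]) for n in range(n_posterior_samples)
            ])
            ds = [cosine_distance(target_counts[out_i], mix[z]) for z in zs]
            dists[out_i] = float(np.median(ds))
        return dists
    return runner
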