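"""Detect a perturbation response in a longitudinal particle study.

Simulates three subjects sampled at six time points with a perturbation
active at times 2-3.  One assemblage responds (its log-weight shifts by +2 at
onset and back at offset); the Bayes factor on the perturbation indicator
should flag exactly that assemblage, with BF > 10 read as strong evidence.
"""

import numpy as np

from mcspace import (Hyperparameters, InferenceConfig, StudyDesign,
                     SimulationConfig, default_baseline, simulate_timeseries,
                     fit, summarize_beta, perturbed_assemblages)

design = StudyDesign(timepoints=np.arange(6.0),
                     perturbations={"high_fat_diet": frozenset([2.0, 3.0])})
theta0, beta0 = default_baseline(K0=4, O=20, seed=3)

c = np.zeros((4, 1)); c[0, 0] = 1.0          # assemblage 0 responds
delta = np.zeros((4, 1)); delta[0, 0] = 2.0  # log-weight shift at onset

cfg = SimulationConfig(n_particles=200, read_depth=800, contamination=0.01,
                       seed=3)
m, truth = simulate_timeseries(theta0, beta0, design, cfg, sigma2_w=0.05,
                               c=c, delta=delta, n_subjects=3)
print("simulated proportions of the responding assemblage (subject 0):",
      truth.beta[0, :, 0].round(3))

vp = fit(m, design, Hyperparameters(K=10),
         InferenceConfig(epochs=2000, n_restarts=1, seed=3))
ens = summarize_beta(vp, seed=0)

hits = perturbed_assemblages(ens, bf_threshold=10.0)
print(f"\n{vp.n_active()} assemblages retained; "
      f"{len(hits)} flagged as perturbed (BF > 10):")
for k, pert, bf in hits:
    print(f"  assemblage {k} responds to {pert}: Bayes factor {bf:.0f}")
print("\nA Bayes factor above 10 means the posterior odds of a perturbation")
print("effect are more than tenfold the sparse prior odds.")
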