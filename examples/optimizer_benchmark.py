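"""The aging-leader particle swarm on two standard test functions.

Sphere (unimodal) shows convergence depth; Rastrigin (deceptive, multimodal)
shows that leader aging does not trade away the plain swarm's performance —
the challenger mechanism only fires when the leader stagnates.
"""

import numpy as np

from lipidsites.alcpso import PsoConfig, optimize, optimize_plain


def sphere(X):
    return -np.sum(X**2, axis=1)


def rastrigin(X):
    return -(10 * X.shape[1] + np.sum(X**2 - 10 * np.cos(2 * np.pi * X), axis=1))


res = optimize(sphere, 5, [(-5, 5)] * 5, PsoConfig(seed=0, max_iterations=500))
print(f"sphere d=5: best fitness {res.fitness:.3e} "
      f"after {res.n_evaluations} evaluations (optimum 0)")

bounds = [(-5.12, 5.12)] * 5
alc, plain = [], []
for seed in range(20):
    cfg = PsoConfig(seed=seed, max_iterations=150, stagnation_limit=None)
    alc.append(optimize(rastrigin, 5, bounds, cfg).fitness)
    plain.append(optimize_plain(rastrigin, 5, bounds, cfg).fitness)
print(f"rastrigin d=5, median over 20 seeds: "
      f"aging leader {np.median(alc):.2f} vs plain PSO {np.median(plain):.2f} "
      f"(0 is optimal; less negative is better)")
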