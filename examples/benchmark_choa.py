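"""Minimize the 5-D sphere function with the chimp optimizer.

Prints the best value found and a few points of the best-so-far trace;
the trace is non-increasing because the four leader roles keep the best
solutions ever evaluated.  A uniform random search at the same
evaluation budget gives a sense of how much the swarm structure helps.
"""

import numpy as np

import coat2fcm as c2

sphere = lambda x: float((x**2).sum())

params = c2.ChoaParams(bounds=[(-10.0, 10.0)] * 5, pop_size=20, iterations=100, seed=0)
best, best_fit, trace = c2.choa_optimize(sphere, params)

print(f"ChOA best fitness: {best_fit:.3e} at {np.round(best, 4)}")
print("best-so-far trace (iterations 0, 25, 50, 75, 100):",
      [f"{trace[t]:.3e}" for t in (0, 25, 50, 75, 100)])

rng = np.random.default_rng(12345)
pts = rng.uniform(-10, 10, size=(20 * 101, 5))
print(f"random search at equal budget: {(pts**2).sum(axis=1).min():.3e}")
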