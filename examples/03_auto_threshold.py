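"""Self-tune the threshold with the stability objective + simulated annealing.

The objective L compares the segmentation at t_h against t_h + 1: it is
~1 per stable cluster and explodes when contours flicker between the two,
so its minimum valley sits where the border locks onto the dark halo.
Three different starting points land on the same λ*.
"""

import numpy as np

import gcvol as g

stack, truth = g.make_phantom(g.single_gc_spec((12, 64, 64), noise_sigma=5.0, seed=3))
ev = g.ObjectiveEvaluator(stack, s_floor=20)

# landscape cut: one flat valley walled by instability spikes
df = g.sweep_threshold(stack, s_min=100, t_range=(60, 220), evaluator=ev)
finite = df[np.isfinite(df.objective)]
best = finite.loc[finite.objective.idxmin()]
print(f"sweep: min L = {best.objective:.6f} at t_h = {int(best.t_h)}, "
      f"max L = {finite.objective.max():.3g} (instability wall)")

for i, (th0, s0) in enumerate([(120, 50), (150, 200), (185, 400)]):
    params, state = g.optimize(stack, g.SegmentationParams(th0, s0), rng_seed=10 + i,
                               s_bounds=(20, 20000), evaluator=ev)
    print(f"init (t_h={th0}, s_min={s0}) -> λ* = ({params.t_h}, {params.s_min}), "
          f"L* = {state.best_value:.6f}, {state.n_evaluations} evaluations")

params, _ = g.optimize(stack, g.SegmentationParams(150, 100), rng_seed=0,
                       s_bounds=(20, 20000), evaluator=ev)
seg = np.zeros(stack.shape, bool)
for c in g.segment(stack, params):
    seg[c.coords[:, 0], c.coords[:, 1], c.coords[:, 2]] = True
tm = truth.mask()
dice = 2 * (seg & tm).sum() / (seg.sum() + tm.sum())
print(f"Dice against ground truth at λ*: {dice:.4f}")
# Dice ~1.0 means the tuned threshold recovers the GC exactly despite noise.
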