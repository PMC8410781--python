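"""Control scaling across random network ensembles.

Samples small p-K truth-table networks and signed threshold networks,
computes the first-order control-kernel approximation |CK1| = m + |w1|
(input nodes plus minimal distinguishing nodes), and checks it against the
logarithmic benchmarks: <|CK1|> is typically near log2 r and provably
bounded by 2 log2 r when the per-group witness bound holds.  Zero-threshold
networks biased toward activation can harbor 'repellor' fixed points
(basin size 1) whose kernels are much larger.
"""

import math

import boolck as bk

print("kind       n  seed   r   m   <|CK1|>  log2 r  2log2 r")
for kind in ("pK", "zero", "balanced"):
    for seed in range(4):
        n = 10
        if kind == "pK":
            net = bk.generate_pk(n, 2, 0.5, seed=seed)
        else:
            net = bk.generate_threshold(n, 3, 0.5, kind, seed=seed)
        aset = bk.find_attractors_exhaustive(net)
        if aset.r < 2:
            continue
        _, mean_ck1 = bk.first_order_approx(net, aset)
        if mean_ck1 is None:
            continue
        ent = bk.input_entropy_bounds(net, aset)
        print(f"{kind:9s} {n:3d} {seed:4d} {aset.r:4d} {ent['m']:3d}"
              f"   {mean_ck1:6.2f}  {math.log2(aset.r):6.2f}"
              f"  {2 * math.log2(aset.r):6.2f}")

# repellors: biased (mostly excitatory) zero-threshold networks keep the
# all-OFF fixed point, often with a basin of exactly one state
print("\nbiased zero-threshold networks (p_I = 0.1):")
for seed in range(4):
    net = bk.generate_threshold(10, 4, 0.1, "zero", seed=seed)
    aset = bk.find_attractors_exhaustive(net)
    reps = bk.repellors(aset)
    print(f"  seed {seed}: r={aset.r:3d}, repellor fixed points: {len(reps)}")

# the random-map heuristic behind small attractor counts: a uniformly random
# transition table has 1 fixed point on average, independent of size
sim = bk.random_map_fixed_points(10, 10_000, seed=0)
print(f"\nrandom maps on 2^10 states: mean fixed points = {sim['mean']:.3f}"
      f" +- {sim['se']:.3f} (expected 1)")
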