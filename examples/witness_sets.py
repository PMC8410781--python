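"""Witness sets: typical logarithmic scaling and the projective-plane exception.

A witness set for a binary vector within a family is a set of coordinates
that distinguishes it from every other member.  For random families the mean
minimal witness size stays below log2 r.  The incidence rows of a finite
projective plane plus the identity rows form the classic exception: their
mean grows like sqrt(r), overtaking log2 r at plane order p = 17 (r = 614).
"""

import math

import boolck as bk

# random families: mean minimal witness vs log2 r
print("random families (n=12):")
for r in (4, 16, 64):
    means = []
    for seed in range(10):
        fam = bk.random_vector_family(12, r, seed=seed)
        means.append(bk.mean_min_witness(fam))
    print(f"  r={r:3d}: <|w|> = {sum(means)/len(means):.2f}  "
          f"(log2 r = {math.log2(r):.2f})")

# the order-2 projective plane family: 7 lines + 7 points, r = 14
fam = bk.pp_vector_family(2)
results = bk.minimal_witnesses(fam)
print(f"\norder-2 projective plane family: r={fam.r}, n={fam.n}")
print(f"  line witness sizes:  {sorted({x.size for x in results[:7]})}")
print(f"  point witness sizes: {sorted({x.size for x in results[7:]})}")
print(f"  mean = {bk.mean_min_witness(fam):.1f} = (p+4)/2, "
      f"teaching dimension = {bk.teaching_dimension(fam)}")

# where the construction overtakes log2 r
p, r, n = bk.first_prime_exceeding_log()
print(f"\nfirst prime order beating log2 r: p={p} (r={r} vectors, n={n})")
print(f"real-valued crossing of (p+4)/2 over log2 r: r = "
      f"{bk.real_valued_crossing()}")

# single bit flips do not rescue logarithmic scaling at small order
new, delta, _ = bk.bitflip_perturbation(fam, 0, 0)
print(f"\nflipping one bit of one line vector: mean {new:.3f} "
      f"(change {delta:+.3f})")
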