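# boolck — attractors, control kernels and witness sets of Boolean networks

`boolck` analyzes the *static controllability* of synchronous Boolean
dynamical networks — the workhorse models of gene regulatory logic.  It is
written for systems biologists and complex-systems researchers who want to
ask, for a given Boolean model: how many genes must be forced (pinned to
constant values) so that the network ends up in one chosen attractor no
matter where it starts?

## The model

A Boolean network has `n` nodes with states `x_i(t) ∈ {0, 1}` updated
synchronously:

    x_i(t+1) = f_i(x_1(t), …, x_n(t)),   i = 1…n.

Trajectories on the finite state space converge to **attractors**: fixed
points or cycles.  Pinning `p` nodes (node-state override) maps the system
to an `(n−p)`-node system.  A **control kernel** (CK) of an attractor `A`
is a minimal node set whose pinning to `A`'s values makes `A`'s basin the
entire configuration space.  The package decomposes each CK into three
parts,

    m + |w⁽¹⁾|  ≤  |CK|  ≤  m + Σᵢ |w⁽ⁱ⁾| ,

where `m` counts **input nodes** (identity update rules — every CK must
contain them), `w⁽¹⁾` is a minimal **distinguishing set** separating `A`
from the other attractors once inputs are pinned (a minimum *witness set*
problem over the attractor profiles, NP-hard), and later rounds `w⁽ⁱ⁾`
remove attractors newly created by earlier pinning.  Neglecting those
additional nodes gives the first-order approximation
`|CK⁽¹⁾| = m + |w⁽¹⁾|`, which is bounded by `log₂ r + (m − μ) ≤ 2 log₂ r`
(`r` attractors, input entropy `μ`) — the mechanism behind the empirical
observation that mean CK size tracks `log₂ r`.

The toolkit provides:

* exhaustive, **modular** (SCC-by-SCC with gcd/lcm phase composition), and
  sampled attractor search with basins;
* exact CK search over distinguishing sets of increasing size, cyclic-
  attractor controllability screening, iterative pinning bounds, union CKs;
* minimal **witness sets** / teaching dimension by hitting-set enumeration
  with greedy fallback, including the cycle rules for attractor families;
* random ensembles (p–K truth-table networks, signed threshold networks on
  directed Erdős–Rényi graphs), random vector families, random-map
  fixed-point simulation, and the finite **projective plane** family — the
  known construction whose mean witness size `(p+4)/2 ~ √r` eventually
  beats `log₂ r`;
* a `boolck` CLI (`attractors`, `ck`, `bound`, `witness`, `ensemble`,
  `pplane`, `scaling`, `plan`, `fixtures`) over BoolNet-style rule files.

## Worked example

```python
import boolck as bk

net = bk.parse_network("G, G\nX, G & !Y\nY, G & X\n")
aset = bk.find_attractors_exhaustive(net)
for a in aset.attractors:
    res = bk.find_control_kernel(net, a, aset)
    print(a.states, res.ck, res.size, res.m, res.w1_size)
```

prints

```
(0,) ('G',) 1 1 0
(1, 3, 7, 5) ('G',) 1 1 0
```

The gate `G` is an input node driving a 2-gene oscillator: the network has
one fixed point (everything OFF, basin 4/8) and one 4-cycle (basin 4/8).
Both control kernels are `{G}` with size 1 = `m + |w¹|` = 1 + 0: pinning
the single input decides the fate, and `log₂ r = log₂ 2 = 1` — logarithmic
control in miniature.  The scripts in `examples/` walk through modular
decomposition, witness scaling versus `log₂ r`, the projective-plane
exception (lines need 2 pins, points need `p+2`, mean `(p+4)/2`), and
ensemble studies with repellor fixed points.

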