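"""Attractor detection for synchronous Boolean networks.

Deterministic synchronous dynamics on a finite state space always converge to
a fixed state or a cycle of states.  This module finds those attractors and
their basins either exhaustively (every state visited once, memoized
trajectory walking) or by sampling random initial states.

Attractor identity is the set of states in the cycle: cycles are stored in a
canonical rotation starting at the minimal integer-encoded state, so equality
is rotation-invariant and phase is never part of identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import BooleanNetwork, state_to_bits

__all__ = [
    "Attractor",
    "AttractorSet",
    "find_attractors_exhaustive",
    "find_attractors_sampled",
    "repellors",
    "canonical_cycle",
    "restrict_cycle",
]


def canonical_cycle(states) -> tuple[int, ...]:
    """Rotate a cycle of distinct states to start at the minimal one."""
    states = tuple(int(s) for s in states)
    k = states.index(min(states))
    return states[k:] + states[:k]


def _minimal_period(seq: tuple[int, ...]) -> tuple[int, ...]:
    L = len(seq)
    for d in range(1, L + 1):
        if L % d == 0 and all(seq[t] == seq[t % d] for t in range(L)):
            return seq[:d]
    return seq  # pragma: no cover


def restrict_cycle(states, keep: list[int]) -> tuple[int, ...]:
    """Project a cycle onto the node indices in ``keep`` (re-encoded with
    ``keep[0]`` as bit 0) and reduce to its minimal period, canonicalized.

    Valid whenever the kept coordinates form a dynamically closed subsystem
    (e.g. the unpinned nodes of a pinned network), in which case the
    projection is itself a deterministic cycle.
    """
    proj = []
    for s in states:
        v = 0
        for b, j in enumerate(keep):
            v |= ((int(s) >> j) & 1) << b
        proj.append(v)
    reduced = _minimal_period(tuple(proj))
    if len(set(reduced)) != len(reduced):
        raise ValueError("projection is not deterministic on these coordinates")
    return canonical_cycle(reduced)


@dataclass(frozen=True)
class Attractor:
    """A fixed state (length-1 cycle) or cycle of states, canonicalized."""

    states: tuple[int, ...]
    basin_size: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "states", canonical_cycle(self.states))

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def constant_profile(self, n: int) -> tuple[int, int]:
        """(mask, values): bit i of mask set iff node i is constant over the
        cycle; for constant nodes the bit of ``values`` is that value."""
        ones = self.states[0]
        zeros = ~self.states[0]
        for s in self.states[1:]:
            ones &= s
            zeros &= ~s
        full = (1 << n) - 1
        mask = (ones | zeros) & full
        return mask, ones & full

    def constant_nodes(self, n: int) -> dict[int, int]:
        """Node index -> fixed value, for nodes constant across the cycle."""
        mask, values = self.constant_profile(n)
        return {i: (values >> i) & 1 for i in range(n) if (mask >> i) & 1}

    def key(self) -> tuple[int, ...]:
        return self.states


@dataclass
class AttractorSet:
    """The attractors of one network, with search-mode metadata.

    ``mode`` is ``exhaustive`` (basins exact, summing to 2^n), ``modular``
    (attractor list exact, basins absent) or ``sampled`` (attractors are a
    subset; basin sizes are sampled counts over ``n_samples`` trajectories).
    """

    attractors: list[Attractor]
    n: int
    mode: str
    n_samples: int | None = None
    seed: int | None = None
    node_names: list[str] | None = None
    #: sampled mode only: the exact initial states used, kept so that pinned
    #: re-tests can reuse the same sample (projected onto unpinned nodes).
    initial_states: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.attractors = sorted(self.attractors, key=lambda a: a.states)

    @property
    def r(self) -> int:
        return len(self.attractors)

    def keys(self) -> set[tuple[int, ...]]:
        return {a.states for a in self.attractors}

    def to_json_obj(self) -> dict:
        names = self.node_names
        return {
            "n": self.n,
            "mode": self.mode,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "nodes": names,
            "attractors": [
                {
                    "states": ["".join(map(str, state_to_bits(s, self.n)))
                               for s in a.states],
                    "length": a.length,
                    "basin_size": a.basin_size,
                }
                for a in self.attractors
            ],
        }


def find_attractors_exhaustive(net: BooleanNetwork, cap: int = 22) -> AttractorSet:
    """All attractors and exact basin sizes by full state-space traversal.

    Every state is visited once: trajectories are walked with memoization and
    each state is labeled with the attractor its trajectory reaches.  Basin
    sizes therefore sum to 2^n.  Raises for n > cap (use the modular or
    sampled finders instead).
    """
    if net.n == 0:
        return AttractorSet([Attractor((0,), basin_size=1)], 0, "exhaustive",
                            node_names=list(net.node_names))
    succ = net.successor_table(cap=cap)
    size = 1 << net.n
    label = np.full(size, -1, dtype=np.int64)
    cycles: list[tuple[int, ...]] = []
    for s0 in range(size):
        if label[s0] != -1:
            continue
        path = []
        on_path = {}
        cur = s0
        while label[cur] == -1 and cur not in on_path:
            on_path[cur] = len(path)
            path.append(cur)
            cur = int(succ[cur])
        if label[cur] != -1:
            aid = label[cur]
        else:
            cycle = tuple(path[on_path[cur]:])
            aid = len(cycles)
            cycles.append(cycle)
        for x in path:
            label[x] = aid
    basins = np.bincount(label, minlength=len(cycles))
    attrs = [Attractor(c, basin_size=int(basins[i])) for i, c in enumerate(cycles)]
    return AttractorSet(attrs, net.n, "exhaustive", node_names=list(net.node_names))


def _walk_to_cycle(net: BooleanNetwork, start: int, memo: dict[int, int],
                   cycles: list[tuple[int, ...]]) -> int:
    """Walk one trajectory until a revisit; returns the attractor id."""
    path = []
    on_path = {}
    cur = start
    while cur not in memo and cur not in on_path:
        on_path[cur] = len(path)
        path.append(cur)
        cur = net.step(cur)
    if cur in memo:
        aid = memo[cur]
    else:
        cycle = canonical_cycle(path[on_path[cur]:])
        aid = None
        for i, c in enumerate(cycles):
            if c == cycle:
                aid = i
                break
        if aid is None:
            aid = len(cycles)
            cycles.append(cycle)
    for x in path:
        memo[x] = aid
    return aid


def find_attractors_sampled(net: BooleanNetwork, n_samples: int, seed: int,
                            initial_states=None) -> AttractorSet:
    """Attractors reached from ``n_samples`` uniformly random initial states.

    Deterministic given the seed.  Initial states are drawn with replacement;
    each trajectory is iterated until a state repeats (at most 2^n steps).
    Basin sizes are the sampled trajectory counts, summing to ``n_samples``.
    ``initial_states`` overrides the draw (used to re-test pinned dynamics on
    the same sample).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if initial_states is None:
        rng = np.random.default_rng(seed)
        initial_states = sample_states(rng, net.n, n_samples)
    memo: dict[int, int] = {}
    cycles: list[tuple[int, ...]] = []
    counts: dict[int, int] = {}
    for s0 in initial_states:
        aid = _walk_to_cycle(net, int(s0), memo, cycles)
        counts[aid] = counts.get(aid, 0) + 1
    attrs = [Attractor(c, basin_size=counts.get(i, 0)) for i, c in enumerate(cycles)]
    return AttractorSet(attrs, net.n, "sampled", n_samples=n_samples, seed=seed,
                        node_names=list(net.node_names),
                        initial_states=np.asarray(initial_states, dtype=np.int64))


def sample_states(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    """Uniform states with replacement; supports n > 63 bit-safely for n<=62."""
    if n > 62:
        raise ValueError("sampling supports n <= 62")
    return rng.integers(0, 1 << max(n, 1), size=count, dtype=np.int64) \
        if n > 0 else np.zeros(count, dtype=np.int64)


def repellors(aset: AttractorSet) -> list[Attractor]:
    """Fixed points whose basin is exactly their own state (size 1).

    Such 'repellor' fixed points are unstable in the sense that every
    perturbation leads away; they drive the large-control-kernel outliers in
    activation-biased threshold ensembles.  Requires exact basins.
    """
    if aset.mode != "exhaustive":
        raise ValueError("repellor detection requires exhaustive basin sizes")
    return [a for a in aset.attractors if a.is_fixed_point and a.basin_size == 1]
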