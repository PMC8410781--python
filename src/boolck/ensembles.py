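"""Random ensembles and constructions used to probe logarithmic control.

Generators for:

* p-K random Boolean networks: every node reads K randomly chosen nodes and
  each truth-table output bit is 1 with probability ``p_on``;
* random threshold networks on a directed Erdos-Renyi graph: each node
  compares the signed sum of its inputs s_i = sum_j A_ij x_j to a threshold,
  keeping its state on a tie (zero thresholds, or "balanced" thresholds set
  to half the summed signed in-edges);
* random families of distinct binary vectors (witness-set experiments);
* the finite projective plane of prime order p (q = p^2 + p + 1 points and
  lines) and the 2q-vector family of incidence rows plus identity rows —
  the known counterexample to logarithmic witness scaling, with mean minimal
  witness size (p + 4)/2;
* uniformly random transition maps, whose expected number of fixed points
  is 1 regardless of size.

All stochastic generators require an explicit seed and are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork
from .witness import VectorFamily, mean_min_witness

__all__ = [
    "generate_pk",
    "generate_threshold",
    "random_vector_family",
    "ProjectivePlane",
    "projective_plane",
    "pp_vector_family",
    "pp_mean_witness_closed_form",
    "first_prime_exceeding_log",
    "real_valued_crossing",
    "bitflip_perturbation",
    "random_map_fixed_points",
    "is_prime",
]


def generate_pk(n: int, K: int, p_on: float, seed: int) -> BooleanNetwork:
    """A p-K (Kauffman NK-style) random network.

    Each node reads ``K`` distinct nodes sampled uniformly (self-input
    permitted); each of its 2^K truth-table outputs is 1 independently with
    probability ``p_on``.  Deterministic given the seed.
    """
    if not 0 <= p_on <= 1:
        raise ValueError("p_on must lie in [0, 1]")
    if not 1 <= K <= n:
        raise ValueError("need 1 <= K <= n")
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n)]
    rules = []
    for _ in range(n):
        inputs = sorted(rng.choice(n, size=K, replace=False).tolist())
        bits = (rng.random(1 << K) < p_on).astype(np.uint8)
        rules.append(([names[j] for j in inputs], bits))
    return BooleanNetwork(names, rules)


def generate_threshold(n: int, d: float, p_I: float, mode: str,
                       seed: int) -> BooleanNetwork:
    """A random threshold network on a directed Erdos-Renyi graph.

    Each ordered pair (j -> i, i != j) carries an edge independently with
    probability d/(n-1) (expected in-degree d); each edge is inhibitory (-1)
    with probability ``p_I``, else excitatory (+1).  The update compares
    s_i = sum_j A_ij x_j(t) against the threshold: below -> 0, above -> 1,
    tie -> keep x_i(t).  ``mode='zero'`` sets every threshold to 0 (the
    all-OFF state is then a fixed point); ``mode='balanced'`` sets
    tau_i = (1/2) sum_j A_ij, compared exactly (2 s_i vs the integer sum).
    Nodes with no incoming edges always tie and are therefore input nodes.
    """
    if mode not in ("zero", "balanced"):
        raise ValueError("mode must be 'zero' or 'balanced'")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    names = [f"x{i}" for i in range(n)]
    rules = []
    adjacency: dict[tuple[int, int], int] = {}
    prob = d / (n - 1)
    for i in range(n):
        in_nodes = [j for j in range(n) if j != i and rng.random() < prob]
        signs = [(-1 if rng.random() < p_I else 1) for _ in in_nodes]
        for j, sg in zip(in_nodes, signs):
            adjacency[(j, i)] = sg
        # self is an input because a tie keeps the current state
        inputs = sorted(set(in_nodes) | {i})
        sign_of = dict(zip(in_nodes, signs))
        k = len(inputs)
        bits = np.zeros(1 << k, dtype=np.uint8)
        twice_tau = 0 if mode == "zero" else sum(signs)
        for idx in range(1 << k):
            s = sum(sign_of[j] * ((idx >> b) & 1)
                    for b, j in enumerate(inputs) if j in sign_of)
            xi = (idx >> inputs.index(i)) & 1
            if 2 * s > twice_tau:
                bits[idx] = 1
            elif 2 * s == twice_tau:
                bits[idx] = xi
        rules.append(([names[j] for j in inputs], bits))
    net = BooleanNetwork(names, rules)
    net.meta = {"adjacency": adjacency, "mode": mode, "d": d, "p_I": p_I,
                "seed": seed}
    return net


def random_vector_family(n: int, r: int, seed: int) -> VectorFamily:
    """r distinct binary n-tuples drawn uniformly without replacement."""
    if r > (1 << n):
        raise ValueError(f"cannot draw {r} distinct tuples of length {n}")
    rng = np.random.default_rng(seed)
    if n <= 30:
        codes = rng.choice(1 << n, size=r, replace=False)
        vectors = [[(int(c) >> b) & 1 for b in range(n)] for c in codes]
    else:  # rejection sampling for long tuples
        seen, vectors = set(), []
        while len(vectors) < r:
            v = tuple(rng.integers(0, 2, size=n).tolist())
            if v not in seen:
                seen.add(v)
                vectors.append(list(v))
    return VectorFamily.from_vectors(vectors)


def is_prime(p: int) -> bool:
    """Deterministic trial division (intended for small orders)."""
    if p < 2:
        return False
    for d in range(2, int(math.isqrt(p)) + 1):
        if p % d == 0:
            return False
    return True


@dataclass(frozen=True)
class ProjectivePlane:
    """Finite projective plane of prime order p over GF(p).

    q = p^2 + p + 1 points and q lines; ``incidence[l, pt] == 1`` iff point
    ``pt`` lies on line ``l``.  The four axioms (two points determine one
    line, two lines one point, p+1 points per line, p+1 lines per point) are
    verified at construction.
    """

    order: int
    q: int
    incidence: np.ndarray

    def __post_init__(self):
        inc = self.incidence
        p, q = self.order, self.q
        if inc.shape != (q, q):
            raise ValueError("incidence matrix must be q x q")
        if not (inc.sum(axis=1) == p + 1).all():
            raise ValueError("axiom violated: lines must contain p+1 points")
        if not (inc.sum(axis=0) == p + 1).all():
            raise ValueError("axiom violated: points must lie on p+1 lines")
        expected = np.ones((q, q), dtype=np.int64)
        np.fill_diagonal(expected, p + 1)
        if not np.array_equal(inc @ inc.T, expected):
            raise ValueError("axiom violated: two lines share exactly one point")
        if not np.array_equal(inc.T @ inc, expected):
            raise ValueError("axiom violated: two points lie on exactly one line")


def projective_plane(p: int) -> ProjectivePlane:
    """Construct the projective plane of prime order p.

    Points and lines are projective classes of nonzero triples over GF(p)
    (normalized so the first nonzero coordinate is 1); incidence is a zero
    dot product mod p.
    """
    if not is_prime(p):
        raise ValueError(f"order must be prime, got {p}")
    classes = []
    seen = set()
    for triple in itertools.product(range(p), repeat=3):
        if triple == (0, 0, 0) or triple in seen:
            continue
        lead = next(v for v in triple if v)
        inv = pow(lead, p - 2, p) if p > 2 else lead  # lead^-1 mod p
        norm = tuple((v * inv) % p for v in triple)
        if norm in seen:
            continue
        seen.add(norm)
        # mark the whole class as seen
        for lam in range(1, p):
            seen.add(tuple((v * lam) % p for v in norm))
        classes.append(norm)
    q = p * p + p + 1
    assert len(classes) == q
    inc = np.zeros((q, q), dtype=np.int64)
    for li, line in enumerate(classes):
        for pi, pt in enumerate(classes):
            if sum(a * b for a, b in zip(line, pt)) % p == 0:
                inc[li, pi] = 1
    return ProjectivePlane(p, q, inc)


def pp_vector_family(p: int) -> VectorFamily:
    """The 2q-vector witness family of the order-p plane: the q incidence
    rows (line vectors) followed by the q identity rows (point vectors)."""
    plane = projective_plane(p)
    vectors = [row.tolist() for row in plane.incidence]
    vectors += [row.tolist() for row in np.eye(plane.q, dtype=np.int64)]
    return VectorFamily.from_vectors(vectors)


def pp_mean_witness_closed_form(p: int) -> float:
    """Closed-form mean minimal witness size of the order-p plane family:
    lines need 2 coordinates, points need p+2, so the mean is (p+4)/2."""
    return (p + 4) / 2


def first_prime_exceeding_log(p_max: int = 1000) -> tuple[int, int, int]:
    """First prime order whose plane family beats logarithmic scaling.

    Scans primes in increasing order and returns ``(p, r, n)`` for the first
    with (p+4)/2 > log2(2 q), where q = p^2 + p + 1, r = 2q vectors of
    length n = q.
    """
    for p in range(2, p_max + 1):
        if not is_prime(p):
            continue
        q = p * p + p + 1
        if (p + 4) / 2 > math.log2(2 * q):
            return p, 2 * q, q
    raise ValueError(f"no exceedance found for primes up to {p_max}")


def real_valued_crossing(r_max: int = 100_000) -> int:
    """Smallest integer r >= 6 where the real-valued extension of the plane
    mean, (p+4)/2 with p = (sqrt(2r-3)-1)/2, strictly exceeds log2 r."""
    for r in range(6, r_max + 1):
        p = (math.sqrt(2 * r - 3) - 1) / 2
        if (p + 4) / 2 > math.log2(r):
            return r
    raise ValueError(f"no crossing found for r up to {r_max}")


def bitflip_perturbation(fam: VectorFamily, vector_index: int,
                         coordinate: int) -> tuple[float, float, VectorFamily]:
    """Recompute the exact mean minimal witness size after one bit flip.

    Returns ``(new_mean, delta, perturbed_family)``; flipping a bit that
    creates a duplicate tuple raises (families must stay distinct).
    """
    vectors = [list(m.values) for m in fam.members]
    if not all(all(m.constant) for m in fam.members):
        raise ValueError("bit-flip perturbation applies to plain vector families")
    vectors[vector_index][coordinate] ^= 1
    perturbed = VectorFamily.from_vectors(vectors)
    old = mean_min_witness(fam)
    new = mean_min_witness(perturbed)
    return new, new - old, perturbed


def random_map_fixed_points(n_prime: int, replicates: int,
                            seed: int) -> dict[str, float]:
    """Monte Carlo fixed-point count of uniformly random transition tables.

    Each replicate assigns every one of the 2^n' states a successor drawn
    uniformly at random; self-mapped states are counted.  For a uniformly
    random map the expected count is exactly 1 for any n'.  Returns mean,
    sd, standard error and a 3-SE interval.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    size = 1 << n_prime
    idx = np.arange(size, dtype=np.int64)
    counts = np.empty(replicates, dtype=np.int64)
    chunk = max(1, min(replicates, (1 << 24) // size))
    done = 0
    while done < replicates:
        b = min(chunk, replicates - done)
        succ = rng.integers(0, size, size=(b, size), dtype=np.int64)
        counts[done:done + b] = (succ == idx[None, :]).sum(axis=1)
        done += b
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if replicates > 1 else 0.0
    se = sd / math.sqrt(replicates) if replicates > 1 else 0.0
    return {"mean": mean, "sd": sd, "se": se,
            "ci_low": mean - 3 * se, "ci_high": mean + 3 * se,
            "replicates": replicates, "n_prime": n_prime}
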