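"""Control kernels of synchronous Boolean networks.

A control kernel (CK) of an attractor is a minimal set of nodes whose static
pinning to the attractor's values makes that attractor's basin the entire
configuration space.  The search here follows the efficient exact strategy of
checking only *distinguishing* node sets of increasing size (every CK must
contain all input nodes and one distinguishing set), re-solving the pinned
dynamics for each candidate.

The module also provides:

* the iterative pinning bound  m + |w1| <= |CK| <= m + sum_i |w_i|, obtained
  by repeatedly pinning minimal distinguishing sets of the attractors that
  remain after earlier rounds (round zero pins the input nodes);
* the first-order approximation |CK1| = m + |w1|, which ignores the
  additional rounds;
* the input entropy mu of the distribution of attractors over input
  configurations, and the resulting bounds <|w1|> and <|CK1|> <= log2 r +
  (m - mu) <= 2 log2 r;
* union CKs and per-network scaling summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attractors import (Attractor, AttractorSet, find_attractors_exhaustive,
                         find_attractors_sampled, repellors, restrict_cycle,
                         sample_states)
from .network import BooleanNetwork, pin_nodes
from .witness import (FamilyMember, VectorFamily, all_minimal_witnesses,
                      minimal_witness)

__all__ = [
    "ControlKernelResult",
    "find_control_kernel",
    "controllable_cycle_check",
    "iterative_bound",
    "first_order_approx",
    "input_entropy_bounds",
    "union_ck",
    "network_summary",
    "scaling_summary",
]

DEFAULT_PIN_TEST_BUDGET = 1_000_000
DEFAULT_ROUND_CAP = 50


@dataclass(frozen=True)
class ControlKernelResult:
    """CK search outcome for one target attractor.

    ``status`` is ``exact`` (minimal CK found), ``bound_only`` (budget or
    round cap hit; only the iterative bounds are reported) or
    ``not_statically_controllable`` (cyclic target with no static CK).
    The decomposition splits the CK size into input nodes (m), minimal
    distinguishing nodes (|w1|) and additional nodes pinned in later rounds.
    """

    target: tuple[int, ...]
    ck: tuple[str, ...] | None
    size: int | None
    m: int
    w1_size: int | None
    additional: int | None
    lower: int | None
    upper: int | None
    status: str
    rounds: tuple = ()

    @property
    def controllable(self) -> bool:
        return self.status == "exact"


def _input_indices(net: BooleanNetwork) -> list[int]:
    return [i for i in range(net.n) if net.is_identity_rule(i)]


def _project_states(states: np.ndarray, kept: list[int]) -> np.ndarray:
    out = np.zeros_like(states)
    for b, j in enumerate(kept):
        out |= ((states >> j) & 1) << b
    return out


def _pinned_attractor_set(net: BooleanNetwork, pin_names: dict[str, int],
                          aset: AttractorSet) -> tuple[AttractorSet, list[int]]:
    """Attractors of the pinned network, in the same search mode as ``aset``.

    In sampled mode the *same* random initial states are reused, projected
    onto the unpinned nodes, so sampled CK statements are exact relative to
    the sampled attractor set.
    """
    pinned_idx = {net.index(nm) for nm in pin_names}
    kept = [i for i in range(net.n) if i not in pinned_idx]
    sub = pin_nodes(net, pin_names)
    if aset.mode == "sampled":
        if aset.initial_states is not None:
            full = np.asarray(aset.initial_states, dtype=np.int64)
        else:
            rng = np.random.default_rng(aset.seed)
            full = sample_states(rng, net.n, aset.n_samples)
        init = _project_states(full, kept)
        pa = find_attractors_sampled(sub, aset.n_samples, aset.seed,
                                     initial_states=init)
    else:
        pa = find_attractors_exhaustive(sub)
    return pa, kept


def _single_attractor_equals(pa: AttractorSet, target_restricted) -> bool:
    return pa.r == 1 and pa.attractors[0].states == target_restricted


def controllable_cycle_check(net: BooleanNetwork, cycle: Attractor,
                             aset: AttractorSet) -> bool:
    """Static controllability screen for a cyclic attractor.

    Pins every node that is constant across the cycle (the most aggressive
    static pinning compatible with it); the cycle has a CK iff exactly one
    attractor remains.
    """
    if cycle.length <= 1:
        raise ValueError("check applies to cycles (length > 1)")
    const = cycle.constant_nodes(net.n)
    if not const:
        return aset.r == 1
    pins = {net.node_names[i]: v for i, v in const.items()}
    pa, kept = _pinned_attractor_set(net, pins, aset)
    return _single_attractor_equals(pa, restrict_cycle(cycle.states, kept))


def _target_position(aset: AttractorSet, target: Attractor) -> int:
    for i, a in enumerate(aset.attractors):
        if a.states == target.states:
            return i
    raise ValueError("target attractor is not in the attractor set")


def _w1_for_target(net: BooleanNetwork, aset: AttractorSet, target: Attractor,
                   budget: int):
    """Minimal distinguishing set after round-zero input pinning.

    The attractors of the input-pinned network are exactly the original
    attractors sharing the target's input configuration (input pinning never
    creates attractors), so w1 is computed directly on that group.  Input
    coordinates never enter the difference sets (the group shares them).
    """
    inputs = _input_indices(net)
    tconst = target.constant_nodes(net.n)
    conf = tuple(tconst[i] for i in inputs)
    group, pos = [], None
    for a in aset.attractors:
        aconst = a.constant_nodes(net.n)
        if tuple(aconst.get(i) for i in inputs) == conf:
            if a.states == target.states:
                pos = len(group)
            group.append(a)
    fam = VectorFamily.from_attractors(group, net.n)
    return minimal_witness(fam, pos, budget=budget), len(group)


def find_control_kernel(net: BooleanNetwork, target: Attractor,
                        aset: AttractorSet, *,
                        budget: int = DEFAULT_PIN_TEST_BUDGET,
                        witness_budget: int | None = None,
                        enumerate_all: bool = False):
    """Minimal control kernel for ``target`` by size-ordered search.

    Candidate sets contain all input nodes, are restricted to the target's
    constant nodes, must be distinguishing with respect to every other
    attractor (cycle rules included), and are tested by pinning them to the
    target's values and re-solving the attractors of the pinned network;
    success means a single attractor equal to the target's restriction.
    Enumeration is by size then lexicographically, so ties are deterministic.

    ``budget`` caps the number of pinned-dynamics evaluations; if hit, the
    iterative bound is returned with status ``bound_only``.  With
    ``enumerate_all`` a list of every minimal CK is returned instead.
    """
    if witness_budget is None:
        witness_budget = budget
    names = net.node_names
    inputs = _input_indices(net)
    m = len(inputs)
    _target_position(aset, target)
    w1_res, _ = _w1_for_target(net, aset, target, witness_budget)
    w1 = w1_res.size if w1_res.status == "exact" else None

    def _result(ck, size, status, lower=None, upper=None, rounds=()):
        add = None
        if size is not None and w1 is not None:
            add = size - m - w1
        lo = m + w1 if w1 is not None else (lower if lower is not None else m)
        return ControlKernelResult(
            target=target.states, ck=ck, size=size, m=m, w1_size=w1,
            additional=add, lower=lo, upper=upper if upper is not None else size,
            status=status, rounds=rounds)

    if target.length > 1 and not controllable_cycle_check(net, target, aset):
        res = _result(None, None, "not_statically_controllable")
        return [res] if enumerate_all else res
    if aset.r == 1:
        res = _result((), 0, "exact")
        return [res] if enumerate_all else res

    tconst = target.constant_nodes(net.n)
    pinnable = sorted(tconst)
    extras = [i for i in pinnable if i not in inputs]
    profiles = [FamilyMember.from_attractor(a, net.n) for a in aset.attractors]
    tprof = FamilyMember.from_attractor(target, net.n)
    masks = []
    for a, prof in zip(aset.attractors, profiles):
        if a.states == target.states:
            continue
        msk = 0
        for j in range(net.n):
            if tprof.constant[j] and (not prof.constant[j]
                                      or prof.values[j] != tprof.values[j]):
                msk |= 1 << j
        masks.append(msk)

    tests = 0
    found: list[ControlKernelResult] = []
    for k in range(len(extras) + 1):
        for combo in itertools.combinations(extras, k):
            smask = 0
            for c in combo:
                smask |= 1 << c
            for c in inputs:
                smask |= 1 << c
            if not all(mk & smask for mk in masks):
                continue  # not a distinguishing set
            tests += 1
            if tests > budget:
                lo, up, rounds, st = iterative_bound(net, target, aset)
                res = _result(None, None, "bound_only", lower=lo, upper=up,
                              rounds=rounds)
                return [res] if enumerate_all else res
            S = sorted(inputs + list(combo))
            pins = {names[i]: tconst[i] for i in S}
            pa, kept = _pinned_attractor_set(net, pins, aset)
            if _single_attractor_equals(pa, restrict_cycle(target.states, kept)):
                res = _result(tuple(names[i] for i in S), len(S), "exact")
                if not enumerate_all:
                    return res
                found.append(res)
        if found:
            return found
    # Unreachable for fixed points (pinning all nodes always controls); a
    # cycle that passed the screen is controlled by pinning all its constant
    # nodes, which is itself enumerated above.
    raise AssertionError("search exhausted without success")


def iterative_bound(net: BooleanNetwork, target: Attractor, aset: AttractorSet,
                    *, round_cap: int = DEFAULT_ROUND_CAP,
                    witness_budget: int = DEFAULT_PIN_TEST_BUDGET,
                    max_alternatives: int = 200):
    """Bounds on |CK| from iterative pinning of minimal distinguishing sets.

    Round zero pins the input nodes to the target's values.  Each later round
    computes the minimal distinguishing sets of the (restricted) target
    against all attractors currently present, pins the one that creates the
    fewest new attractors (ties broken lexicographically), and repeats until
    a single attractor remains or ``round_cap`` is hit.

    Returns ``(lower, upper, rounds, status)`` where ``rounds`` is a tuple of
    ``(pinned node names, size, attractors remaining after the round)`` and
    ``lower = m + |w1|``, ``upper = m + sum_i |w_i|``.
    """
    names = net.node_names
    inputs = _input_indices(net)
    m = len(inputs)
    tconst = target.constant_nodes(net.n)
    pins0 = {names[i]: tconst[i] for i in inputs}
    cur_net = pin_nodes(net, pins0) if pins0 else net
    if pins0:
        cur_aset, kept = _pinned_attractor_set(net, pins0, aset)
        cur_target = restrict_cycle(target.states, kept)
    else:
        cur_aset, cur_target = aset, target.states
    rounds = []
    status = "exact"
    for _ in range(round_cap):
        if _single_attractor_equals(cur_aset, cur_target):
            break
        keys = cur_aset.keys()
        attrs = list(cur_aset.attractors)
        if cur_target not in keys:  # possible only in sampled mode
            attrs.append(Attractor(cur_target, basin_size=0))
        fam = VectorFamily.from_attractors(attrs, cur_net.n)
        pos = next(i for i, a in enumerate(attrs) if a.states == cur_target)
        options = all_minimal_witnesses(fam, pos, budget=witness_budget)
        if options[0].status == "nonexistent":
            status = "not_statically_controllable"
            break
        if options[0].status == "upper_bound":
            status = "bound_only"
            options = options[:1]
        options = options[:max_alternatives]
        tprof = Attractor(cur_target).constant_nodes(cur_net.n)
        best = None
        for res in options:
            pins = {cur_net.node_names[c]: tprof[c] for c in res.witness}
            pa, kept = _pinned_attractor_set(cur_net, pins, cur_aset)
            prev_restricted = set()
            pinned_idx = {cur_net.index(nm) for nm in pins}
            for a in cur_aset.attractors:
                aconst = a.constant_nodes(cur_net.n)
                if all(aconst.get(i) == pins[cur_net.node_names[i]]
                       for i in pinned_idx):
                    prev_restricted.add(restrict_cycle(a.states, kept))
            n_new = len(pa.keys() - prev_restricted)
            if best is None or n_new < best[0]:
                best = (n_new, res, pa, kept, pins)
        n_new, res, pa, kept, pins = best
        rounds.append((tuple(sorted(pins)), res.size, pa.r))
        cur_target = restrict_cycle(cur_target, kept)
        cur_net = pin_nodes(cur_net, pins)
        cur_aset = pa
    else:
        status = "bound_only"
    if status == "not_statically_controllable":
        return None, None, tuple(rounds), status
    w1 = rounds[0][1] if rounds else 0
    lower = m + w1
    upper = m + sum(rnd[1] for rnd in rounds)
    return lower, upper, tuple(rounds), status


def first_order_approx(net: BooleanNetwork, aset: AttractorSet,
                       budget: int = DEFAULT_PIN_TEST_BUDGET):
    """Per-attractor and mean first-order CK size |CK1| = m + |w1|.

    For each attractor, w1 is the minimal distinguishing set computed after
    round-zero input pinning, i.e. against the attractors that share the
    target's input configuration.  Attractors whose w1 does not exist
    (uncontrollable cycles) are excluded from the mean.
    """
    m = len(_input_indices(net))
    per = []
    for a in aset.attractors:
        res, r_j = _w1_for_target(net, aset, a, budget)
        per.append({
            "target": a.states,
            "m": m,
            "r_j": r_j,
            "w1_size": res.size if res.exists else None,
            "ck1": m + res.size if res.exists else None,
            "status": res.status,
        })
    sizes = [p["ck1"] for p in per if p["ck1"] is not None]
    mean_ck1 = sum(sizes) / len(sizes) if sizes else None
    return per, mean_ck1


def input_entropy_bounds(net: BooleanNetwork, aset: AttractorSet) -> dict:
    """Input entropy mu and the resulting bounds on <|w1|> and <|CK1|>.

    Attractors are partitioned by their (constant) input-node values into
    counts r_j; mu = -sum (r_j/r) log2 (r_j/r).  Returns the evaluated
    bounds  <|w1|> <= x log2 x + x log2 r  with x = 1 - (2^m - 1)/r, and
    <|CK1|> <= log2 r + (m - mu).
    """
    inputs = _input_indices(net)
    m = len(inputs)
    r = aset.r
    counts: dict[tuple, int] = {}
    for a in aset.attractors:
        aconst = a.constant_nodes(net.n)
        conf = tuple(aconst[i] for i in inputs)
        counts[conf] = counts.get(conf, 0) + 1
    r_j = sorted(counts.values(), reverse=True)
    mu = -sum((c / r) * math.log2(c / r) for c in r_j if c)
    x = 1 - (2 ** m - 1) / r
    w1_bound = (x * math.log2(x) if x > 0 else 0.0) + x * math.log2(r)
    ck1_bound = math.log2(r) + (m - mu)
    return {"m": m, "r": r, "r_j": r_j, "mu": mu,
            "w1_bound": w1_bound, "ck1_bound": ck1_bound}


def union_ck(net: BooleanNetwork, aset: AttractorSet,
             results: list[ControlKernelResult] | None = None,
             budget: int = DEFAULT_PIN_TEST_BUDGET) -> set[str]:
    """Union of the per-attractor CKs found (no cross-attractor minimization).

    A single set of nodes containing a CK for every statically controllable
    attractor; comparable to a feedback vertex set in role.
    """
    if results is None:
        results = [find_control_kernel(net, a, aset, budget=budget)
                   for a in aset.attractors]
    out: set[str] = set()
    for res in results:
        if res.status == "exact" and res.ck:
            out.update(res.ck)
    return out


def network_summary(net: BooleanNetwork, aset: AttractorSet,
                    results: list[ControlKernelResult] | None = None,
                    budget: int = DEFAULT_PIN_TEST_BUDGET) -> dict:
    """Per-network scaling statistics over statically controllable attractors.

    Reports r, m, mean/sd of |CK|, mean |w1|, mean |CK1| (= m + mean |w1|
    identically), input entropy mu, uncontrollable-cycle count, repellor
    count (exhaustive mode), and flags for violations of the empirical
    bounds <|w1_j|> <= log2 r_j and <|CK1|> <= 2 log2 r.
    """
    if results is None:
        results = [find_control_kernel(net, a, aset, budget=budget)
                   for a in aset.attractors]
    ent = input_entropy_bounds(net, aset)
    per, mean_ck1 = first_order_approx(net, aset, budget)
    ck_sizes = [r.size for r in results if r.status == "exact"]
    w1_sizes = [p["w1_size"] for p in per if p["w1_size"] is not None]
    # Eq-4-style check per input configuration
    groups: dict[tuple, list[int]] = {}
    inputs = _input_indices(net)
    for a, p in zip(aset.attractors, per):
        conf = tuple(a.constant_nodes(net.n)[i] for i in inputs)
        if p["w1_size"] is not None:
            groups.setdefault(conf, []).append(p["w1_size"])
    eq4_violations = sum(
        1 for conf, sizes in groups.items()
        if sum(sizes) / len(sizes) > math.log2(max(len(sizes), 1)) + 1e-9
        and len(sizes) > 0)
    r = aset.r
    mean_w1 = sum(w1_sizes) / len(w1_sizes) if w1_sizes else None
    eq5_violation = (mean_ck1 is not None and r > 1
                     and mean_ck1 > 2 * math.log2(r) + 1e-9)
    n_rep = len(repellors(aset)) if aset.mode == "exhaustive" else None
    return {
        "n": net.n,
        "r": r,
        "m": ent["m"],
        "mu": ent["mu"],
        "mean_ck": float(np.mean(ck_sizes)) if ck_sizes else None,
        "sd_ck": float(np.std(ck_sizes)) if ck_sizes else None,
        "mean_w1": mean_w1,
        "mean_ck1": mean_ck1,
        "n_controllable": len(ck_sizes),
        "n_uncontrollable": sum(
            1 for x in results if x.status == "not_statically_controllable"),
        "n_bound_only": sum(1 for x in results if x.status == "bound_only"),
        "n_repellors": n_rep,
        "eq4_violations": eq4_violations,
        "eq5_violation": bool(eq5_violation),
    }


def scaling_summary(records: list[dict]) -> pd.DataFrame:
    """Assemble per-network summary dicts into a tidy table."""
    return pd.DataFrame.from_records(records)
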