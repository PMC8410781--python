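"""Modular attractor computation via hierarchical decomposition.

The causal (essential dependency) graph of a Boolean network decomposes into
strongly connected components; their condensation is a DAG of modules with
upstream modules feeding downstream ones.  Attractors of the whole network
can then be computed module-by-module: solve upstream modules first, and for
each consistent combination of upstream attractors solve the downstream
module's conditional dynamics by brute force with the upstream nodes clamped
to their (possibly time-varying) attractor values.

Two subtleties are handled by a single ``combine`` primitive over *partial
attractors* (cycles over a subset of nodes):

* combinations of upstream attractors that disagree on shared ancestor
  modules are inconsistent and dropped;
* combining cycles of lengths l1 and l2 over disjoint node sets yields
  gcd(l1, l2) distinct attractors of length lcm(l1, l2), one per phase-shift
  class — ``combine`` tries every relative shift and deduplicates.

Basin sizes are not computed in this mode.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx

from .attractors import Attractor, AttractorSet, canonical_cycle
from .network import BooleanNetwork, dependency_graph

__all__ = [
    "PartialAttractor",
    "ModuleDecomposition",
    "decompose",
    "combine",
    "compose_cycles",
    "consistent_upstream_combinations",
    "find_attractors_modular",
    "module_ck_nodes",
    "assemble_modular_ck",
]


@dataclass(frozen=True)
class PartialAttractor:
    """A cycle over a subset of nodes (given as sorted global indices).

    ``states`` are integer-encoded little-endian with respect to position in
    ``nodes`` (nodes[0] is bit 0), canonically rotated, minimal period.
    """

    nodes: tuple[int, ...]
    states: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.states)

    def value(self, node: int, t: int) -> int:
        b = self.nodes.index(node)
        return (self.states[t % self.length] >> b) & 1


_EMPTY = PartialAttractor((), (0,))


@dataclass(frozen=True)
class ModuleDecomposition:
    """SCC modules of the causal graph, with their acyclic condensation."""

    modules: tuple[tuple[int, ...], ...]  # node indices per module
    dag_edges: tuple[tuple[int, int], ...]  # upstream -> downstream module ids
    topo_order: tuple[int, ...]

    def parents(self, mid: int) -> list[int]:
        return sorted(u for u, v in self.dag_edges if v == mid)

    def sinks(self) -> list[int]:
        with_out = {u for u, _ in self.dag_edges}
        return sorted(m for m in range(len(self.modules)) if m not in with_out)


def decompose(net: BooleanNetwork) -> ModuleDecomposition:
    """SCC condensation of the essential dependency graph.

    Singleton nodes without self-dependence form their own (acyclic) modules.
    """
    g = dependency_graph(net)
    gi = nx.relabel_nodes(g, {nm: net.index(nm) for nm in g.nodes})
    cond = nx.condensation(gi)
    order = list(nx.topological_sort(cond))
    relabel = {old: new for new, old in enumerate(order)}
    modules = [tuple(sorted(cond.nodes[old]["members"])) for old in order]
    edges = tuple(sorted((relabel[u], relabel[v]) for u, v in cond.edges))
    return ModuleDecomposition(tuple(modules), edges,
                               tuple(range(len(modules))))


def combine(a: PartialAttractor, b: PartialAttractor) -> list[PartialAttractor]:
    """All consistent phase-aligned merges of two partial attractors.

    Every relative phase shift of ``b`` against ``a`` is tried over the
    combined period lcm(l1, l2); shifts that disagree on shared nodes are
    dropped, and equivalent merges (same cycle up to rotation) deduplicated.
    For disjoint node sets this returns exactly gcd(l1, l2) attractors of
    length lcm(l1, l2).
    """
    overlap = sorted(set(a.nodes) & set(b.nodes))
    nodes = tuple(sorted(set(a.nodes) | set(b.nodes)))
    pos = {node: i for i, node in enumerate(nodes)}
    l1, l2 = a.length, b.length
    period = math.lcm(l1, l2)
    a_bit = {node: a.nodes.index(node) for node in a.nodes}
    b_bit = {node: b.nodes.index(node) for node in b.nodes}
    out: list[PartialAttractor] = []
    seen = set()
    for shift in range(l2):
        ok = True
        for t in range(period):
            sa, sb = a.states[t % l1], b.states[(t + shift) % l2]
            for node in overlap:
                if ((sa >> a_bit[node]) & 1) != ((sb >> b_bit[node]) & 1):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        seq = []
        for t in range(period):
            sa, sb = a.states[t % l1], b.states[(t + shift) % l2]
            v = 0
            for node in a.nodes:
                v |= ((sa >> a_bit[node]) & 1) << pos[node]
            for node in b.nodes:
                v |= ((sb >> b_bit[node]) & 1) << pos[node]
            seq.append(v)
        merged = PartialAttractor(nodes, canonical_cycle(_min_period(seq)))
        if merged.states not in seen:
            seen.add(merged.states)
            out.append(merged)
    return out


def _min_period(seq: list[int]) -> tuple[int, ...]:
    L = len(seq)
    for d in range(1, L + 1):
        if L % d == 0 and all(seq[t] == seq[t % d] for t in range(L)):
            return tuple(seq[:d])
    return tuple(seq)  # pragma: no cover


def compose_cycles(u1: Attractor | PartialAttractor, n1: int,
                   u2: Attractor | PartialAttractor, n2: int | None = None):
    """Combine attractors of two modules with disjoint node sets.

    ``u1`` occupies node indices 0..n1-1 and ``u2`` the next block (or pass
    ``PartialAttractor``s directly).  Returns gcd(l1, l2) combined attractors
    of length lcm(l1, l2), one per phase-shift class; two fixed points give a
    single fixed point.
    """
    if isinstance(u1, Attractor):
        u1 = PartialAttractor(tuple(range(n1)), u1.states)
    if isinstance(u2, Attractor):
        if n2 is None:
            raise ValueError("n2 required when u2 is an Attractor")
        u2 = PartialAttractor(tuple(range(n1, n1 + n2)), u2.states)
    if set(u1.nodes) & set(u2.nodes):
        raise ValueError("compose_cycles requires disjoint node sets")
    return combine(u1, u2)


def consistent_upstream_combinations(
        tables: list[list[PartialAttractor]]) -> list[PartialAttractor]:
    """All consistent joint attractors over several upstream lineages.

    ``tables[i]`` lists the attractors of upstream lineage i (each over its
    ancestor-closed node set).  Combinations that do not agree on every
    shared node (including phase where cycles overlap) are removed;
    independent lineages contribute a full product.
    """
    combos = [_EMPTY]
    for table in tables:
        nxt: list[PartialAttractor] = []
        seen = set()
        for base, cand in itertools.product(combos, table):
            for merged in combine(base, cand):
                key = (merged.nodes, merged.states)
                if key not in seen:
                    seen.add(key)
                    nxt.append(merged)
        combos = nxt
    return combos


def _conditional_attractors(net: BooleanNetwork, ctx: PartialAttractor,
                            module: tuple[int, ...],
                            pins: dict[int, int] | None = None,
                            cap: int = 1 << 22) -> list[PartialAttractor]:
    """Attractors of ``module`` clamped to upstream context ``ctx``.

    Brute force over the product system (context phase, module state); with
    ``pins`` some module nodes are overridden to constants.  Returns partial
    attractors over ctx nodes + free module nodes.
    """
    pins = pins or {}
    free = [i for i in module if i not in pins]
    s = len(free)
    lc = ctx.length
    if lc * (1 << s) > cap:
        raise ValueError(
            f"module conditional state space {lc * (1 << s)} exceeds cap; "
            "use the sampled finder")
    ctx_pos = {node: b for b, node in enumerate(ctx.nodes)}
    free_pos = {node: b for b, node in enumerate(free)}
    out_nodes = tuple(sorted(set(ctx.nodes) | set(free)))
    out_pos = {node: b for b, node in enumerate(out_nodes)}

    def local_value(node, t, x):
        if node in pins:
            return pins[node]
        if node in free_pos:
            return (x >> free_pos[node]) & 1
        return (ctx.states[t % lc] >> ctx_pos[node]) & 1

    def step(t, x):
        nx_ = 0
        for node in free:
            idx = 0
            for b, j in enumerate(net.inputs_[node]):
                idx |= local_value(j, t, x) << b
            nx_ |= int(net.tables_[node][idx]) << free_pos[node]
        return (t + 1) % lc, nx_

    total = lc * (1 << s)
    label = [-1] * total
    cycles: list[tuple[tuple[int, int], ...]] = []
    for start in range(total):
        if label[start] != -1:
            continue
        path, on_path = [], {}
        cur = start
        while label[cur] == -1 and cur not in on_path:
            on_path[cur] = len(path)
            path.append(cur)
            t, x = divmod(cur, 1 << s)
            t2, x2 = step(t, x)
            cur = t2 * (1 << s) + x2
        if label[cur] != -1:
            aid = label[cur]
        else:
            aid = len(cycles)
            cyc = path[on_path[cur]:]
            cycles.append(tuple(divmod(c, 1 << s) for c in cyc))
        for p in path:
            label[p] = aid
    results, seen = [], set()
    for cyc in cycles:
        seq = []
        for t, x in cyc:
            v = 0
            for node in ctx.nodes:
                v |= ((ctx.states[t % lc] >> ctx_pos[node]) & 1) << out_pos[node]
            for node in free:
                v |= ((x >> free_pos[node]) & 1) << out_pos[node]
            seq.append(v)
        pa = PartialAttractor(out_nodes, canonical_cycle(_min_period(seq)))
        if pa.states not in seen:
            seen.add(pa.states)
            results.append(pa)
    return results


def _closure_attractors(net: BooleanNetwork, decomp: ModuleDecomposition,
                        cap: int = 1 << 22) -> dict[int, list[PartialAttractor]]:
    """Joint attractors of each module's ancestor closure, computed in
    topological order per the modular algorithm."""
    closure: dict[int, list[PartialAttractor]] = {}
    for mid in decomp.topo_order:
        parents = decomp.parents(mid)
        if parents:
            contexts = consistent_upstream_combinations(
                [closure[p] for p in parents])
        else:
            contexts = [_EMPTY]
        attrs: list[PartialAttractor] = []
        seen = set()
        for ctx in contexts:
            for pa in _conditional_attractors(net, ctx, decomp.modules[mid],
                                              cap=cap):
                key = (pa.nodes, pa.states)
                if key not in seen:
                    seen.add(key)
                    attrs.append(pa)
        closure[mid] = attrs
    return closure


def find_attractors_modular(net: BooleanNetwork, cap: int = 1 << 22) -> AttractorSet:
    """All attractors via modular decomposition (no basin sizes).

    Produces the same canonical attractor set as the exhaustive finder
    whenever both can run, at the cost of solving each module's conditional
    dynamics instead of the full 2^n state space.
    """
    decomp = decompose(net)
    closure = _closure_attractors(net, decomp, cap=cap)
    full = consistent_upstream_combinations(
        [closure[mid] for mid in decomp.sinks()])
    attrs = []
    for pa in full:
        assert pa.nodes == tuple(range(net.n))
        attrs.append(Attractor(pa.states, basin_size=None))
    return AttractorSet(attrs, net.n, "modular", node_names=list(net.node_names))


def module_ck_nodes(net: BooleanNetwork, decomp: ModuleDecomposition, mid: int,
                    ctx: PartialAttractor, target: PartialAttractor,
                    cap: int = 1 << 22) -> tuple[int, ...]:
    """Minimal in-module pinning leaving a single conditional attractor.

    Given a fixed upstream context, searches subsets of the module's nodes
    (restricted to nodes constant in the target, by increasing size, ties
    lexicographic) whose pinning to target values leaves exactly one module
    attractor equal to the target's restriction.  Control exerted downstream
    of the module cannot affect it, so these sets compose along the DAG.
    """
    module = decomp.modules[mid]
    tpos = {node: b for b, node in enumerate(target.nodes)}
    const: dict[int, int] = {}
    for node in module:
        vals = {(s >> tpos[node]) & 1 for s in target.states}
        if len(vals) == 1:
            const[node] = vals.pop()
    pinnable = sorted(const)
    for k in range(len(pinnable) + 1):
        for combo in itertools.combinations(pinnable, k):
            pins = {c: const[c] for c in combo}
            found = _conditional_attractors(net, ctx, module, pins=pins, cap=cap)
            if len(found) != 1:
                continue
            keep = [b for b, node in enumerate(target.nodes)
                    if node not in pins]
            restr = _restrict_partial(target, keep)
            if found[0].nodes == restr.nodes and found[0].states == restr.states:
                return combo
    raise ValueError(
        "module attractor is not statically controllable in this context")


def _restrict_partial(pa: PartialAttractor, keep_positions: list[int]):
    nodes = tuple(pa.nodes[b] for b in keep_positions)
    seq = []
    for s in pa.states:
        v = 0
        for nb, b in enumerate(keep_positions):
            v |= ((s >> b) & 1) << nb
        seq.append(v)
    return PartialAttractor(nodes, canonical_cycle(_min_period(seq)))


def assemble_modular_ck(net: BooleanNetwork, target: Attractor,
                        cap: int = 1 << 22) -> tuple[str, ...]:
    """Global CK candidate as the union of per-module CK nodes along the DAG.

    For each module (topological order) the upstream context is the target's
    restriction to the module's ancestor closure; the per-module minimal sets
    are computed against that fixed context and united.  Verified against the
    direct search in the test suite; minimality of the union is an empirical
    property, not a theorem.
    """
    decomp = decompose(net)
    full = PartialAttractor(tuple(range(net.n)), target.states)
    ancestors: dict[int, set[int]] = {}
    for mid in decomp.topo_order:
        anc = set()
        for p in decomp.parents(mid):
            anc |= ancestors[p] | set(decomp.modules[p])
        ancestors[mid] = anc
    chosen: list[int] = []
    for mid in decomp.topo_order:
        anc_nodes = sorted(ancestors[mid])
        keep = [b for b, node in enumerate(full.nodes) if node in set(anc_nodes)]
        ctx = _restrict_partial(full, keep) if anc_nodes else _EMPTY
        keep_t = [b for b, node in enumerate(full.nodes)
                  if node in ancestors[mid] | set(decomp.modules[mid])]
        tgt = _restrict_partial(full, keep_t)
        chosen.extend(module_ck_nodes(net, decomp, mid, ctx, tgt, cap=cap))
    return tuple(net.node_names[i] for i in sorted(chosen))
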