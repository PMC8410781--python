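"""Synchronous Boolean networks: representation, parsing, dynamics, pinning.

A network is a list of named nodes, each carrying one Boolean update function
over the full network state.  Updates are applied synchronously: the state of
every node at time t+1 is its function evaluated on the state at time t.

Internally every update function is stored as a truth table over the node's
*essential* inputs (inputs whose value can actually change the output).  A
network state is a length-n binary vector encoded as a Python integer with
node index 0 as the least-significant bit; this little-endian convention is
used in every serialization.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "BooleanNetwork",
    "ParseError",
    "PinAssignment",
    "parse_network",
    "state_to_bits",
    "bits_to_state",
    "input_nodes",
    "pin_nodes",
    "dependency_graph",
]

#: Above this many syntactic inputs, essential-input probing (which costs
#: 2^k table entries) is skipped and syntactic dependencies are kept, flagged.
ESSENTIAL_INPUT_CAP = 20


class ParseError(ValueError):
    """Raised for malformed rule files or truth-table documents."""


# ---------------------------------------------------------------------------
# state encoding helpers


def state_to_bits(state: int, n: int) -> tuple[int, ...]:
    """Decode an integer state into its length-n bit vector (node 0 = LSB)."""
    return tuple((state >> i) & 1 for i in range(n))


def bits_to_state(bits) -> int:
    """Encode a bit vector into an integer state (node 0 = LSB)."""
    s = 0
    for i, b in enumerate(bits):
        if b not in (0, 1):
            raise ValueError(f"non-binary value {b!r} at position {i}")
        s |= b << i
    return s


# ---------------------------------------------------------------------------
# truth-table manipulation

def _depends_on(table: np.ndarray, k: int, b: int) -> bool:
    """Whether a 2^k truth table depends on its b-th input (b = bit position)."""
    t = table.reshape((2,) * k)
    ax = k - 1 - b  # axis 0 is the highest bit; bit b is axis k-1-b
    return not np.array_equal(np.take(t, 0, axis=ax), np.take(t, 1, axis=ax))


def _restrict_input(table: np.ndarray, k: int, b: int, value: int) -> np.ndarray:
    """Fix input b of a 2^k table to `value`; remaining inputs keep their order."""
    t = table.reshape((2,) * k)
    return np.ascontiguousarray(np.take(t, value, axis=k - 1 - b)).reshape(-1)


def _reduce_essential(inputs: tuple[int, ...], table: np.ndarray):
    """Drop non-essential inputs from (inputs, table)."""
    inputs = list(inputs)
    k = len(inputs)
    for b in range(k - 1, -1, -1):
        if not _depends_on(table, len(inputs), b):
            table = _restrict_input(table, len(inputs), b, 0)
            del inputs[b]
    return tuple(inputs), np.ascontiguousarray(table, dtype=np.uint8)


@dataclass(frozen=True)
class PinAssignment:
    """A node-state override: a map node name -> {0, 1}.

    Pinning p nodes maps an n-node system onto an (n-p)-node system whose
    dynamics are the original dynamics restricted to states consistent with
    the pinned values.
    """

    pins: dict[str, int]

    @property
    def p(self) -> int:
        return len(self.pins)

    def validate(self, net: "BooleanNetwork") -> None:
        for name, v in self.pins.items():
            if name not in net._index:
                raise ValueError(f"pinned node {name!r} not in network")
            if v not in (0, 1):
                raise ValueError(f"pin value for {name!r} must be 0 or 1")


class BooleanNetwork:
    """A synchronous Boolean network.

    Parameters
    ----------
    node_names:
        Ordered, unique node identifiers.  Node order fixes the bit layout of
        integer-encoded states (node 0 is the least-significant bit).
    rules:
        One ``(input_names, output_bits)`` pair per node, in node order.
        ``output_bits`` is indexed little-endian in the listed input order
        (the first input is the least-significant index bit).  Inputs are
        reduced to the essential set at construction.
    """

    def __init__(self, node_names, rules, *, _reduced=False):
        self.node_names: list[str] = list(node_names)
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("duplicate node names")
        self._index: dict[str, int] = {nm: i for i, nm in enumerate(self.node_names)}
        self.n = len(self.node_names)
        self.inputs_: list[tuple[int, ...]] = []
        self.tables_: list[np.ndarray] = []
        #: node indices whose dependencies are syntactic only (too many inputs
        #: for essential probing); consumers should treat their dependency
        #: edges as an over-approximation.
        self.syntactic_only: frozenset[int]
        synt = set()
        if len(rules) != self.n:
            raise ValueError("one rule required per node")
        for i, (inp_names, bits) in enumerate(rules):
            idx = tuple(self._index[nm] if isinstance(nm, str) else int(nm)
                        for nm in inp_names)
            table = np.asarray(bits, dtype=np.uint8)
            if table.shape != (1 << len(idx),):
                raise ValueError(
                    f"node {self.node_names[i]!r}: table length {table.size} "
                    f"does not match {len(idx)} inputs")
            if len(idx) > ESSENTIAL_INPUT_CAP:
                synt.add(i)
            elif not _reduced:
                idx, table = _reduce_essential(idx, table)
            self.inputs_.append(idx)
            self.tables_.append(np.ascontiguousarray(table, dtype=np.uint8))
        self.syntactic_only = frozenset(synt)
        self._succ_cache: np.ndarray | None = None
        #: free-form generator metadata (e.g. the raw signed adjacency of a
        #: threshold network, before essential-input reduction)
        self.meta: dict = {}

    # -- basic queries ------------------------------------------------------

    def index(self, name: str) -> int:
        return self._index[name]

    def node_output(self, i: int, state: int) -> int:
        """Value of node i at t+1 given the full integer state at t."""
        idx = 0
        for b, j in enumerate(self.inputs_[i]):
            idx |= ((state >> j) & 1) << b
        return int(self.tables_[i][idx])

    def step(self, state: int) -> int:
        """One synchronous update of an integer-encoded state."""
        if not 0 <= state < (1 << self.n) and self.n > 0:
            raise ValueError("state out of range")
        out = 0
        for i in range(self.n):
            out |= self.node_output(i, state) << i
        return out

    def successor_table(self, cap: int = 22) -> np.ndarray:
        """Vectorized image of every state; requires n <= cap."""
        if self.n > cap:
            raise ValueError(
                f"n={self.n} exceeds exhaustive cap {cap}; use the modular or "
                "sampled attractor finders")
        if self._succ_cache is None:
            size = 1 << self.n
            states = np.arange(size, dtype=np.int64)
            succ = np.zeros(size, dtype=np.int64)
            for i in range(self.n):
                idx = np.zeros(size, dtype=np.int64)
                for b, j in enumerate(self.inputs_[i]):
                    idx |= ((states >> j) & 1) << b
                succ |= self.tables_[i][idx].astype(np.int64) << i
            self._succ_cache = succ
        return self._succ_cache

    def is_identity_rule(self, i: int) -> bool:
        """Semantic check of Definition-style input nodes: f_i(x) = x_i."""
        return self.inputs_[i] == (i,) and self.tables_[i].tolist() == [0, 1]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "nodes": self.node_names,
            "tables": {
                self.node_names[i]: {
                    "inputs": [self.node_names[j] for j in self.inputs_[i]],
                    "output_bits": "".join(map(str, self.tables_[i].tolist())),
                }
                for i in range(self.n)
            },
        }
        return json.dumps(doc, indent=1)

    def to_bnet(self) -> str:
        """Serialize as BoolNet-style rules (expressions in DNF)."""
        lines = ["targets, factors"]
        for i in range(self.n):
            lines.append(f"{self.node_names[i]}, {self._expr(i)}")
        return "\n".join(lines) + "\n"

    def _expr(self, i: int) -> str:
        inp, tab = self.inputs_[i], self.tables_[i]
        if not inp:
            return str(int(tab[0]))
        if self.is_identity_rule(i):
            return self.node_names[i]
        terms = []
        for idx in range(tab.size):
            if tab[idx]:
                lits = []
                for b, j in enumerate(inp):
                    nm = self.node_names[j]
                    lits.append(nm if (idx >> b) & 1 else f"!{nm}")
                terms.append("(" + " & ".join(lits) + ")")
        return " | ".join(terms) if terms else "0"

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"BooleanNetwork(n={self.n}, nodes={self.node_names!r})"


# ---------------------------------------------------------------------------
# expression parsing (BoolNet-style dialect)

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.]*)|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(expr: str, line_no: int):
    pos, out = 0, []
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m or m.end() == pos:
            raise ParseError(f"line {line_no}: cannot parse {expr[pos:]!r}")
        if m.lastgroup == "name":
            out.append(("name", m.group("name")))
        elif m.lastgroup == "const":
            out.append(("const", int(m.group("const"))))
        else:
            out.append(("op", m.group("op")))
        pos = m.end()
    return out


class _ExprParser:
    """Recursive-descent parser for  expr := term ('|' term)* ;
    term := factor ('&' factor)* ; factor := '!' factor | '(' expr ')' | atom.
    """

    def __init__(self, tokens, line_no):
        self.toks = tokens
        self.pos = 0
        self.line_no = line_no

    def _peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else (None, None)

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.pos != len(self.toks):
            raise ParseError(f"line {self.line_no}: trailing tokens")
        return node

    def expr(self):
        node = self.term()
        while self._peek() == ("op", "|"):
            self._next()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self._peek() == ("op", "&"):
            self._next()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        kind, val = self._next()
        if (kind, val) == ("op", "!"):
            return ("not", self.factor())
        if (kind, val) == ("op", "("):
            node = self.expr()
            if self._next() != ("op", ")"):
                raise ParseError(f"line {self.line_no}: missing ')'")
            return node
        if kind == "name":
            return ("var", val)
        if kind == "const":
            return ("const", val)
        raise ParseError(f"line {self.line_no}: unexpected token")


def _expr_vars(node, acc):
    if node[0] == "var":
        if node[1] not in acc:
            acc.append(node[1])
    elif node[0] == "not":
        _expr_vars(node[1], acc)
    elif node[0] in ("and", "or"):
        _expr_vars(node[1], acc)
        _expr_vars(node[2], acc)
    return acc


def _expr_eval(node, env):
    op = node[0]
    if op == "var":
        return env[node[1]]
    if op == "const":
        return np.uint8(node[1])
    if op == "not":
        return 1 - _expr_eval(node[1], env)
    a = _expr_eval(node[1], env)
    b = _expr_eval(node[2], env)
    return a & b if op == "and" else a | b


def _tabulate(ast, var_order):
    """Truth table of an expression over var_order (first var = LSB index bit)."""
    k = len(var_order)
    if k > ESSENTIAL_INPUT_CAP:
        raise ParseError(
            f"expression has {k} inputs; at most {ESSENTIAL_INPUT_CAP} supported")
    size = 1 << k
    grid = np.arange(size, dtype=np.int64)
    env = {nm: ((grid >> b) & 1).astype(np.uint8) for b, nm in enumerate(var_order)}
    out = _expr_eval(ast, env)
    if np.isscalar(out) or out.shape == ():
        out = np.full(size, int(out), dtype=np.uint8)
    return out.astype(np.uint8)


def parse_network(text: str, dialect: str = "bnet") -> BooleanNetwork:
    """Parse a Boolean network from rule text.

    ``bnet``: one ``name, expression`` line per node, operators ``& | ! ( )``
    and constants ``0``/``1``; comment lines start with ``#``; an optional
    ``targets, factors`` header is skipped.  Node order is the order of first
    definition.

    ``json-truthtable``: ``{"nodes": [...], "tables": {node: {"inputs": [...],
    "output_bits": "0101..."}}}`` with output bits indexed little-endian in
    the listed input order.
    """
    if dialect == "json-truthtable":
        return _parse_json(text)
    if dialect != "bnet":
        raise ValueError(f"unknown dialect {dialect!r}")

    names: list[str] = []
    asts: dict[str, object] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if re.fullmatch(r"targets\s*,\s*factors", line, flags=re.IGNORECASE):
            continue
        if "," not in line:
            raise ParseError(f"line {line_no}: expected 'name, expression'")
        name, expr = line.split(",", 1)
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", name):
            raise ParseError(f"line {line_no}: bad node name {name!r}")
        if name in asts:
            raise ParseError(f"line {line_no}: duplicate definition of {name!r}")
        ast = _ExprParser(_tokenize(expr, line_no), line_no).parse()
        names.append(name)
        asts[name] = ast
    if not names:
        raise ParseError("no node definitions found")
    declared = set(names)
    rules = []
    for name in names:
        ast = asts[name]
        vars_ = _expr_vars(ast, [])
        for v in vars_:
            if v not in declared:
                raise ParseError(f"rule for {name!r} references undeclared node {v!r}")
        vars_ = sorted(vars_, key=names.index)
        rules.append((vars_, _tabulate(ast, vars_)))
    return BooleanNetwork(names, rules)


def _parse_json(text: str) -> BooleanNetwork:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON: {e}") from None
    try:
        names = list(doc["nodes"])
        tables = doc["tables"]
    except (KeyError, TypeError):
        raise ParseError("expected keys 'nodes' and 'tables'") from None
    declared = set(names)
    rules = []
    for name in names:
        if name not in tables:
            raise ParseError(f"missing table for node {name!r}")
        entry = tables[name]
        inp = list(entry["inputs"])
        for v in inp:
            if v not in declared:
                raise ParseError(f"table for {name!r} references undeclared node {v!r}")
        bits = [int(c) for c in entry["output_bits"]]
        if any(b not in (0, 1) for b in bits):
            raise ParseError(f"non-binary output bits for node {name!r}")
        if len(bits) != 1 << len(inp):
            raise ParseError(f"table length mismatch for node {name!r}")
        rules.append((inp, bits))
    return BooleanNetwork(names, rules)


# ---------------------------------------------------------------------------
# operations

def input_nodes(net: BooleanNetwork) -> set[str]:
    """Nodes whose update rule is (semantically) the identity on themselves.

    Such nodes hold whatever value they start with, so each setting of the
    inputs supports at least one distinct attractor, and every control kernel
    must contain all of them.  A constant rule is *not* an input node.
    """
    return {net.node_names[i] for i in range(net.n) if net.is_identity_rule(i)}


def pin_nodes(net: BooleanNetwork, pins: PinAssignment | dict) -> BooleanNetwork:
    """Apply a node-state override, returning the reduced (n-p)-node network.

    Pinned values are substituted as constants into the remaining update
    functions; on the transition matrix this is exactly deletion of the pinned
    columns and of all rows inconsistent with the pins.  Pinning every node
    yields an empty network flagged via ``net.n == 0``.
    """
    if isinstance(pins, dict):
        pins = PinAssignment(dict(pins))
    pins.validate(net)
    pinned = {net._index[nm]: v for nm, v in pins.pins.items()}
    kept = [i for i in range(net.n) if i not in pinned]
    remap = {old: new for new, old in enumerate(kept)}
    names = [net.node_names[i] for i in kept]
    rules = []
    for i in kept:
        inp = list(net.inputs_[i])
        tab = net.tables_[i]
        for b in range(len(inp) - 1, -1, -1):
            if inp[b] in pinned:
                tab = _restrict_input(tab, len(inp), b, pinned[inp[b]])
                del inp[b]
        rules.append(([remap[j] for j in inp], tab))
    sub = BooleanNetwork.__new__(BooleanNetwork)
    sub.node_names = names
    sub._index = {nm: i for i, nm in enumerate(names)}
    sub.n = len(names)
    sub.inputs_ = []
    sub.tables_ = []
    synt = set()
    for new_i, (inp, tab) in enumerate(rules):
        if len(inp) > ESSENTIAL_INPUT_CAP:
            synt.add(new_i)
            sub.inputs_.append(tuple(inp))
            sub.tables_.append(np.ascontiguousarray(tab, dtype=np.uint8))
        else:
            ridx, rtab = _reduce_essential(tuple(inp), tab)
            sub.inputs_.append(ridx)
            sub.tables_.append(rtab)
    sub.syntactic_only = frozenset(synt)
    sub._succ_cache = None
    sub.meta = {}
    return sub


def dependency_graph(net: BooleanNetwork) -> nx.DiGraph:
    """Directed causal graph: edge j -> i iff f_i depends essentially on x_j.

    Essential dependence is established by truth-table probing (done once at
    construction); nodes with more than ``ESSENTIAL_INPUT_CAP`` syntactic
    inputs fall back to syntactic dependencies and carry ``syntactic=True``.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.node_names)
    for i in range(net.n):
        for j in net.inputs_[i]:
            g.add_edge(net.node_names[j], net.node_names[i])
        if i in net.syntactic_only:
            g.nodes[net.node_names[i]]["syntactic"] = True
    return g
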