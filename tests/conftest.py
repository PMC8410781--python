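"""Shared fixtures: small hand-checkable networks and random-net factories."""

import pytest

import boolck as bk
from boolck.pipeline import FIXTURES


@pytest.fixture
def toggle():
    """Mutual negation: 2 fixed points plus one uncontrollable 2-cycle."""
    return bk.parse_network(FIXTURES["toggle"])


@pytest.fixture
def chain():
    """One input node copied down a chain: m=1, two fixed points."""
    return bk.parse_network(FIXTURES["input_chain"])


@pytest.fixture
def copy2():
    """A, A / B, A — the 2-node input-copy network."""
    return bk.parse_network("A, A\nB, A\n")


@pytest.fixture
def gated_oscillator():
    """Input gate G switches a 2-node oscillator on; the on-cycle's only
    constant node is G, so pinning G=1 isolates it (controllable cycle)."""
    return bk.parse_network(FIXTURES["gated_oscillator"])


@pytest.fixture
def double_toggle():
    return bk.parse_network(FIXTURES["double_toggle"])


def random_networks(count, n, seed0=0, kinds=("pK", "zero", "balanced")):
    """A reproducible stream of small random networks of mixed kinds."""
    out = []
    for i in range(count):
        kind = kinds[i % len(kinds)]
        seed = seed0 + i
        if kind == "pK":
            p_on = (0.25, 0.5, 0.75)[i % 3]
            out.append(bk.generate_pk(n, 2, p_on, seed))
        elif kind == "zero":
            out.append(bk.generate_threshold(n, 2 + (i % 3), 0.5, "zero", seed))
        else:
            out.append(bk.generate_threshold(n, 2 + (i % 3), 0.5, "balanced", seed))
    return out


def ring_network(length, offset=0, prefix="R"):
    """Pure rotation ring: node i copies node i-1 (mod length).

    The orbit of the single-1 state is a cycle of exactly `length` states.
    Returns rule text with node names offset for disjoint unions.
    """
    lines = []
    for i in range(length):
        lines.append(f"{prefix}{offset + i}, {prefix}{offset + (i - 1) % length}")
    return "\n".join(lines) + "\n"
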