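"""Modular decomposition, cycle composition, and modular attractor finding."""

import math

import pytest

import boolck as bk
from boolck.modular import PartialAttractor, combine, _EMPTY
from conftest import random_networks, ring_network


class TestDecompose:
    def test_copy_network_two_modules(self, copy2):
        d = bk.decompose(copy2)
        mods = [set(m) for m in d.modules]
        assert mods == [{0}, {1}]
        assert d.dag_edges == ((0, 1),)

    def test_toggle_single_module(self, toggle):
        d = bk.decompose(toggle)
        assert [set(m) for m in d.modules] == [{0, 1}]

    def test_disjoint_union_no_dag_edges(self, double_toggle):
        d = bk.decompose(double_toggle)
        assert len(d.modules) == 2 and d.dag_edges == ()


class TestComposeCycles:
    def test_2_and_3_give_one_of_length_6(self):
        u1 = bk.Attractor((0, 3))       # a 2-cycle on 2 nodes
        u2 = bk.Attractor((1, 2, 4))    # a 3-cycle on 3 nodes
        out = bk.compose_cycles(u1, 2, u2, 3)
        assert len(out) == 1 and out[0].length == 6

    def test_2_and_2_give_two_of_length_2(self):
        u1 = bk.Attractor((0, 3))
        u2 = bk.Attractor((0, 3))
        out = bk.compose_cycles(u1, 2, u2, 2)
        assert len(out) == 2 and all(c.length == 2 for c in out)

    def test_fixed_point_times_cycle(self):
        u1 = bk.Attractor((1,))
        u2 = bk.Attractor((1, 2, 4))
        out = bk.compose_cycles(u1, 1, u2, 3)
        assert len(out) == 1 and out[0].length == 3

    @pytest.mark.parametrize("l1,l2", [(l1, l2) for l1 in range(1, 7)
                                       for l2 in range(l1, 7)])
    def test_gcd_lcm_rule_against_exhaustive_oracle(self, l1, l2):
        """Composing the single-1 rotation cycles of two disjoint rings must
        reproduce exactly the attractors of the union network whose
        projections are those cycles: gcd(l1,l2) of them, length lcm."""
        text = ring_network(l1, prefix="P") + ring_network(l2, prefix="Q")
        net = bk.parse_network(text)
        full = bk.find_attractors_exhaustive(net)

        # the two module cycles: orbit of the single-1 state under rotation
        u1 = bk.Attractor(tuple((1 << (i % l1)) for i in range(l1))
                          if l1 > 1 else (1,))
        u2 = bk.Attractor(tuple((1 << (i % l2)) for i in range(l2))
                          if l2 > 1 else (1,))
        composed = bk.compose_cycles(u1, l1, u2, l2)
        assert len(composed) == math.gcd(l1, l2)
        assert all(c.length == math.lcm(l1, l2) for c in composed)

        # oracle: union attractors whose projections match u1 and u2
        def project(states, lo, ln):
            seq = tuple((s >> lo) & ((1 << ln) - 1) for s in states)
            # reduce to minimal period and canonicalize
            L = len(seq)
            for d in range(1, L + 1):
                if L % d == 0 and all(seq[t] == seq[t % d] for t in range(L)):
                    return bk.Attractor(seq[:d]).states
            raise AssertionError

        matching = {
            a.states for a in full.attractors
            if project(a.states, 0, l1) == u1.states
            and project(a.states, l1, l2) == u2.states}
        composed_keys = {bk.Attractor(c.states).states for c in composed}
        assert composed_keys == matching


class TestConsistentCombinations:
    def test_independent_ancestors_full_product(self):
        t1 = [PartialAttractor((0,), (0,)), PartialAttractor((0,), (1,))]
        t2 = [PartialAttractor((1,), (0,)), PartialAttractor((1,), (1,))]
        out = bk.consistent_upstream_combinations([t1, t2])
        assert len(out) == 4

    def test_single_ancestor_unchanged(self):
        t1 = [PartialAttractor((0,), (0,)), PartialAttractor((0,), (1,))]
        out = bk.consistent_upstream_combinations([t1])
        assert {(c.nodes, c.states) for c in out} == \
               {(c.nodes, c.states) for c in t1}

    def test_shared_ancestor_conflicts_removed(self):
        # two lineages both containing node 0; they must agree on it
        t1 = [PartialAttractor((0, 1), (0b00,)), PartialAttractor((0, 1), (0b01,))]
        t2 = [PartialAttractor((0, 2), (0b00,)), PartialAttractor((0, 2), (0b01,))]
        out = bk.consistent_upstream_combinations([t1, t2])
        # only combinations agreeing on node 0 survive: 2 of 4
        assert len(out) == 2
        for c in out:
            assert c.nodes == (0, 1, 2)

    def test_phase_overlap_agreement(self):
        # both lineages carry the same oscillating node 0; the two relative
        # phases collapse to the consistent alignments only
        cyc1 = PartialAttractor((0, 1), (0b00, 0b01))  # node0: 0,1
        cyc2 = PartialAttractor((0, 2), (0b00, 0b01))  # node0: 0,1
        out = combine(cyc1, cyc2)
        assert len(out) == 1  # only the in-phase alignment is consistent
        assert out[0].length == 2


class TestModularFinder:
    def test_input_chain_two_fixed_points(self, chain):
        aset = bk.find_attractors_modular(chain)
        assert aset.r == 2
        assert aset.keys() == bk.find_attractors_exhaustive(chain).keys()

    def test_two_disjoint_toggles_product(self, double_toggle):
        """3 attractors each; fixed x fixed -> 4, fixed x cycle -> 4, and the
        two 2-cycles compose into gcd(2,2)=2 attractors: 10 in total."""
        aset = bk.find_attractors_modular(double_toggle)
        assert aset.r == 10
        assert aset.keys() == bk.find_attractors_exhaustive(double_toggle).keys()

    def test_basins_absent_in_modular_mode(self, chain):
        aset = bk.find_attractors_modular(chain)
        assert aset.mode == "modular"
        assert all(a.basin_size is None for a in aset.attractors)

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_exhaustive_on_random_networks(self, seed):
        net = random_networks(1, 10, seed0=400 + seed)[0]
        assert bk.find_attractors_modular(net).keys() == \
            bk.find_attractors_exhaustive(net).keys()


class TestModuleCK:
    def test_single_conditional_attractor_needs_nothing(self):
        net = bk.parse_network("A, A\nB, A\n")
        d = bk.decompose(net)
        # module {B} under the context A=1 has a unique attractor
        ctx = PartialAttractor((0,), (1,))
        tgt = PartialAttractor((0, 1), (0b11,))
        assert bk.module_ck_nodes(net, d, 1, ctx, tgt) == ()

    def test_input_module_needs_itself(self):
        net = bk.parse_network("A, A\nB, A\n")
        d = bk.decompose(net)
        tgt = PartialAttractor((0,), (1,))
        assert bk.module_ck_nodes(net, d, 0, _EMPTY, tgt) == (0,)

    def test_toggle_module_fixed_point_size_one(self, toggle):
        d = bk.decompose(toggle)
        tgt = PartialAttractor((0, 1), (0b01,))
        ck = bk.module_ck_nodes(toggle, d, 0, _EMPTY, tgt)
        assert len(ck) == 1 and ck == (0,)  # lexicographic tie-break

    @pytest.mark.parametrize("fixture", ["input_chain", "double_toggle",
                                         "gated_oscillator", "rings_2_3"])
    def test_assembled_ck_matches_direct_search(self, fixture):
        """Union of per-module CK nodes along the DAG reproduces the size of
        the direct control-kernel search (tested, not assumed)."""
        from boolck.pipeline import FIXTURES
        net = bk.parse_network(FIXTURES[fixture])
        aset = bk.find_attractors_exhaustive(net)
        for a in aset.attractors:
            direct = bk.find_control_kernel(net, a, aset)
            if direct.status != "exact":
                continue
            try:
                assembled = bk.assemble_modular_ck(net, a)
            except ValueError:
                # module attractor uncontrollable in context: direct search
                # must not have found an exact CK either
                raise AssertionError(
                    f"assembly failed where direct search succeeded: {a}")
            assert len(assembled) == direct.size
            # the assembled set actually controls the target
            pins = {nm: a.constant_nodes(net.n)[net.index(nm)]
                    for nm in assembled}
            sub = bk.pin_nodes(net, pins)
            sub_aset = bk.find_attractors_exhaustive(sub)
            assert sub_aset.r == 1
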