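"""Control-kernel search, iterative bounds, first-order approximation."""

import itertools
import math

import pytest

import boolck as bk
from conftest import random_networks


def attractor_by_states(aset, states):
    return next(a for a in aset.attractors if a.states == states)


class TestFindControlKernel:
    def test_copy_network_kernel_is_the_input(self, copy2):
        aset = bk.find_attractors_exhaustive(copy2)
        res = bk.find_control_kernel(copy2, attractor_by_states(aset, (3,)), aset)
        assert res.ck == ("A",) and res.size == 1
        assert (res.m, res.w1_size, res.additional) == (1, 0, 0)

    def test_single_attractor_network_empty_kernel(self):
        net = bk.parse_network("A, !A\n")
        aset = bk.find_attractors_exhaustive(net)
        res = bk.find_control_kernel(net, aset.attractors[0], aset)
        assert res.ck == () and res.size == 0 and res.status == "exact"

    def test_toggle_fixed_point_and_uncontrollable_cycle(self, toggle):
        aset = bk.find_attractors_exhaustive(toggle)
        fixed = bk.find_control_kernel(toggle, attractor_by_states(aset, (2,)),
                                       aset)
        assert fixed.size == 1 and fixed.ck == ("A",)  # lexicographic tie
        cyc = bk.find_control_kernel(toggle, attractor_by_states(aset, (0, 3)),
                                     aset)
        assert cyc.status == "not_statically_controllable"
        assert cyc.ck is None and cyc.size is None

    def test_gated_oscillator_cycle_controllable(self, gated_oscillator):
        aset = bk.find_attractors_exhaustive(gated_oscillator)
        cyc = next(a for a in aset.attractors if a.length > 1)
        res = bk.find_control_kernel(gated_oscillator, cyc, aset)
        assert res.status == "exact" and res.ck == ("G",)

    def test_enumerate_all_minimal_kernels(self, toggle):
        aset = bk.find_attractors_exhaustive(toggle)
        all_cks = bk.find_control_kernel(
            toggle, attractor_by_states(aset, (2,)), aset, enumerate_all=True)
        assert [r.ck for r in all_cks] == [("A",), ("B",)]

    @pytest.mark.parametrize("seed", range(15))
    def test_definitional_postcondition_and_propositions(self, seed):
        """Every exact CK, re-pinned, leaves exactly one attractor equal to
        the target's restriction; contains all inputs (Prop 1) and is a
        distinguishing set (Prop 2)."""
        net = random_networks(1, 9, seed0=500 + seed)[0]
        aset = bk.find_attractors_exhaustive(net)
        inputs = bk.input_nodes(net)
        for a in aset.attractors:
            res = bk.find_control_kernel(net, a, aset)
            if res.status != "exact":
                continue
            assert inputs <= set(res.ck)
            const = a.constant_nodes(net.n)
            pins = {nm: const[net.index(nm)] for nm in res.ck}
            sub = bk.pin_nodes(net, pins)
            sub_aset = bk.find_attractors_exhaustive(sub)
            kept = [i for i in range(net.n)
                    if net.node_names[i] not in pins]
            from boolck.attractors import restrict_cycle
            assert sub_aset.r == 1
            assert sub_aset.attractors[0].states == restrict_cycle(a.states, kept)
            # Prop 2: pinned values are incompatible with every other attractor
            for b in aset.attractors:
                if b.states == a.states:
                    continue
                bconst = b.constant_nodes(net.n)
                assert any(bconst.get(net.index(nm)) != v
                           for nm, v in pins.items())


class TestControllableCycleCheck:
    def test_toggle_cycle_uncontrollable(self, toggle):
        aset = bk.find_attractors_exhaustive(toggle)
        cyc = attractor_by_states(aset, (0, 3))
        assert not bk.controllable_cycle_check(toggle, cyc, aset)

    def test_unique_attractor_cycle_controllable(self):
        net = bk.parse_network("A, !A\n")
        aset = bk.find_attractors_exhaustive(net)
        assert bk.controllable_cycle_check(net, aset.attractors[0], aset)

    def test_gated_cycle_controllable(self, gated_oscillator):
        aset = bk.find_attractors_exhaustive(gated_oscillator)
        cyc = next(a for a in aset.attractors if a.length > 1)
        assert bk.controllable_cycle_check(gated_oscillator, cyc, aset)

    def test_rejects_fixed_points(self, toggle):
        aset = bk.find_attractors_exhaustive(toggle)
        with pytest.raises(ValueError):
            bk.controllable_cycle_check(toggle, attractor_by_states(aset, (1,)),
                                        aset)


class TestIterativeBound:
    def test_copy_network_tight(self, copy2):
        aset = bk.find_attractors_exhaustive(copy2)
        lo, up, rounds, status = bk.iterative_bound(
            copy2, attractor_by_states(aset, (3,)), aset)
        assert (lo, up, status) == (1, 1, "exact")

    def test_single_attractor_zero(self):
        net = bk.parse_network("A, !A\n")
        aset = bk.find_attractors_exhaustive(net)
        lo, up, rounds, status = bk.iterative_bound(net, aset.attractors[0],
                                                    aset)
        assert (lo, up, rounds) == (0, 0, ())

    @pytest.mark.parametrize("seed", range(15))
    def test_sandwich_on_random_networks(self, seed):
        net = random_networks(1, 8, seed0=600 + seed)[0]
        aset = bk.find_attractors_exhaustive(net)
        for a in aset.attractors:
            res = bk.find_control_kernel(net, a, aset)
            if res.status != "exact":
                continue
            lo, up, rounds, status = bk.iterative_bound(net, a, aset)
            assert status == "exact"
            assert lo <= res.size <= up
            # rounds record attractors remaining; final round reaches 1
            if rounds:
                assert rounds[-1][2] == 1


class TestFirstOrder:
    def test_one_attractor_per_input_configuration(self):
        net = bk.parse_network("A, A\nB, B\nC, A & B\n")
        aset = bk.find_attractors_exhaustive(net)
        per, mean_ck1 = bk.first_order_approx(net, aset)
        assert all(p["w1_size"] == 0 and p["ck1"] == 2 for p in per)
        assert mean_ck1 == 2.0

    def test_toggle_per_attractor_sizes(self, toggle):
        aset = bk.find_attractors_exhaustive(toggle)
        per, mean_ck1 = bk.first_order_approx(toggle, aset)
        sizes = {tuple(p["target"]): p["w1_size"] for p in per}
        assert sizes[(1,)] == 1 and sizes[(2,)] == 1
        assert sizes[(0, 3)] is None  # no static witness for the bare cycle

    def test_identity_with_mean_w1(self, copy2):
        aset = bk.find_attractors_exhaustive(copy2)
        per, mean_ck1 = bk.first_order_approx(copy2, aset)
        m = per[0]["m"]
        mean_w1 = sum(p["w1_size"] for p in per) / len(per)
        assert mean_ck1 == m + mean_w1


class TestInputEntropy:
    def test_copy_network_uniform(self, copy2):
        aset = bk.find_attractors_exhaustive(copy2)
        ent = bk.input_entropy_bounds(copy2, aset)
        assert ent["m"] == 1 and ent["r_j"] == [1, 1]
        assert ent["mu"] == pytest.approx(1.0)

    def test_no_inputs_zero_entropy(self, toggle):
        aset = bk.find_attractors_exhaustive(toggle)
        ent = bk.input_entropy_bounds(toggle, aset)
        assert ent["m"] == 0 and ent["mu"] == pytest.approx(0.0)
        assert ent["ck1_bound"] == pytest.approx(math.log2(3))

    def test_uniform_distribution_mu_equals_m(self):
        net = bk.parse_network("A, A\nB, B\nC, A | B\n")
        aset = bk.find_attractors_exhaustive(net)
        ent = bk.input_entropy_bounds(net, aset)
        assert ent["mu"] == pytest.approx(ent["m"])


class TestUnionCK:
    def test_single_attractor_empty(self):
        net = bk.parse_network("A, !A\n")
        aset = bk.find_attractors_exhaustive(net)
        assert bk.union_ck(net, aset) == set()

    def test_copy_network(self, copy2):
        aset = bk.find_attractors_exhaustive(copy2)
        assert bk.union_ck(copy2, aset) == {"A"}

    def test_toggle_deterministic(self, toggle):
        aset = bk.find_attractors_exhaustive(toggle)
        # both fixed points choose {A} under the lexicographic tie-break
        assert bk.union_ck(toggle, aset) == {"A"}


class TestSummary:
    def test_summary_identities(self):
        records = []
        for seed in range(8):
            net = random_networks(1, 8, seed0=700 + seed)[0]
            aset = bk.find_attractors_exhaustive(net)
            s = bk.network_summary(net, aset)
            assert aset.r >= 2 ** s["m"]
            if s["mean_ck1"] is not None and s["mean_w1"] is not None:
                assert s["mean_ck1"] == pytest.approx(s["m"] + s["mean_w1"])
            records.append(s)
        df = bk.scaling_summary(records)
        assert {"r", "m", "mu", "mean_ck", "mean_ck1"} <= set(df.columns)
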