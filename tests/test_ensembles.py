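"""Random network ensembles, projective plane, random-map fixed points."""

import math

import numpy as np
import pytest

import boolck as bk


class TestPK:
    def test_all_on_bias_gives_all_on_fixed_point(self):
        net = bk.generate_pk(8, 2, 1.0, seed=0)
        assert net.step((1 << 8) - 1) == (1 << 8) - 1

    def test_all_off_bias_gives_all_off_fixed_point(self):
        net = bk.generate_pk(8, 2, 0.0, seed=0)
        assert net.step(0) == 0

    def test_reproducible_given_seed(self):
        a = bk.generate_pk(10, 2, 0.5, seed=11)
        b = bk.generate_pk(10, 2, 0.5, seed=11)
        assert a.to_bnet() == b.to_bnet()
        assert a.to_bnet() != bk.generate_pk(10, 2, 0.5, seed=12).to_bnet()

    def test_truth_table_bias_within_binomial_ci(self):
        """Mean fraction of 1 outputs over 100 seeds ~ p_on = 0.5."""
        ones = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            inputs = [sorted(rng.choice(10, size=2, replace=False).tolist())
                      for _ in range(10)]
            bits = rng.random((10, 4)) < 0.5
            ones += bits.sum()
            total += bits.size
        # direct construction draws n*2^K bits per net; 3-sigma binomial CI
        frac = ones / total
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / total)

    def test_generated_bias_matches_raw_draws(self):
        """The network's stored tables reproduce the generator's raw draws
        (same seed, same consumption order) before essential reduction."""
        net = bk.generate_pk(6, 2, 0.3, seed=42)
        rng = np.random.default_rng(42)
        for i in range(6):
            inputs = sorted(rng.choice(6, size=2, replace=False).tolist())
            bits = (rng.random(4) < 0.3).astype(int)
            for idx in range(4):
                state = (((idx >> 0) & 1) << inputs[0]) | (((idx >> 1) & 1) << inputs[1])
                assert net.node_output(i, state) == bits[idx]


class TestThreshold:
    @pytest.mark.parametrize("seed", range(25))
    def test_zero_threshold_all_off_fixed_point(self, seed):
        net = bk.generate_threshold(10, 3, 0.3, "zero", seed=seed)
        assert net.step(0) == 0

    def test_isolated_node_is_input(self):
        # d=0: no edges at all, every node ties at its threshold
        net = bk.generate_threshold(5, 0, 0.5, "zero", seed=1)
        assert bk.input_nodes(net) == set(net.node_names)

    def test_update_rule_matches_threshold_semantics(self):
        """Independent re-evaluation of the signed-sum rule on random states."""
        for mode in ("zero", "balanced"):
            net = bk.generate_threshold(9, 3, 0.4, mode, seed=17)
            adj = net.meta["adjacency"]  # {(source, target): sign}
            rng = np.random.default_rng(0)
            for state in rng.integers(0, 1 << 9, size=200):
                state = int(state)
                nxt = net.step(state)
                for i in range(9):
                    s = sum(sign * ((state >> j) & 1)
                            for (j, tgt), sign in adj.items() if tgt == i)
                    twice_tau = (0 if mode == "zero" else
                                 sum(sign for (j, tgt), sign in adj.items()
                                     if tgt == i))
                    if 2 * s > twice_tau:
                        expect = 1
                    elif 2 * s < twice_tau:
                        expect = 0
                    else:
                        expect = (state >> i) & 1
                    assert (nxt >> i) & 1 == expect

    def test_mean_in_degree_matches_d(self):
        """Edge count over 200 seeds within a 3-sigma binomial interval."""
        edges = 0
        trials = 0
        for seed in range(200):
            net = bk.generate_threshold(10, 3, 0.5, "zero", seed=seed)
            edges += len(net.meta["adjacency"])
            trials += 10 * 9
        p = 3 / 9
        assert abs(edges / trials - p) < 3 * math.sqrt(p * (1 - p) / trials)

    def test_reproducible(self):
        a = bk.generate_threshold(8, 2, 0.5, "balanced", seed=3)
        b = bk.generate_threshold(8, 2, 0.5, "balanced", seed=3)
        assert a.to_bnet() == b.to_bnet()


class TestRandomVectors:
    def test_full_family_is_all_tuples(self):
        fam = bk.random_vector_family(3, 8, seed=0)
        assert {m.values for m in fam.members} == \
            {tuple((c >> b) & 1 for b in range(3)) for c in range(8)}

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            bk.random_vector_family(3, 9, seed=0)

    def test_distinct_and_reproducible(self):
        fam1 = bk.random_vector_family(12, 30, seed=4)
        fam2 = bk.random_vector_family(12, 30, seed=4)
        assert [m.values for m in fam1.members] == [m.values for m in fam2.members]
        assert len({m.values for m in fam1.members}) == 30


class TestProjectivePlane:
    @pytest.mark.parametrize("p", [2, 3, 5, 7, 11, 13, 17])
    def test_axioms_hold(self, p):
        plane = bk.projective_plane(p)
        q = p * p + p + 1
        assert plane.q == q and plane.incidence.shape == (q, q)
        # axioms re-checked through the constructor; spot-check line size
        assert (plane.incidence.sum(axis=1) == p + 1).all()

    def test_non_prime_rejected(self):
        with pytest.raises(ValueError, match="prime"):
            bk.projective_plane(4)

    def test_family_shape_and_order(self):
        fam = bk.pp_vector_family(2)
        assert fam.r == 14 and fam.n == 7
        # lines first (weight p+1), then identity rows (weight 1)
        assert all(sum(m.values) == 3 for m in fam.members[:7])
        assert all(sum(m.values) == 1 for m in fam.members[7:])

    def test_column_density(self):
        for p in (2, 3):
            fam = bk.pp_vector_family(p)
            q = p * p + p + 1
            cols = np.array([m.values for m in fam.members])
            assert (cols.sum(axis=0) == p + 2).all()
            assert cols.mean() == pytest.approx((p + 2) / (2 * q))

    @pytest.mark.parametrize("p,expect", [(2, 3.0), (3, 3.5)])
    def test_closed_form_matches_exhaustive_mean(self, p, expect):
        fam = bk.pp_vector_family(p)
        assert bk.mean_min_witness(fam) == pytest.approx(expect)
        assert bk.pp_mean_witness_closed_form(p) == pytest.approx(expect)


class TestScans:
    def test_first_prime_exceeding_log(self):
        assert bk.first_prime_exceeding_log() == (17, 614, 307)

    def test_p13_does_not_exceed(self):
        q = 13 * 13 + 13 + 1
        assert (13 + 4) / 2 < math.log2(2 * q)

    def test_real_valued_crossing(self):
        assert bk.real_valued_crossing() == 369
        # one step earlier the inequality still fails
        p = (math.sqrt(2 * 368 - 3) - 1) / 2
        assert (p + 4) / 2 <= math.log2(368)


class TestBitflip:
    def test_flip_then_flip_back_restores_mean(self):
        fam = bk.pp_vector_family(2)
        base = bk.mean_min_witness(fam)
        new, delta, perturbed = bk.bitflip_perturbation(fam, 0, 0)
        back, delta2, restored = bk.bitflip_perturbation(perturbed, 0, 0)
        assert back == pytest.approx(base)
        assert delta == pytest.approx(-delta2)

    def test_duplicate_creating_flip_rejected(self):
        fam = bk.VectorFamily.from_vectors([(0, 0), (0, 1), (1, 1)])
        with pytest.raises(ValueError, match="distinct"):
            bk.bitflip_perturbation(fam, 0, 1)


class TestRandomMap:
    def test_mean_near_one(self):
        out = bk.random_map_fixed_points(8, 4000, seed=2)
        assert abs(out["mean"] - 1.0) <= 3 * out["se"]

    def test_seed_reproducible(self):
        a = bk.random_map_fixed_points(6, 500, seed=5)
        b = bk.random_map_fixed_points(6, 500, seed=5)
        assert a == b

    def test_single_node_expectation(self):
        # n'=1: each of 2 states self-maps w.p. 1/2; mean over many maps -> 1
        out = bk.random_map_fixed_points(1, 20000, seed=8)
        assert out["mean"] == pytest.approx(1.0, abs=3 * out["se"] + 1e-9)
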