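import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_instance, unit_instance
from sdx.features import FeatureMatrix
from sdx.optimize import (
    NoResponsiveMassError,
    WeightedInstance,
    build_instance,
    enumerate_weights,
    normalize_scores,
    penalty_counts,
    set_weight,
    solve_owxtc_bruteforce,
    solve_owxtc_ilp,
)


class TestNormalizeScores:
    def test_increased(self):
        dp, rho = normalize_scores([-2, -1, 1], "increased")
        np.testing.assert_allclose(dp, [-2 / 3, -1 / 3, 1 / 3])
        np.testing.assert_allclose(rho, [-2 / 3, -1 / 3, -1 / 3])
        assert dp[dp < 0].sum() == pytest.approx(-1, abs=1e-9)

    def test_decreased(self):
        dp, rho = normalize_scores([-1, 2, 2], "decreased")
        np.testing.assert_allclose(dp, [-0.25, 0.5, 0.5])
        assert dp[dp > 0].sum() == pytest.approx(1, abs=1e-9)
        np.testing.assert_allclose(rho, [0.25, 0.5, 0.5])

    def test_unit_mass(self):
        dp, _ = normalize_scores([-1, 0], "increased")
        np.testing.assert_allclose(dp, [-1, 0])

    def test_no_responsive_mass(self):
        with pytest.raises(NoResponsiveMassError):
            normalize_scores([1.0, 2.0], "increased")


def three_feature_instance():
    fm = FeatureMatrix(["f1", "f2", "f3"], ["s1", "s2", "s3"],
                       np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int8))
    return WeightedInstance(np.array([-0.6, -0.4, 0.3]), np.array([-0.6, -0.4, -0.3]),
                            "increased", fm)


class TestSetWeight:
    def test_hand_computed_penalty(self):
        inst = three_feature_instance()
        assert set_weight(["f1", "f2"], inst) == pytest.approx(-0.4, abs=1e-12)
        assert set_weight(["f2"], inst) == pytest.approx(-1.0, abs=1e-12)

    def test_dendrix_identity_example(self):
        inst = unit_instance([[1, 1, 0], [0, 1, 1]])
        assert set_weight(["f0", "f1"], inst) == pytest.approx(2.0, abs=1e-12)  # 2*3 - 4

    def test_two_hit_exception(self):
        fm = FeatureMatrix(["TP53(I)", "TP53(O)"], ["s1", "s2"], np.array([[1, 0], [1, 0]], dtype=np.int8))
        inst = WeightedInstance(np.array([-0.5, 0.5]), np.array([-0.5, -0.5]), "increased", fm,
                                twohit_pairs=[(0, 1)])
        assert set_weight(["TP53(I)", "TP53(O)"], inst) == pytest.approx(-0.5, abs=1e-12)

    def test_two_hit_pair_autodetected(self):
        fm = FeatureMatrix(["TP53(I)", "TP53(O)", "KRAS(A)"], ["s1"],
                           np.array([[1], [1], [1]], dtype=np.int8))
        inst = build_instance(np.array([-1.0]), "increased", fm)
        assert inst.twohit_pairs == [(0, 1)]
        # same-gene I+O exempt; KRAS co-occurrence still penalized
        assert set_weight(["TP53(I)", "TP53(O)"], inst) == pytest.approx(-1.0)
        assert set_weight(["TP53(I)", "KRAS(A)"], inst) == pytest.approx(-1.0 - (-1.0) * 1)

    def test_empty_set(self):
        assert set_weight([], three_feature_instance()) == 0.0

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            set_weight(["nope"], three_feature_instance())


class TestSolvers:
    def test_ilp_prefers_exclusive_cover(self):
        inst = three_feature_instance()
        res = solve_owxtc_ilp(inst, k=2)
        assert res.feature_set == ["f2"]
        assert res.weight == pytest.approx(-1.0, abs=1e-9)
        assert res.covered_samples == ["s1", "s2"]

    def test_background_only_features_give_empty_set(self):
        fm = FeatureMatrix(["f1"], ["s1", "s2"], np.array([[0, 1]], dtype=np.int8))
        inst = WeightedInstance(np.array([-1.0, 0.5]), np.array([-1.0, -0.5]), "increased", fm)
        for solver in (solve_owxtc_ilp, solve_owxtc_bruteforce):
            res = solver(inst, k=1)
            assert res.feature_set == [] and res.weight == 0.0

    def test_bruteforce_single_feature(self):
        fm = FeatureMatrix(["f1"], ["s1", "s2"], np.array([[1, 0]], dtype=np.int8))
        inst = WeightedInstance(np.array([-1.0, 0.5]), np.array([-1.0, -0.5]), "increased", fm)
        res = solve_owxtc_bruteforce(inst, k=1)
        assert res.feature_set == ["f1"]
        assert res.weight == pytest.approx(-1.0)  # W = d' of the covered responsive sample

    def test_bruteforce_matches_ilp_on_example(self):
        inst = three_feature_instance()
        b = solve_owxtc_bruteforce(inst, k=2)
        i = solve_owxtc_ilp(inst, k=2)
        assert b.feature_set == i.feature_set
        assert b.weight == pytest.approx(i.weight, abs=1e-9)

    def test_bruteforce_optimum_beats_every_subset(self, rng):
        inst = random_instance(rng, n_max=15, m_max=12)
        res = solve_owxtc_bruteforce(inst, k=3)
        subsets, w = enumerate_weights(inst, k=3)
        if inst.direction == "increased":
            assert res.weight <= w.min() + 1e-9
        else:
            assert res.weight >= w.max() - 1e-9

    def test_budget_guard(self):
        fm = FeatureMatrix([f"f{i}" for i in range(40)], ["s1"], np.ones((40, 1), dtype=np.int8))
        inst = WeightedInstance(np.array([-1.0]), np.array([-1.0]), "increased", fm)
        with pytest.raises(ValueError, match="budget"):
            enumerate_weights(inst, k=None)

    def test_ilp_oracle_equivalence_sample(self, rng):
        for _ in range(40):
            inst = random_instance(rng)
            k = int(rng.integers(1, 5))
            b = solve_owxtc_bruteforce(inst, k)
            i = solve_owxtc_ilp(inst, k)
            assert i.weight == pytest.approx(b.weight, abs=1e-9)

    def test_ilp_weight_matches_closed_form(self, rng):
        for _ in range(10):
            inst = random_instance(rng)
            res = solve_owxtc_ilp(inst, k=3)
            assert res.weight == pytest.approx(set_weight(res.feature_set, inst), abs=1e-9)


@settings(max_examples=60, deadline=None)
@given(st.integers(2, 6), st.integers(3, 10), st.integers(0, 10**6))
def test_dendrix_reduction_identity(m, n, seed):
    """With d' = rho = 1, W(M) = 2|Gamma(M)| - sum_m |Gamma(m)| for every M."""
    a = (np.random.default_rng(seed).random((m, n)) < 0.4).astype(np.int8)
    inst = unit_instance(a)
    subsets, w = enumerate_weights(inst, k=None)
    for sub, wv in zip(subsets, w):
        if not sub:
            assert wv == 0.0
            continue
        gamma = (a[list(sub)].sum(axis=0) > 0).sum()
        expected = 2 * gamma - a[list(sub)].sum()
        assert wv == pytest.approx(expected, abs=1e-12)


class TestObjectiveStructure:
    def test_per_sample_contributions(self, rng):
        """Covered responsive samples contribute (2 - c_j) d'_j; covered
        background samples contribute c_j |d'_j| (increased direction)."""
        for _ in range(20):
            inst = random_instance(rng, twohit_prob=0.0)
            if inst.direction != "increased":
                continue
            m = inst.features.m
            sub = [i for i in range(m) if rng.random() < 0.5]
            raw, c = penalty_counts(inst, sub)
            dp = inst.d_prime
            contrib = np.where(
                raw > 0, np.where(dp < 0, (2 - c) * dp, c * np.abs(dp)), 0.0
            )
            assert set_weight(sub, inst) == pytest.approx(contrib.sum(), abs=1e-9)

    def test_exclusive_responsive_coverage_improves(self, rng):
        for _ in range(20):
            inst = random_instance(rng, m_max=6, twohit_prob=0.0)
            resp = inst.responsive_mask
            uncovered_resp = np.flatnonzero(resp)
            if uncovered_resp.size == 0:
                continue
            # append a synthetic feature covering exactly one uncovered responsive sample
            extra = np.zeros(inst.features.n, dtype=np.int8)
            extra[uncovered_resp[0]] = 1
            fm2 = FeatureMatrix(
                inst.features.feature_ids + ["extra"],
                inst.features.sample_ids,
                np.vstack([inst.features.a, extra]),
            )
            inst2 = WeightedInstance(inst.d_prime, inst.rho, inst.direction, fm2, inst.twohit_pairs)
            base = [i for i in range(inst.features.m) if not inst.features.a[i, uncovered_resp[0]]]
            w_without = set_weight(base, inst2)
            w_with = set_weight(base + [inst.features.m], inst2)
            if inst.direction == "increased":
                assert w_with < w_without - 1e-12
            else:
                assert w_with > w_without + 1e-12

    def test_background_only_feature_never_improves(self, rng):
        for _ in range(20):
            inst = random_instance(rng, m_max=6, twohit_prob=0.0)
            bg = ~inst.responsive_mask
            if not bg.any():
                continue
            extra = np.zeros(inst.features.n, dtype=np.int8)
            extra[np.flatnonzero(bg)] = 1
            fm2 = FeatureMatrix(
                inst.features.feature_ids + ["extra"], inst.features.sample_ids,
                np.vstack([inst.features.a, extra]),
            )
            inst2 = WeightedInstance(inst.d_prime, inst.rho, inst.direction, fm2, inst.twohit_pairs)
            sub = [i for i in range(inst.features.m) if rng.random() < 0.4]
            w0 = set_weight(sub, inst2)
            w1 = set_weight(sub + [inst.features.m], inst2)
            if inst.direction == "increased":
                assert w1 >= w0 - 1e-12
            else:
                assert w1 <= w0 + 1e-12
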