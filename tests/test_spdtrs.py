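import numpy as np
import pytest

from roughpnn.granulation import GranuleStats
from roughpnn.spdtrs import (
    DegenerateThresholds,
    assign_regions,
    bayes_risk,
    decision_thresholds,
    exhaustive_reduct_oracle,
    loss_matrix,
    reduce_attributes,
)

from conftest import make_table


def brute_risk(X, y, delta, xi, classes=None):
    """Independent plain-loop evaluation of the overall Bayes risk."""
    n = len(y)
    classes = classes if classes is not None else sorted(set(y))
    total = 0.0
    for cls in classes:
        n_X = sum(1 for v in y if v == cls)
        n_Xc = n - n_X
        for i in range(n):
            mem = [
                j for j in range(n)
                if np.linalg.norm(X[i] - X[j]) <= delta + 1e-12
            ]
            k = len(mem)
            k_X = sum(1 for j in mem if y[j] == cls)
            p, sx, sc = k_X / k, k_X / n_X, (k - k_X) / n_Xc
            lbp = max(sx * (p - xi), 0.0)
            lbn = max(sc * (1 - p - xi), 0.0)
            lpn, lnp = sc, sx
            dpn, dnp = lpn - lbn, lnp - lbp
            da, db = dpn + lbp, lbn + dnp
            ok = da > 0 and db > 0 and dpn >= 0 and dnp >= 0
            if ok:
                a, b = dpn / da, lbn / db
                ok = not (b > a)
            r_pos, r_bnd, r_neg = (1 - p) * lpn, p * lbp + (1 - p) * lbn, p * lnp
            if ok:
                term = r_pos if p >= a else (r_neg if p <= b else r_bnd)
            else:
                term = r_pos if r_pos <= r_neg else r_neg
            total += term
    return total


class TestLossMatrix:
    def test_accept_and_reject_corner_losses_vanish(self):
        lm = loss_matrix(GranuleStats(p_x=0.3, s_x=0.2, s_c=0.7), xi=0.1)
        assert lm.lambda_pp == 0.0
        assert lm.lambda_nn == 0.0

    def test_direct_substitution(self):
        lm = loss_matrix(GranuleStats(p_x=0.6, s_x=0.5, s_c=0.25), xi=0.25)
        assert lm.lambda_bp == pytest.approx(0.175)
        assert lm.lambda_bn == pytest.approx(0.0375)
        assert lm.lambda_pn == pytest.approx(0.25)
        assert lm.lambda_np == pytest.approx(0.5)

    def test_vanishing_factor_at_p_equal_xi(self):
        lm = loss_matrix(GranuleStats(p_x=0.25, s_x=0.5, s_c=0.5), xi=0.25)
        assert lm.lambda_bp == 0.0

    def test_negative_factors_clamped(self):
        lm = loss_matrix(GranuleStats(p_x=0.1, s_x=0.5, s_c=0.5), xi=0.25)
        assert lm.lambda_bp == 0.0  # p < xi
        lm = loss_matrix(GranuleStats(p_x=0.9, s_x=0.5, s_c=0.5), xi=0.25)
        assert lm.lambda_bn == 0.0  # 1 - p < xi

    def test_nonpositive_xi_rejected(self):
        with pytest.raises(ValueError):
            loss_matrix(GranuleStats(p_x=0.5, s_x=0.5, s_c=0.5), xi=0.0)

    def test_xi_above_range_warns(self):
        with pytest.warns(UserWarning, match="recommended range"):
            loss_matrix(GranuleStats(p_x=0.5, s_x=0.5, s_c=0.5), xi=0.6)


class TestDecisionThresholds:
    def test_hand_arithmetic(self):
        lm = loss_matrix(GranuleStats(p_x=0.6, s_x=0.5, s_c=0.25), xi=0.25)
        alpha, beta = decision_thresholds(lm)
        assert alpha == pytest.approx(0.2125 / 0.3875)
        assert beta == pytest.approx(0.0375 / 0.3625)
        assert beta < alpha

    def test_symmetric_losses_sum_to_one(self):
        # lambda_PN == lambda_NP and lambda_BP == lambda_BN
        lm = loss_matrix(GranuleStats(p_x=0.5, s_x=0.4, s_c=0.4), xi=0.2)
        assert lm.lambda_pn == lm.lambda_np and lm.lambda_bp == lm.lambda_bn
        alpha, beta = decision_thresholds(lm)
        assert alpha + beta == pytest.approx(1.0)

    def test_zero_denominator_degenerates(self):
        # p < xi clamps lambda_BP to lambda_PP = 0, and s_c = 0 kills the
        # lambda_PN - lambda_BN numerator: alpha's denominator is 0
        lm = loss_matrix(GranuleStats(p_x=0.1, s_x=0.5, s_c=0.0), xi=0.25)
        assert lm.lambda_bp == lm.lambda_pp
        with pytest.raises(DegenerateThresholds):
            decision_thresholds(lm)


class TestAssignRegions:
    def test_separated_classes_have_empty_boundary(self):
        t = make_table([[0.0], [0.05], [0.9], [0.95]], ["a", "a", "b", "b"])
        r = assign_regions(t, [1], 0.1, 0.25, target_class="a")
        assert r.pos == frozenset({0, 1})
        assert r.neg == frozenset({2, 3})
        assert r.bnd == frozenset()

    def test_regions_partition_universe(self, random_table):
        r = assign_regions(random_table, [1, 2, 3], 0.3, 0.25, target_class="a")
        assert r.pos | r.bnd | r.neg == frozenset(range(random_table.n_samples))

    def test_matches_brute_force_reimplementation(self):
        rng = np.random.default_rng(17)
        t = make_table(rng.uniform(size=(12, 3)), ["a"] * 5 + ["b"] * 7)
        r = assign_regions(t, [1, 2], 0.25, 0.2, target_class="a")
        # recompute region of every sample with plain loops
        X = t.restrict([1, 2])
        y = list(t.labels)
        for i in range(12):
            mem = [j for j in range(12) if np.linalg.norm(X[i] - X[j]) <= 0.25 + 1e-12]
            k = len(mem)
            k_X = sum(1 for j in mem if y[j] == "a")
            p, sx, sc = k_X / k, k_X / 5, (k - k_X) / 7
            lbp = max(sx * (p - 0.2), 0.0)
            lbn = max(sc * (1 - p - 0.2), 0.0)
            dpn, dnp = sc - lbn, sx - lbp
            da, db = dpn + lbp, lbn + dnp
            ok = da > 0 and db > 0 and dpn >= 0 and dnp >= 0
            if ok:
                a, b = dpn / da, lbn / db
                ok = not (b > a)
            if ok:
                want = "pos" if p >= a else ("neg" if p <= b else "bnd")
            else:
                want = "pos" if (1 - p) * sc <= p * sx else "neg"
            assert i in getattr(r, want), f"sample {i}"


class TestBayesRisk:
    def test_consistent_table_has_zero_risk(self):
        t = make_table([[0.0], [0.05], [0.9], [0.95]], ["a", "a", "b", "b"])
        assert bayes_risk(t, [1], 0.1, 0.25) == 0.0

    def test_hand_worked_four_sample_value(self, four_sample_table):
        # one mixed granule per class contributes 1/6 (POS) + 1/8 (BND)
        risk = bayes_risk(four_sample_table, [1], 0.15, 0.25)
        assert risk == pytest.approx(7 / 12, rel=1e-12)

    def test_matches_independent_loop_oracle(self):
        rng = np.random.default_rng(23)
        for trial in range(5):
            n = int(rng.integers(6, 16))
            k = int(rng.integers(1, 4))
            labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
            t = make_table(rng.uniform(size=(n, k)), labels)
            B = list(range(1, k + 1))
            got = bayes_risk(t, B, 0.2, 0.25)
            want = brute_risk(t.restrict(B), labels, 0.2, 0.25)
            assert got == pytest.approx(want, rel=1e-10)

    def test_risk_is_nonnegative(self):
        rng = np.random.default_rng(31)
        for trial in range(5):
            t = make_table(rng.uniform(size=(10, 2)), ["a"] * 5 + ["b"] * 5)
            assert bayes_risk(t, [1, 2], 0.3, 0.25) >= 0.0


class TestReduction:
    def test_informative_attribute_beats_noise(self):
        rng = np.random.default_rng(3)
        sep = np.concatenate([np.linspace(0, 0.1, 10), np.linspace(0.9, 1.0, 10)])
        noise = rng.uniform(size=20)
        t = make_table(np.column_stack([sep, noise]), ["a"] * 10 + ["b"] * 10)
        greedy = reduce_attributes(t, 0.25, 0.15)
        oracle = exhaustive_reduct_oracle(t, 0.25, 0.15)
        assert greedy.selected_B == (1,)
        assert oracle.selected_B == (1,)

    def test_duplicated_attribute_not_selected_twice(self):
        # one attribute whose granules are already pure: duplicating it
        # cannot change any risk, so a single copy is kept
        a = np.concatenate([np.linspace(0, 0.2, 10), np.linspace(0.8, 1.0, 10)])
        t = make_table(np.column_stack([a, a]), ["a"] * 10 + ["b"] * 10)
        res = reduce_attributes(t, 0.25, 0.15)
        assert res.selected_B == (1,)

    def test_trace_and_conditions(self, random_table):
        res = reduce_attributes(random_table, 0.25, 0.2)
        assert res.selected_B
        assert res.risk_B <= res.risk_C + 1e-9
        # accepted forward steps never raise the risk outside plateau escape
        risks = [r for _, r in res.trace]
        assert risks[-1] == pytest.approx(res.risk_B)

    def test_single_attribute_table_rejected(self):
        t = make_table([[0.1], [0.9]], ["a", "b"])
        with pytest.raises(ValueError, match="2 attributes"):
            reduce_attributes(t, 0.25, 0.15)


class TestExhaustiveOracle:
    def test_consistent_redundant_pair_reduces_to_singleton(self):
        a = np.concatenate([np.linspace(0, 0.2, 8), np.linspace(0.8, 1.0, 8)])
        t = make_table(np.column_stack([a, a * 0.9]), ["a"] * 8 + ["b"] * 8)
        res = exhaustive_reduct_oracle(t, 0.25, 0.15)
        assert res.is_reduct
        assert res.selected_B == (1,)  # tie between pure singletons: lowest label

    def test_refuses_large_tables(self):
        rng = np.random.default_rng(7)
        t = make_table(rng.uniform(size=(5, 11)), ["a", "a", "b", "b", "b"])
        with pytest.raises(ValueError, match="exhaustive"):
            exhaustive_reduct_oracle(t, 0.25, 0.15, max_attributes=11)

    def test_oracle_admits_greedy_on_random_tables(self):
        """Greedy attains condition (1) and one-deletion minimality whenever
        the oracle finds any admissible subset, and never beats the oracle."""
        rng = np.random.default_rng(13)
        for trial in range(8):
            n = int(rng.integers(10, 30))
            k = int(rng.integers(2, 6))
            n_a = int(rng.integers(3, n - 3))
            labels = ["a"] * n_a + ["b"] * (n - n_a)
            t = make_table(rng.uniform(size=(n, k)), labels)
            oracle = exhaustive_reduct_oracle(t, 0.25, 0.2)
            greedy = reduce_attributes(t, 0.25, 0.2)
            if oracle.is_reduct:
                assert greedy.is_reduct
                assert greedy.risk_B <= greedy.risk_C + 1e-9
                assert greedy.risk_B >= oracle.risk_B - 1e-9
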