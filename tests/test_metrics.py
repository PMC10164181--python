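import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_table, table_from_correctness
from shiftbench.metrics import (
    F1UncertaintyCurve,
    adp,
    adp_bootstrap_ci,
    confidence,
    ece,
    f1_retention_curve,
    f1_uncertainty_curve,
    micro_f1,
    percent_decrease,
    samplewise_calibration_error,
    shannon_entropy,
    uncertainty_scores,
)
from shiftbench.tables import PredictionTable

# ---------------------------------------------------------------------------
# independent brute-force oracles (plain Python loops, no shared code)


def f1_auc_brute(table, uncertainty):
    n = table.n
    order = sorted(range(n), key=lambda i: (-uncertainty[i], i))
    preds = list(table.predicted_label)
    true = list(table.true_label)
    points = []
    for step in range(n):
        f1 = sum(p == t for p, t in zip(preds, true)) / n
        points.append(((n - step) / n, f1))
        i = order[step]
        preds[i] = true[i]
    points.append((0.0, 1.0))
    area = 0.0
    for (x1, y1), (x2, y2) in zip(points[:-1], points[1:]):
        area += (x1 - x2) * (y1 + y2) / 2.0
    return area


def adp_brute(dev_table, prod_table, u_dev, u_prod, f1_min, f1_max, step):
    n_dev = dev_table.n
    order = sorted(range(n_dev), key=lambda i: (-u_dev[i], i))
    dev_correct = list(dev_table.correct)
    dev_points = []
    for s in range(n_dev):
        retained = order[s:]
        f1 = sum(dev_correct[i] for i in retained) / len(retained)
        dev_points.append((u_dev[order[s]], f1))
    if max(f1 for _, f1 in dev_points) < f1_max:
        raise ValueError("development curve never attains the top of the range")
    prod_correct = list(prod_table.correct)
    grid = np.linspace(f1_min, f1_max, int(round((f1_max - f1_min) / step)) + 1)
    decreases = []
    for f1_nom in grid:
        u_accept = max(thr for thr, f1 in dev_points if f1 >= f1_nom)
        accepted = [i for i in range(prod_table.n) if u_prod[i] <= u_accept]
        if not accepted:
            raise ValueError("empty production retained set")
        f1_prod = sum(prod_correct[i] for i in accepted) / len(accepted)
        decreases.append((f1_nom - f1_prod) * 100.0)
    return sum(decreases) / len(decreases)


# ---------------------------------------------------------------------------
# pointwise statistics


class TestPointwiseStats:
    def test_confidence_examples(self):
        probs = np.array([[0.2, 0.5, 0.3]])
        assert confidence(probs)[0] == 0.5
        assert confidence(np.full((1, 5), 0.2))[0] == pytest.approx(0.2)
        assert confidence(np.array([[1.0, 0.0, 0.0]]))[0] == 1.0

    def test_confidence_rejects_nonstochastic(self):
        with pytest.raises(ValueError):
            confidence(np.array([[0.5, 0.6]]))

    def test_entropy_examples(self):
        assert shannon_entropy(np.array([[1.0, 0.0, 0.0]]))[0] == 0.0
        assert shannon_entropy(np.full((1, 3), 1 / 3))[0] == pytest.approx(np.log(3))
        assert shannon_entropy(np.array([[0.5, 0.5, 0.0]]))[0] == pytest.approx(np.log(2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 8), st.integers(1, 30))
    def test_entropy_bounds_random(self, seed, k, n):
        """0 <= H <= ln K, with the extremes at one-hot and uniform rows."""
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(k), size=n)
        h = shannon_entropy(probs)
        assert np.all(h >= 0.0)
        assert np.all(h <= np.log(k) + 1e-12)

    def test_micro_f1(self):
        assert micro_f1(["a", "b", "c", "d"], ["a", "b", "c", "x"]) == 0.75
        assert micro_f1(["a", "a"], ["a", "a"]) == 1.0
        # unseen-class samples can never be predicted correctly
        assert micro_f1(["a", "b"], ["UNSEEN1", "UNSEEN2"]) == 0.0
        with pytest.raises(ValueError):
            micro_f1([], [])

    def test_percent_decrease(self):
        # ADP-style: reference is the worse (higher) value
        assert percent_decrease(4.28, 9.24, "lower_is_better") == pytest.approx(
            53.68, abs=0.005
        )
        # F1-AUC-style: reference is the better (higher) value
        assert percent_decrease(93.67, 93.25, "higher_is_better") == pytest.approx(
            0.45, abs=0.005
        )
        assert percent_decrease(5.0, 5.0, "lower_is_better") == 0.0
        # swapping roles flips the sign
        a = percent_decrease(4.28, 9.24, "lower_is_better")
        b = percent_decrease(9.24, 4.28, "lower_is_better")
        assert a > 0 > b
        with pytest.raises(ValueError):
            percent_decrease(1.0, 0.0, "lower_is_better")


# ---------------------------------------------------------------------------
# calibration


class TestECE:
    def test_perfect_confidence_perfect_accuracy(self):
        res = ece(np.ones(5), np.ones(5, dtype=bool), 10)
        assert res.ece == 0.0

    def test_single_occupied_bin(self):
        # 10 samples, confidence 0.9, 6 correct: |0.6 - 0.9| = 0.3
        conf = np.full(10, 0.9)
        correct = np.array([True] * 6 + [False] * 4)
        res = ece(conf, correct, 10)
        assert res.ece == pytest.approx(0.3, abs=1e-12)

    def test_two_occupied_bins(self):
        # 0.4*|0.75-0.95| + 0.6*|0.5-0.55| = 0.11
        conf = np.array([0.95] * 4 + [0.55] * 6)
        correct = np.array([True] * 3 + [False] * 1 + [True] * 3 + [False] * 3)
        res = ece(conf, correct, 10)
        assert res.ece == pytest.approx(0.11, abs=1e-12)

    def test_counts_partition_samples(self):
        rng = np.random.default_rng(7)
        conf = rng.random(100)
        res = ece(conf, rng.random(100) < conf, 10)
        assert res.counts.sum() == 100
        assert 0.0 <= res.ece <= 1.0

    def test_bin_accuracy_matching_confidence_gives_zero(self):
        # every bin's accuracy equals its (constant) mean confidence
        conf = np.array([0.8] * 10 + [0.5] * 10)
        correct = np.array([True] * 8 + [False] * 2 + [True] * 5 + [False] * 5)
        assert ece(conf, correct, 10).ece == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 20))
    def test_ece_bounded(self, seed, m_bins):
        rng = np.random.default_rng(seed)
        conf = rng.random(50)
        correct = rng.random(50) < 0.5
        assert 0.0 <= ece(conf, correct, m_bins).ece <= 1.0


class TestSamplewiseCalibration:
    def test_perfectly_calibrated_bin_gives_zeros(self):
        # constant confidence 0.8 with 4/5 correct: bin accuracy 0.8, gap 0
        probs = np.tile([0.8, 0.2], (5, 1))
        correct = [True] * 4 + [False]
        t = PredictionTable(
            sample_id=[f"s{i}" for i in range(5)],
            true_label=["A" if c else "B" for c in correct],
            probs=probs,
            classes=["A", "B"],
        )
        errs = samplewise_calibration_error(t, 10)
        np.testing.assert_allclose(errs, 0.0, atol=1e-12)

    def test_single_bin_constant_gap(self):
        # confidence 0.9, 6/10 correct: every sample |0.9 - 0.6| = 0.3
        probs = np.tile([0.9, 0.1], (10, 1))
        correct = [True] * 6 + [False] * 4
        t = PredictionTable(
            sample_id=[f"s{i}" for i in range(10)],
            true_label=["A" if c else "B" for c in correct],
            probs=probs,
            classes=["A", "B"],
        )
        np.testing.assert_allclose(samplewise_calibration_error(t, 10), 0.3, atol=1e-12)

    def test_mean_recovers_ece_for_one_sided_bins(self):
        """When each bin's confidences sit on one side of its accuracy, the
        sample mean of the per-sample errors equals the ECE."""
        rows, correct = [], []
        for conf, n, n_correct in [(0.95, 8, 4), (0.62, 5, 2), (0.35, 4, 0)]:
            rows += [[conf, 1 - conf]] * n
            correct += [True] * n_correct + [False] * (n - n_correct)
        t = PredictionTable(
            sample_id=[f"s{i}" for i in range(len(rows))],
            true_label=["A" if c else "B" for c in correct],
            probs=np.array(rows),
            classes=["A", "B"],
        )
        errs = samplewise_calibration_error(t, 10)
        res = ece(t.confidence, t.correct, 10)
        assert np.mean(errs) == pytest.approx(res.ece, abs=1e-12)


# ---------------------------------------------------------------------------
# retention curve


class TestRetentionCurve:
    def test_all_correct_curve_is_flat_one(self):
        t = table_from_correctness([True] * 6)
        curve = f1_retention_curve(t, t.entropy)
        assert np.all(curve.f1 == 1.0)
        assert curve.auc == pytest.approx(1.0, abs=1e-12)

    def test_two_most_uncertain_wrong(self):
        # replacement order: the two wrong predictions first
        u = np.array([3.0, 2.0, 1.0, 0.5])
        t = table_from_correctness([False, False, True, True], u)
        curve = f1_retention_curve(t, u)
        np.testing.assert_allclose(curve.retention[:4], [1.0, 0.75, 0.5, 0.25])
        np.testing.assert_allclose(curve.f1[:4], [0.5, 0.75, 1.0, 1.0])
        assert curve.retention[-1] == 0.0 and curve.f1[-1] == 1.0
        assert curve.auc == pytest.approx(f1_auc_brute(t, u), abs=1e-15)

    def test_tied_uncertainty_permutations_equal_auc(self):
        import itertools

        correct = [True, False, True, False, True]
        probs = np.tile([0.6, 0.4], (5, 1))
        aucs = set()
        for perm in itertools.permutations(range(5)):
            pattern = [correct[i] for i in perm]
            if pattern != correct:
                continue
            t = PredictionTable(
                sample_id=[f"s{i}" for i in range(5)],
                true_label=["A" if c else "B" for c in pattern],
                probs=probs,
                classes=["A", "B"],
            )
            aucs.add(round(f1_retention_curve(t, t.entropy).auc, 15))
        assert len(aucs) == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_under_replacement(self, seed):
        """Replacing predictions with ground truth can never lower F1."""
        rng = np.random.default_rng(seed)
        t = random_table(rng, n=int(rng.integers(3, 30)))
        curve = f1_retention_curve(t, t.entropy)
        assert np.all(np.diff(curve.f1) >= -1e-15)
        assert 0.0 <= curve.auc <= 1.0

    def test_matches_bruteforce_on_200_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            t = random_table(rng, n=20, k=4)
            u = t.entropy
            assert f1_retention_curve(t, u).auc == pytest.approx(
                f1_auc_brute(t, u), abs=1e-12
            )


# ---------------------------------------------------------------------------
# discard curve and ADP


class TestF1UncertaintyCurve:
    def test_all_correct(self):
        t = table_from_correctness([True] * 5)
        curve = f1_uncertainty_curve(t, t.entropy)
        assert np.all(curve.f1 == 1.0)
        assert np.all(np.diff(curve.thresholds) <= 0)
        assert list(curve.n_retained) == [5, 4, 3, 2, 1]

    def test_single_wrong_most_uncertain(self):
        u = np.array([5.0, 2.0, 1.0])
        t = table_from_correctness([False, True, True], u)
        curve = f1_uncertainty_curve(t, u)
        np.testing.assert_allclose(curve.f1, [2 / 3, 1.0, 1.0])

    def test_row_shuffle_invariance(self, rng):
        t = random_table(rng, n=15, k=3)
        perm = rng.permutation(15)
        shuffled = t.subset(perm)
        a = f1_uncertainty_curve(t, t.entropy)
        b = f1_uncertainty_curve(shuffled, shuffled.entropy)
        np.testing.assert_allclose(a.thresholds, b.thresholds, atol=1e-15)
        np.testing.assert_allclose(a.f1, b.f1, atol=1e-15)


def _fine_grained_table(n=2000, n_wrong=50, seed=0):
    """Large table whose discard curve sweeps smoothly through [0.975, 1.0]."""
    rng = np.random.default_rng(seed)
    correct = np.ones(n, dtype=bool)
    wrong = rng.choice(n // 2, size=n_wrong, replace=False)  # errors among most uncertain half
    correct[wrong] = False
    u = np.linspace(2.0, 0.01, n)  # row i has the i-th largest uncertainty
    return table_from_correctness(correct, u), u


class TestADP:
    def test_identical_tables_give_near_zero(self):
        """With dev == prod the transferred threshold recovers (to curve
        granularity) the nominal F1, so the mean decrease vanishes."""
        t, u = _fine_grained_table()
        dev = f1_uncertainty_curve(t, u, "development")
        prod = f1_uncertainty_curve(t, u, "production")
        res = adp(dev, prod)
        assert res.adp <= 1e-9
        assert abs(res.adp) < 0.1  # percentage points; 1/n granularity

    def test_constant_production_f1_closed_form(self):
        dev = F1UncertaintyCurve(
            thresholds=np.array([0.9, 0.5]),
            f1=np.array([0.98, 1.0]),
            n_retained=np.array([2, 1]),
        )
        prod = F1UncertaintyCurve(
            thresholds=np.linspace(0.01, 0.001, 10),
            f1=np.full(10, 0.95),
            n_retained=np.arange(10, 0, -1),
            flavour="production",
        )
        res = adp(dev, prod)
        # mean of (F1_nom - 0.95)*100 over the arithmetic grid [0.975, 0.990]
        assert res.adp == pytest.approx(3.25, abs=1e-9)

    def test_matches_bruteforce_on_200_random_tables(self):
        rng = np.random.default_rng(77)
        checked = 0
        for _ in range(200):
            dev_t = random_table(rng, n=20, k=4, force_most_certain_correct=True)
            prod_t = random_table(rng, n=20, k=4)
            u_dev, u_prod = dev_t.entropy, prod_t.entropy
            dev = f1_uncertainty_curve(dev_t, u_dev, "development")
            prod = f1_uncertainty_curve(prod_t, u_prod, "production")
            try:
                expected = adp_brute(dev_t, prod_t, u_dev, u_prod, 0.975, 0.990, 1e-5)
            except ValueError:
                with pytest.raises(ValueError):
                    adp(dev, prod)
                continue
            assert adp(dev, prod).adp == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked >= 100  # most toy tables admit the full grid

    def test_toy_dev_curve_against_bruteforce(self, rng):
        prod_t = random_table(rng, n=10, k=3)
        u_prod = prod_t.entropy
        prod = f1_uncertainty_curve(prod_t, u_prod, "production")
        dev = F1UncertaintyCurve(
            thresholds=np.array([2.0, 1.2, 1.0]),
            f1=np.array([0.97, 0.98, 1.0]),
            n_retained=np.array([3, 2, 1]),
        )
        grid = np.linspace(0.975, 0.990, 1501)
        decreases = []
        for f1_nom in grid:
            u_accept = max(
                thr for thr, f1 in zip(dev.thresholds, dev.f1) if f1 >= f1_nom
            )
            accepted = [i for i in range(10) if u_prod[i] <= u_accept]
            f1_prod = sum(prod_t.correct[i] for i in accepted) / len(accepted)
            decreases.append((f1_nom - f1_prod) * 100)
        assert adp(dev, prod).adp == pytest.approx(np.mean(decreases), abs=1e-12)

    def test_monotone_rescaling_invariance(self):
        t_dev, u_dev = _fine_grained_table(seed=1)
        t_prod, u_prod = _fine_grained_table(n_wrong=120, seed=2)
        base = adp(
            f1_uncertainty_curve(t_dev, u_dev, "development"),
            f1_uncertainty_curve(t_prod, u_prod, "production"),
        ).adp
        for transform in (np.exp, lambda x: 3 * x + 1, np.sqrt):
            rescaled = adp(
                f1_uncertainty_curve(t_dev, transform(u_dev), "development"),
                f1_uncertainty_curve(t_prod, transform(u_prod), "production"),
            ).adp
            assert rescaled == pytest.approx(base, abs=1e-12)

    def test_unreachable_top_of_range_is_an_error(self):
        # most-certain prediction wrong: curve peaks at F1 = 0.5
        u = np.arange(4.0)
        t = table_from_correctness([False, True, False, True], u)
        dev = f1_uncertainty_curve(t, u, "development")
        prod = f1_uncertainty_curve(t, u, "production")
        with pytest.raises(ValueError, match="sufficiently large"):
            adp(dev, prod)

    def test_empty_production_set_is_an_error(self):
        t_dev, u_dev = _fine_grained_table()
        dev = f1_uncertainty_curve(t_dev, u_dev, "development")
        # every production uncertainty above every dev threshold
        prod = F1UncertaintyCurve(
            thresholds=np.array([99.0, 98.0]),
            f1=np.array([1.0, 1.0]),
            n_retained=np.array([2, 1]),
            flavour="production",
        )
        with pytest.raises(ValueError, match="empty production"):
            adp(dev, prod)


class TestADPBootstrap:
    def test_zero_variance_production_gives_degenerate_ci(self):
        t_dev, u_dev = _fine_grained_table()
        # production: every prediction correct with identical uncertainty ->
        # every resample yields the same (flat, perfect) curve and adp
        probs = np.vstack([np.tile([0.9, 0.1], (20, 1)), np.tile([0.1, 0.9], (20, 1))])
        prod = PredictionTable(
            sample_id=[f"p{i}" for i in range(40)],
            true_label=["A"] * 20 + ["B"] * 20,
            probs=probs,
            classes=["A", "B"],
        )
        low, high = adp_bootstrap_ci(t_dev, prod, n_boot=200, seed=0)
        assert low == pytest.approx(high, abs=1e-12)

    def test_ci_brackets_point_estimate_and_is_deterministic(self):
        t_dev, u_dev = _fine_grained_table(seed=3)
        t_prod, _ = _fine_grained_table(n=400, n_wrong=60, seed=4)
        point = adp(
            f1_uncertainty_curve(t_dev, t_dev.entropy, "development"),
            f1_uncertainty_curve(t_prod, t_prod.entropy, "production"),
        ).adp
        ci1 = adp_bootstrap_ci(t_dev, t_prod, n_boot=1000, seed=11)
        ci2 = adp_bootstrap_ci(t_dev, t_prod, n_boot=1000, seed=11)
        assert ci1 == ci2
        assert ci1[0] <= point <= ci1[1]

    def test_rejects_tiny_resample_count(self):
        t_dev, _ = _fine_grained_table()
        with pytest.raises(ValueError):
            adp_bootstrap_ci(t_dev, t_dev, n_boot=10)


class TestUncertaintyScores:
    def test_entropy_and_confidence_flavours(self, rng):
        t = random_table(rng, n=10)
        np.testing.assert_array_equal(uncertainty_scores(t, "entropy"), t.entropy)
        np.testing.assert_allclose(
            uncertainty_scores(t, "confidence"), 1.0 - t.confidence
        )
        with pytest.raises(ValueError):
            uncertainty_scores(t, "variance")
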