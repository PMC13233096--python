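import numpy as np
import pytest

from rtmeta.type2 import (
    DegenerateBinningWarning,
    SecondaryVariable,
    bin_by_quantiles,
    confidence_variable,
    counts_by_cell,
    type2_roc,
)

from conftest import make_table, random_table


# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate cutoffs, count, trapezoid
# ---------------------------------------------------------------------------

def oracle_auc(levels, correct, K):
    xs, ys = [0.0], [0.0]
    n_inc = sum(1 for c in correct if not c)
    n_cor = sum(1 for c in correct if c)
    for cut in range(K, 1, -1):
        fa = sum(1 for l, c in zip(levels, correct) if l >= cut and not c)
        hi = sum(1 for l, c in zip(levels, correct) if l >= cut and c)
        xs.append(fa / n_inc)
        ys.append(hi / n_cor)
    xs.append(1.0)
    ys.append(1.0)
    area = 0.0
    for i in range(1, len(xs)):
        area += (xs[i] - xs[i - 1]) * (ys[i] + ys[i - 1]) / 2.0
    return area


class TestBinByQuantiles:
    def test_tertiles_of_nine_values_descending(self):
        sv = bin_by_quantiles(np.arange(100, 1000, 100), 3, "descending")
        assert list(sv.values) == [3, 3, 3, 2, 2, 2, 1, 1, 1]
        assert sv.K == 3

    def test_all_equal_gives_single_level_with_warning(self):
        with pytest.warns(DegenerateBinningWarning):
            sv = bin_by_quantiles(np.full(10, 7.0), 4)
        assert sv.K == 1
        assert set(sv.values) == {1}

    def test_exact_equal_counts_for_distinct_values(self, rng):
        x = rng.uniform(0, 1, 1000)
        sv = bin_by_quantiles(x, 10, "descending")
        counts = np.bincount(sv.values)[1:]
        assert list(counts) == [100] * 10

    def test_descending_maps_smallest_to_highest_level(self, rng):
        x = rng.uniform(0, 1, 300)
        down = bin_by_quantiles(x, 5, "descending").values
        up = bin_by_quantiles(x, 5, "ascending").values
        assert np.array_equal(down, 6 - up)

    def test_fewer_distinct_than_bins_merges(self):
        with pytest.warns(DegenerateBinningWarning):
            sv = bin_by_quantiles([1.0, 1.0, 1.0, 1.0, 2.0], 4)
        assert sv.K < 4


class TestCountsByCell:
    def test_single_trial_lands_in_expected_slot(self):
        t = make_table(["S1"], ["S1"], [2], [500.0], k_levels=2)
        cm = counts_by_cell(t, confidence_variable(t))
        # S1 stimulus, S1 response, highest level -> first slot of nR_S1
        assert cm.nR_S1[0] == 1
        assert cm.nR_S1.sum() == 1
        assert cm.nR_S2.sum() == 0  # no S2-stimulus trials

    def test_conservation_of_trials(self, rng):
        t = random_table(rng, 157, K=3)
        cm = counts_by_cell(t, confidence_variable(t))
        assert cm.nR_S1.sum() + cm.nR_S2.sum() == 157

    def test_regrouping_by_correctness_matches_crosstab(self, rng):
        t = random_table(rng, 200, K=4)
        sv = confidence_variable(t)
        cm = counts_by_cell(t, sv)
        K = cm.K
        # regroup the count matrix into correct/incorrect x level
        correct_counts = np.zeros(K, int)
        incorrect_counts = np.zeros(K, int)
        for j in range(1, K + 1):
            # S1 stim: resp S1 correct (slot K-j), resp S2 incorrect (K-1+j)
            correct_counts[j - 1] += cm.nR_S1[K - j] + cm.nR_S2[K - 1 + j]
            incorrect_counts[j - 1] += cm.nR_S1[K - 1 + j] + cm.nR_S2[K - j]
        d = t.data
        for j in range(1, K + 1):
            m = d["confidence"] == j
            assert correct_counts[j - 1] == int((m & d["correct"]).sum())
            assert incorrect_counts[j - 1] == int((m & ~d["correct"]).sum())


class TestType2Roc:
    def test_independent_secondary_variable_gives_half(self):
        # identical level distributions for correct and incorrect
        t = make_table(["S1"] * 8, ["S1"] * 4 + ["S2"] * 4,
                       [1, 1, 2, 2, 1, 1, 2, 2], [100.0] * 8, k_levels=2)
        curve = type2_roc(t, confidence_variable(t))
        assert curve.auc == pytest.approx(0.5, abs=1e-12)

    def test_frozen_two_level_example(self):
        # correct: 30 high / 10 low; incorrect: 10 high / 30 low
        stim = ["S1"] * 40 + ["S2"] * 40
        resp = ["S1"] * 40 + ["S1"] * 40  # first 40 correct, last 40 incorrect
        conf = [2] * 30 + [1] * 10 + [2] * 10 + [1] * 30
        t = make_table(stim, resp, conf, [100.0] * 80, k_levels=2)
        curve = type2_roc(t, confidence_variable(t))
        assert curve.points.tolist() == [[0.25, 0.75]]
        assert curve.auc == pytest.approx(0.75, abs=1e-12)

    def test_perfect_separation_curve(self):
        stim = ["S1"] * 20 + ["S2"] * 20
        resp = ["S1"] * 20 + ["S1"] * 20
        conf = [2] * 20 + [1] * 20
        t = make_table(stim, resp, conf, [100.0] * 40, k_levels=2)
        curve = type2_roc(t, confidence_variable(t))
        assert curve.points.tolist() == [[0.0, 1.0]]
        assert curve.auc == pytest.approx(
            oracle_auc(conf, [True] * 20 + [False] * 20, 2), abs=1e-12
        )

    def test_all_correct_raises(self):
        t = make_table(["S1", "S2"], ["S1", "S2"], [1, 2], [100.0, 200.0],
                       k_levels=2)
        with pytest.raises(ValueError, match="incorrect"):
            type2_roc(t, confidence_variable(t))

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 100:
            n = int(rng.integers(10, 201))
            K = int(rng.integers(2, 7))
            t = random_table(rng, n, K=K)
            correct = t.data["correct"].to_numpy()
            if correct.all() or not correct.any():
                continue
            curve = type2_roc(t, confidence_variable(t))
            assert curve.auc == pytest.approx(
                oracle_auc(t.data["confidence"], correct, K), abs=1e-12
            )
            checked += 1

    def test_monotone_relabeling_invariance(self, rng):
        t = random_table(rng, 150, K=4)
        sv = confidence_variable(t)
        auc0 = type2_roc(t, sv).auc
        # strictly monotone relabeling 1,2,3,4 -> 1,3,4,9 then re-indexed
        relabeled = np.vectorize({1: 1, 2: 3, 3: 4, 4: 9}.get)(sv.values)
        dense = np.vectorize({1: 1, 3: 2, 4: 3, 9: 4}.get)(relabeled)
        auc1 = type2_roc(t, SecondaryVariable(dense, "confidence", 4)).auc
        assert auc1 == pytest.approx(auc0, abs=1e-12)

    def test_slowing_incorrect_trials_never_decreases_rt_auc(self, rng):
        n = 120
        correct = rng.random(n) < 0.7
        rt = rng.uniform(300, 900, n)
        stim = np.where(rng.random(n) < 0.5, "S1", "S2")
        resp = np.where(correct, stim, np.where(stim == "S1", "S2", "S1"))
        t0 = make_table(stim, resp, np.ones(n, int) + 1, rt, k_levels=2)
        sv0 = bin_by_quantiles(rt, 4, "descending")
        auc0 = type2_roc(t0, sv0).auc
        for shift in (50.0, 200.0, 1000.0):
            rt_shift = rt + np.where(correct, 0.0, shift)
            sv1 = bin_by_quantiles(rt_shift, 4, "descending")
            auc1 = type2_roc(t0, sv1).auc
            assert auc1 >= auc0 - 1e-12
            auc0 = auc1


# ---------------------------------------------------------------------------
# property: quantile binning depends only on ranks
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.lists(st.floats(min_value=1.0, max_value=1e4,
                       allow_nan=False, allow_infinity=False),
             min_size=12, max_size=120, unique=True),
    st.integers(min_value=2, max_value=6),
)
def test_binning_is_rank_based(values, n_bins):
    """A strictly increasing transform of distinct values never changes bins."""
    x = np.asarray(values)
    a = bin_by_quantiles(x, n_bins, "ascending").values
    b = bin_by_quantiles(np.log(x), n_bins, "ascending").values
    assert np.array_equal(a, b)
    assert a.min() >= 1 and a.max() <= n_bins
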