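import numpy as np
import pandas as pd
import pytest

from rtmeta.dsd2 import simulate_subjects
from rtmeta.io_trials import TrialTable
from rtmeta.reliability_meta import (
    disattenuate,
    meta_analyze_r,
    partial_correlation,
    reliability_from_halves,
    spearman_brown,
    split_half_metad,
)


class TestClosedForms:
    def test_spearman_brown_closed_form_grid(self):
        for r in np.linspace(-0.5, 0.99, 31):
            assert spearman_brown(r) == pytest.approx(2 * r / (1 + r),
                                                      abs=1e-12)

    def test_disattenuation_identity_and_value(self):
        assert disattenuate(0.3, 1.0, 1.0)[0] == pytest.approx(0.3, abs=1e-12)
        val, over = disattenuate(0.3, 0.36, 0.36)
        assert val == pytest.approx(0.3 / 0.36, abs=1e-12)
        assert not over

    def test_disattenuation_clamps_overcorrection(self):
        val, over = disattenuate(0.5, 0.2, 0.2)
        assert val == 1.0
        assert over

    def test_disattenuation_rejects_nonpositive_reliability(self):
        with pytest.raises(ValueError):
            disattenuate(0.3, 0.0, 0.5)

    def test_partial_correlation_independence_identity(self, rng):
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        z = rng.normal(size=500)  # independent of both
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        r_p, _, _ = partial_correlation(x, y, z)
        expected = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2)
        )
        assert r_p == pytest.approx(expected, abs=1e-12)

    def test_partial_correlation_degenerate_control(self, rng):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        with pytest.raises(ValueError):
            partial_correlation(x, y, x)

    def test_partial_correlation_recovers_known_structure(self):
        # x and y share z but are conditionally independent: partial ~ 0
        rng = np.random.default_rng(42)
        n = 10_000
        z = rng.normal(size=n)
        x = 0.7 * z + rng.normal(size=n)
        y = 0.7 * z + rng.normal(size=n)
        r_p, _, _ = partial_correlation(x, y, z)
        assert abs(r_p) < 0.02

    def test_partial_correlation_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=200)
        y = 0.4 * x + rng.normal(size=200)
        z = 0.3 * x + rng.normal(size=200)
        r_p, _, _ = partial_correlation(x, y, z)
        ref = pingouin.partial_corr(
            data=pd.DataFrame({"x": x, "y": y, "z": z}),
            x="x", y="y", covar="z",
        )["r"].iloc[0]
        assert r_p == pytest.approx(float(ref), abs=1e-9)


class TestMetaAnalysis:
    def test_single_study_identity(self):
        res = meta_analyze_r([(0.4, 50)])
        assert res.pooled_r == pytest.approx(0.4, abs=1e-12)
        assert res.tau2 == 0.0

    def test_homogeneous_studies_pool_to_common_r(self):
        res = meta_analyze_r([(0.3, 40), (0.3, 80), (0.3, 200)])
        assert res.pooled_r == pytest.approx(0.3, abs=1e-12)
        assert res.tau2 == 0.0

    def test_matches_independent_dl_implementation(self):
        # independently coded DerSimonian-Laird on the Fisher-z scale
        studies = [(0.10, 40), (0.35, 60), (0.52, 120), (-0.05, 30),
                   (0.61, 80)]
        zs = np.array([np.arctanh(r) for r, _ in studies])
        v = np.array([1.0 / (n - 3) for _, n in studies])
        w = 1.0 / v
        zbar = (w * zs).sum() / w.sum()
        q = (w * (zs - zbar) ** 2).sum()
        tau2 = max(0.0, (q - (len(zs) - 1)) / (w.sum() - (w**2).sum() / w.sum()))
        wstar = 1.0 / (v + tau2)
        z_pool = (wstar * zs).sum() / wstar.sum()
        res = meta_analyze_r(studies)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)
        assert res.pooled_r == pytest.approx(np.tanh(z_pool), abs=1e-10)

    def test_matches_statsmodels_combine_effects(self):
        from statsmodels.stats.meta_analysis import combine_effects

        studies = [(0.10, 40), (0.35, 60), (0.52, 120), (-0.05, 30),
                   (0.61, 80)]
        zs = np.array([np.arctanh(r) for r, _ in studies])
        v = np.array([1.0 / (n - 3) for _, n in studies])
        ref = combine_effects(zs, v, method_re="chi2")  # DL estimator
        res = meta_analyze_r(studies)
        assert res.pooled_r == pytest.approx(
            np.tanh(ref.mean_effect_re), abs=1e-10
        )
        assert res.tau2 == pytest.approx(ref.tau2, abs=1e-10)

    def test_ci_width_shrinks_with_study_count(self):
        small = meta_analyze_r([(0.3, 50)] * 3)
        large = meta_analyze_r([(0.3, 50)] * 30)
        assert (large.pooled_ci[1] - large.pooled_ci[0]) < (
            small.pooled_ci[1] - small.pooled_ci[0]
        )

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError):
            meta_analyze_r([(1.0, 50)])


class TestSplitHalf:
    def test_duplicated_trials_give_identical_halves(self):
        # even trials are exact copies of odd trials -> both halves see
        # the same data and the deterministic fit returns the same value
        base = simulate_subjects(1, 400, seed=77)
        df = base.data.drop(columns=["trial_index"])
        dup = pd.concat(
            [df.loc[df.index.repeat(2)].reset_index(drop=True)]
        ).reset_index(drop=True)
        table = TrialTable(dup, k_levels=base.k_levels)
        halves = split_half_metad(table, "confidence")
        (odd, even), = halves.values()
        assert odd == even

    def test_heterogeneous_observers_correlate_across_halves(self):
        table = simulate_subjects(14, 2_000, seed=5)
        halves = split_half_metad(table, "confidence")
        assert len(halves) >= 12
        odd = np.array([v[0] for v in halves.values()])
        even = np.array([v[1] for v in halves.values()])
        rel = reliability_from_halves(odd, even)
        assert rel.r_half > 0.5
        assert rel.r_sb == pytest.approx(
            2 * rel.r_half / (1 + rel.r_half), abs=1e-12
        )

    def test_small_n_reliability_fails_screen(self):
        # identical true observers with only 40 trials each: the
        # odd/even meta-d' estimates are pure measurement noise, so the
        # Spearman-Brown screen fails
        from rtmeta.dsd2 import DSDParams, simulate_condition

        frames = []
        for j in range(16):
            t = simulate_condition(DSDParams(), 40, seed=600 + j,
                                   subject=f"s{j:02d}", n_levels=4)
            frames.append(t.data)
        table = TrialTable(pd.concat(frames, ignore_index=True), k_levels=4)
        halves = split_half_metad(table, "confidence", min_trials_half=15)
        assert len(halves) >= 8
        odd = np.array([v[0] for v in halves.values()])
        even = np.array([v[1] for v in halves.values()])
        rel = reliability_from_halves(odd, even, threshold=0.45)
        assert not rel.passes_screen

    def test_disattenuated_exceeds_raw_on_synthetic_datasets(self):
        # heterogeneous 2DSD observers, two meta-d' indices (confidence
        # and RT): correcting for split-half measurement error moves the
        # correlation away from zero, as in the classical theory
        table = simulate_subjects(14, 2_000, seed=8)
        per_subject = {}
        rel = {}
        for kind in ("confidence", "rt"):
            halves = split_half_metad(table, kind, n_bins=10)
            odd = np.array([v[0] for v in halves.values()])
            even = np.array([v[1] for v in halves.values()])
            rel[kind] = reliability_from_halves(odd, even)
            per_subject[kind] = {
                s: 0.5 * (o + e) for s, (o, e) in halves.items()
            }
        common = sorted(set(per_subject["confidence"]) & set(per_subject["rt"]))
        x = np.array([per_subject["confidence"][s] for s in common])
        y = np.array([per_subject["rt"][s] for s in common])
        r_xy = np.corrcoef(x, y)[0, 1]
        corrected, _ = disattenuate(r_xy, rel["confidence"].r_sb,
                                    rel["rt"].r_sb)
        assert abs(corrected) >= abs(r_xy) - 1e-12
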