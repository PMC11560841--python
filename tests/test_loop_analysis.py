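import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sc3dmulti import loop_analysis as la
from sc3dmulti import matrix_core as mc


def stats_from_cells(cells):
    """Build PseudobulkStats directly from a stack of per-cell matrices."""
    cells = [np.asarray(c, dtype=np.float32) for c in cells]
    return mc.aggregate_pseudobulk([(c, c, c) for c in cells])


class TestPseudobulkTstat:
    def test_all_zero_gives_zero(self):
        stats = stats_from_cells([np.zeros((4, 4))] * 3)
        assert not la.pseudobulk_tstat(stats, "E").any()

    def test_two_cell_closed_form(self):
        # cells {1, 3}: mean 2, meansq 5 -> t = 2 / sqrt(1/2) = 2.828...
        stats = stats_from_cells([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
        t = la.pseudobulk_tstat(stats, "E")
        assert t[0, 0] == pytest.approx(2 * np.sqrt(2), rel=1e-6)

    def test_oracle_equivalence_direct_computation(self, rng):
        # summaries route == direct per-cell computation (population variance)
        for _ in range(100):
            cells = rng.normal(size=(rng.integers(2, 8), 3, 3))
            stats = stats_from_cells(list(cells))
            t = la.pseudobulk_tstat(stats, "E")
            raw = cells.astype(np.float64)
            direct = raw.mean(0) / np.sqrt(
                np.maximum(raw.var(0), la.EPS_VAR) / raw.shape[0])
            assert np.allclose(t, direct, atol=1e-6)

    def test_single_cell_rejected(self):
        stats = stats_from_cells([np.ones((2, 2))])
        with pytest.raises(ValueError):
            la.pseudobulk_tstat(stats, "E")


class TestEmpiricalFdr:
    def test_fdr_zero_at_max_when_shuffle_below(self, rng):
        obs = rng.normal(size=500)
        shuf = obs.min() - 1 + rng.random(500) * 0.5
        fdr = la.empirical_fdr(obs, shuf)
        assert fdr[np.argmax(obs)] == 0.0

    def test_identical_distributions_fdr_near_one_at_median(self, rng):
        x = rng.normal(size=4000)
        fdr = la.empirical_fdr(x, x.copy())
        med_idx = np.argsort(x)[len(x) // 2]
        assert fdr[med_idx] > 0.9

    def test_monotone_non_increasing_in_t(self, rng):
        obs = rng.normal(size=300)
        shuf = rng.normal(size=300)
        fdr = la.empirical_fdr(obs, shuf)
        order = np.argsort(obs)
        assert (np.diff(fdr[order]) <= 1e-12).all()

    def test_empty_shuffle_raises(self):
        with pytest.raises(ValueError):
            la.empirical_fdr(np.ones(3), np.empty(0))


def brute_force_fold_changes(q, band):
    """Offset-enumeration oracle for the four local backgrounds."""
    n = q.shape[0]
    oe = la._oe_normalize(q, band)
    out = {}
    for name, offsets in la._BACKGROUNDS.items():
        fc = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                vals = []
                for di, dj in offsets:
                    a, b = i + di, j + dj
                    if 0 <= a < n and 0 <= b < n and abs(a - b) <= band:
                        vals.append(oe[a, b])
                bg = np.mean(vals) if vals else 0.0
                if bg > 0:
                    fc[i, j] = oe[i, j] / bg
                else:
                    fc[i, j] = np.inf if oe[i, j] > 0 else 1.0
        out[name] = fc
    return out


class TestBackgroundFoldChanges:
    def test_uniform_matrix_all_one(self):
        # interior pixels only: at the matrix corners some backgrounds have
        # no in-bounds offsets at all (candidate_mask excludes those pixels)
        q = np.ones((20, 20))
        fcs = la.background_fold_changes(q, band=19)
        for fc in fcs.values():
            assert np.allclose(fc[5:-5, 5:-5], 1.0)

    def test_bright_pixel_on_flat_zero_background(self):
        q = np.zeros((30, 30))
        q[5, 25] = q[25, 5] = 4.0
        fcs = la.background_fold_changes(q, band=29)
        # O/E puts the only mass of diagonal 20 at the pixel; backgrounds are 0
        for fc in fcs.values():
            assert np.isinf(fc[5, 25])

    def test_matches_offset_enumeration(self, rng):
        q = rng.poisson(3, size=(15, 15)).astype(float)
        q = q + q.T
        band = 10
        fcs = la.background_fold_changes(q, band)
        expected = brute_force_fold_changes(q, band)
        inband = mc.band_mask(15, band)
        for name in fcs:
            got, want = fcs[name][inband], expected[name][inband]
            finite = np.isfinite(want)
            assert np.allclose(got[finite], want[finite], atol=1e-8), name
            assert np.array_equal(np.isinf(got), np.isinf(want)), name


class TestCallLoops:
    def test_planted_recovery(self, mini_loop_cohort):
        from sc3dmulti import pipeline
        cohort = mini_loop_cohort
        res = pipeline.loop_stage(
            cohort.contacts, cohort.config.chrom.length,
            {c: "a" for c in cohort.contacts}, seed=0)
        n_bins = cohort.config.chrom.length // 10_000
        summits = la.loop_summits(res.calls["a"], n_bins)
        truth = cohort.truth.loops
        matched = 0
        for _, t in truth.iterrows():
            near = summits[(abs(summits.bin1 - t.bin1) <= 2)
                           & (abs(summits.bin2 - t.bin2) <= 2)]
            matched += int(len(near) > 0)
        assert matched / len(truth) >= 0.8            # recall
        precise = sum(
            bool(((abs(truth.bin1 - s.bin1) <= 2)
                  & (abs(truth.bin2 - s.bin2) <= 2)).any())
            for _, s in summits.iterrows())
        assert precise / max(len(summits), 1) >= 0.8  # precision

    def test_relaxing_thresholds_never_removes(self, mini_loop_cohort):
        from sc3dmulti import pipeline
        cohort = mini_loop_cohort
        groups = {c: "a" for c in cohort.contacts}
        strict = pipeline.loop_stage(cohort.contacts,
                                     cohort.config.chrom.length, groups,
                                     seed=0).calls["a"]
        relaxed_thr = la.LoopThresholds(fc_donut=1.0, fc_lowerleft=1.0,
                                        fc_horizontal=1.0, fc_vertical=1.0,
                                        fdr=0.05)
        relaxed = pipeline.loop_stage(cohort.contacts,
                                      cohort.config.chrom.length, groups,
                                      seed=0,
                                      thresholds=relaxed_thr).calls["a"]
        strict_set = set(map(tuple, strict.loc[strict.is_loop,
                                               ["bin1", "bin2"]].to_numpy()))
        relaxed_set = set(map(tuple, relaxed.loc[relaxed.is_loop,
                                                 ["bin1", "bin2"]].to_numpy()))
        assert strict_set <= relaxed_set


class TestAnova:
    def test_equal_group_means_zero(self):
        groups = [(3, np.full((2, 2), 2.0), np.full((2, 2), 5.0)),
                  (4, np.full((2, 2), 2.0), np.full((2, 2), 6.0))]
        assert not la.anova_from_summaries(groups).any()

    def test_hand_computed_example(self):
        # G1 = {0, 2}, G2 = {3, 5} -> F = 4.5
        g1 = (2, np.array([[1.0]]), np.array([[2.0]]))
        g2 = (2, np.array([[4.0]]), np.array([[17.0]]))
        assert la.anova_from_summaries([g1, g2])[0, 0] == pytest.approx(4.5)

    def test_oracle_equivalence_scipy_f_oneway(self, rng):
        from scipy.stats import f_oneway
        for _ in range(100):
            sizes = rng.integers(2, 7, size=rng.integers(2, 5))
            cells = [rng.normal(size=(s, 2, 2)) for s in sizes]
            groups = [(len(c), c.mean(0), (c ** 2).mean(0)) for c in cells]
            f = la.anova_from_summaries(groups)
            direct = f_oneway(*[c.reshape(len(c), -1) for c in cells]).statistic
            assert np.allclose(f.ravel(), direct, atol=1e-8)

    def test_zero_within_variance_inf(self):
        g1 = (2, np.array([[1.0]]), np.array([[1.0]]))
        g2 = (2, np.array([[2.0]]), np.array([[4.0]]))
        assert np.isinf(la.anova_from_summaries([g1, g2])[0, 0])

    def test_small_groups_rejected(self):
        g = (1, np.zeros((1, 1)), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            la.anova_from_summaries([g, g])


class TestSelectDifferential:
    def test_constant_f_selects_nothing(self):
        out = la.select_differential(np.ones(50), np.ones(50))
        assert not out["is_differential"].any()

    def test_threshold_is_085_normal_quantile(self):
        assert round(la.differential_z_threshold(0.85), 3) == 1.036
        assert la.DIFFERENTIAL_Z == pytest.approx(norm.ppf(0.85), abs=5e-4)

    def test_scale_invariance(self, rng):
        f_q = rng.lognormal(size=200)
        f_t = rng.lognormal(size=200)
        a = la.select_differential(f_q, f_t)
        b = la.select_differential(f_q * 37.0, f_t * 0.01)
        assert a["is_differential"].equals(b["is_differential"])

    def test_minority_elevated_group_selected(self, rng):
        f = np.concatenate([np.full(5, 40.0), rng.uniform(0.5, 2.0, 45)])
        out = la.select_differential(f, f)
        assert out["is_differential"][:5].all()
        assert not out["is_differential"][5:].any()


class TestCumulativeLoopScore:
    def _loops(self):
        return pd.DataFrame({"chrom": "chr1", "bin1": [10, 10, 200],
                             "bin2": [40, 60, 300],
                             "E_mean": [1.5, 2.5, 7.0]})

    def test_no_loop_within_5kb(self):
        promoters = pd.DataFrame({"name": ["g"], "tss": [800_000]})
        scores = la.cumulative_loop_score(self._loops(), promoters)
        assert scores["g"] == 0.0

    def test_two_loops_at_anchor_sum(self):
        promoters = pd.DataFrame({"name": ["g"], "tss": [105_000]})
        scores = la.cumulative_loop_score(self._loops(), promoters)
        assert scores["g"] == pytest.approx(4.0)

    def test_5001_bp_boundary_excluded(self):
        loops = pd.DataFrame({"chrom": "chr1", "bin1": [10], "bin2": [40],
                              "E_mean": [2.0]})
        # anchor [100000, 110000); TSS below: gap = 100000 - tss
        at_5000 = pd.DataFrame({"name": ["a"], "tss": [95_000]})
        at_5001 = pd.DataFrame({"name": ["b"], "tss": [94_999]})
        assert la.cumulative_loop_score(loops, at_5000)["a"] == 2.0
        assert la.cumulative_loop_score(loops, at_5001)["b"] == 0.0

    def test_count_mode(self):
        promoters = pd.DataFrame({"name": ["g"], "tss": [105_000]})
        scores = la.cumulative_loop_score(self._loops(), promoters, mode="count")
        assert scores["g"] == 2.0


class TestSips:
    def test_threshold_at_unit_sigma(self):
        assert la.sip_score_threshold(1.0) == pytest.approx(3.2905, abs=5e-4)

    def test_doubling_scores_keeps_sip_set(self, rng):
        scores = pd.Series(np.abs(rng.normal(size=500)))
        scores.iloc[0] = 20.0
        a = la.call_sips(scores)
        b = la.call_sips(scores * 2.0)
        assert a["is_SIP"].equals(b["is_SIP"])
        assert b["sigma"].iloc[0] == pytest.approx(2 * a["sigma"].iloc[0])

    def test_p_at_sigma(self):
        # scores {3, -3, 3, -3} have sigma = 3; p at a score of exactly
        # sigma is 2(1 - Phi(1)) = 0.3173...
        scores = pd.Series([3.0, -3.0, 3.0, -3.0])
        out = la.call_sips(scores)
        assert out["sigma"].iloc[0] == pytest.approx(3.0)
        assert out["p_halfgauss"].iloc[0] == pytest.approx(0.31731, abs=1e-5)

    def test_p_decreasing_in_score(self, rng):
        scores = pd.Series(np.abs(rng.normal(size=100)))
        out = la.call_sips(scores)
        order = np.argsort(out["cumulative_score"].to_numpy())
        assert (np.diff(out["p_halfgauss"].to_numpy()[order]) <= 1e-15).all()

    def test_zero_sigma_raises(self):
        with pytest.raises(ValueError):
            la.call_sips(pd.Series([1.0, 1.0, 1.0]))


class TestCumulativeDifferentialScore:
    def test_no_differential_loops_zero_trajectory(self):
        loops = pd.DataFrame({"chrom": [], "bin1": [], "bin2": []})
        stages = pd.DataFrame({"s1": [], "s2": []})
        promoters = pd.DataFrame({"name": ["g"], "tss": [100_000]})
        out = la.cumulative_differential_score(loops, stages, promoters)
        assert (out.to_numpy() == 0).all()

    def test_stage_permutation_permutes_trajectory(self):
        loops = pd.DataFrame({"chrom": ["chr1"], "bin1": [10], "bin2": [40]})
        stages = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]})
        promoters = pd.DataFrame({"name": ["g"], "tss": [100_500]})
        out = la.cumulative_differential_score(loops, stages, promoters)
        out_perm = la.cumulative_differential_score(
            loops, stages[["s3", "s1", "s2"]], promoters)
        assert out.loc["g", "s3"] == out_perm.loc["g", "s3"]
        assert list(out_perm.columns) == ["s3", "s1", "s2"]

    def test_gained_loop_nondecreasing(self):
        loops = pd.DataFrame({"chrom": ["chr1"], "bin1": [10], "bin2": [40]})
        stages = pd.DataFrame({"e": [0.2], "m": [1.0], "l": [2.5]})
        promoters = pd.DataFrame({"name": ["g"], "tss": [100_500]})
        out = la.cumulative_differential_score(loops, stages, promoters)
        assert (np.diff(out.loc["g"].to_numpy()) >= 0).all()
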