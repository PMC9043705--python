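import numpy as np
import pandas as pd
import pytest

import udlbias as u


def _obs(participant, d, rt, bias, **kw):
    n = len(rt)
    base = dict(participant=participant, block=2, trial=np.arange(n),
                phase="test", target_deg=0.0, is_probe=True, feedback="none",
                group="exp1", probe_distance=d, bias_deg=bias, rt_s=rt,
                mt_s=0.3, valid=True, reason="ok")
    base.update(kw)
    return pd.DataFrame(base)


class TestQuintiles:
    def test_five_trials_one_per_bin(self):
        rt = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        bias = np.array([50.0, 40.0, 30.0, 20.0, 10.0])
        q = u.quintile_summary(_obs(0, 90, rt, bias))
        cells = q.cells.sort_values("quintile")
        assert (cells.n == 1).all()
        np.testing.assert_allclose(cells.mean_bias_deg, bias)
        np.testing.assert_allclose(cells.mean_rt_s, rt)

    def test_bin_means_match_explicit_sort_oracle(self):
        rng = np.random.default_rng(0)
        rt = rng.uniform(0.1, 0.6, 10)
        bias = 100 - 100 * rt
        q = u.quintile_summary(_obs(0, 90, rt, bias))
        order = np.argsort(rt, kind="stable")
        # 10 trials -> five bins of 2
        expect = [bias[order[2 * i:2 * i + 2]].mean() for i in range(5)]
        np.testing.assert_allclose(
            q.cells.sort_values("quintile").mean_bias_deg, expect)

    def test_bins_partition_valid_trials(self, exp1_obs):
        q = u.quintile_summary(exp1_obs)
        per_cell = q.cells.groupby(["participant", "probe_distance"])["n"].sum()
        probes = u.select_probes(exp1_obs)
        counts = probes.groupby(["participant", "probe_distance"]).size()
        pd.testing.assert_series_equal(per_cell, counts, check_names=False)

    def test_remainder_goes_to_fastest_bins(self):
        rt = np.linspace(0.1, 0.7, 7)
        q = u.quintile_summary(_obs(0, 90, rt, rt * 0))
        sizes = q.cells.sort_values("quintile").n.tolist()
        assert sizes == [2, 2, 1, 1, 1]

    def test_generator_bias_decreases_across_quintiles(self, exp1_obs):
        q = u.quintile_summary(exp1_obs)
        far = q.group[q.group.probe_distance == 90].sort_values("quintile")
        assert far.mean_bias_deg.is_monotonic_decreasing


class TestSlopes:
    def test_noiseless_linear_bias_recovers_slope_exactly(self):
        rt = np.linspace(0.1, 0.5, 20)
        frames = [_obs(p, 90, rt, 50 - 100 * rt) for p in range(3)]
        res = u.slope_fit(pd.concat(frames, ignore_index=True), 90)
        assert res.slope == pytest.approx(-100.0, abs=1e-9)
        assert res.per_participant.std() == pytest.approx(0.0, abs=1e-9)

    def test_permuted_rts_rarely_significant(self):
        rng = np.random.default_rng(0)
        rt = rng.uniform(0.1, 0.6, 30)
        bias = 60 - 80 * rt + rng.normal(0, 5, 30)
        rejections = 0
        for s in range(100):
            prng = np.random.default_rng(s)
            frames = [_obs(p, 90, prng.permutation(rt), bias)
                      for p in range(4)]
            res = u.slope_fit(pd.concat(frames, ignore_index=True), 90)
            rejections += res.p_value < 0.05
        assert rejections <= 10

    def test_two_stage_and_mixed_agree_on_balanced_cohort(self, exp1_obs):
        for d in (60, 90):
            a = u.slope_fit(exp1_obs, d, method="two_stage")
            b = u.slope_fit(exp1_obs, d, method="pooled_mixed")
            assert np.sign(a.slope) == np.sign(b.slope)
            assert abs(a.slope - b.slope) < 2 * max(a.se, b.se)

    def test_normalization_commutes_with_slope(self):
        rt = np.linspace(0.1, 0.5, 20)
        obs = pd.concat([_obs(p, 60, rt, 60 - 120 * rt) for p in range(2)],
                        ignore_index=True)
        norm = u.normalize_bias(obs).rename(
            columns={"bias_deg": "raw", "bias_norm": "bias_deg"})
        a = u.slope_fit(norm, 60).slope
        b = u.slope_fit(obs, 60).slope / 60.0
        assert a == pytest.approx(b, abs=1e-12)


class TestNormalizeBias:
    @pytest.mark.parametrize("d,bias,expect", [(90, 90.0, 1.0),
                                               (30, 3.0, 0.1),
                                               (60, 0.0, 0.0)])
    def test_fraction_of_maximal_inward_bias(self, d, bias, expect):
        obs = _obs(0, d, np.full(5, 0.3), np.full(5, bias))
        out = u.normalize_bias(obs)
        assert (out.bias_norm == expect).all()

    def test_frequent_target_excluded(self):
        obs = _obs(0, 0, np.full(5, 0.3), np.zeros(5))
        assert len(u.normalize_bias(obs)) == 0


class TestDistanceContrasts:
    def test_all_zero_biases_reject_nothing(self):
        rng = np.random.default_rng(1)
        frames = [_obs(p, d, rng.uniform(0.2, 0.5, 10), rng.normal(0, 1e-9, 10))
                  for p in range(4) for d in (30, 60, 90)]
        res = u.distance_contrasts(pd.concat(frames, ignore_index=True))
        assert res.per_distance.mean_bias_deg.abs().max() < 1e-6

    def test_constructed_cohort_matches_textbook_paired_test(self):
        # cohort with per-participant means near {8, 20, 28}
        rng = np.random.default_rng(2)
        frames = []
        for p in range(8):
            for d, m in zip((30, 60, 90), (8, 20, 28)):
                frames.append(_obs(p, d, rng.uniform(0.2, 0.5, 12),
                                   np.full(12, m + rng.normal(0, 2))))
        res = u.distance_contrasts(pd.concat(frames, ignore_index=True))
        means = res.per_distance.set_index("probe_distance").mean_bias_deg
        assert means[30] < means[60] < means[90]
        c = res.contrasts.set_index(["d_low", "d_high"])
        assert c.loc[(30, 60), "p_bonf"] < 0.05
        # oracle: scipy paired t-test on the participant means
        from scipy import stats as sps
        data = pd.concat(frames, ignore_index=True)
        pm = (u.select_probes(data)
              .groupby(["participant", "probe_distance"]).bias_deg.mean()
              .unstack())
        t_ref, p_ref = sps.ttest_rel(pm[60], pm[30])
        assert c.loc[(30, 60), "t"] == pytest.approx(t_ref, abs=1e-9)
        assert c.loc[(30, 60), "p_raw"] == pytest.approx(p_ref, abs=1e-12)

    def test_bonferroni_is_three_times_raw(self, exp1_obs):
        res = u.distance_contrasts(exp1_obs)
        np.testing.assert_allclose(res.contrasts.p_bonf,
                                   np.minimum(1.0, 3 * res.contrasts.p_raw))


class TestRewardCompare:
    def test_identical_data_in_both_groups_gives_zero_statistic(self):
        rng = np.random.default_rng(3)
        acc = {p: np.sin(np.arange(20.0)) + 0.1 * p for p in range(4)}
        probe = {(p, d): rng.normal(d / 30, 1, 10)
                 for p in range(4) for d in (30, 60, 90)}
        frames = []
        for g in ("reward", "no_reward"):   # byte-identical data per group
            for p in range(4):
                frames.append(_obs(p, 0, np.full(20, 0.3), acc[p], group=g,
                                   is_probe=False))
                for d in (30, 60, 90):
                    frames.append(_obs(p, d, np.full(10, 0.3), probe[(p, d)],
                                       group=g))
        res = u.reward_compare(pd.concat(frames, ignore_index=True))
        assert res.accuracy_t == pytest.approx(0.0, abs=1e-9)
        assert res.accuracy_d == pytest.approx(0.0, abs=1e-9)

    def test_unknown_group_labels_rejected(self, exp1_obs):
        with pytest.raises(ValueError):
            u.reward_compare(exp1_obs)
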