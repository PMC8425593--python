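"""Paired pre/post statistics, the signed-rank test, and trajectories."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cfqpcr import cohort as ch
from cfqpcr.simulate import SimulationConfig, simulate_cohort
from cfqpcr.normalize import normalize

from conftest import noise_free_targets, two_timepoints


def _expr_meta(records):
    """records: (patient, label, phase, day, value) for a single target."""
    expr = pd.DataFrame({
        "sample_id": [f"{p}_{l}" for p, l, *_ in records],
        "target": "TPO",
        "expression": [v for *_, v in records],
    })
    meta = pd.DataFrame({
        "sample_id": [f"{p}_{l}" for p, l, *_ in records],
        "patient_id": [p for p, *_ in records],
        "day": [d for _, _, _, d, _ in records],
        "phase": [ph for _, _, ph, _, _ in records],
        "timepoint_label": [l for _, l, *_ in records],
        "cohort_group": "treatment",
    })
    return expr, meta


class TestPairing:
    RECORDS = [
        ("P1", "pre", "pre", -1, 10.0),
        ("P1", "24h", "post", 1, 5.0),
        ("P1", "1wk", "post", 7, 3.0),
        ("P1", "1mo", "post", 30, 6.0),
    ]

    @pytest.mark.parametrize("policy, expected_value, expected_label", [
        ("earliest_post", 5.0, "24h"),
        ("latest_post", 6.0, "1mo"),
        ("any_fall", 3.0, "1wk"),   # minimum across post visits
    ])
    def test_policies(self, policy, expected_value, expected_label):
        expr, meta = _expr_meta(self.RECORDS)
        pairs = ch.pair_pre_post(expr, meta, policy=policy)
        assert len(pairs) == 1
        assert pairs.loc[0, "expression_pre"] == 10.0
        assert pairs.loc[0, "expression_post"] == expected_value
        assert pairs.loc[0, "post_timepoint_used"] == expected_label

    def test_single_pre_single_post_same_under_every_policy(self):
        expr, meta = _expr_meta([("P1", "pre", "pre", -1, 8.0), ("P1", "24h", "post", 1, 2.0)])
        for policy in ch.PAIRING_POLICIES:
            pairs = ch.pair_pre_post(expr, meta, policy=policy)
            assert (pairs.loc[0, "expression_pre"], pairs.loc[0, "expression_post"]) == (8.0, 2.0)

    def test_patient_without_pre_skipped_with_warning(self):
        expr, meta = _expr_meta([("P1", "24h", "post", 1, 2.0),
                                 ("P2", "pre", "pre", -1, 9.0), ("P2", "24h", "post", 1, 3.0)])
        with pytest.warns(UserWarning, match="P1"):
            pairs = ch.pair_pre_post(expr, meta)
        assert pairs["patient_id"].tolist() == ["P2"]


class TestFallStatistics:
    @pytest.mark.parametrize("pre, post, expected", [
        (19.8, 3.9, True), (5.0, 5.0, False), (0.0, 2.0, False)])
    def test_fall_is_strict_decrease(self, pre, post, expected):
        assert ch.fall_flag(pre, post) is expected

    @pytest.mark.parametrize("n_fall, n_total, expected", [
        (17, 27, 63), (20, 27, 74), (19, 27, 70), (7, 16, 44), (0, 10, 0), (5, 8, 63)])
    def test_fall_proportion_rounding(self, n_fall, n_total, expected):
        assert ch.fall_proportion(n_fall, n_total) == expected

    def test_fall_proportion_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            ch.fall_proportion(0, 0)

    @pytest.mark.parametrize("values, expected", [
        ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0)),
        ([7.0] * 6, (7.0, 7.0, 7.0)),
        ([4.2], (4.2, 4.2, 4.2)),
    ])
    def test_median_iqr(self, values, expected):
        assert ch.median_iqr(values) == pytest.approx(expected)

    @pytest.mark.parametrize("pre, post, expected", [
        (19.8, 3.9, -80), (32.1, 29.6, -8), (31.8, 30.3, -5), (30.4, 28.2, -7),
        (10.0, 12.0, 20),   # a rise keeps its sign
    ])
    def test_percent_fall_of_medians(self, pre, post, expected):
        assert ch.percent_fall_of_medians(pre, post) == expected

    def test_percent_fall_undefined_for_zero_baseline(self):
        assert ch.percent_fall_of_medians(0.0, 0.0) is None


def wilcoxon_oracle(pre, post, alternative="two_sided"):
    """Exhaustive 2^n enumeration of the signed-rank null distribution."""
    d = np.asarray(pre, float) - np.asarray(post, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, keep in zip(ranks, signs) if keep)
        for signs in itertools.product([False, True], repeat=n)
    ])
    p_ge = np.mean(ws >= w_obs)
    p_le = np.mean(ws <= w_obs)
    if alternative == "greater_fall":
        return float(p_ge)
    return float(min(1.0, 2 * min(p_ge, p_le)))


class TestWilcoxon:
    def test_five_concordant_falls_exact(self):
        pre = [10.0, 11.0, 12.0, 13.0, 14.0]
        post = [9.0, 8.0, 7.0, 6.0, 5.0]
        res = ch.wilcoxon_signed_rank(pre, post)
        assert res.p_value == pytest.approx(0.0625)  # 2/2^5
        assert res.method == "exact"

    def test_identical_arrays_give_p_one(self):
        with pytest.warns(UserWarning):
            res = ch.wilcoxon_signed_rank([3.0, 4.0], [3.0, 4.0])
        assert res.p_value == 1.0
        assert res.method == "degenerate"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=10).flatmap(
            lambda n: st.tuples(
                st.lists(st.floats(0, 60, allow_nan=False), min_size=n, max_size=n),
                st.lists(st.floats(0, 60, allow_nan=False), min_size=n, max_size=n),
            )
        ),
        st.sampled_from(["two_sided", "greater_fall"]),
    )
    def test_matches_enumeration_oracle(self, pair, alternative):
        pre, post = pair
        d = np.asarray(pre) - np.asarray(post)
        d = d[d != 0]
        if d.size == 0 or np.unique(np.abs(d)).size < d.size:
            return  # degenerate or tied |differences|: exact method not defined
        res = ch.wilcoxon_signed_rank(pre, post, alternative=alternative)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_oracle(pre, post, alternative))

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        pre = rng.uniform(0, 60, 30)
        post = pre - rng.normal(1.0, 2.0, 30)
        res = ch.wilcoxon_signed_rank(pre, post)
        assert res.method == "approx"
        assert 0 <= res.p_value <= 1


class TestDetectionRate:
    def _make(self, detected_patients, n_patients):
        records = []
        for i in range(n_patients):
            val = 5.0 if i < detected_patients else 0.0
            records.append((f"P{i}", "pre", "pre", -1, val))
            records.append((f"P{i}", "24h", "post", 1, 0.0))
        return _expr_meta(records)

    @pytest.mark.parametrize("n_det, n_total, rate", [(7, 16, 44), (0, 10, 0), (12, 12, 100)])
    def test_rates(self, n_det, n_total, rate):
        expr, meta = self._make(n_det, n_total)
        summary = ch.detection_rate(expr, meta, "TPO")
        assert (summary.n_detected_patients, summary.n_patients, summary.rate) == (n_det, n_total, rate)


class TestSummarizeTargets:
    def test_zero_noise_uniform_fall(self, zero_noise_config):
        ct, meta, panel, _ = simulate_cohort(zero_noise_config)
        expr, _ = normalize(ct, panel)
        summary = ch.summarize_targets(expr, meta, panel)
        row = summary[summary["target"] == "THY1"].iloc[0]
        assert row["n_fall"] == 4 and row["n_total"] == 4
        assert row["fall_proportion"] == 100
        # four concordant falls of identical magnitude (tied |differences|,
        # so the tie-corrected approximation applies): clearly significant
        assert row["p_value"] < 0.05

    def test_never_amplified_target_has_zero_medians_and_na_fall(self):
        records = [(f"P{i}", l, ph, d, 0.0)
                   for i in range(3)
                   for l, ph, d in [("pre", "pre", -1), ("24h", "post", 1)]]
        expr, meta = _expr_meta(records)
        panel = pd.DataFrame({"target": ["TPO", "ACTB", "LUC"],
                              "target_class": ["thyroid_specific", "housekeeping", "spike_in"],
                              "expected_tm": [82.0, 87.0, 78.0]})
        summary = ch.summarize_targets(expr, meta, panel)
        row = summary[summary["target"] == "TPO"].iloc[0]
        assert row["median_pre"] == 0.0 and row["median_post"] == 0.0
        assert np.isnan(row["percent_fall_of_medians"])

    def test_patient_order_invariance(self):
        cfg = SimulationConfig(n_patients=8, seed=19)
        ct, meta, panel, _ = simulate_cohort(cfg)
        expr, _ = normalize(ct, panel)
        a = ch.summarize_targets(expr, meta, panel)
        perm = expr.sample(frac=1.0, random_state=2).reset_index(drop=True)
        b = ch.summarize_targets(perm, meta, panel)
        pd.testing.assert_frame_equal(a, b)


class TestTrajectory:
    def test_output_time_ordered_despite_shuffled_input(self):
        records = [("P1", "1mo", "post", 30, 4.0), ("P1", "pre", "pre", -1, 9.0),
                   ("P1", "24h", "post", 1, 6.0)]
        expr, meta = _expr_meta(records)
        meta["serum_tg"] = [np.nan, 25.0, 10.0]
        meta["tsh_stimulated"] = False
        traj = ch.trajectory(expr, meta, "P1", "TPO")
        assert traj["day"].tolist() == [-1, 1, 30]
        # missing TG stays missing, never 0
        assert np.isnan(traj.loc[traj["timepoint_label"] == "1mo", "serum_tg"].iloc[0])

    def test_unknown_patient_is_lookup_error(self):
        expr, meta = _expr_meta([("P1", "pre", "pre", -1, 9.0)])
        with pytest.raises(KeyError):
            ch.trajectory(expr, meta, "NOPE", "TPO")

    def test_simulated_course_fall_then_persistently_low(self, zero_noise_config):
        ct, meta, panel, truth = simulate_cohort(zero_noise_config)
        expr, _ = normalize(ct, panel)
        traj = ch.trajectory(expr, meta, "P001", "THY1")
        assert traj.loc[0, "expression"] > traj.loc[1, "expression"]
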