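"""Trajectory stratification, median ratio and the univariate battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrstrat.stratify import (STRATA, correlate_response, detect_mixing,
                               median_ratio, paired_battery,
                               trajectory_distance)


def _scores_frame(rows):
    """rows: (patient, t_pre, t_post) triples -> aligned series."""
    pids, tps, scores = [], [], []
    for pid, t_pre, t_post in rows:
        pids += [pid, pid]
        tps += ["pre", "post"]
        scores += [t_pre, t_post]
    return pd.Series(scores), pd.Series(tps), pd.Series(pids)


class TestDetectMixing:
    @pytest.mark.parametrize("t_pre,t_post,expected", [
        (-2.0, 3.0, "Grey"),   # both samples on their expected sides
        (-1.0, -0.5, "Red"),   # post stuck on the pre side
        (0.3, 1.0, "Green"),   # pre already on the post side
        (0.5, -0.2, "Red"),    # both crossed: Red takes precedence
    ])
    def test_stratum_assignment(self, t_pre, t_post, expected):
        # anchor patients keep the orientation well defined
        rows = [("anchor1", -5.0, 5.0), ("anchor2", -4.0, 6.0),
                ("case", t_pre, t_post)]
        out = detect_mixing(*_scores_frame(rows))
        assert out.loc["case", "stratum"] == expected

    def test_orientation_flip_is_normalized(self):
        rows = [("a", -2.0, 3.0), ("b", -1.0, 4.0), ("c", 1.0, -0.5)]
        flipped = [(pid, -pre, -post) for pid, pre, post in rows]
        out = detect_mixing(*_scores_frame(rows))
        out_f = detect_mixing(*_scores_frame(flipped))
        pd.testing.assert_series_equal(out["stratum"], out_f["stratum"])

    def test_unpaired_patient_excluded_and_reported(self):
        scores = pd.Series([-1.0, 2.0, 0.5])
        tps = pd.Series(["pre", "post", "pre"])
        pids = pd.Series(["a", "a", "orphan"])
        out = detect_mixing(scores, tps, pids)
        assert "orphan" not in out.index
        assert out.attrs["excluded"] == ["orphan"]

    def test_strata_partition_cohort(self):
        rng = np.random.default_rng(0)
        rows = [(f"p{i}", rng.normal(-1, 1), rng.normal(1, 1))
                for i in range(40)]
        out = detect_mixing(*_scores_frame(rows))
        assert len(out) == 40
        assert set(out["stratum"]) <= set(STRATA)


class TestTrajectoryDistance:
    @pytest.mark.parametrize("t_pre,t_post,dist,correct", [
        (-2.0, 3.0, 5.0, True),
        (1.0, 1.0, 0.0, False),
        (2.0, -1.0, 3.0, False),  # reversed trajectory
    ])
    def test_distance_and_direction(self, t_pre, t_post, dist, correct):
        d, ok = trajectory_distance(t_pre, t_post)
        assert d == pytest.approx(dist)
        assert ok is correct


class TestMedianRatio:
    @pytest.mark.parametrize("a,b,expected", [
        ([2.0], [4.0], 50.0),
        ([3.0, 3.0], [3.0], 0.0),
        ([1.0], [100.0], 99.0),
    ])
    def test_known_values(self, a, b, expected):
        assert median_ratio(a, b) == pytest.approx(expected)

    def test_symmetric_in_group_order(self):
        assert median_ratio([2.0], [8.0]) == median_ratio([8.0], [2.0])

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            median_ratio([-1.0, 1.0, -2.0], [5.0])

    @given(st.lists(st.floats(0.1, 1e6), min_size=1, max_size=9),
           st.lists(st.floats(0.1, 1e6), min_size=1, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval_percent(self, a, b):
        assert 0.0 <= median_ratio(a, b) < 100.0


def _metabolite_frame(pre, post, name="met"):
    rows = []
    for i, (a, b) in enumerate(zip(pre, post)):
        pid = f"p{i:02d}"
        rows.append({"sample_id": f"{pid}_pre", "patient_id": pid,
                     "timepoint": "pre", name: float(a)})
        rows.append({"sample_id": f"{pid}_post", "patient_id": pid,
                     "timepoint": "post", name: float(b)})
    return pd.DataFrame(rows).set_index("sample_id")


class TestPairedBattery:
    def test_identical_pre_post_gives_p_one_and_zero_ratio(self):
        vals = np.linspace(1.0, 2.0, 12)
        table = paired_battery(_metabolite_frame(vals, vals))
        row = table[(table.test == "WSR")
                    & (table.comparison == "pre_vs_post[all]")].iloc[0]
        assert row.p_value == pytest.approx(1.0)
        assert row.median_ratio_pct == pytest.approx(0.0)

    def test_doubled_post_highly_significant_at_n20(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(1.0, 2.0, 20)
        table = paired_battery(_metabolite_frame(pre, 2.0 * pre))
        row = table[table.test == "WSR"].iloc[0]
        assert row.p_value < 0.001

    def test_identical_strata_kwa_nonsignificant(self):
        vals = np.tile(np.linspace(1.0, 2.0, 4), 3)
        strata = pd.Series(["Grey"] * 4 + ["Red"] * 4 + ["Green"] * 4,
                           index=[f"p{i:02d}" for i in range(12)])
        # identical pre/post vectors in every stratum
        table = paired_battery(_metabolite_frame(vals, vals), strata=strata)
        kwa = table[table.test == "KWA"]
        assert (kwa.p_value > 0.9).all()

    def test_small_groups_skipped_with_reason(self):
        vals = np.linspace(1.0, 2.0, 4)
        strata = pd.Series(["Grey", "Grey", "Grey", "Red"],
                           index=[f"p{i:02d}" for i in range(4)])
        table = paired_battery(_metabolite_frame(vals, vals * 1.1),
                               strata=strata)
        skipped = table[table.note.str.contains("skipped", na=False)]
        assert len(skipped) > 0

    def test_rank_tests_invariant_under_transforms(self):
        # MWU compares value ranks: invariant under any strictly increasing
        # transform.  WSR ranks the magnitudes of paired differences, so
        # invariance holds for positive affine transforms.
        rng = np.random.default_rng(9)
        pre = rng.uniform(1.0, 3.0, 15)
        post = pre * rng.uniform(0.8, 1.6, 15)
        sex = pd.Series(["M"] * 8 + ["F"] * 7,
                        index=[f"p{i:02d}" for i in range(15)])
        t1 = paired_battery(_metabolite_frame(pre, post), sex=sex)
        t_exp = paired_battery(_metabolite_frame(np.exp(pre), np.exp(post)),
                               sex=sex)
        t_aff = paired_battery(_metabolite_frame(3.0 * pre + 2.0,
                                                 3.0 * post + 2.0), sex=sex)
        p = lambda t, test: t[t.test == test]["p_value"].to_numpy()
        np.testing.assert_allclose(p(t1, "MWU"), p(t_exp, "MWU"), rtol=1e-9)
        np.testing.assert_allclose(p(t1, "MWU"), p(t_aff, "MWU"), rtol=1e-9)
        np.testing.assert_allclose(p(t1, "WSR"), p(t_aff, "WSR"), rtol=1e-9)


class TestCorrelateResponse:
    def test_delta_identical_to_response_is_retained_with_r_one(self):
        idx = [f"p{i}" for i in range(10)]
        deltas = pd.DataFrame({"met": np.arange(10.0)}, index=idx)
        responses = pd.DataFrame({"resp": np.arange(10.0)}, index=idx)
        out = correlate_response(deltas, responses)
        assert len(out) == 1
        assert out.iloc[0]["R"] == pytest.approx(1.0)

    def test_constant_response_skipped(self):
        idx = [f"p{i}" for i in range(10)]
        deltas = pd.DataFrame({"met": np.arange(10.0)}, index=idx)
        responses = pd.DataFrame({"resp": np.ones(10)}, index=idx)
        out = correlate_response(deltas, responses, return_all=True)
        assert len(out) == 0

    def test_null_retention_rate_matches_filter(self):
        # independent delta/response at n=50: the |R| > 0.3 cut dominates
        rng = np.random.default_rng(12)
        hits = 0
        reps = 400
        for _ in range(reps):
            idx = [f"p{i}" for i in range(50)]
            deltas = pd.DataFrame({"met": rng.normal(size=50)}, index=idx)
            responses = pd.DataFrame({"resp": rng.normal(size=50)}, index=idx)
            hits += len(correlate_response(deltas, responses))
        rate = hits / reps
        assert 0.005 < rate < 0.065
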