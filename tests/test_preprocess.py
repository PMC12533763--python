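import numpy as np
import pandas as pd
import pytest

from vwpdpa import (
    BinGrid,
    ConfigError,
    FilterRule,
    GazeSample,
    RoiLayout,
    TrialRecord,
    ValidationError,
    accuracy_summary,
    aggregate_participant,
    assign_quadrant,
    assign_roi,
    bin_trial,
    compute_bin_series,
    expand_fixations,
    filter_participants,
    regroup_by_metadata,
    rotate_role_assignment,
)
from vwpdpa.preprocess import QUADRANTS

from conftest import trial_record_from_row

ROLES = ("target", "cu_target", "distractor1", "distractor2")


def make_trial(rotation_id=0, condition="CP", clicked="target", **kw):
    return TrialRecord(
        participant_id="p1",
        trial_id="t1",
        item_id="i1",
        sub_experiment="1",
        condition=condition,
        role_of_quadrant=rotate_role_assignment(ROLES, rotation_id),
        clicked_role=clicked,
        accuracy=kw.pop("accuracy", 1),
        **kw,
    )


class TestRoiLayout:
    def test_padded_boxes_disjoint_and_on_screen(self, layout):
        boxes = list(layout.padded_boxes().values())
        for b in boxes:
            assert 0 <= b.x0 < b.x1 <= layout.screen_w
            assert 0 <= b.y0 < b.y1 <= layout.screen_h
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = boxes[i], boxes[j]
                overlap = a.x0 <= b.x1 and b.x0 <= a.x1 and a.y0 <= b.y1 and b.y0 <= a.y1
                assert not overlap

    def test_rotation_balances_roles_over_quadrants(self):
        seen = {q: set() for q in QUADRANTS}
        for rot in range(4):
            for q, role in rotate_role_assignment(ROLES, rot).items():
                seen[q].add(role)
        assert all(s == set(ROLES) for s in seen.values())


class TestAssignRoi:
    def test_center_of_target_box(self, layout):
        trial = make_trial(rotation_id=0)
        b = layout.image_boxes()["q1"]
        s = GazeSample("p1", "t1", 0.0, (b.x0 + b.x1) / 2, (b.y0 + b.y1) / 2)
        assert assign_roi(s, layout, trial) == "target"

    def test_screen_corner_is_no_roi(self, layout):
        s = GazeSample("p1", "t1", 0.0, 512.0, 384.0)  # screen center, between boxes
        assert assign_roi(s, layout, make_trial()) is None

    def test_fifty_px_margin_left_of_image_belongs_to_image(self):
        # use a roomy screen so the 50 px pad is not clamped at the edge
        layout = RoiLayout(screen_w=1400, screen_h=1100, margin=100)
        trial = make_trial()
        b = layout.image_boxes()["q1"]
        s = GazeSample("p1", "t1", 0.0, b.x0 - 50.0, (b.y0 + b.y1) / 2)
        assert assign_roi(s, layout, trial) == "target"
        s_out = GazeSample("p1", "t1", 0.0, b.x0 - 50.001, (b.y0 + b.y1) / 2)
        assert assign_roi(s_out, layout, trial) is None

    def test_invalid_sample_maps_to_none(self, layout):
        b = layout.image_boxes()["q1"]
        s = GazeSample("p1", "t1", 0.0, b.x0 + 1, b.y0 + 1, valid=False)
        assert assign_roi(s, layout, make_trial()) is None

    def test_matches_brute_force_scan_all_rotations(self, layout):
        rng = np.random.default_rng(7)
        x = rng.uniform(-20, layout.screen_w + 20, 10_000)
        y = rng.uniform(-20, layout.screen_h + 20, 10_000)
        fast = assign_quadrant(x, y, layout)
        boxes = layout.padded_boxes()
        for rot in range(4):
            trial = make_trial(rotation_id=rot)
            for i in range(0, 10_000, 7):  # dense subsample of the grid
                hits = [
                    q
                    for q in QUADRANTS
                    if boxes[q].x0 <= x[i] <= boxes[q].x1
                    and boxes[q].y0 <= y[i] <= boxes[q].y1
                ]
                assert len(hits) <= 1
                expected = trial.role_of_quadrant[hits[0]] if hits else None
                s = GazeSample("p", "t", 0.0, x[i], y[i])
                assert assign_roi(s, layout, trial) == expected
                assert (fast[i] >= 0) == bool(hits)


class TestBinTrial:
    def _grid(self):
        return BinGrid(bin_ms=20, window_start_ms=0, window_end_ms=200)

    def _samples(self, t, x, y, valid=None):
        return pd.DataFrame(
            {
                "t_ms": t,
                "x": x,
                "y": y,
                "valid": np.ones(len(t), bool) if valid is None else valid,
            }
        )

    def test_all_samples_in_target_gives_ones(self, layout):
        trial = make_trial()
        b = layout.image_boxes()["q1"]
        t = np.arange(0, 200)
        s = self._samples(t, np.full(200, b.x0 + 10), np.full(200, b.y0 + 10))
        out = bin_trial(s, layout, trial, self._grid())
        assert np.allclose(out["target"], 1.0)
        for role in ("cu_target", "distractor1", "distractor2"):
            assert np.allclose(out[role], 0.0)
        assert (out["n_valid"] == 20).all()  # 1000 Hz, 20 ms bins

    def test_alternating_roles_give_half_each(self, layout):
        trial = make_trial()
        b1 = layout.image_boxes()["q1"]
        b2 = layout.image_boxes()["q2"]
        t = np.arange(0, 200)
        x = np.where(t % 2 == 0, b1.x0 + 5, b2.x0 + 5)
        y = np.full(200, b1.y0 + 5)
        out = bin_trial(self._samples(t, x, y), layout, trial, self._grid())
        assert np.allclose(out["target"], 0.5)
        assert np.allclose(out["cu_target"], 0.5)

    def test_invalid_samples_leave_bins_missing_not_zero(self, layout):
        trial = make_trial()
        b = layout.image_boxes()["q1"]
        t = np.arange(0, 200)
        valid = t < 100  # blink in the second half
        out = bin_trial(
            self._samples(t, np.full(200, b.x0 + 1), np.full(200, b.y0 + 1), valid),
            layout,
            trial,
            self._grid(),
        )
        assert np.allclose(out["target"].iloc[:5], 1.0)
        assert out["target"].iloc[5:].isna().all()
        assert (out["n_valid"].iloc[5:] == 0).all()

    def test_unsorted_samples_rejected(self, layout):
        s = self._samples([0.0, 2.0, 1.0], [0, 0, 0], [0, 0, 0])
        with pytest.raises(ValidationError):
            bin_trial(s, layout, make_trial(), self._grid())


class TestAggregateParticipant:
    def _frame(self, target_vals):
        idx = pd.Index([0.0, 20.0], name="bin_start_ms")
        df = pd.DataFrame({"target": target_vals, "cu_target": 0.0}, index=idx)
        df["n_valid"] = 20
        return df

    def test_mean_over_trials(self):
        bins = [(make_trial(), self._frame([1.0, 1.0])), (make_trial(), self._frame([0.0, 0.0]))]
        out = aggregate_participant(bins)
        assert np.allclose(out["target"], 0.5)
        assert (out["n_trials"] == 2).all()

    def test_incorrect_trials_dropped(self):
        bad = make_trial(clicked="distractor1", accuracy=0)
        bins = [(make_trial(), self._frame([1.0, 1.0])), (bad, self._frame([0.0, 0.0]))]
        out = aggregate_participant(bins, keep_only_correct=True)
        assert np.allclose(out["target"], 1.0)
        out2 = aggregate_participant(bins, keep_only_correct=False)
        assert np.allclose(out2["target"], 0.5)

    def test_missing_trial_bin_excluded_from_mean(self):
        f1 = self._frame([np.nan, 0.8])
        f2 = self._frame([0.4, 0.4])
        out = aggregate_participant([(make_trial(), f1), (make_trial(), f2)])
        assert out["target"].iloc[0] == pytest.approx(0.4)
        assert out["target"].iloc[1] == pytest.approx(0.6)
        assert list(out["n_trials"]) == [1, 2]

    def test_order_invariance(self):
        frames = [self._frame([v, 1 - v]) for v in (0.1, 0.5, 0.9)]
        bins = [(make_trial(), f) for f in frames]
        a = aggregate_participant(bins)
        b = aggregate_participant(list(reversed(bins)))
        pd.testing.assert_frame_equal(a, b)

    def test_zero_trials_is_an_error(self):
        bad = make_trial(clicked="distractor1", accuracy=0)
        with pytest.raises(ValidationError):
            aggregate_participant([(bad, self._frame([1.0, 1.0]))])


class TestComputeBinSeries:
    def test_agrees_with_single_trial_route(self, small_cohort, layout, grid):
        """Vectorized cohort binning must equal bin_trial + aggregate_participant."""
        bs = compute_bin_series(small_cohort.samples, small_cohort.trials, layout, grid)
        pid = small_cohort.participants["participant_id"].iloc[0]
        trials = small_cohort.trials
        sel = trials[
            (trials["participant_id"] == pid)
            & (trials["sub_experiment"] == "1")
            & (trials["condition"] == "CP")
        ]
        per_trial = []
        for _, row in sel.iterrows():
            tr = trial_record_from_row(row)
            s = small_cohort.samples[
                (small_cohort.samples["participant_id"] == pid)
                & (small_cohort.samples["trial_id"] == row["trial_id"])
            ]
            per_trial.append((tr, bin_trial(s, layout, tr, grid)))
        expected = aggregate_participant(per_trial)
        got = bs[
            (bs["participant_id"] == pid)
            & (bs["sub_experiment"] == "1")
            & (bs["condition"] == "CP")
        ]
        for role in ("target", "cu_target", "distractor1", "distractor2"):
            g = got[got["role"] == role].sort_values("bin_index")["proportion"].to_numpy()
            np.testing.assert_allclose(g, expected[role].to_numpy(), atol=1e-12)

    def test_role_proportions_sum_at_most_one(self, small_bin_series):
        sums = (
            small_bin_series.groupby(
                ["participant_id", "sub_experiment", "condition", "bin_index"],
                observed=True,
            )["proportion"]
            .sum()
            .dropna()
        )
        assert (sums <= 1.0 + 1e-9).all()

    def test_proportions_within_unit_interval(self, small_bin_series):
        p = small_bin_series["proportion"].dropna()
        assert ((p >= 0) & (p <= 1)).all()


class TestParticipantFilters:
    def _meta(self):
        return pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "d"],
                "group": ["PwNH", "PwNH", "PwHL_low_demand", "PwHL_high_demand"],
                "intelligibility_pct": [100.0, 40.0, 96.0, 100.0],
                "effort_rating": [8.0, 10.0, 40.0, 15.0],
            }
        )

    def test_intelligibility_threshold_excludes(self):
        kept, log = filter_participants(
            self._meta(), [FilterRule("intelligibility_pct", ">=", 50, "poor_intelligibility")]
        )
        assert kept == ["a", "c", "d"]
        assert log["poor_intelligibility"] == 1

    def test_perfect_intelligibility_subset(self):
        kept, _ = filter_participants(
            self._meta(), [FilterRule("intelligibility_pct", "==", 100)]
        )
        assert kept == ["a", "d"]

    def test_always_true_rule_is_identity(self):
        kept, log = filter_participants(
            self._meta(), [FilterRule("intelligibility_pct", ">=", 0)]
        )
        assert kept == ["a", "b", "c", "d"]

    def test_unknown_field_is_config_error(self):
        with pytest.raises(ConfigError):
            filter_participants(self._meta(), [FilterRule("nonexistent", ">=", 1)])

    def test_tightening_threshold_is_monotone(self):
        rng = np.random.default_rng(3)
        meta = pd.DataFrame(
            {
                "participant_id": [f"p{i}" for i in range(40)],
                "group": "G",
                "intelligibility_pct": rng.uniform(0, 100, 40),
            }
        )
        prev = None
        for thr in (0, 25, 50, 75, 100):
            kept, _ = filter_participants(
                meta, [FilterRule("intelligibility_pct", ">=", thr)]
            )
            if prev is not None:
                assert set(kept) <= prev
            prev = set(kept)

    def test_effort_regrouping_boundary(self):
        meta = self._meta()
        grouping = [
            ("low_effort", [FilterRule("effort_rating", "<", 15)]),
            ("high_effort", [FilterRule("effort_rating", ">", 15)]),
        ]
        mapping, dropped = regroup_by_metadata(meta, grouping)
        assert mapping["a"] == "low_effort"
        assert mapping["c"] == "high_effort"
        assert dropped == ["d"]  # effort exactly 15 matches neither printed rule

    def test_overlapping_groups_rejected(self):
        grouping = [
            ("g1", [FilterRule("effort_rating", "<", 20)]),
            ("g2", [FilterRule("effort_rating", "<", 30)]),
        ]
        with pytest.raises(ConfigError):
            regroup_by_metadata(self._meta(), grouping)


class TestAccuracySummary:
    def test_proportions_and_counts(self):
        trials = pd.DataFrame(
            {
                "participant_id": ["a"] * 100,
                "sub_experiment": "1",
                "condition": "CP",
                "accuracy": [1] * 92 + [0] * 8,
            }
        )
        meta = pd.DataFrame({"participant_id": ["a"], "group": ["G"]})
        out = accuracy_summary(trials, meta)
        assert out["mean_accuracy"].iloc[0] == pytest.approx(0.92)
        assert out["n_trials"].iloc[0] == 100

    def test_simulated_accuracy_near_generating_probability(self, small_cohort):
        """Generated accuracies should sit within binomial error of the
        per-condition generating probabilities."""
        meta = small_cohort.participants
        out = accuracy_summary(small_cohort.trials, meta)
        expected = {("1", "CP"): 0.99, ("1", "CU"): 0.92, ("2", "CP"): 0.97, ("filler", "neutral"): 0.97}
        for (_, row) in out.iterrows():
            p = expected[(row["sub_experiment"], row["condition"])]
            n = row["n_trials"]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(row["mean_accuracy"] - p) < 4 * se + 1e-9


class TestFixationExpansion:
    def test_expansion_matches_sample_grid(self):
        fix = pd.DataFrame(
            {
                "participant_id": ["p"],
                "trial_id": ["t"],
                "fix_start_ms": [10.0],
                "fix_end_ms": [14.0],
                "x": [100.0],
                "y": [200.0],
            }
        )
        out = expand_fixations(fix, sample_rate_hz=1000)
        assert list(out["t_ms"]) == [10.0, 11.0, 12.0, 13.0]
        assert (out["x"] == 100.0).all()
        assert out["valid"].all()
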