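"""Event matching, outcome summaries, calibration error."""

import numpy as np
import pandas as pd
import pytest

from pufov import AlignmentParams, align_track, extract_saccades
from pufov.metrics import calibration_error, match_events, summarize_participant
from pufov.stimulus import ChangeEvent
from pufov.synth import simulate_participant


def _session(grid, events, layout, profile, seed, instructed="motion", video=60.0, grace=1.0):
    s = simulate_participant(grid, events, instructed, profile, layout, seed, video)
    aligned = align_track(s.gaze, grid, AlignmentParams())
    sacs = extract_saccades(aligned, grid, layout)
    out = match_events(
        events, instructed, aligned, sacs, s.keypresses, grid, layout, grace, gaze=s.gaze
    )
    return s, aligned, sacs, out


class TestMatchEvents:
    def test_no_keypresses_means_no_detections(self, grid, short_events, layout, profile):
        s, aligned, sacs, _ = _session(grid, short_events, layout, profile, 3)
        out = match_events(
            short_events, "motion", aligned, sacs, np.array([]), grid, layout, 1.0
        )
        assert not out["detected"].any()
        assert out["key_rt_s"].isna().all()

    def test_noiseless_session_recovers_ground_truth_exactly(
        self, grid, short_events, layout, noiseless_profile
    ):
        s, _, _, out = _session(grid, short_events, layout, noiseless_profile, 21)
        gt = s.ground_truth[s.ground_truth["instructed"]]
        merged = gt.merge(out, on="event_id", suffixes=("_gt", ""))
        assert (merged["detected_gt"] == merged["detected"]).all()
        det = merged[merged["detected"]]
        # keypress times are carried through exactly
        assert np.allclose(det["key_rt_s"], det["keypress_s"] - det["onset_s_gt"])
        # the first aligned look lands within one sampling interval + one
        # update step of the true gaze arrival
        dt = 1.0 / noiseless_profile.rate_hz
        lag = det["gaze_rt_s"] - (det["gaze_arrival_s"] - det["onset_s_gt"])
        assert (lag >= -1e-9).all()
        assert (lag <= 2 * dt + 1e-9).all()

    def test_keypress_after_grace_window_not_counted(self, grid, layout):
        f = int(grid.visible_ids[5])
        ev = [ChangeEvent(0, "color", f, 1.0, 2.5)]
        fobj = grid.feature(f)
        t = np.arange(0, 5, 1 / 60)
        aligned = pd.DataFrame({"t_s": t, "feature_id": f, "v_max": 1.0})
        grace = 1.0
        late = np.array([ev[0].offset + grace + 0.01])
        out = match_events(ev, "color", aligned, [], late, grid, layout, grace)
        assert not out["detected"].any()
        ontime = np.array([ev[0].offset + grace - 0.01])
        out = match_events(ev, "color", aligned, [], ontime, grid, layout, grace)
        assert out["detected"].all()

    def test_keypress_requires_preceding_visit(self, grid, layout):
        a, b = int(grid.visible_ids[5]), int(grid.visible_ids[6])
        ev = [ChangeEvent(0, "color", b, 1.0, 2.5)]
        t = np.arange(0, 5, 1 / 60)
        # gaze never visits b
        aligned = pd.DataFrame({"t_s": t, "feature_id": a, "v_max": 1.0})
        out = match_events(ev, "color", aligned, [], np.array([2.0]), grid, layout, 1.0)
        assert not out["detected"].any()
        # without the visit requirement the keypress suffices
        out = match_events(
            ev, "color", aligned, [], np.array([2.0]), grid, layout, 1.0, require_visit=False
        )
        assert out["detected"].all()

    def test_each_keypress_consumed_once(self, grid, layout):
        a, b = int(grid.visible_ids[5]), int(grid.visible_ids[6])
        ev = [
            ChangeEvent(0, "color", a, 1.0, 2.5),
            ChangeEvent(1, "color", b, 4.0, 5.5),
        ]
        t = np.arange(0, 8, 1 / 60)
        fid = np.where(t < 3.5, a, b)
        aligned = pd.DataFrame({"t_s": t, "feature_id": fid, "v_max": 1.0})
        out = match_events(ev, "color", aligned, [], np.array([2.0, 4.6]), grid, layout, 1.0)
        assert out["detected"].tolist() == [True, True]
        # one keypress can only confirm one of two overlapping windows
        out = match_events(ev, "color", aligned, [], np.array([4.6]), grid, layout, 1.0)
        assert out["detected"].sum() == 1

    def test_detection_monotone_in_grace_on_clean_data(
        self, grid, short_events, layout, noiseless_profile
    ):
        s, aligned, sacs, _ = _session(grid, short_events, layout, noiseless_profile, 23)
        prev: set = set()
        for grace in (0.2, 0.5, 1.0, 2.0):
            out = match_events(
                short_events, "motion", aligned, sacs, s.keypresses, grid, layout, grace
            )
            det = set(out.loc[out["detected"], "event_id"])
            assert prev <= det
            prev = det

    def test_key_rt_not_before_gaze_rt(self, grid, short_events, layout, profile):
        _, _, _, out = _session(grid, short_events, layout, profile, 31)
        det = out[out["detected"] & out["gaze_rt_s"].notna()]
        assert (det["key_rt_s"] >= det["gaze_rt_s"] - 1e-9).all()

    def test_malformed_aligned_track_rejected(self, grid, short_events, layout):
        with pytest.raises(ValueError):
            match_events(
                short_events,
                "motion",
                pd.DataFrame({"time": [0.0]}),
                [],
                np.array([]),
                grid,
                layout,
            )


class TestSummarizeParticipant:
    def test_all_detected_gives_rate_one(self, grid, short_events, layout, noiseless_profile):
        import dataclasses

        from pufov.synth import PerceptionGaussian

        perc = {t: PerceptionGaussian(1.0, 1e9) for t in ("color", "shape", "motion")}
        prof = dataclasses.replace(noiseless_profile, perception=perc)
        _, _, _, out = _session(grid, short_events, layout, prof, 3, instructed="color")
        summary = summarize_participant(out)
        assert summary.per_type.loc["color", "detection_rate"] == 1.0

    def test_missing_types_are_nan_not_zero(self, grid, short_events, layout, profile):
        _, _, _, out = _session(grid, short_events, layout, profile, 3, instructed="shape")
        summary = summarize_participant(out)
        assert np.isnan(summary.per_type.loc["color", "detection_rate"])
        assert summary.per_type.loc["color", "n_events"] == 0

    def test_max_amplitude_at_least_mean(self, grid, short_events, layout, profile):
        _, _, _, out = _session(grid, short_events, layout, profile, 5)
        summary = summarize_participant(out)
        row = summary.per_type.loc["motion"]
        if row["n_detected"] > 0:
            assert row["max_amp_deg"] >= row["mean_amp_deg"] - 1e-9

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ValueError):
            summarize_participant(pd.DataFrame())


class TestCalibrationError:
    def test_reported_per_screen_and_pooled(self, layout, profile):
        from pufov.synth import simulate_calibration

        rec = simulate_calibration(layout, profile, seed=1)
        err = calibration_error(rec, layout)
        assert set(err.index) == {0, 1, 2, "overall"}
        # center screen tracks best, left screen worst (camera placement)
        assert err.loc[1, "error_h_deg"] < err.loc[2, "error_h_deg"] < err.loc[0, "error_h_deg"]

    def test_missing_columns_rejected(self, layout):
        with pytest.raises(ValueError):
            calibration_error(pd.DataFrame({"screen_id": [0]}), layout)
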