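"""Markov/random-walk gaze alignment and saccade extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pufov.alignment import (
    AlignmentParams,
    align_track,
    extract_saccades,
    nearest_feature,
    transition_weight,
)
from pufov.stimulus import generate_grid


def _track(points, rate=60.0, valid=None):
    """Gaze frame from a list of (screen_id, x, y) or None (invalid)."""
    rows = []
    for k, p in enumerate(points):
        if p is None or (valid is not None and not valid[k]):
            rows.append({"t_s": k / rate, "screen_id": -1, "x_px": np.nan, "y_px": np.nan, "valid": False})
        else:
            rows.append({"t_s": k / rate, "screen_id": p[0], "x_px": p[1], "y_px": p[2], "valid": True})
    return pd.DataFrame(rows)


def _feature_track(grid, fids, repeats=3):
    pts = []
    for fid in fids:
        f = grid.feature(fid)
        pts += [(f.screen_id, f.x, f.y)] * repeats
    return _track(pts)


class TestTransitionWeight:
    def test_equidistant_features_give_zero(self):
        g = (0.0, 0.0)
        assert transition_weight(g, (100.0, 0.0), (0.0, 100.0), 150.0) == pytest.approx(0.0)

    def test_on_feature_vs_far_feature_approaches_one(self):
        w = transition_weight((0.0, 0.0), (0.0, 0.0), (1e9, 0.0), 150.0)
        assert w == pytest.approx(1.0)

    def test_closed_form_value(self):
        # d_i = 1, d_j = 2 in units of sigma_T  ->  e^-1 - e^-2
        w = transition_weight((0.0, 0.0), (150.0, 0.0), (300.0, 0.0), 150.0)
        assert w == pytest.approx(np.exp(-1) - np.exp(-2), abs=1e-12)
        assert w == pytest.approx(0.23254, abs=1e-5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        gx=st.floats(0, 5000),
        gy=st.floats(0, 1200),
        fi=st.tuples(st.floats(0, 5000), st.floats(0, 1200)),
        fj=st.tuples(st.floats(0, 5000), st.floats(0, 1200)),
    )
    def test_antisymmetric_in_features(self, gx, gy, fi, fj):
        w_ij = transition_weight((gx, gy), fi, fj, 150.0)
        w_ji = transition_weight((gx, gy), fj, fi, 150.0)
        assert w_ij == pytest.approx(-w_ji, abs=1e-12)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            transition_weight((0, 0), (1, 1), (2, 2), 0.0)


class TestAlignTrack:
    def test_empty_track_rejected(self, grid):
        with pytest.raises(ValueError):
            align_track(_track([]), grid)

    @pytest.mark.parametrize("mode", ["literal", "proximity"])
    def test_gaze_on_feature_aligns_to_it(self, grid, mode):
        fid = int(grid.visible_ids[10])
        track = _feature_track(grid, [fid], repeats=4)
        aligned = align_track(track, grid, AlignmentParams(mode=mode))
        assert (aligned["feature_id"].iloc[1:] == fid).all()

    def test_literal_mode_equals_nearest_feature_oracle(self, grid, rng):
        # the row-convention matrix update, after clipping and renormalizing,
        # must select the nearest visible feature at every sample
        pts = [
            (int(rng.integers(3)), float(rng.uniform(0, 1919)), float(rng.uniform(0, 1199)))
            for _ in range(1000)
        ]
        track = _track(pts)
        aligned = align_track(track, grid, AlignmentParams(mode="literal"))
        oracle = nearest_feature(track, grid)
        assert np.array_equal(aligned["feature_id"].to_numpy(), oracle)

    def test_literal_reduction_identity(self, grid, rng):
        # (T v)_i = exp(-d_i) * sum(v) - <exp(-d), v>: a common offset from
        # exp(-d_i), so the post-clip argmax is the minimal distance
        feats = grid.positions_unrolled(only_visible=True)
        for _ in range(20):
            g = rng.uniform([0, 0], [5760, 1200])
            v = rng.dirichlet(np.ones(len(feats)))
            d = np.hypot(feats[:, 0] - g[0], feats[:, 1] - g[1]) / 150.0
            e = np.exp(-d)
            tv = np.array(
                [sum((e[i] - e[j]) * v[j] for j in range(len(v))) for i in range(len(v))]
            )
            expected = e * v.sum() - e @ v
            assert np.allclose(tv, expected, atol=1e-12)
            assert np.argmax(np.clip(tv, 0, None)) == np.argmin(d)

    def test_state_is_normalized_distribution(self, grid, rng):
        pts = [(1, float(rng.uniform(0, 1919)), float(rng.uniform(0, 1199))) for _ in range(50)]
        aligned = align_track(_track(pts), grid, AlignmentParams(mode="proximity"))
        assert (aligned["v_max"] > 0).all()
        assert (aligned["v_max"] <= 1.0 + 1e-12).all()

    def test_sticky_state_ignores_single_sample_excursion(self, grid):
        # gaze rests on feature a; one sample jumps halfway to the adjacent
        # feature; with lambda = 0.9 the aligned fixation must not change
        a, b = 30, 31
        fa, fb = grid.feature(a), grid.feature(b)
        assert fa.screen_id == fb.screen_id
        mid = ((fa.x + fb.x) / 2.0, (fa.y + fb.y) / 2.0)
        pts = [(fa.screen_id, fa.x, fa.y)] * 10 + [(fa.screen_id, *mid)] + [
            (fa.screen_id, fa.x, fa.y)
        ] * 3
        aligned = align_track(_track(pts), grid, AlignmentParams(mode="proximity", stickiness=0.9))
        assert (aligned["feature_id"].iloc[1:] == a).all()

    def test_hysteresis_grows_with_stickiness(self, grid):
        # minimum excursion duration needed to switch the aligned fixation
        # is monotone in lambda
        a, b = 30, 31
        fa, fb = grid.feature(a), grid.feature(b)

        def switch_samples(lam):
            pts = [(fa.screen_id, fa.x, fa.y)] * 20 + [(fb.screen_id, fb.x, fb.y)] * 40
            aligned = align_track(
                _track(pts), grid, AlignmentParams(mode="proximity", stickiness=lam)
            )
            ids = aligned["feature_id"].to_numpy()
            return int(np.argmax(ids[20:] == b))

        laps = [switch_samples(lam) for lam in (0.0, 0.3, 0.6, 0.9)]
        assert all(b >= a for a, b in zip(laps, laps[1:]))
        assert laps[-1] > laps[0]

    def test_invalid_samples_hold_previous_state(self, grid):
        a, b = 40, 80
        fa, fb = grid.feature(a), grid.feature(b)
        pts = (
            [(fa.screen_id, fa.x, fa.y)] * 5
            + [None] * 5
            + [(fb.screen_id, fb.x, fb.y)] * 5
        )
        aligned = align_track(_track(pts), grid, AlignmentParams(mode="proximity"))
        # during the blink the aligned feature stays put rather than resetting
        assert (aligned["feature_id"].iloc[4:10] == a).all()
        assert aligned["feature_id"].iloc[-1] == b

    def test_modes_agree_for_clean_fixations(self, grid):
        fids = [int(grid.visible_ids[k]) for k in (0, 40, 90)]
        track = _feature_track(grid, fids, repeats=10)
        lit = align_track(track, grid, AlignmentParams(mode="literal"))
        prox = align_track(track, grid, AlignmentParams(mode="proximity", stickiness=0.3))
        # ignore the transition samples right after each jump
        settled = np.ones(len(track), dtype=bool)
        for j in (10, 20):
            settled[j : j + 3] = False
        assert np.array_equal(
            lit["feature_id"].to_numpy()[settled], prox["feature_id"].to_numpy()[settled]
        )


class TestExtractSaccades:
    def test_constant_track_has_no_saccades(self, grid, layout):
        aligned = align_track(_feature_track(grid, [12], repeats=10), grid)
        assert extract_saccades(aligned, grid, layout) == []

    def test_single_jump_between_adjacent_features(self, grid, layout):
        # two horizontally adjacent features on the center screen: one
        # saccade of exactly 200 px
        a = next(
            f.feature_id
            for f in grid.features
            if f.screen_id == 1 and f.x < 1600 and grid.feature(f.feature_id + 1).screen_id == 1
        )
        aligned = align_track(_feature_track(grid, [a, a + 1], repeats=5), grid)
        sacs = extract_saccades(aligned, grid, layout)
        assert len(sacs) == 1
        assert sacs[0].amplitude_px == pytest.approx(200.0)
        assert sacs[0].from_feature == a and sacs[0].to_feature == a + 1

    def test_collinear_jumps_merge_end_to_end(self, grid, layout):
        from pufov.geometry import angular_distance

        # A -> B -> C along one row with sub-threshold dwell: one saccade A->C
        a = next(f.feature_id for f in grid.features if f.screen_id == 1 and f.col == 10)
        b, c = a + 1, a + 2
        aligned = align_track(_feature_track(grid, [a, b, c], repeats=2), grid)
        sacs = extract_saccades(aligned, grid, layout, merge_angle_deg=45.0, merge_gap_s=0.1)
        assert len(sacs) == 1
        assert (sacs[0].from_feature, sacs[0].to_feature) == (a, c)
        fa, fc = grid.feature(a), grid.feature(c)
        assert sacs[0].amplitude_deg == pytest.approx(
            angular_distance(layout, (fa.screen_id, fa.x, fa.y), (fc.screen_id, fc.x, fc.y))
        )
        assert sacs[0].amplitude_px == pytest.approx(400.0)

    def test_slow_jumps_stay_separate(self, grid, layout):
        a = next(f.feature_id for f in grid.features if f.screen_id == 1 and f.col == 10)
        aligned = align_track(_feature_track(grid, [a, a + 1, a + 2], repeats=30), grid)
        sacs = extract_saccades(aligned, grid, layout, merge_gap_s=0.1)
        assert len(sacs) == 2

    def test_amplitude_invariant_to_noise_within_basin(self, grid, layout, rng):
        # gaze noise that never changes the aligned feature leaves saccade
        # amplitudes untouched
        a, b = 30, 33
        fa, fb = grid.feature(a), grid.feature(b)
        clean = [(fa.screen_id, fa.x, fa.y)] * 10 + [(fb.screen_id, fb.x, fb.y)] * 10
        noisy = [
            (s, x + rng.uniform(-40, 40), y + rng.uniform(-40, 40)) for s, x, y in clean
        ]
        amp = lambda pts: [
            s.amplitude_deg
            for s in extract_saccades(
                align_track(_track(pts), grid, AlignmentParams(mode="literal")), grid, layout
            )
        ]
        assert amp(noisy) == amp(clean)
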