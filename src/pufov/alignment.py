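"""Gaze-to-feature alignment via a Markov model with a random walk.

Tracker noise in a wide-FOV simulator is too large to assign raw gaze
samples to 40 px stimulus objects directly.  Because the darkened background
offers no other fixation targets, every displayed feature is treated as a
state of a Markov chain, and a state vector ``v`` holds the relative
likelihood that the current fixation belongs to each feature.  For a gaze
sample ``g_t`` the transition weight from feature ``f_i`` to ``f_j`` is the
difference of saturating distance terms

    T[f_i, f_j] = (1 - exp(-|g_t - f_j| / sigma_T))
                - (1 - exp(-|g_t - f_i| / sigma_T))
                = exp(-d_i) - exp(-d_j),        d_k = |g_t - f_k| / sigma_T,

with distances in pixels on the unrolled three-canvas plane.  Each new
sample rebuilds ``T`` and performs one random-walk iteration
``v_t = T v_{t-1}``; the aligned fixation ``g'_t`` is the feature with
maximal likelihood.

Two update modes are provided:

``literal``
    The matrix iteration exactly as written, with the row convention
    ``(v_t)_i = sum_j T[f_i, f_j] (v_{t-1})_j``, negative entries clipped to
    zero and the vector renormalized.  Algebraically
    ``(v_t)_i = exp(-d_i) * sum(v) - sum_j exp(-d_j) (v_{t-1})_j``, i.e. a
    common offset subtracted from ``exp(-d_i)``; the argmax is therefore
    always the feature nearest to the current sample.  (The opposite, column
    convention would instead favour the *farthest* feature, which is clearly
    not the intended reading.)  This mode carries no memory.

``proximity`` (default)
    A damped variant that keeps the per-sample proximity likelihood
    ``w_i ∝ exp(-d_i)`` but mixes it with the previous state,
    ``v_t = lambda * v_{t-1} + (1 - lambda) * w``.  The stickiness
    ``lambda`` gives the aligned fixation hysteresis against single-sample
    noise excursions; ``lambda = 0`` reduces to per-sample nearest-feature
    snapping.

Whenever the aligned feature changes, the interval between the two samples
is counted as a saccade; strings of saccades in a similar direction with
negligible intervening dwell are merged into a single saccade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import geometry as geom
from .stimulus import FeatureGrid

__all__ = [
    "AlignmentParams",
    "Saccade",
    "transition_weight",
    "align_track",
    "nearest_feature",
    "extract_saccades",
    "saccades_to_frame",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Parameters of the random-walk alignment.

    sigma_t_px : distance scale of the transition weights, in pixels.  The
        default (150 px) is the horizontal tracker error of the reference
        setup expressed in pixels.
    mode : "literal" or "proximity" (see module docstring).
    stickiness : mixing weight lambda of the proximity mode, in [0, 1).
    """

    sigma_t_px: float = 150.0
    mode: str = "proximity"
    stickiness: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_t_px <= 0:
            raise ValueError("sigma_t_px must be positive")
        if self.mode not in ("literal", "proximity"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")
        if not (0.0 <= self.stickiness < 1.0):
            raise ValueError("stickiness must lie in [0, 1)")


@dataclass
class Saccade:
    from_feature: int
    to_feature: int
    t_start: float
    t_end: float
    amplitude_px: float
    amplitude_deg: float
    direction_deg: float  # on the unrolled canvas; 0 = rightward, 90 = upward


def transition_weight(g_t, f_i, f_j, sigma_t_px: float):
    """Transition weight from feature i to feature j for gaze sample g_t.

    All points are (x, y) on the unrolled pixel plane.  Equals
    ``exp(-|g-f_i|/sigma) - exp(-|g-f_j|/sigma)``; antisymmetric in (i, j).
    """
    if sigma_t_px <= 0:
        raise ValueError("sigma_t_px must be positive")
    g = np.asarray(g_t, dtype=float)
    di = np.linalg.norm(g - np.asarray(f_i, dtype=float), axis=-1) / sigma_t_px
    dj = np.linalg.norm(g - np.asarray(f_j, dtype=float), axis=-1) / sigma_t_px
    return np.exp(-di) - np.exp(-dj)


def _gaze_unrolled(gaze: pd.DataFrame, columns_px: int) -> tuple[np.ndarray, np.ndarray]:
    pos = np.column_stack(
        [
            np.asarray(gaze["screen_id"], dtype=float) * columns_px
            + np.asarray(gaze["x_px"], dtype=float),
            np.asarray(gaze["y_px"], dtype=float),
        ]
    )
    valid = np.asarray(gaze["valid"], dtype=bool) & np.isfinite(pos).all(axis=1)
    return pos, valid


def nearest_feature(gaze: pd.DataFrame, grid: FeatureGrid) -> np.ndarray:
    """Per-sample nearest visible feature (the memoryless oracle).

    Invalid samples carry the previous assignment (uniform-prior tie rule,
    i.e. the lowest feature id, before the first valid sample).
    """
    feats = grid.positions_unrolled(only_visible=True)
    ids = grid.visible_ids
    pos, valid = _gaze_unrolled(gaze, grid.columns_px)
    out = np.empty(len(pos), dtype=int)
    last = ids[0]
    for k in range(len(pos)):
        if valid[k]:
            d = np.hypot(feats[:, 0] - pos[k, 0], feats[:, 1] - pos[k, 1])
            last = ids[int(np.argmin(d))]
        out[k] = last
    return out


def align_track(
    gaze: pd.DataFrame,
    grid: FeatureGrid,
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Align a gaze track to the feature grid.

    Returns a frame with columns ``t_s``, ``feature_id`` (the aligned
    fixation g'), and ``v_max`` (its normalized likelihood).  The state is
    initialised uniform over visible features; invalid samples hold the
    previous state.  Argmax ties resolve to the lowest feature id.
    """
    if params is None:
        params = AlignmentParams()
    if len(gaze) == 0:
        raise ValueError("empty gaze track")
    ids = grid.visible_ids
    if len(ids) == 0:
        raise ValueError("no visible features to align to")
    feats = grid.positions_unrolled(only_visible=True)
    pos, valid = _gaze_unrolled(gaze, grid.columns_px)
    n, m = len(pos), len(feats)

    v = np.full(m, 1.0 / m)
    vs = np.empty((n, m))
    if params.mode == "literal":
        for k in range(n):
            if valid[k]:
                d = np.hypot(feats[:, 0] - pos[k, 0], feats[:, 1] - pos[k, 1])
                e = np.exp(-d / params.sigma_t_px)
                # (T v)_i = e_i * sum(v) - <e, v>; clip negatives, renormalize
                u = e * v.sum() - float(e @ v)
                np.clip(u, 0.0, None, out=u)
                s = u.sum()
                if s > 0:
                    v = u / s
                else:
                    # v was a point mass at the nearest feature, so the update
                    # is identically zero after clipping; keep the mass there
                    v = np.zeros(m)
                    v[int(np.argmax(e))] = 1.0
            vs[k] = v
    else:
        lam = params.stickiness
        # exact linear recurrence v_t = lam * v_{t-1} + (1-lam) * w_t,
        # evaluated segment-wise over runs of valid samples so that invalid
        # samples hold the previous state
        k = 0
        while k < n:
            if not valid[k]:
                vs[k] = v
                k += 1
                continue
            end = k
            while end < n and valid[end]:
                end += 1
            seg = pos[k:end]
            d = np.hypot(
                feats[None, :, 0] - seg[:, None, 0], feats[None, :, 1] - seg[:, None, 1]
            )
            w = np.exp(-d / params.sigma_t_px)
            w /= w.sum(axis=1, keepdims=True)
            out, _ = lfilter(
                [1.0 - lam], [1.0, -lam], w, axis=0, zi=(lam * v)[None, :]
            )
            out /= out.sum(axis=1, keepdims=True)  # guard accumulation drift
            vs[k:end] = out
            v = out[-1]
            k = end

    idx = np.argmax(vs, axis=1)  # ties -> first (lowest feature id)
    return pd.DataFrame(
        {
            "t_s": np.asarray(gaze["t_s"], dtype=float),
            "feature_id": ids[idx],
            "v_max": vs[np.arange(n), idx],
        }
    )


# ---------------------------------------------------------------------------
# saccade extraction


def _direction_deg(dx: float, dy: float) -> float:
    """Direction on the unrolled canvas, 0 = rightward, 90 = upward."""
    return float(np.degrees(np.arctan2(-dy, dx)))


def _angle_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def extract_saccades(
    aligned: pd.DataFrame,
    grid: FeatureGrid,
    layout: geom.ScreenLayout,
    merge_angle_deg: float = 45.0,
    merge_gap_s: float = 0.1,
) -> list[Saccade]:
    """Segment an aligned track into saccades.

    Every change of the aligned feature yields a saccade from the last sample
    on the old feature to the first sample on the new one.  Consecutive
    saccades whose directions differ by less than ``merge_angle_deg`` and
    whose intervening dwell is shorter than ``merge_gap_s`` are merged into a
    single saccade from the first origin to the last target, with direction
    and both amplitudes recomputed end to end.
    """
    if len(aligned) == 0:
        raise ValueError("empty aligned track")
    t = np.asarray(aligned["t_s"], dtype=float)
    fid = np.asarray(aligned["feature_id"], dtype=int)

    # per-feature unit viewing directions and unrolled positions, computed
    # once so per-saccade amplitudes are table lookups
    pos = np.array(
        [[f.screen_id * grid.columns_px + f.x, f.y] for f in grid.features]
    )
    dirs = np.stack(
        [geom.pixel_to_direction(layout, f.screen_id, f.x, f.y) for f in grid.features]
    )

    def make(f_from: int, f_to: int, t0: float, t1: float) -> Saccade:
        dx = pos[f_to, 0] - pos[f_from, 0]
        dy = pos[f_to, 1] - pos[f_from, 1]
        cosang = float(np.clip(dirs[f_from] @ dirs[f_to], -1.0, 1.0))
        return Saccade(
            from_feature=f_from,
            to_feature=f_to,
            t_start=t0,
            t_end=t1,
            amplitude_px=float(np.hypot(dx, dy)),
            amplitude_deg=float(np.degrees(np.arccos(cosang))),
            direction_deg=_direction_deg(dx, dy),
        )

    raw: list[Saccade] = []
    change = np.nonzero(fid[1:] != fid[:-1])[0]
    for k in change:
        raw.append(make(int(fid[k]), int(fid[k + 1]), float(t[k]), float(t[k + 1])))

    merged: list[Saccade] = []
    for sac in raw:
        if (
            merged
            and _angle_diff(sac.direction_deg, merged[-1].direction_deg) < merge_angle_deg
            and (sac.t_start - merged[-1].t_end) < merge_gap_s
        ):
            prev = merged.pop()
            merged.append(make(prev.from_feature, sac.to_feature, prev.t_start, sac.t_end))
        else:
            merged.append(sac)
    return merged


def saccades_to_frame(saccades: list[Saccade]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "from_feature": [s.from_feature for s in saccades],
            "to_feature": [s.to_feature for s in saccades],
            "t_start_s": [s.t_start for s in saccades],
            "t_end_s": [s.t_end for s in saccades],
            "amplitude_px": [s.amplitude_px for s in saccades],
            "amplitude_deg": [s.amplitude_deg for s in saccades],
            "direction_deg": [s.direction_deg for s in saccades],
        }
    )
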