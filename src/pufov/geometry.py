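"""Three-screen simulator geometry.

The simulator consists of three planar projection canvases arranged around the
driver: a center screen perpendicular to the straight-ahead viewing direction
and two side screens sharing vertical edges with it, each rotated inward so
that adjacent screen planes enclose a configurable angle (151 degrees in the
reference setup).  This module converts between per-screen pixel coordinates,
3-D viewing directions from the (fixed) eye point, and visual angles, and it
defines the "unrolled" 5760 x 1200 pixel plane on which pixel-space distances
are measured.

Conventions
-----------
* Eye point at the origin; ``+z`` points from the eye to the center of the
  center screen, ``+x`` right, ``+y`` up.  All lengths in meters.
* Screens are indexed left=0, center=1, right=2.
* Pixels are 0-based with ``(0, 0)`` the *center* of the top-left pixel;
  pixel x grows rightward, pixel y grows downward.
* Public interfaces use degrees; radians appear only internally.
* Pixel-space (as opposed to angular) distances live on the unrolled canvas:
  ``global_x = screen_id * columns + x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ScreenLayout",
    "VisualAngle",
    "ConfigurationError",
    "build_layout",
    "layout_with_coverage",
    "pixel_to_direction",
    "direction_to_pixel",
    "angular_distance",
    "visual_angle_of",
    "px_distance",
    "unroll_x",
    "max_measurable_eccentricity",
]

N_SCREENS = 3


class ConfigurationError(ValueError):
    """Raised for inconsistent or out-of-range layout parameters."""


@dataclass(frozen=True)
class VisualAngle:
    """Angular position of a viewing direction relative to straight ahead.

    Attributes
    ----------
    eccentricity : float
        Total angle in degrees from the reference (straight-ahead) direction,
        in ``[0, 180]``.
    horizontal : float
        Signed azimuth in degrees, rightward positive.
    vertical : float
        Signed elevation in degrees, upward positive.
    """

    eccentricity: float
    horizontal: float
    vertical: float


@dataclass(frozen=True)
class ScreenLayout:
    """Fixed 3-D placement of the three projection canvases.

    Parameters are the physical screen size, the pixel grid, the angle
    enclosed by adjacent screen planes, and the eye-to-center-screen
    distance.  Derived per-screen plane origins (top-left *corner*, not pixel
    center) and in-plane basis vectors are computed once at construction.
    """

    screen_width_m: float = 3.05
    screen_height_m: float = 1.89
    screen_px: tuple[int, int] = (1920, 1200)  # (columns, rows)
    inter_screen_angle_deg: float = 151.0
    eye_distance_m: float = 3.75

    # derived, filled in __post_init__
    eye_point: np.ndarray = field(init=False, repr=False, compare=False)
    _origins: np.ndarray = field(init=False, repr=False, compare=False)
    _ex: np.ndarray = field(init=False, repr=False, compare=False)
    _ey: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        w, h, d = self.screen_width_m, self.screen_height_m, self.eye_distance_m
        cols, rows = self.screen_px
        if w <= 0 or h <= 0 or d <= 0 or cols <= 0 or rows <= 0:
            raise ConfigurationError("screen dimensions and eye distance must be positive")
        if not (90.0 < self.inter_screen_angle_deg <= 180.0):
            raise ConfigurationError(
                f"inter_screen_angle_deg must lie in (90, 180], got {self.inter_screen_angle_deg}"
            )
        # rotation of each side screen relative to the center-screen plane
        theta = np.radians(180.0 - self.inter_screen_angle_deg)
        c, s = np.cos(theta), np.sin(theta)

        ey = np.array([0.0, -1.0, 0.0])  # pixel y grows downward for every screen
        ex_c = np.array([1.0, 0.0, 0.0])
        ex_r = np.array([c, 0.0, -s])  # right screen bends toward the viewer
        ex_l = np.array([c, 0.0, s])

        top = h / 2.0
        origin_c = np.array([-w / 2.0, top, d])
        # side screens share the vertical edges of the center screen
        origin_r = np.array([w / 2.0, top, d])
        origin_l = np.array([-w / 2.0, top, d]) - w * ex_l

        object.__setattr__(self, "eye_point", np.zeros(3))
        object.__setattr__(self, "_origins", np.stack([origin_l, origin_c, origin_r]))
        object.__setattr__(self, "_ex", np.stack([ex_l, ex_c, ex_r]))
        object.__setattr__(self, "_ey", np.stack([ey, ey, ey]))

    # -- basic plane queries -------------------------------------------------

    @property
    def pixel_pitch_m(self) -> tuple[float, float]:
        """Physical size of one pixel, (horizontal, vertical), in meters."""
        cols, rows = self.screen_px
        return self.screen_width_m / cols, self.screen_height_m / rows

    def plane_point(self, screen_id: int, a_m, b_m) -> np.ndarray:
        """3-D point at in-plane metric coordinates (a, b) from the top-left corner."""
        self._check_screen(screen_id)
        a = np.asarray(a_m, dtype=float)[..., None]
        b = np.asarray(b_m, dtype=float)[..., None]
        return self._origins[screen_id] + a * self._ex[screen_id] + b * self._ey[screen_id]

    def pixel_point(self, screen_id: int, x, y) -> np.ndarray:
        """3-D position of the center of pixel (x, y) on a screen."""
        px, py = self.pixel_pitch_m
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return self.plane_point(screen_id, (x + 0.5) * px, (y + 0.5) * py)

    def _check_screen(self, screen_id: int) -> None:
        if not (0 <= int(screen_id) < N_SCREENS):
            raise ValueError(f"screen_id must be 0, 1 or 2, got {screen_id}")

    def _check_pixel(self, screen_id: int, x, y) -> None:
        cols, rows = self.screen_px
        x = np.asarray(x)
        y = np.asarray(y)
        if np.any(x < -0.5) or np.any(x > cols - 0.5) or np.any(y < -0.5) or np.any(y > rows - 0.5):
            raise ValueError(f"pixel ({x}, {y}) outside screen bounds {cols}x{rows}")
        self._check_screen(screen_id)

    # -- coverage ------------------------------------------------------------

    @property
    def horizontal_coverage_deg(self) -> float:
        """Field of view between the outer vertical edges of the side screens,
        measured through the screens' vertical midline."""
        h2 = self.screen_height_m / 2.0
        left = self.plane_point(0, 0.0, h2)
        right = self.plane_point(2, self.screen_width_m, h2)
        return _angle_deg(left, right)

    @property
    def vertical_coverage_deg(self) -> float:
        """Field of view between top and bottom edges of the center screen."""
        w2 = self.screen_width_m / 2.0
        top = self.plane_point(1, w2, 0.0)
        bot = self.plane_point(1, w2, self.screen_height_m)
        return _angle_deg(top, bot)


def _angle_deg(p: np.ndarray, q: np.ndarray) -> float:
    u = p / np.linalg.norm(p)
    v = q / np.linalg.norm(q)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# construction


def build_layout(config: dict | None = None, **overrides) -> ScreenLayout:
    """Build a :class:`ScreenLayout` from a parameter mapping.

    Recognised keys mirror the ``ScreenLayout`` fields.  Unknown keys raise a
    :class:`ConfigurationError` so that typos in config files fail loudly.
    """
    params: dict = {}
    for src in (config or {}), overrides:
        for key, value in src.items():
            if key not in ScreenLayout.__dataclass_fields__ or key in (
                "eye_point",
                "_origins",
                "_ex",
                "_ey",
            ):
                raise ConfigurationError(f"unknown layout parameter {key!r}")
            params[key] = tuple(value) if key == "screen_px" else value
    try:
        return ScreenLayout(**params)
    except ConfigurationError:
        raise
    except (TypeError, ValueError) as exc:  # e.g. malformed screen_px
        raise ConfigurationError(str(exc)) from exc


def layout_with_coverage(horizontal_deg: float, **overrides) -> ScreenLayout:
    """Layout achieving a target horizontal coverage by solving for eye distance.

    The screen sizes and the inter-screen angle are kept at their (possibly
    overridden) values; the eye-to-center distance is adjusted so that the
    horizontal field of view between the outer screen edges equals
    ``horizontal_deg``.  Used e.g. to realise the 149-degree configuration in
    which the maximum measurable eccentricity is 74.5 degrees.
    """
    base = build_layout(overrides)

    def gap(d: float) -> float:
        return (
            build_layout(overrides, eye_distance_m=d).horizontal_coverage_deg
            - horizontal_deg
        )

    # Coverage peaks (at 180 deg) where the outer screen edges pass the eye
    # plane, i.e. at eye distance W*sin(theta); it decreases monotonically for
    # larger distances, so the physically sensible root lies to the right.
    theta = np.radians(180.0 - base.inter_screen_angle_deg)
    lo = base.screen_width_m * np.sin(theta) + 1e-9
    hi = max(10.0 * base.eye_distance_m, 50.0)
    if gap(lo) < 0 or gap(hi) > 0:
        raise ConfigurationError(
            f"horizontal coverage {horizontal_deg} deg not reachable for this geometry"
        )
    d = brentq(gap, lo, hi, xtol=1e-10)
    return build_layout(overrides, eye_distance_m=float(d))


# ---------------------------------------------------------------------------
# directions and angles


def pixel_to_direction(layout: ScreenLayout, screen_id: int, x, y) -> np.ndarray:
    """Unit direction from the eye point through the center of pixel (x, y)."""
    layout._check_pixel(screen_id, x, y)
    p = layout.pixel_point(screen_id, x, y) - layout.eye_point
    return p / np.linalg.norm(p, axis=-1, keepdims=True)


def direction_to_pixel(layout: ScreenLayout, screen_id: int, direction) -> tuple[float, float]:
    """Intersect a viewing ray with a screen plane; inverse of pixel_to_direction.

    Returns fractional pixel coordinates; raises ``ValueError`` if the ray does
    not hit the screen within its bounds.
    """
    layout._check_screen(screen_id)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ex, ey = layout._ex[screen_id], layout._ey[screen_id]
    n = np.cross(ex, ey)
    denom = float(np.dot(d, n))
    if abs(denom) < 1e-12:
        raise ValueError("ray is parallel to the screen plane")
    t = float(np.dot(layout._origins[screen_id] - layout.eye_point, n)) / denom
    if t <= 0:
        raise ValueError("ray points away from the screen")
    hit = layout.eye_point + t * d - layout._origins[screen_id]
    px, py = layout.pixel_pitch_m
    x = float(np.dot(hit, ex)) / px - 0.5
    y = float(np.dot(hit, ey)) / py - 0.5
    layout._check_pixel(screen_id, x, y)
    return x, y


def angular_distance(
    layout: ScreenLayout,
    a: tuple[int, float, float],
    b: tuple[int, float, float],
) -> float:
    """Angle in degrees between the viewing directions of two on-screen points.

    Points are ``(screen_id, x, y)`` pixel triples.  Symmetric, in [0, 180].
    """
    u = pixel_to_direction(layout, *a)
    v = pixel_to_direction(layout, *b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def visual_angle_of(layout: ScreenLayout, screen_id: int, x, y) -> VisualAngle:
    """Visual angle of a pixel relative to the straight-ahead direction."""
    d = pixel_to_direction(layout, screen_id, x, y)
    ecc = float(np.degrees(np.arccos(np.clip(d[2], -1.0, 1.0))))
    horiz = float(np.degrees(np.arctan2(d[0], d[2])))
    vert = float(np.degrees(np.arcsin(np.clip(d[1], -1.0, 1.0))))
    return VisualAngle(eccentricity=ecc, horizontal=horiz, vertical=vert)


# ---------------------------------------------------------------------------
# pixel-plane ("unrolled") distances


def unroll_x(screen_id, x, columns: int = 1920):
    """Global x coordinate on the unrolled three-canvas pixel plane."""
    return np.asarray(screen_id) * columns + np.asarray(x, dtype=float)


def px_distance(
    a: tuple[int, float, float],
    b: tuple[int, float, float],
    columns: int = 1920,
) -> float:
    """Euclidean pixel distance on the unrolled 3-canvas plane.

    This is the pixel scale used for saccade amplitudes and for the distance
    term of the gaze-alignment transition weights.
    """
    ax = unroll_x(a[0], a[1], columns)
    bx = unroll_x(b[0], b[1], columns)
    return float(np.hypot(ax - bx, a[2] - b[2]))


def px_per_degree(layout: ScreenLayout, screen_id: int) -> tuple[float, float]:
    """Local pixel-per-degree scale (horizontal, vertical) at a screen's center.

    Used to express angular tracker noise and angular calibration errors on
    the pixel grid; exact at the screen center, a small-angle approximation
    elsewhere on the screen.
    """
    cols, rows = layout.screen_px
    cx, cy = (cols - 1) / 2.0, (rows - 1) / 2.0
    dh = angular_distance(layout, (screen_id, cx, cy), (screen_id, cx + 1.0, cy))
    dv = angular_distance(layout, (screen_id, cx, cy), (screen_id, cx, cy + 1.0))
    return 1.0 / dh, 1.0 / dv


def max_measurable_eccentricity(layout: ScreenLayout) -> float:
    """Largest eccentricity at which a stimulus can appear for a centrally
    directed gaze: half the horizontal coverage of the setup.

    A setup covering 149 degrees horizontally therefore bounds the measurable
    peripheral field at 74.5 degrees to either side.
    """
    return layout.horizontal_coverage_deg / 2.0
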