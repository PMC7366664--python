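"""Visual stimulus synthesis: random dot kinematograms (RDKs), drifting
checkerboard bars for Fourier retinotopy, and flashing checker bars for
single-cell receptive-field mapping.

All generators are seeded and return frame-indexed ground-truth logs; pixel
rendering is optional since downstream analyses consume the logs.

Coordinate conventions: azimuth runs 0 deg (nasal) to +130 deg (temporal),
elevation runs -50 deg (lower field) to +50 deg (upper field). Screen-local
flat coordinates are centimetres with the origin on the eye's optical axis
through the screen centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenSpec",
    "CoherenceTrace",
    "RDKFrameLog",
    "BarSweepSpec",
    "WIDEFIELD_SCREEN",
    "TWOPHOTON_SCREEN",
    "COHERENCE_LEVELS",
    "visual_angle_span",
    "make_coherence_trace",
    "generate_rdk",
    "spherical_correction",
    "screen_position",
    "generate_bar_sweep",
    "generate_checker_bars",
]

#: Admissible RDK coherence levels (fractions of dots sharing one direction).
COHERENCE_LEVELS = (0.03, 0.06, 0.12, 0.24, 0.48, 0.96)

#: The eight admissible coherent-motion directions, degrees.
RDK_DIRECTIONS = tuple(range(0, 360, 45))


def visual_angle_span(extent_cm: float, distance_cm: float) -> float:
    """Angular span (degrees) subtended by a flat extent seen from a given
    distance, eye on the perpendicular axis through the extent's centre.

    span = 2 * atan(extent / (2 * distance))
    """
    if extent_cm <= 0 or distance_cm <= 0:
        raise ValueError("extent_cm and distance_cm must be positive")
    return math.degrees(2.0 * math.atan(extent_cm / (2.0 * distance_cm)))


@dataclass(frozen=True)
class ScreenSpec:
    """Physical geometry of the stimulus monitor."""

    width_cm: float
    height_cm: float
    distance_cm: float
    resolution_px: tuple[int, int] = (1600, 900)
    refresh_hz: float = 60.0
    width_deg: float = None  # type: ignore[assignment]
    height_deg: float = None  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("width_cm", "height_cm", "distance_cm", "refresh_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        geo_w = visual_angle_span(self.width_cm, self.distance_cm)
        geo_h = visual_angle_span(self.height_cm, self.distance_cm)
        if self.width_deg is None:
            object.__setattr__(self, "width_deg", geo_w)
        if self.height_deg is None:
            object.__setattr__(self, "height_deg", geo_h)
        if abs(self.width_deg - geo_w) > 1.0 or abs(self.height_deg - geo_h) > 1.0:
            raise ValueError("declared angular span disagrees with geometry by >1 deg")


#: 43 x 24 cm monitor 10 cm from the eye: ~130 x 100 deg of visual field.
WIDEFIELD_SCREEN = ScreenSpec(width_cm=43.0, height_cm=24.0, distance_cm=10.0,
                              resolution_px=(1600, 900), refresh_hz=60.0)

#: 17.5 x 13 cm monitor 5 cm from the eye: ~120 x 105 deg.
TWOPHOTON_SCREEN = ScreenSpec(width_cm=17.5, height_cm=13.0, distance_cm=5.0,
                              resolution_px=(800, 600), refresh_hz=60.0)


@dataclass
class CoherenceTrace:
    """Per-frame coherent-motion fraction; the regressor for the
    coherent-motion correlation."""

    values: np.ndarray
    frame_rate: float
    block_boundaries: np.ndarray = field(default_factory=lambda: np.array([], int))
    levels: tuple = COHERENCE_LEVELS

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.block_boundaries = np.asarray(self.block_boundaries, int)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("coherence trace must be a nonempty 1-D array")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("coherence values must lie in [0, 1]")

    def __len__(self):
        return self.values.size


def make_coherence_trace(levels=COHERENCE_LEVELS, block_frames: int = 50,
                         mode: str = "blocked", seed: int = 0,
                         n_cycles: int = 1, gray_frames: int = 0,
                         frame_rate: float = 10.0) -> CoherenceTrace:
    """Build a seeded coherence trace.

    ``blocked``: each cycle presents every level exactly once, in a seeded
    pseudorandom order, constant within a block of ``block_frames`` frames;
    ``gray_frames`` of zero coherence (blank gray screen) precede each cycle.
    ``smooth``: piecewise-linear interpolation between a seeded random level
    sequence (one target per block).
    """
    levels = tuple(levels)
    if not levels:
        raise ValueError("levels must be nonempty")
    if block_frames < 1:
        raise ValueError("block_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "blocked":
        chunks, bounds, pos = [], [], 0
        for _ in range(n_cycles):
            if gray_frames:
                chunks.append(np.zeros(gray_frames))
                bounds.append(pos)
                pos += gray_frames
            for lev in rng.permutation(levels):
                chunks.append(np.full(block_frames, lev))
                bounds.append(pos)
                pos += block_frames
        values = np.concatenate(chunks)
        return CoherenceTrace(values, frame_rate, np.array(bounds), levels)
    if mode == "smooth":
        n_targets = n_cycles * len(levels) + 1
        targets = rng.choice(levels, size=n_targets)
        knots = np.arange(n_targets) * block_frames
        frames = np.arange(knots[-1] + 1)
        values = np.interp(frames, knots, targets)
        return CoherenceTrace(values, frame_rate, knots[:-1].copy(), levels)
    raise ValueError(f"unknown mode: {mode!r}")


@dataclass
class RDKFrameLog:
    """Full frame-indexed RDK ground truth.

    Arrays are frames x dots. ``coherent`` flags dots assigned to the common
    direction for that frame's coherence block.
    """

    x_deg: np.ndarray
    y_deg: np.ndarray
    direction_deg: np.ndarray
    age: np.ndarray
    coherent: np.ndarray
    coherent_direction: float
    trace: CoherenceTrace
    dot_diameter_deg: float = 2.0
    speed_deg_s: float = 80.0
    lifetime_frames: int = 60
    occupancy: float = 0.2

    @property
    def n_dots(self) -> int:
        return self.x_deg.shape[1]

    def to_frame_table(self) -> pd.DataFrame:
        """Long-format per-(frame, dot) table for CSV export."""
        n_f, n_d = self.x_deg.shape
        frames = np.repeat(np.arange(n_f), n_d)
        dots = np.tile(np.arange(n_d), n_f)
        return pd.DataFrame({
            "frame": frames, "dot_id": dots,
            "x_deg": self.x_deg.ravel(), "y_deg": self.y_deg.ravel(),
            "dir_deg": self.direction_deg.ravel(),
            "coherent": self.coherent.ravel(),
        })


def _rdk_dot_count(screen: ScreenSpec, diameter_deg: float, occupancy: float) -> int:
    area = screen.width_deg * screen.height_deg
    dot_area = math.pi * (diameter_deg / 2.0) ** 2
    return int(round(occupancy * area / dot_area))


def generate_rdk(screen: ScreenSpec, trace: CoherenceTrace,
                 coherent_direction: float, seed: int = 0,
                 dot_diameter_deg: float = 2.0, speed_deg_s: float = 80.0,
                 lifetime_frames: int = 60, occupancy: float = 0.2,
                 refresh_hz: float | None = None) -> RDKFrameLog:
    """Simulate an RDK session and return its frame log.

    Dot count fills ``occupancy`` of the screen area (overlap ignored). At
    each frame round(c * N) dots (a fixed seeded subset per coherence block)
    share ``coherent_direction``; the rest hold independent uniform
    directions assigned at birth. Dots expiring (age reaching the lifetime)
    or exiting the screen are reborn at uniform random positions.
    """
    if coherent_direction % 45 != 0:
        raise ValueError("coherent_direction must be a multiple of 45 deg")
    if len(trace) == 0:
        raise ValueError("empty coherence trace")
    refresh = refresh_hz or screen.refresh_hz
    rng = np.random.default_rng(seed)
    n = _rdk_dot_count(screen, dot_diameter_deg, occupancy)
    w, h = screen.width_deg, screen.height_deg
    step = speed_deg_s / refresh
    n_frames = len(trace)

    # fixed dot ordering: the first round(c*N) of this permutation are the
    # coherent subset for any block with coherence c
    order = rng.permutation(n)
    rank = np.empty(n, int)
    rank[order] = np.arange(n)

    x = rng.uniform(0, w, n)
    y = rng.uniform(-h / 2, h / 2, n)
    age = rng.integers(0, lifetime_frames, n)  # staggered so rebirths spread out
    random_dir = rng.uniform(0, 360, n)

    X = np.empty((n_frames, n), np.float32)
    Y = np.empty((n_frames, n), np.float32)
    D = np.empty((n_frames, n), np.float32)
    A = np.empty((n_frames, n), np.int32)
    C = np.empty((n_frames, n), bool)

    for f in range(n_frames):
        n_coh = int(round(trace.values[f] * n))
        coh = rank < n_coh
        direc = np.where(coh, coherent_direction, random_dir)
        X[f], Y[f], D[f], A[f], C[f] = x, y, direc, age, coh
        # advance
        rad = np.deg2rad(direc)
        x = x + step * np.cos(rad)
        y = y + step * np.sin(rad)
        age = age + 1
        dead = (age >= lifetime_frames) | (x < 0) | (x > w) | (y < -h / 2) | (y > h / 2)
        k = int(dead.sum())
        if k:
            x[dead] = rng.uniform(0, w, k)
            y[dead] = rng.uniform(-h / 2, h / 2, k)
            age[dead] = 0
            random_dir[dead] = rng.uniform(0, 360, k)

    return RDKFrameLog(X, Y, D, A, C, coherent_direction, trace,
                       dot_diameter_deg, speed_deg_s, lifetime_frames, occupancy)


def spherical_correction(flat_xy_cm: np.ndarray, screen: ScreenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Map flat screen points (cm, origin at screen centre) to spherical
    visual coordinates (azimuth, altitude) in degrees.

    The eye sits on the perpendicular axis through the screen centre at
    ``screen.distance_cm``. Azimuth is the angle in the horizontal plane,
    altitude the angle above that plane; this removes the apparent
    compression of constant-size flat stimuli near the screen edges.
    """
    pts = np.asarray(flat_xy_cm, float)
    x = pts[..., 0]
    y = pts[..., 1]
    d = screen.distance_cm
    if d <= 0:
        raise ValueError("screen distance must be positive (point behind the eye)")
    az = np.degrees(np.arctan2(x, d))
    alt = np.degrees(np.arctan2(y, np.hypot(x, d)))
    return az, alt


def screen_position(azimuth_deg, altitude_deg, screen: ScreenSpec) -> np.ndarray:
    """Inverse of :func:`spherical_correction`: flat screen coordinates (cm)
    of given spherical angles. Used to draw constant-angular-size stimuli.
    """
    az = np.deg2rad(np.asarray(azimuth_deg, float))
    alt = np.deg2rad(np.asarray(altitude_deg, float))
    if np.any(np.abs(az) >= np.pi / 2) or np.any(np.abs(alt) >= np.pi / 2):
        raise ValueError("angle >= 90 deg lies behind the eye plane")
    d = screen.distance_cm
    x = d * np.tan(az)
    y = d * np.tan(alt) / np.cos(az)
    return np.stack([x, y], axis=-1)


@dataclass(frozen=True)
class BarSweepSpec:
    """Drifting checkerboard bar for Fourier-phase retinotopy."""

    direction: str  # 'left_right' | 'right_left' | 'bottom_top' | 'top_bottom'
    speed_deg_s: float = 10.8
    checker_sf_cpd: float = 0.05
    checker_tf_hz: float = 2.0
    n_repeats: int = 20

    _DIRECTIONS = ("left_right", "right_left", "bottom_top", "top_bottom")

    def __post_init__(self):
        if self.direction not in self._DIRECTIONS:
            raise ValueError(f"direction must be one of {self._DIRECTIONS}")

    @property
    def axis(self) -> str:
        return "azimuth" if self.direction in ("left_right", "right_left") else "elevation"

    @property
    def width_deg(self) -> float:
        # 9 deg bar for azimuth sweeps, 8 deg for elevation sweeps
        return 9.0 if self.axis == "azimuth" else 8.0

    @property
    def reversed_(self) -> bool:
        return self.direction in ("right_left", "top_bottom")


def generate_bar_sweep(spec: BarSweepSpec, screen: ScreenSpec,
                       frame_rate: float = 10.0, render: bool = False,
                       deg_per_px: float = 2.0):
    """Per-frame bar-centre log (and optionally a rendered stack) for a
    periodic drifting-bar sweep.

    The bar centre advances at ``spec.speed_deg_s`` along the swept axis in
    spherical coordinates; the sweep repeats ``spec.n_repeats`` times. The
    log gives ground-truth bar position per frame.
    """
    if spec.axis == "azimuth":
        lo, hi = 0.0, screen.width_deg
    else:
        lo, hi = -screen.height_deg / 2.0, screen.height_deg / 2.0
    span = hi - lo
    period_s = span / spec.speed_deg_s
    frames_per_sweep = int(round(period_s * frame_rate))
    t = np.arange(frames_per_sweep * spec.n_repeats) / frame_rate
    pos = lo + (t * spec.speed_deg_s) % span
    if spec.reversed_:
        pos = hi - (pos - lo)
    log = pd.DataFrame({"frame": np.arange(pos.size), "time_s": t,
                        "bar_center_deg": pos})
    log.attrs.update(axis=spec.axis, span_deg=span, sweep_freq_hz=1.0 / period_s,
                     direction=spec.direction, frame_rate=frame_rate)
    if not render:
        return log
    stack = _render_bar_stack(pos, spec, screen, t, deg_per_px)
    return log, stack


def _render_bar_stack(pos, spec, screen, t, deg_per_px):
    """Render the bar in angular coordinates (already spherically uniform)."""
    w = int(screen.width_deg / deg_per_px)
    h = int(screen.height_deg / deg_per_px)
    az = np.arange(w) * deg_per_px
    el = np.arange(h) * deg_per_px - screen.height_deg / 2.0
    azg, elg = np.meshgrid(az, el)
    axis_grid = azg if spec.axis == "azimuth" else elg
    ortho_grid = elg if spec.axis == "azimuth" else azg
    checker = np.sign(np.sin(2 * np.pi * spec.checker_sf_cpd * azg) *
                      np.sin(2 * np.pi * spec.checker_sf_cpd * elg))
    checker[checker == 0] = 1.0
    del ortho_grid
    stack = np.zeros((pos.size, h, w), np.float32)
    reversal = np.sign(np.sin(2 * np.pi * spec.checker_tf_hz * t))
    reversal[reversal == 0] = 1.0
    for f in range(pos.size):
        inside = np.abs(axis_grid - pos[f]) <= spec.width_deg / 2.0
        stack[f] = 0.5 + 0.5 * checker * reversal[f] * inside
    return stack


def generate_checker_bars(axis: str, screen: ScreenSpec, seed: int = 0,
                          n_repeats: int = 10, bar_width_deg: float = 20.0,
                          on_s: float = 1.0, gray_s: float = 2.0,
                          frame_rate: float = 10.0,
                          checker_sf_cpd: float = 0.04,
                          checker_tf_hz: float = 5.0) -> pd.DataFrame:
    """Trial table for flashing checker-bar receptive-field mapping.

    30 overlapping bar locations for elevation (horizontal bars), 40 for
    azimuth (vertical bars); each location shown ``on_s`` seconds in a seeded
    random order per repeat, with ``gray_s`` of blank gray between repeats.
    """
    if axis == "elevation":
        n_loc = 30
        lo, hi = -screen.height_deg / 2.0, screen.height_deg / 2.0
    elif axis == "azimuth":
        n_loc = 40
        lo, hi = 0.0, screen.width_deg
    else:
        raise ValueError("axis must be 'azimuth' or 'elevation'")
    centers = np.linspace(lo, hi, n_loc)
    rng = np.random.default_rng(seed)
    rows = []
    frame = int(round(gray_s * frame_rate))
    on_frames = int(round(on_s * frame_rate))
    for rep in range(n_repeats):
        for loc in rng.permutation(n_loc):
            rows.append({"repeat": rep, "onset_frame": frame,
                         "offset_frame": frame + on_frames,
                         "location_index": int(loc),
                         "location_deg": centers[loc]})
            frame += on_frames
        frame += int(round(gray_s * frame_rate))
    table = pd.DataFrame(rows)
    table.attrs.update(axis=axis, n_locations=n_loc, frame_rate=frame_rate,
                       bar_width_deg=bar_width_deg, centers=centers,
                       checker_sf_cpd=checker_sf_cpd, checker_tf_hz=checker_tf_hz,
                       n_frames=frame)
    return table
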