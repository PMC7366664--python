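"""Synthetic widefield and two-photon sessions with planted ground truth.

The generators emulate the study conditions end to end: a cortical sheet
with a large V1-like patch and mirrored satellite patches carrying smooth
retinotopic gradients and alternating visual field sign; per-pixel calcium
responses with exponential indicator dynamics, trial noise, and a coherence
gain that varies linearly with preferred elevation; and two-photon fields
of discrete cells with retinotopically ordered receptive fields, von Mises
direction tuning, coherence gains, and shared neuropil contamination with a
known mixing coefficient. Every generator returns data together with the
truth needed to score downstream stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .io import FrameStack
from .stimulus import CoherenceTrace, generate_checker_bars, make_coherence_trace

__all__ = [
    "CANONICAL_LAYOUT",
    "CorticalSheetTruth",
    "TwoPhotonTruth",
    "TwoPhotonSession",
    "make_cortical_sheet",
    "simulate_widefield_session",
    "make_twophoton_truth",
    "simulate_twophoton_session",
]

# Canonical area layout: satellite angle (degrees, atan2(d_row, d_col) from
# the V1 centroid) and visual field sign. V1 is +1 by convention; mirror-image
# neighbours flip sign. Order fixes which areas small layouts include.
CANONICAL_LAYOUT: dict[str, tuple[float, int]] = {
    "LM": (0.0, -1),
    "AL": (60.0, +1),
    "RL": (120.0, -1),
    "AM": (180.0, +1),
    "PM": (240.0, -1),
    "LI": (300.0, +1),
}

AZIMUTH_RANGE = (0.0, 130.0)
ELEVATION_RANGE = (-50.0, 50.0)


@dataclass
class CorticalSheetTruth:
    """Planted ground truth for a widefield sheet."""

    azimuth: np.ndarray          # H x W, deg, NaN outside areas
    elevation: np.ndarray        # H x W, deg, NaN outside areas
    labels: np.ndarray           # H x W int, 0 = background, 1 = V1, ...
    area_names: list[str]
    signs: dict[str, int]
    gain_intercept: float = 1.0
    gain_elevation_slope: float = -0.01
    noise_sd: float = 0.0
    tau_s: float = 1.5
    rf_sigma_deg: float = 10.0   # widefield pixels pool ~10 deg receptive fields

    @property
    def shape(self):
        return self.labels.shape

    @property
    def coherence_gain(self) -> np.ndarray:
        """Per-pixel coherence gain g = g0 + s_elev * elevation_pref."""
        return self.gain_intercept + self.gain_elevation_slope * self.elevation


def _ellipse_mask(shape, center, radii) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / radii[0]) ** 2 +
            ((cc - center[1]) / radii[1]) ** 2) <= 1.0


def _affine_retinotopy(mask, center, radii, az_angle_deg, sign,
                       az_range=AZIMUTH_RANGE, el_range=ELEVATION_RANGE):
    """Affine azimuth/elevation maps over an elliptical patch.

    The azimuth gradient points along ``az_angle_deg`` (array convention,
    atan2(d_row, d_col)); the elevation gradient is rotated +90 deg for
    field sign +1 and -90 deg for sign -1. Each patch covers the full
    stimulus span so all areas share visual field coverage.
    """
    rr, cc = np.nonzero(mask)
    d_r, d_c = rr - center[0], cc - center[1]
    th = math.radians(az_angle_deg)
    e_az = (math.sin(th), math.cos(th))          # (row, col) components
    th_el = th + sign * math.pi / 2.0
    e_el = (math.sin(th_el), math.cos(th_el))

    def project(e):
        extent = math.hypot(radii[0] * e[0], radii[1] * e[1])
        p = (d_r * e[0] + d_c * e[1]) / (2.0 * extent) + 0.5  # in [0, 1]
        return 0.05 + 0.9 * p  # keep preferences off the span edges

    az = az_range[0] + project(e_az) * (az_range[1] - az_range[0])
    el = el_range[0] + project(e_el) * (el_range[1] - el_range[0])
    return rr, cc, az, el


def make_cortical_sheet(shape=(64, 64), n_areas: int = 7, seed: int = 0,
                        gain_intercept: float = 1.0,
                        gain_elevation_slope: float = -0.01,
                        tau_s: float = 1.5,
                        v1_radii_frac=(0.17, 0.14),
                        satellite_distance_frac: float = 0.31,
                        satellite_radius_frac: float = 0.09) -> CorticalSheetTruth:
    """Build a sheet with one large V1-like patch plus ``n_areas - 1``
    satellite patches, each with an affine retinotopic gradient; field signs
    alternate between mirror-image neighbours per :data:`CANONICAL_LAYOUT`.

    Raises if the requested patches overlap.
    """
    if n_areas < 1:
        raise ValueError("need at least one area")
    if n_areas > 1 + len(CANONICAL_LAYOUT):
        raise ValueError(f"at most {1 + len(CANONICAL_LAYOUT)} areas supported")
    rng = np.random.default_rng(seed)
    h, w = shape
    scale = min(h, w)
    v1_center = (h / 2.0, w / 2.0)
    v1_radii = (v1_radii_frac[0] * scale, v1_radii_frac[1] * scale)
    sat_dist = satellite_distance_frac * scale
    sat_radius = satellite_radius_frac * scale

    azimuth = np.full(shape, np.nan)
    elevation = np.full(shape, np.nan)
    labels = np.zeros(shape, int)
    names = ["V1"]
    signs = {"V1": +1}

    # V1: azimuth gradient along +col, elevation along +row (sign +1)
    v1_mask = _ellipse_mask(shape, v1_center, v1_radii)
    rr, cc, az, el = _affine_retinotopy(v1_mask, v1_center, v1_radii, 0.0, +1)
    azimuth[rr, cc], elevation[rr, cc] = az, el
    labels[rr, cc] = 1

    # jitter satellite gradient orientations a little so maps are not all
    # perfectly axis aligned
    for k, (name, (angle, sign)) in enumerate(CANONICAL_LAYOUT.items()):
        if k + 2 > n_areas:
            break
        th = math.radians(angle)
        center = (v1_center[0] + sat_dist * math.sin(th),
                  v1_center[1] + sat_dist * math.cos(th))
        radii = (sat_radius, sat_radius)
        mask = _ellipse_mask(shape, center, radii)
        if not mask.any():
            raise ValueError(f"area {name} fell outside the grid")
        if (labels[mask] != 0).any():
            raise ValueError(f"area {name} overlaps an existing patch")
        az_angle = angle + 180.0 + rng.uniform(-10, 10)  # mirrored toward V1
        rr, cc, az, el = _affine_retinotopy(mask, center, radii, az_angle, sign)
        azimuth[rr, cc], elevation[rr, cc] = az, el
        labels[rr, cc] = k + 2
        names.append(name)
        signs[name] = sign

    return CorticalSheetTruth(azimuth, elevation, labels, names, signs,
                              gain_intercept, gain_elevation_slope,
                              tau_s=tau_s)


def calcium_filter(drive: np.ndarray, tau_s: float, frame_rate: float) -> np.ndarray:
    """Causal single-exponential indicator kernel (unit DC gain) applied
    along axis 0. tau_s = 0 returns the drive unchanged."""
    if tau_s <= 0:
        return drive
    a = math.exp(-1.0 / (tau_s * frame_rate))
    return signal.lfilter([1.0 - a], [1.0, -a], drive, axis=0)


def simulate_widefield_session(truth: CorticalSheetTruth, stimulus_log,
                               session_kind: str, seed: int = 0,
                               frame_rate: float = 10.0, snr: float = 3.0,
                               tau: float | None = None,
                               baseline: float = 100.0,
                               amplitude: float = 0.05,
                               n_trials: int = 1):
    """Simulate a widefield fluorescence movie for one session.

    Per-pixel drive:
      * ``bar``   - Gaussian receptive-field overlap with the bar position
                    (``stimulus_log`` is a bar-position table from
                    :func:`cohmap.stimulus.generate_bar_sweep`);
      * ``rdk``   - baseline + g(x, y) * m(t) with the planted elevation-
                    dependent gain (``stimulus_log`` is a CoherenceTrace);
      * ``movie`` - g(x, y) * motion_energy(t) (``stimulus_log`` is a 1-D
                    regressor array).

    The drive is convolved with an exponential calcium kernel and scaled
    onto the baseline with multiplicative Gaussian trial noise of standard
    deviation ``amplitude / snr`` (in dF/F units). Returns
    ``(FrameStack, info)`` where ``info['trialwise']`` views the data as
    trials x T x H x W.
    """
    tau = truth.tau_s if tau is None else tau
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    inside = truth.labels > 0

    if session_kind == "bar":
        pos = np.asarray(stimulus_log["bar_center_deg"], float)
        axis = stimulus_log.attrs.get("axis", "azimuth")
        pref = truth.azimuth if axis == "azimuth" else truth.elevation
        drive = np.exp(-(pos[:, None, None] - pref[None]) ** 2 /
                       (2.0 * truth.rf_sigma_deg ** 2)).astype(np.float32)
        frame_rate = stimulus_log.attrs.get("frame_rate", frame_rate)
    elif session_kind == "rdk":
        if not isinstance(stimulus_log, CoherenceTrace):
            raise ValueError("rdk sessions take a CoherenceTrace log")
        m = stimulus_log.values
        frame_rate = stimulus_log.frame_rate
        gain = truth.coherence_gain
        gmax = np.nanmax(np.abs(gain))
        drive = (m[:, None, None] *
                 (gain / (gmax if gmax > 0 else 1.0))[None]).astype(np.float32)
    elif session_kind == "movie":
        m = np.asarray(stimulus_log, float)
        if m.ndim != 1:
            raise ValueError("movie sessions take a 1-D motion-energy regressor")
        m = m / (np.max(np.abs(m)) or 1.0)
        gain = truth.coherence_gain
        gmax = np.nanmax(np.abs(gain))
        drive = (m[:, None, None] *
                 (gain / (gmax if gmax > 0 else 1.0))[None]).astype(np.float32)
    else:
        raise ValueError(f"unknown session_kind: {session_kind!r}")

    if drive.shape[1:] != (h, w):
        raise ValueError("stimulus log grid does not match the sheet")
    drive = np.nan_to_num(drive, nan=0.0)
    drive[:, ~inside] = 0.0
    drive = calcium_filter(drive, tau, frame_rate).astype(np.float32)

    t = drive.shape[0]
    noise_sd = 0.0 if not np.isfinite(snr) else amplitude / snr
    data = np.empty((n_trials * t, h, w), np.float32)
    for trial in range(n_trials):
        noise = rng.standard_normal((t, h, w)).astype(np.float32) * noise_sd
        data[trial * t:(trial + 1) * t] = baseline * (1.0 + amplitude * drive + noise)

    stack = FrameStack(data, frame_rate)
    info = {
        "n_trials": n_trials,
        "frames_per_trial": t,
        "trialwise": data.reshape(n_trials, t, h, w),
        "trial_table": pd.DataFrame({
            "trial": np.arange(n_trials),
            "start_frame": np.arange(n_trials) * t,
            "stop_frame": (np.arange(n_trials) + 1) * t,
        }),
    }
    return stack, info


# ---------------------------------------------------------------------------
# two-photon synthesis
# ---------------------------------------------------------------------------

@dataclass
class TwoPhotonTruth:
    """Planted cellular ground truth for a two-photon field."""

    shape: tuple
    centers: np.ndarray          # n x 2 (row, col)
    radius_px: float
    masks: np.ndarray            # H x W int labels, 0 = background
    rf_elevation: np.ndarray     # n, deg
    rf_azimuth: np.ndarray       # n, deg
    preferred_direction: np.ndarray  # n, deg (von Mises mu)
    kappa: np.ndarray            # n
    coherence_gain: np.ndarray   # n
    alpha_true: float            # neuropil mixing coefficient in [0, 1]
    f0_true: float               # cellular baseline fluorescence
    um_per_px: float

    @property
    def n_cells(self) -> int:
        return len(self.centers)


def make_twophoton_truth(shape=(96, 96), n_cells: int = 20, seed: int = 0,
                         radius_px: float = 3.0, alpha: float = 0.7,
                         kappa: float = 3.0, field_width_um: float = 425.0,
                         elevation_span: tuple = (-25.0, 25.0),
                         azimuth_span: tuple = (40.0, 80.0),
                         gain_intercept: float = 1.0,
                         gain_elevation_slope: float = -0.012,
                         rf_jitter_deg: float = 1.5) -> TwoPhotonTruth:
    """Place disjoint disk somata with a planted retinotopic gradient of
    receptive fields (elevation along rows, azimuth along columns), von
    Mises direction tuning, and elevation-dependent coherence gains."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 2.5 * radius_px
    centers = []
    min_sep = 2.0 * radius_px + 3.0
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place disjoint cells; lower n_cells")
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    centers = np.array(centers)

    masks = np.zeros(shape, int)
    rr, cc = np.mgrid[0:h, 0:w]
    for i, (r0, c0) in enumerate(centers):
        masks[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px ** 2] = i + 1

    el = (elevation_span[0] + centers[:, 0] / h *
          (elevation_span[1] - elevation_span[0]) +
          rng.normal(0, rf_jitter_deg, n_cells))
    az = (azimuth_span[0] + centers[:, 1] / w *
          (azimuth_span[1] - azimuth_span[0]) +
          rng.normal(0, rf_jitter_deg, n_cells))
    mu = rng.uniform(0, 360, n_cells)
    gain = np.clip(gain_intercept + gain_elevation_slope * el +
                   rng.normal(0, 0.05, n_cells), 0.05, None)
    return TwoPhotonTruth(shape, centers, radius_px, masks, el, az, mu,
                          np.full(n_cells, float(kappa)), gain, float(alpha),
                          100.0, field_width_um / w)


@dataclass
class TwoPhotonSession:
    """Simulated two-photon movie plus its stimulus bookkeeping."""

    stack: FrameStack
    direction_segments: dict       # direction deg -> (start, stop)
    direction_traces: dict         # direction deg -> coherence values
    bar_table: pd.DataFrame        # checker-bar trials (frames are absolute)
    bar_segment: tuple
    true_shifts: np.ndarray        # planted per-frame (row, col) motion
    truth: TwoPhotonTruth


def _von_mises_tuning(theta_deg, mu_deg, kappa):
    """Tuning factor in [0, 1], peak 1 at mu."""
    d = np.deg2rad(np.asarray(theta_deg, float) - np.asarray(mu_deg, float))
    return np.exp(kappa * (np.cos(d) - 1.0))


def simulate_twophoton_session(truth: TwoPhotonTruth, seed: int = 0,
                               frame_rate: float = 10.0, tau_s: float = 0.7,
                               directions=tuple(range(0, 360, 45)),
                               coherence_block_frames: int = 25,
                               bar_repeats: int = 4,
                               response_amplitude: float = 0.8,
                               bar_amplitude: float = 1.0,
                               cell_level: float = 60.0,
                               background_level: float = 30.0,
                               pixel_noise_sd: float = 2.0,
                               motion_amplitude_px: int = 2) -> TwoPhotonSession:
    """Simulate a full cellular session: one smooth-coherence RDK block per
    motion direction followed by flashing checker bars for elevation
    receptive-field mapping, with planted frame-to-frame motion, a shared
    neuropil field mixed into every pixel with coefficient ``alpha_true``,
    and Gaussian pixel noise.

    Cell response to direction theta at coherence c is proportional to
    gain * c * vonMises(theta; mu, kappa); bar responses are Gaussian in bar
    position around the planted receptive-field centre.
    """
    if len(directions) < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    n = truth.n_cells

    # --- stimulus timeline ---
    trace = make_coherence_trace(block_frames=coherence_block_frames,
                                 mode="smooth", seed=seed + 1,
                                 frame_rate=frame_rate)
    seg_len = len(trace) + 10  # 1 s gray tail between directions
    segments, traces = {}, {}
    chunks = []
    pos = 0
    for d in directions:
        segments[d] = (pos, pos + len(trace))
        traces[d] = trace.values.copy()
        pos += seg_len
    n_rdk_frames = pos

    bar_screen_frames = generate_checker_bars(
        "elevation", _TWOPHOTON_SCREEN_LAZY(), seed=seed + 2,
        n_repeats=bar_repeats, frame_rate=frame_rate)
    bar_table = bar_screen_frames.copy()
    bar_table["onset_frame"] += n_rdk_frames
    bar_table["offset_frame"] += n_rdk_frames
    bar_table.attrs.update(bar_screen_frames.attrs)
    n_bar_frames = int(bar_screen_frames.attrs["n_frames"]) + 20
    n_frames = n_rdk_frames + n_bar_frames
    bar_segment = (n_rdk_frames, n_frames)

    # --- per-cell drive ---
    drive = np.zeros((n_frames, n), np.float32)
    for d in directions:
        s0, s1 = segments[d]
        tune = _von_mises_tuning(d, truth.preferred_direction, truth.kappa)
        drive[s0:s1] = (truth.coherence_gain * tune)[None, :] * trace.values[:, None]
    rf_sigma = 10.0
    for _, row in bar_table.iterrows():
        resp = bar_amplitude * np.exp(
            -(row["location_deg"] - truth.rf_elevation) ** 2 / (2 * rf_sigma ** 2))
        drive[int(row["onset_frame"]):int(row["offset_frame"])] += resp[None, :]

    dff = response_amplitude * calcium_filter(drive, tau_s, frame_rate)

    # --- shared neuropil trace: slow, stimulus-independent ---
    raw = rng.standard_normal(n_frames)
    npil = calcium_filter(raw, 1.0, frame_rate)
    npil = 0.3 * npil / (np.std(npil) + 1e-12)

    # --- assemble pixel movie ---
    neuropil_field = background_level * (1.0 + npil)          # T
    movie = np.empty((n_frames, h, w), np.float32)
    movie[:] = neuropil_field[:, None, None]
    for i in range(n):
        m = truth.masks == i + 1
        movie[:, m] = (cell_level * (1.0 + dff[:, i])[:, None] +
                       truth.alpha_true * neuropil_field[:, None])
    movie += rng.standard_normal(movie.shape).astype(np.float32) * pixel_noise_sd

    # --- planted rigid motion ---
    if motion_amplitude_px > 0:
        shifts = rng.integers(-motion_amplitude_px, motion_amplitude_px + 1,
                              size=(n_frames, 2))
        shifts[0] = 0
        for f in range(n_frames):
            if shifts[f].any():
                movie[f] = np.roll(movie[f], tuple(shifts[f]), axis=(0, 1))
    else:
        shifts = np.zeros((n_frames, 2), int)

    return TwoPhotonSession(FrameStack(movie, frame_rate), segments, traces,
                            bar_table, bar_segment, shifts, truth)


def _TWOPHOTON_SCREEN_LAZY():
    from .stimulus import TWOPHOTON_SCREEN
    return TWOPHOTON_SCREEN
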