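"""Reliability maps, Horn-Schunck optical flow and motion energy,
coherent-motion correlation mapping, areal summaries, and the
retinotopic-asymmetry statistics.

The two headline pixel statistics:

* reliability R: mean over trials of the Pearson correlation between one
  trial's response and the average of all other trials;
* coherent-motion correlation M: Pearson correlation between the
  trial-averaged dF/F response and the stimulus regressor m(t) (RDK
  coherence fraction, or the motion energy of a natural movie).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FrameStack
from .retinotopy import DFFStack
from .stimulus import CoherenceTrace

__all__ = ["MotionEnergyTrace", "reliability_map", "horn_schunck_flow",
           "motion_energy", "uniformity_index",
           "coherent_motion_correlation_map", "areal_summary",
           "retinotopic_asymmetry", "coherence_response_curve",
           "visually_driven_response", "deconvolve_exponential"]


@dataclass
class MotionEnergyTrace:
    """Per frame-pair magnitude of the frame-summed optical flow vector."""

    values: np.ndarray
    lambda_smooth: float
    n_iter: int

    def __len__(self):
        return self.values.size


def _pearson_along_axis0(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of two (T, ...) arrays along time. Degenerate columns
    (zero variance) yield NaN without warnings."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    den = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den > 0, out, np.nan)


def reliability_map(trialwise: np.ndarray) -> np.ndarray:
    """Across-trial reliability per pixel: mean over trials t of the Pearson
    correlation between trial t and the mean of all other trials.

    ``trialwise`` is trials x T x H x W (or trials x T x P). Constant-trace
    terms are NaN and excluded from the mean; all-degenerate pixels stay NaN.
    """
    trialwise = np.asarray(trialwise, float)
    n_trials = trialwise.shape[0]
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    total = trialwise.sum(axis=0)
    terms = np.empty((n_trials,) + trialwise.shape[2:])
    for t in range(n_trials):
        loo_mean = (total - trialwise[t]) / (n_trials - 1)
        terms[t] = _pearson_along_axis0(trialwise[t], loo_mean)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(terms, axis=0)


def horn_schunck_flow(frame_a: np.ndarray, frame_b: np.ndarray,
                      lambda_smooth: float = 1.0, n_iter: int = 100,
                      tol: float = 1e-4):
    """Classic Horn-Schunck optical flow between two frames.

    Iteratively minimises the brightness-constancy residual plus
    ``lambda_smooth`` times the flow smoothness penalty:

        u <- u_avg - Ix (Ix u_avg + Iy v_avg + It) / (lambda + Ix^2 + Iy^2)

    Returns per-pixel ``(u, v)`` with u the column (x) and v the row (y)
    component, in pixels per frame. If the update has not converged after
    ``n_iter`` iterations the last iterate is returned with a warning.
    """
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("frames must be finite")
    # spatial derivatives averaged over the two frames; temporal difference
    ix = 0.5 * (np.gradient(a, axis=1) + np.gradient(b, axis=1))
    iy = 0.5 * (np.gradient(a, axis=0) + np.gradient(b, axis=0))
    it = b - a
    avg_kernel = np.array([[1, 2, 1], [2, 0, 2], [1, 2, 1]]) / 12.0
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom_base = lambda_smooth + ix ** 2 + iy ** 2
    converged = False
    for _ in range(n_iter):
        u_avg = ndimage.convolve(u, avg_kernel)
        v_avg = ndimage.convolve(v, avg_kernel)
        common = (ix * u_avg + iy * v_avg + it) / denom_base
        u_new = u_avg - ix * common
        v_new = v_avg - iy * common
        delta = max(np.abs(u_new - u).max(), np.abs(v_new - v).max())
        u, v = u_new, v_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Horn-Schunck did not converge; returning last iterate")
    return u, v


def motion_energy(movie, lambda_smooth: float = 1.0,
                  n_iter: int = 100) -> MotionEnergyTrace:
    """Net motion energy per frame pair: the magnitude of the vector sum of
    all pixel flow vectors. Length is frames - 1."""
    data = movie.data if isinstance(movie, FrameStack) else np.asarray(movie, float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    mags = np.empty(data.shape[0] - 1)
    for f in range(data.shape[0] - 1):
        u, v = horn_schunck_flow(data[f], data[f + 1], lambda_smooth, n_iter)
        mags[f] = math.hypot(u.sum(), v.sum())
    return MotionEnergyTrace(mags, lambda_smooth, n_iter)


def uniformity_index(mean_magnitude_map: np.ndarray) -> float:
    """ANSI-style image uniformity: tile the map into nine equal sections,
    take the per-section mean brightness B, and return
    1 - (Bmax - Bmin) / (Bmax + Bmin). An all-zero map returns 1."""
    img = np.asarray(mean_magnitude_map, float)
    h, w = img.shape
    if h < 3 or w < 3:
        raise ValueError("map must be at least 3 x 3")
    rows = np.array_split(np.arange(h), 3)
    cols = np.array_split(np.arange(w), 3)
    b = np.array([[img[np.ix_(r, c)].mean() for c in cols] for r in rows])
    bmax, bmin = b.max(), b.min()
    if bmax + bmin == 0:
        warnings.warn("all-zero magnitude map; uniformity defined as 1")
        return 1.0
    return 1.0 - (bmax - bmin) / (bmax + bmin)


def deconvolve_exponential(dff: np.ndarray, tau_s: float,
                           frame_rate: float) -> np.ndarray:
    """Exact inverse of the causal single-exponential indicator filter
    along axis 0 (first frame passed through unchanged)."""
    a = math.exp(-1.0 / (tau_s * frame_rate))
    out = np.array(dff, float, copy=True)
    out[1:] = (dff[1:] - a * dff[:-1]) / (1.0 - a)
    return out


def _resample_to(values: np.ndarray, n: int) -> np.ndarray:
    if values.size == n:
        return values
    src = np.linspace(0, 1, values.size)
    dst = np.linspace(0, 1, n)
    return np.interp(dst, src, values)


def coherent_motion_correlation_map(dff, regressor, deconvolve: bool = False,
                                    tau: float = 1.5,
                                    lag_s: float = 0.5) -> np.ndarray:
    """Coherent-motion correlation M per pixel: Pearson correlation between
    the (trial-averaged) dF/F response and the stimulus regressor.

    ``dff`` is a DFFStack or a T x H x W array; ``regressor`` a
    CoherenceTrace, MotionEnergyTrace, or plain 1-D array (gray periods
    enter as regressor value 0). The regressor is resampled to the imaging
    frame count and lagged by ``lag_s`` to compensate the indicator group
    delay; set ``deconvolve=True`` to instead inverse-filter the response
    with an exponential kernel of time constant ``tau`` (then no lag is
    applied). Constant responses give NaN.
    """
    if isinstance(dff, DFFStack):
        data, frame_rate = dff.data, dff.frame_rate
    else:
        data = np.asarray(dff, float)
        frame_rate = None
    if isinstance(regressor, (CoherenceTrace, MotionEnergyTrace)):
        m = np.asarray(regressor.values, float)
    else:
        m = np.asarray(regressor, float)
    m = _resample_to(m, data.shape[0])
    if deconvolve:
        if frame_rate is None:
            raise ValueError("deconvolution needs a DFFStack with frame rate")
        data = deconvolve_exponential(data, tau, frame_rate)
    elif frame_rate is not None and lag_s > 0:
        shift = int(round(lag_s * frame_rate))
        if shift:
            m = np.concatenate([np.full(shift, m[0]), m[:-shift]])
    return _pearson_along_axis0(np.broadcast_to(m.reshape(-1, *([1] * (data.ndim - 1))),
                                                data.shape), data)


def areal_summary(pixel_map: np.ndarray, segmentation: np.ndarray,
                  names: dict[int, str] | None = None,
                  session: str = "session0") -> pd.DataFrame:
    """Mean of finite pixels per labelled area; one table row per
    (session, area). Empty or all-NaN areas give NaN with a warning."""
    if pixel_map.shape != segmentation.shape:
        raise ValueError("map and segmentation must be co-registered")
    rows = []
    for label in np.unique(segmentation):
        if label == 0:
            continue
        vals = pixel_map[segmentation == label]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"area {label} has no finite pixels")
            mean = float("nan")
        else:
            mean = float(vals.mean())
        rows.append({"session": session, "label": int(label),
                     "area": (names or {}).get(int(label), str(label)),
                     "mean": mean, "n_pixels": int(vals.size)})
    return pd.DataFrame(rows)


def retinotopic_asymmetry(m_map: np.ndarray, azimuth: np.ndarray,
                          elevation: np.ndarray, mask: np.ndarray,
                          z_score: bool = True):
    """Correlation of per-pixel coherent-motion correlation with preferred
    azimuth and elevation over a mask.

    M is z-scored within the session (across masked pixels) to make sessions
    comparable; z-scoring does not change the Pearson correlations. Returns
    ``(r_azimuth, r_elevation)``; degenerate variance gives NaN.
    """
    sel = mask & np.isfinite(m_map) & np.isfinite(azimuth) & np.isfinite(elevation)
    if sel.sum() < 10:
        raise ValueError("need at least 10 valid pixels")
    m = m_map[sel]
    if z_score:
        sd = m.std()
        if sd == 0:
            return float("nan"), float("nan")
        m = (m - m.mean()) / sd
    r_az = _pearson_along_axis0(m, azimuth[sel])
    r_el = _pearson_along_axis0(m, elevation[sel])
    return float(r_az), float(r_el)


def coherence_response_curve(dff, trace: CoherenceTrace,
                             lag_s: float = 0.5):
    """Mean response per coherence level and the least-squares slope of the
    response curve, per pixel.

    Frames are assigned to the level active ``lag_s`` earlier (indicator
    delay compensation). Returns ``(levels, level_means, slope_map)`` with
    ``level_means`` stacked as len(levels) x pixel-shape. A single distinct
    level gives an all-NaN slope.
    """
    if isinstance(dff, DFFStack):
        data, frame_rate = dff.data, dff.frame_rate
    else:
        data, frame_rate = np.asarray(dff, float), 10.0
    m = _resample_to(np.asarray(trace.values, float), data.shape[0])
    shift = int(round(lag_s * frame_rate))
    if shift:
        m = np.concatenate([np.full(shift, m[0]), m[:-shift]])
    levels = np.unique(m)
    means = np.stack([data[m == lev].mean(axis=0) for lev in levels])
    if levels.size < 2:
        return levels, means, np.full(data.shape[1:], np.nan)
    x = levels - levels.mean()
    slope = np.tensordot(x, means - means.mean(axis=0), axes=(0, 0)) / (x ** 2).sum()
    return levels, means, slope


def visually_driven_response(dff, onset_frames, pre_frames: int = 5,
                             post_frames: int = 5) -> np.ndarray:
    """Stimulus-onset amplitude map: mean (post-onset minus pre-onset) dF/F
    per pixel across onsets."""
    data = dff.data if isinstance(dff, DFFStack) else np.asarray(dff, float)
    onset_frames = np.asarray(onset_frames, int)
    if onset_frames.size == 0:
        raise ValueError("need at least one onset")
    t = data.shape[0]
    if (onset_frames - pre_frames < 0).any() or (onset_frames + post_frames > t).any():
        raise ValueError("window exceeds the record")
    amps = [data[f:f + post_frames].mean(axis=0) - data[f - pre_frames:f].mean(axis=0)
            for f in onset_frames]
    return np.mean(amps, axis=0)
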