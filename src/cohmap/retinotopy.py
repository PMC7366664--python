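"""Widefield retinotopy: pixel-wise dF/F, Fourier-phase maps from periodic
bar sweeps, visual field sign, and area segmentation with the split/merge
redundancy rule.

Phase convention: for a forward sweep that moves from the low edge of the
span to the high edge, a pixel whose receptive field sits at position ``p``
responds with first-harmonic phase ``-2*pi*p/span`` (plus a common indicator
delay). Subtracting the phases of opposite sweep directions cancels the
delay, leaving the position phase ``theta = pi - 2*pi*p/span``.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.restoration import unwrap_phase
from skimage.segmentation import expand_labels
from sklearn.cluster import KMeans

from .io import FrameStack
from .synthetic import (AZIMUTH_RANGE, CANONICAL_LAYOUT, ELEVATION_RANGE,
                        CorticalSheetTruth)

__all__ = ["DFFStack", "RetinotopyResult", "compute_dff", "fourier_phase_map",
           "combine_opposite_sweeps", "compute_sign_map", "segment_areas",
           "visual_field_overlap", "label_areas", "coverage_span",
           "recover_retinotopy"]


@dataclass
class DFFStack:
    """T x H x W dF/F values with the per-pixel median baseline."""

    data: np.ndarray
    baseline: np.ndarray
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class RetinotopyResult:
    azimuth: np.ndarray
    elevation: np.ndarray
    phase_maps: dict = field(default_factory=dict)
    sign_map: np.ndarray | None = None
    segmentation: np.ndarray | None = None
    area_names: dict = field(default_factory=dict)


def compute_dff(stack: FrameStack) -> DFFStack:
    """dF/F = (F - median(F)) / median(F) per pixel; pixels whose median is
    not positive are flagged invalid (NaN), never divided."""
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    data = np.asarray(stack.data, np.float64)
    med = np.median(data, axis=0)
    bad = med <= 0
    safe = np.where(bad, 1.0, med)
    dff = (data - med) / safe
    dff[:, bad] = np.nan
    return DFFStack(dff.astype(np.float32), med, stack.frame_rate)


def fourier_phase_map(dff: DFFStack, sweep_freq_hz: float,
                      unwrap: bool = False):
    """Per-pixel phase (and amplitude) of the Fourier component at the sweep
    frequency.

    Returns ``(phase, amplitude)``; phase is wrapped to (-pi, pi] unless
    ``unwrap=True``, in which case it is spatially unwrapped for smooth
    transitions between pixels. Pixels with zero amplitude get NaN phase.
    """
    t = dff.n_frames
    if t * sweep_freq_hz / dff.frame_rate < 2:
        raise ValueError("record must cover at least 2 sweep cycles")
    times = np.arange(t) / dff.frame_rate
    basis = np.exp(-2j * np.pi * sweep_freq_hz * times)
    data = np.nan_to_num(dff.data, nan=0.0)
    data = data - data.mean(axis=0, keepdims=True)
    coeff = np.tensordot(basis, data, axes=(0, 0))
    amplitude = 2.0 * np.abs(coeff) / t
    phase = np.angle(coeff)
    invalid = (amplitude == 0) | np.isnan(dff.data).any(axis=0)
    phase[invalid] = np.nan
    if unwrap:
        phase = _masked_unwrap(phase)
    return phase, amplitude


def _masked_unwrap(phase: np.ndarray) -> np.ndarray:
    mask = ~np.isfinite(phase)
    if mask.all():
        return phase
    un = unwrap_phase(np.ma.masked_array(np.nan_to_num(phase), mask))
    out = np.asarray(un, float)
    out[mask] = np.nan
    return out


def combine_opposite_sweeps(phase_fwd: np.ndarray, phase_rev: np.ndarray,
                            span_deg: float, origin_deg: float = 0.0,
                            phase_reference: str = "sweep_start"):
    """Combine phase maps of opposite sweep directions into a retinotopic
    map in degrees.

    Re-referenced to mid-sweep, the measured phases decompose as
    ``phase_fwd = theta + delta`` and ``phase_rev = -theta + delta`` where
    ``theta`` is the position phase (0 at the span centre, pi at the span
    origin) and ``delta`` the common response delay. The half-sum recovers
    ``delta`` and the delay-corrected forward phase recovers ``theta`` on
    the full (-pi, pi] branch per pixel, so no spatial unwrapping is needed.
    The delay must satisfy |delta| < pi/2 (a quarter sweep period); a causal
    single-exponential indicator kernel always does, since its phase lag is
    -atan(omega * tau) > -pi/2.

    ``phase_reference`` says how the input phases were measured:
    ``"sweep_start"`` (the default; the bar sits at the span origin / far
    edge at time zero, as produced by Fourier analysis of a raw sweep
    record) or ``"mid_sweep"`` (already re-referenced). Returns
    ``(position_deg, theta)``.
    """
    if phase_fwd.shape != phase_rev.shape:
        raise ValueError("phase maps must share a grid")
    if phase_reference == "sweep_start":
        phase_fwd = phase_fwd + np.pi
        phase_rev = phase_rev + np.pi
    elif phase_reference != "mid_sweep":
        raise ValueError("phase_reference must be 'sweep_start' or 'mid_sweep'")
    delta = np.angle(np.exp(1j * (phase_fwd + phase_rev))) / 2.0
    theta = np.angle(np.exp(1j * (phase_fwd - delta)))
    pos = span_deg * (np.pi - theta) / (2.0 * np.pi) + origin_deg
    return pos, theta


def _nan_gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs (normalised convolution)."""
    if sigma <= 0:
        return img
    mask = np.isfinite(img)
    filled = np.where(mask, img, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = np.full_like(img, np.nan, dtype=float)
    ok = den > 1e-6
    out[ok] = num[ok] / den[ok]
    out[~mask] = np.nan
    return out


def compute_sign_map(azimuth_map: np.ndarray, elevation_map: np.ndarray,
                     smoothing_sigma: float = 2.0) -> np.ndarray:
    """Visual field sign: the sine of the angle between the azimuth and
    elevation map gradients, after Gaussian smoothing of both maps.

    With azimuth increasing along +x (columns) and elevation along +y
    (rows) the sign is +1; mirror-imaging either map flips it. Pixels with a
    vanishing gradient get NaN.
    """
    if azimuth_map.shape != elevation_map.shape:
        raise ValueError("maps must be co-registered")
    az = _nan_gaussian_smooth(azimuth_map, smoothing_sigma)
    el = _nan_gaussian_smooth(elevation_map, smoothing_sigma)
    gar, gac = np.gradient(az)
    ger, gec = np.gradient(el)
    theta_az = np.arctan2(gar, gac)
    theta_el = np.arctan2(ger, gec)
    sign = np.sin(theta_el - theta_az)
    degenerate = (np.hypot(gar, gac) < 1e-12) | (np.hypot(ger, gec) < 1e-12)
    sign[degenerate] = np.nan
    return sign


def visual_field_overlap(patch_a: np.ndarray, patch_b: np.ndarray,
                         azimuth: np.ndarray, elevation: np.ndarray,
                         bin_deg: float = 10.0) -> float:
    """Shared visual-field coverage fraction of two patches.

    Coverage = set of occupied bins of a ``bin_deg`` x ``bin_deg`` histogram
    of pixel preferences; shared fraction = |A & B| / min(|A|, |B|).
    """
    sets = []
    for patch in (patch_a, patch_b):
        if not np.any(patch):
            raise ValueError("empty patch")
        a = azimuth[patch]
        e = elevation[patch]
        ok = np.isfinite(a) & np.isfinite(e)
        ia = np.floor(a[ok] / bin_deg).astype(int)
        ie = np.floor(e[ok] / bin_deg).astype(int)
        sets.append(set(zip(ia.tolist(), ie.tolist())))
    a_bins, b_bins = sets
    denom = min(len(a_bins), len(b_bins))
    if denom == 0:
        return 0.0
    return len(a_bins & b_bins) / denom


def _coverage_redundancy(mask: np.ndarray, azimuth: np.ndarray,
                         elevation: np.ndarray, bin_deg: float = 10.0,
                         min_cluster_px: int = 5) -> float:
    """Fraction of visual-field bins whose pixels form two or more spatially
    disconnected clusters inside the patch.

    A single-valued retinotopic map puts each bin's pixels in one contiguous
    stripe; a patch that covers the field twice (two areas fused into one
    patch) yields two separate clusters for most bins.
    """
    rr, cc = np.nonzero(mask)
    a, e = azimuth[rr, cc], elevation[rr, cc]
    ok = np.isfinite(a) & np.isfinite(e)
    rr, cc, a, e = rr[ok], cc[ok], a[ok], e[ok]
    if rr.size == 0:
        return 0.0
    ia = np.floor(a / bin_deg).astype(int)
    ie = np.floor(e / bin_deg).astype(int)
    keys = ia * 10000 + ie
    occupied = redundant = 0
    sub = np.zeros(mask.shape, bool)
    for key in np.unique(keys):
        sel = keys == key
        if sel.sum() < min_cluster_px:
            continue
        occupied += 1
        sub[:] = False
        sub[rr[sel], cc[sel]] = True
        lab, n = ndimage.label(ndimage.binary_dilation(sub, iterations=1))
        sizes = np.bincount(lab.ravel())[1:]
        if (sizes >= min_cluster_px).sum() >= 2:
            redundant += 1
    return redundant / occupied if occupied else 0.0


def _split_patch(mask: np.ndarray) -> list[np.ndarray]:
    rr, cc = np.nonzero(mask)
    coords = np.column_stack([rr, cc]).astype(float)
    km = KMeans(n_clusters=2, n_init=4, random_state=0).fit(coords)
    out = []
    for k in (0, 1):
        m = np.zeros(mask.shape, bool)
        sel = km.labels_ == k
        m[rr[sel], cc[sel]] = True
        out.append(m)
    return out


def split_merge(patches: list[np.ndarray], signs: list[int],
                azimuth: np.ndarray, elevation: np.ndarray,
                bin_deg: float = 10.0, overlap_threshold: float = 0.1,
                redundancy_threshold: float = 0.1,
                adjacency_px: int = 4, max_iter: int = 10):
    """Iterative refinement: split patches with redundant visual-field
    coverage (>10% of bins covered twice); merge adjacent same-sign patches
    with little shared coverage (<10%). Idempotent on its own output."""
    patches = [p.copy() for p in patches]
    signs = list(signs)
    for _ in range(max_iter):
        changed = False
        # split pass
        i = 0
        while i < len(patches):
            red = _coverage_redundancy(patches[i], azimuth, elevation, bin_deg)
            if red > redundancy_threshold:
                halves = _split_patch(patches[i])
                if all(h.sum() >= 4 for h in halves):
                    s = signs[i]
                    del patches[i], signs[i]
                    patches.extend(halves)
                    signs.extend([s, s])
                    changed = True
                    continue
            i += 1
        # merge pass
        merged = True
        while merged:
            merged = False
            for i in range(len(patches)):
                for j in range(i + 1, len(patches)):
                    if signs[i] != signs[j]:
                        continue
                    grown = ndimage.binary_dilation(patches[i],
                                                    iterations=adjacency_px)
                    if not (grown & patches[j]).any():
                        continue
                    if visual_field_overlap(patches[i], patches[j], azimuth,
                                            elevation, bin_deg) < overlap_threshold:
                        patches[i] = patches[i] | patches[j]
                        del patches[j], signs[j]
                        merged = changed = True
                        break
                if merged:
                    break
        if not changed:
            break
    return patches, signs


def segment_areas(sign_map: np.ndarray, azimuth: np.ndarray,
                  elevation: np.ndarray, threshold: float = 0.3,
                  dilation_px: int = 3, min_size_px: int = 100,
                  bin_deg: float = 10.0, overlap_threshold: float = 0.1,
                  redundancy_threshold: float = 0.1):
    """Segment the sign map into labelled visual areas.

    Thresholds |sign| > ``threshold``, takes connected components per sign,
    applies the iterative split (redundant coverage) / merge (adjacent
    same-sign, little shared coverage) refinement, dilates patches to close
    the gaps between areas (without overlap), and removes patches below
    ``min_size_px``. Returns ``(labels, signs)`` with labels ordered by
    decreasing patch size; an empty segmentation triggers a warning.
    """
    finite = np.isfinite(sign_map)
    if finite.mean() < 0.5:
        raise ValueError("sign map must be finite on at least half the pixels")
    patches, signs = [], []
    for s in (+1, -1):
        binary = np.where(finite, s * sign_map, 0) > threshold
        binary = ndimage.binary_opening(binary)
        lab, n = ndimage.label(binary)
        for k in range(1, n + 1):
            m = lab == k
            if m.sum() >= max(min_size_px // 4, 4):
                patches.append(m)
                signs.append(s)
    patches, signs = split_merge(patches, signs, azimuth, elevation, bin_deg,
                                 overlap_threshold, redundancy_threshold,
                                 adjacency_px=max(2 * dilation_px, 2))
    labels = np.zeros(sign_map.shape, int)
    order = np.argsort([-p.sum() for p in patches])
    next_label = 1
    kept_signs = {}
    for idx in order:
        labels[patches[idx] & (labels == 0)] = next_label
        kept_signs[next_label] = signs[idx]
        next_label += 1
    labels = expand_labels(labels, distance=dilation_px)
    out = np.zeros_like(labels)
    out_signs = {}
    new = 1
    for k in sorted(kept_signs, key=lambda k: -(labels == k).sum()):
        m = labels == k
        if m.sum() >= min_size_px:
            out[m] = new
            out_signs[new] = kept_signs[k]
            new += 1
    if not out_signs:
        import warnings
        warnings.warn("no sign patch survived segmentation")
    return out, out_signs


def label_areas(labels: np.ndarray, signs: dict[int, int]) -> dict[int, str]:
    """Name each patch by matching sign and position against the canonical
    layout: the largest positive patch is V1; satellites are matched by the
    angle of their centroid offset from V1 and their sign; unmatched patches
    are labelled 'unknown'."""
    ids = [k for k in signs if (labels == k).any()]
    if not ids:
        raise ValueError("need at least one patch")
    if len(ids) == 1:
        return {ids[0]: "V1"}
    sizes = {k: int((labels == k).sum()) for k in ids}
    positive = [k for k in ids if signs[k] > 0]
    v1 = max(positive or ids, key=lambda k: sizes[k])
    props = {p.label: p.centroid for p in regionprops(labels)}
    v1_c = props[v1]
    names = {v1: "V1"}
    available = dict(CANONICAL_LAYOUT)
    rest = sorted([k for k in ids if k != v1], key=lambda k: -sizes[k])
    for k in rest:
        dr, dc = props[k][0] - v1_c[0], props[k][1] - v1_c[1]
        ang = math.degrees(math.atan2(dr, dc)) % 360.0
        best, best_err = None, 45.0
        for name, (a0, s0) in available.items():
            if s0 != signs[k]:
                continue
            err = abs((ang - a0 + 180.0) % 360.0 - 180.0)
            if err < best_err:
                best, best_err = name, err
        if best is None:
            names[k] = "unknown"
        else:
            names[k] = best
            del available[best]
    return names


def coverage_span(patch: np.ndarray, pref_map: np.ndarray,
                  q: float = 0.95) -> float:
    """Central interval width (degrees) containing fraction ``q`` of the
    patch's pixel preferences (e.g. E95 for elevation at q = 0.95)."""
    if not np.any(patch):
        raise ValueError("empty patch")
    vals = pref_map[patch]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    lo, hi = np.percentile(vals, [50 * (1 - q), 50 * (1 + q)])
    return float(hi - lo)


def recover_retinotopy(truth: CorticalSheetTruth, seed: int = 0,
                       snr: float = 3.0, tau: float = 1.5,
                       frame_rate: float = 10.0, n_cycles: int = 6,
                       amplitude: float = 0.05,
                       smoothing_sigma: float = 2.0,
                       responsive_factor: float = 4.0) -> RetinotopyResult:
    """End-to-end retinotopy from four simulated bar sweeps on a synthetic
    sheet: dF/F, per-direction Fourier phase, opposite-sweep combination,
    and the field sign map.

    Pixels whose Fourier amplitude at the sweep frequency falls below
    ``responsive_factor`` times the across-pixel median (noise floor) carry
    no retinotopic signal: their position estimates are NaN and their field
    sign is 0, so they never cross the segmentation threshold.
    """
    from .stimulus import WIDEFIELD_SCREEN, BarSweepSpec, generate_bar_sweep
    from .synthetic import simulate_widefield_session

    phases, amps, spans = {}, {}, {}
    for direction in ("left_right", "right_left", "bottom_top", "top_bottom"):
        spec = BarSweepSpec(direction, n_repeats=n_cycles)
        log = generate_bar_sweep(spec, WIDEFIELD_SCREEN, frame_rate=frame_rate)
        stack, _ = simulate_widefield_session(
            truth, log, "bar", seed=seed + zlib.crc32(direction.encode()) % 1000,
            frame_rate=frame_rate, snr=snr, tau=tau, amplitude=amplitude)
        dff = compute_dff(stack)
        phase, amp = fourier_phase_map(dff, log.attrs["sweep_freq_hz"])
        phases[direction], amps[direction] = phase, amp
        spans[direction] = log.attrs["span_deg"]

    amp_all = np.stack(list(amps.values()))
    score = np.exp(np.log(amp_all + 1e-30).mean(axis=0))  # geometric mean
    responsive = score > responsive_factor * np.median(score)

    azimuth, _ = combine_opposite_sweeps(phases["left_right"],
                                         phases["right_left"],
                                         spans["left_right"],
                                         origin_deg=AZIMUTH_RANGE[0])
    elevation, _ = combine_opposite_sweeps(phases["bottom_top"],
                                           phases["top_bottom"],
                                           spans["bottom_top"],
                                           origin_deg=ELEVATION_RANGE[0])
    azimuth[~responsive] = np.nan
    elevation[~responsive] = np.nan
    sign = compute_sign_map(azimuth, elevation, smoothing_sigma)
    sign = np.nan_to_num(sign, nan=0.0)
    return RetinotopyResult(azimuth, elevation, phases, sign)
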