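"""Two-photon cellular pipeline: rigid registration, activity-map ROI
extraction, neuropil correction, mode-baseline dF/F, receptive-field mapping
with a shuffle-based session QC, direction/coherence tuning, and circular
statistics.

Neuropil correction follows F_corrected = F_soma - alpha * F_neuropil with
alpha chosen in [0, 1] to minimise |corr(F_corrected, F_neuropil)|; the
minimiser has the closed form clip(cov(F_soma, F_neuropil) /
var(F_neuropil), 0, 1). The signed correlation is not minimised directly
because it decreases monotonically toward -1 as alpha grows, which would
degenerate to alpha = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats as sps
from skimage.feature import peak_local_max
from skimage.filters import threshold_local
from skimage.measure import regionprops
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .io import FrameStack

__all__ = ["CellRecord", "SessionQC", "register_frames", "activity_map",
           "segment_rois", "neuropil_region", "extract_traces",
           "neuropil_correct", "neuropil_alpha_grid", "dff_cell",
           "map_receptive_field", "session_qc", "direction_coherence_tuning",
           "hodges_ajne", "elevation_binned_tuning", "run_cell_pipeline",
           "CellPipelineResult"]


# ---------------------------------------------------------------------------
# registration and ROI extraction
# ---------------------------------------------------------------------------

def register_frames(stack: FrameStack, n_passes: int = 2,
                    max_shift_frac: float = 0.1):
    """Rigid X-Y registration of every frame to the pixel-wise mean
    reference image by 2-D cross-correlation.

    Returns ``(registered_stack, shifts, flagged)``; ``shifts`` are the
    integer (row, col) corrections applied per frame. Frames whose measured
    shift exceeds ``max_shift_frac`` of the field are flagged and their
    shift clamped to zero.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    data = np.asarray(stack.data, np.float32).copy()
    h, w = data.shape[1:]
    limit = max_shift_frac * min(h, w)
    total = np.zeros((stack.n_frames, 2), int)
    flagged = np.zeros(stack.n_frames, bool)
    for _ in range(n_passes):
        reference = data.mean(axis=0)
        moved = False
        for f in range(data.shape[0]):
            shift, _, _ = phase_cross_correlation(reference, data[f],
                                                  upsample_factor=1,
                                                  normalization=None)
            shift = np.round(shift).astype(int)
            if np.abs(shift).max() > limit:
                flagged[f] = True
                continue
            if shift.any():
                data[f] = np.roll(data[f], tuple(shift), axis=(0, 1))
                total[f] += shift
                moved = True
        if not moved:
            break
    return FrameStack(data, stack.frame_rate), total, flagged


def activity_map(stack) -> np.ndarray:
    """Pixel-wise activity score: modified excess kurtosis with moments
    taken about the temporal *median* instead of the mean,

        k = E[(F - median F)^4] / E[(F - median F)^2]^2 - 3.

    For quiescent pixels the median matches the mean and k is ordinary
    excess kurtosis (~0 for Gaussian noise, exactly 0 for a constant pixel);
    for pixels carrying positive calcium transients the median stays at
    baseline, so the transients inflate the fourth moment and k rises well
    above the noise floor even when responses are frequent."""
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    if data.shape[0] < 100:
        raise ValueError("need at least 100 frames for a stable kurtosis")
    centred = data.astype(np.float64) - np.median(data, axis=0)
    m2 = (centred ** 2).mean(axis=0)
    m4 = (centred ** 4).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = m4 / m2 ** 2 - 3.0
    return np.where(m2 > 0, score, 0.0)


def segment_rois(activity: np.ndarray, cell_diameter_px: float = 7.0,
                 block_size: int = 25, min_area: int = 10,
                 max_area: int | None = None,
                 max_eccentricity: float = 0.95) -> np.ndarray:
    """Soma segmentation by local adaptive threshold and iterative peeling.

    The activity map is binarised against a local-mean threshold, distance-
    transform watershed splits touching somata, and components are gated on
    size and eccentricity. Returns a label image (0 = background) with
    pairwise-disjoint masks; an empty result warns.
    """
    if not np.isfinite(activity).all():
        raise ValueError("activity map must be finite")
    if max_area is None:
        max_area = int(4.0 * math.pi * (cell_diameter_px / 2.0) ** 2)
    block = block_size if block_size % 2 else block_size + 1
    thresh = threshold_local(activity, block, method="mean")
    binary = activity > np.maximum(thresh, activity.mean() + activity.std())
    binary = ndimage.binary_opening(binary)
    if not binary.any():
        warnings.warn("no ROIs found")
        return np.zeros(activity.shape, int)
    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(distance, min_distance=max(int(cell_diameter_px // 2), 1),
                           labels=binary)
    markers = np.zeros(activity.shape, int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=binary)
    out = np.zeros_like(labels)
    next_id = 1
    for prop in regionprops(labels):
        if prop.area < min_area or prop.area > max_area:
            continue
        if prop.eccentricity > max_eccentricity:
            continue
        out[labels == prop.label] = next_id
        next_id += 1
    if next_id == 1:
        warnings.warn("no ROIs passed the size/eccentricity gates")
    return out


def neuropil_region(roi_labels: np.ndarray, cell_id: int,
                    radius_px: float) -> np.ndarray:
    """Neuropil mask for one cell: pixels closer than ``radius_px`` to the
    ROI border, excluding every ROI."""
    roi = roi_labels == cell_id
    grown = ndimage.binary_dilation(roi, iterations=int(round(radius_px)))
    return grown & (roi_labels == 0)


def extract_traces(stack, roi_labels: np.ndarray,
                   neuropil_radius_px: float = 10.0):
    """Mean soma and neuropil fluorescence traces per ROI.

    Returns ``(F_soma, F_neuropil)`` arrays of shape (n_cells, T), ordered
    by ROI label.
    """
    data = stack.data if isinstance(stack, FrameStack) else np.asarray(stack)
    flat = data.reshape(data.shape[0], -1)
    ids = [int(k) for k in np.unique(roi_labels) if k != 0]
    soma = np.empty((len(ids), data.shape[0]))
    npil = np.empty_like(soma)
    for i, k in enumerate(ids):
        soma[i] = flat[:, (roi_labels == k).ravel()].mean(axis=1)
        region = neuropil_region(roi_labels, k, neuropil_radius_px)
        if not region.any():
            region = roi_labels == 0
        npil[i] = flat[:, region.ravel()].mean(axis=1)
    return soma, npil


# ---------------------------------------------------------------------------
# neuropil correction and dF/F
# ---------------------------------------------------------------------------

def neuropil_correct(f_soma: np.ndarray, f_neuropil: np.ndarray):
    """Neuropil-corrected trace and the mixing coefficient alpha.

    alpha = argmin over [0, 1] of |corr(F_soma - alpha * F_neuropil,
    F_neuropil)| = clip(cov(F_soma, F_neuropil) / var(F_neuropil), 0, 1).
    A constant neuropil trace gives alpha = 0.
    """
    f_soma = np.asarray(f_soma, float)
    f_neuropil = np.asarray(f_neuropil, float)
    if f_soma.shape != f_neuropil.shape or f_soma.size < 10:
        raise ValueError("traces must be equal length >= 10")
    var = f_neuropil.var()
    if var == 0:
        return f_soma.copy(), 0.0
    cov = ((f_soma - f_soma.mean()) * (f_neuropil - f_neuropil.mean())).mean()
    alpha = float(np.clip(cov / var, 0.0, 1.0))
    return f_soma - alpha * f_neuropil, alpha


def neuropil_alpha_grid(f_soma, f_neuropil, step: float = 1e-3) -> float:
    """Grid-search reference for the alpha minimiser (cross-check for the
    closed form)."""
    f_soma = np.asarray(f_soma, float)
    f_neuropil = np.asarray(f_neuropil, float)
    if f_neuropil.var() == 0:
        return 0.0
    alphas = np.arange(0.0, 1.0 + step / 2, step)
    nc = f_neuropil - f_neuropil.mean()
    best_alpha, best_val = 0.0, np.inf
    for a in alphas:
        resid = f_soma - a * f_neuropil
        rc = resid - resid.mean()
        denom = math.sqrt((rc ** 2).sum() * (nc ** 2).sum())
        val = abs((rc * nc).sum() / denom) if denom > 0 else 0.0
        if val < best_val:
            best_val, best_alpha = val, a
    return best_alpha


def dff_cell(f_corrected: np.ndarray, n_grid: int = 512):
    """Cellular dF/F with the baseline F0 taken as the mode of a Gaussian
    kernel-density estimate of the corrected fluorescence distribution.

    Returns ``(dff, f0)``. Raises if the estimated F0 is not positive (the
    cell should be flagged invalid).
    """
    f = np.asarray(f_corrected, float)
    if f.size < 100:
        raise ValueError("need at least 100 samples")
    if np.ptp(f) == 0:
        f0 = float(f[0])
        if f0 <= 0:
            raise ValueError("non-positive baseline; cell invalid")
        return np.zeros_like(f), f0
    kde = sps.gaussian_kde(f)  # Scott/Silverman-class bandwidth
    grid = np.linspace(f.min(), f.max(), n_grid)
    f0 = float(grid[np.argmax(kde(grid))])
    if f0 <= 0:
        raise ValueError("non-positive baseline; cell invalid")
    return (f - f0) / f0, f0


# ---------------------------------------------------------------------------
# receptive fields and session QC
# ---------------------------------------------------------------------------

@dataclass
class RFFit:
    responsive: bool
    anova_p: float
    center_deg: float = float("nan")
    sigma_deg: float = float("nan")
    amplitude: float = float("nan")
    offset: float = float("nan")


def _gaussian(x, amp, center, sigma, offset):
    return offset + amp * np.exp(-(x - center) ** 2 / (2.0 * sigma ** 2))


def map_receptive_field(responses: np.ndarray, location_centers: np.ndarray,
                        alpha: float = 0.05) -> RFFit:
    """Receptive-field estimate from trial responses per bar location.

    ``responses`` is locations x repeats. A one-way ANOVA across locations
    screens for location-preferential responses; cells passing (p < alpha)
    are fit with a 1-D Gaussian whose centre is the preferred location in
    degrees. Fit failure marks the cell unresponsive.
    """
    responses = np.asarray(responses, float)
    location_centers = np.asarray(location_centers, float)
    if responses.shape[0] < 5 or responses.shape[1] < 2:
        raise ValueError("need >= 5 locations and >= 2 repeats")
    groups = [responses[i] for i in range(responses.shape[0])]
    if np.ptp(responses) == 0:
        return RFFit(False, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.f_oneway(*groups)
    if not np.isfinite(p):
        # zero within-location variance: responsive iff the means differ
        p = 0.0 if np.ptp(responses.mean(axis=1)) > 0 else 1.0
    if p >= alpha:
        return RFFit(False, float(p))
    mean_resp = responses.mean(axis=1)
    span = location_centers.max() - location_centers.min()
    guess = [mean_resp.max() - mean_resp.min(),
             location_centers[np.argmax(mean_resp)], span / 10.0,
             mean_resp.min()]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _gaussian, location_centers, mean_resp, p0=guess,
                bounds=([0, location_centers.min() - span / 2, 0.5, -np.inf],
                        [np.inf, location_centers.max() + span / 2, span, np.inf]),
                maxfev=2000)
    except (RuntimeError, ValueError):
        return RFFit(False, float(p))
    return RFFit(True, float(p), center_deg=float(popt[1]),
                 sigma_deg=float(popt[2]), amplitude=float(popt[0]),
                 offset=float(popt[3]))


@dataclass
class SessionQC:
    observed: float
    shuffled: np.ndarray
    threshold: float
    passed: bool
    n_cells: int


def session_qc(positions: np.ndarray, rf_prefs: np.ndarray,
               n_shuffle: int = 5000, pct: float = 99.0,
               seed: int = 0) -> SessionQC:
    """Shuffle QC for retinotopic consistency of an imaging field.

    The observed |correlation| between receptive-field preference and cell
    position along the retinotopic axis is compared against the ``pct``-th
    percentile of the same statistic under ``n_shuffle`` random permutations
    of the cell positions; the session passes if it exceeds the threshold.
    """
    positions = np.asarray(positions, float)
    rf_prefs = np.asarray(rf_prefs, float)
    n = positions.size
    if n < 10:
        raise ValueError("QC undefined for fewer than 10 significant cells")
    xc = positions - positions.mean()
    yc = rf_prefs - rf_prefs.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise ValueError("degenerate positions or preferences")
    observed = abs(float((xc * yc).sum() / denom))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(xc, (n_shuffle, n)).copy(), axis=1)
    shuffled = np.abs(perms @ yc / denom)
    threshold = float(np.percentile(shuffled, pct))
    return SessionQC(observed, shuffled, threshold, observed > threshold, n)


# ---------------------------------------------------------------------------
# direction tuning and circular statistics
# ---------------------------------------------------------------------------

def direction_coherence_tuning(dff_trace: np.ndarray, segments: dict,
                               traces: dict, frame_rate: float = 10.0,
                               lag_s: float = 0.5):
    """Per-direction coherence correlations, the vector-sum preferred
    direction, and the best-direction correlation.

    ``segments`` maps direction (deg) -> (start, stop) frame of its RDK
    block; ``traces`` maps direction -> per-frame coherence values. The
    preferred direction is the angle of sum_d max(M_d, 0) * (cos d, sin d)
    (negative correlations carry no directional evidence since null-direction
    responses are weak); a zero resultant gives NaN.
    """
    if len(segments) != len(traces) or not segments:
        raise ValueError("segments and traces must describe the same directions")
    shift = int(round(lag_s * frame_rate))
    corrs = {}
    for d, (s0, s1) in segments.items():
        resp = np.asarray(dff_trace[s0:s1], float)
        m = np.asarray(traces[d], float)[:resp.size]
        if shift:
            m = np.concatenate([np.full(shift, m[0]), m[:-shift]])
        mc = m - m.mean()
        rc = resp - resp.mean()
        denom = math.sqrt((mc ** 2).sum() * (rc ** 2).sum())
        corrs[d] = float((mc * rc).sum() / denom) if denom > 0 else float("nan")
    weights = {d: max(c, 0.0) for d, c in corrs.items() if np.isfinite(c)}
    resultant = sum(w * np.exp(1j * math.radians(d)) for d, w in weights.items())
    if abs(resultant) < 1e-12:
        preferred = float("nan")
    else:
        preferred = math.degrees(np.angle(resultant)) % 360.0
    finite = [c for c in corrs.values() if np.isfinite(c)]
    best = max(finite) if finite else float("nan")
    return corrs, preferred, best


def hodges_ajne_m(angles: np.ndarray) -> int:
    """Hodges-Ajne statistic: the minimal number of observations inside any
    closed half-circle."""
    a = np.sort(np.asarray(angles, float) % (2 * np.pi))
    n = a.size
    ext = np.concatenate([a, a + 2 * np.pi])
    counts = np.searchsorted(ext, a + np.pi, side="left") - np.arange(n)
    return int(min(counts.min(), (n - counts).min()))


def hodges_ajne_pvalue(n: int, m: int) -> float:
    """Tail probability of the Hodges-Ajne statistic under uniformity.

    The exact tail p = (n - 2m) * C(n, m) * 2^(1-n) applies for m < n/3; the
    large-sample approximation p ~ sqrt(2*pi)/A * exp(-pi^2/(8 A^2)) with
    A = pi*sqrt(n) / (2 (n - 2m)) is used otherwise. Returns min(p, 1).
    """
    if n == 2 * m:
        return 1.0
    if m < n / 3.0:
        logp = (math.log(n - 2 * m) + math.lgamma(n + 1) - math.lgamma(m + 1)
                - math.lgamma(n - m + 1) + (1 - n) * math.log(2.0))
        return float(min(math.exp(logp), 1.0))
    big_a = math.pi * math.sqrt(n) / (2.0 * (n - 2 * m))
    p = math.sqrt(2.0 * math.pi) / big_a * math.exp(-math.pi ** 2 / (8 * big_a ** 2))
    return float(min(p, 1.0))


def hodges_ajne(angles: np.ndarray) -> float:
    """Hodges-Ajne omnibus test for circular non-uniformity: p-value for the
    minimal half-circle count m of the sample."""
    angles = np.asarray(angles, float)
    if angles.size < 4:
        raise ValueError("need at least 4 angles")
    return hodges_ajne_pvalue(angles.size, hodges_ajne_m(angles))


def elevation_binned_tuning(elevations: np.ndarray, best_corrs: np.ndarray,
                            bin_deg: float = 10.0, n_boot: int = 1000,
                            seed: int = 0, z_score: bool = True) -> dict:
    """Elevation dependence of single-cell coherent-motion correlation.

    z-scores the best-direction correlations across cells, averages them in
    ``bin_deg`` elevation bins (mean +/- s.e.m.), fits a least-squares line
    on the cell-level data, and bootstraps 95% confidence intervals for the
    slope and intercept.
    """
    el = np.asarray(elevations, float)
    y = np.asarray(best_corrs, float)
    ok = np.isfinite(el) & np.isfinite(y)
    el, y = el[ok], y[ok]
    if z_score:
        sd = y.std()
        if sd > 0:
            y = (y - y.mean()) / sd
    edges = np.arange(math.floor(el.min() / bin_deg) * bin_deg,
                      el.max() + bin_deg, bin_deg)
    idx = np.digitize(el, edges) - 1
    centers, means, sems = [], [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if not sel.any():
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        means.append(float(y[sel].mean()))
        sems.append(float(y[sel].std(ddof=1) / math.sqrt(sel.sum()))
                    if sel.sum() > 1 else float("nan"))
    if len(centers) < 2:
        raise ValueError("need at least 2 nonempty elevation bins")
    slope, intercept = np.polyfit(el, y, 1)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    n = el.size
    for b in range(n_boot):
        take = rng.integers(0, n, n)
        if np.ptp(el[take]) == 0:
            boots[b] = (np.nan, np.nan)
            continue
        boots[b] = np.polyfit(el[take], y[take], 1)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return {"bin_centers": np.array(centers), "bin_means": np.array(means),
            "bin_sems": np.array(sems), "slope": float(slope),
            "intercept": float(intercept),
            "slope_ci": (float(lo[0]), float(hi[0])),
            "intercept_ci": (float(lo[1]), float(hi[1]))}


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class CellRecord:
    cell_id: int
    row: float
    col: float
    alpha: float
    f0: float
    rf: RFFit
    direction_correlations: dict
    preferred_direction: float
    best_correlation: float


@dataclass
class CellPipelineResult:
    table: pd.DataFrame
    records: list
    masks: np.ndarray
    shifts: np.ndarray
    qc: SessionQC | None = None


def run_cell_pipeline(session, um_per_px: float,
                      neuropil_radius_um: float = 30.0,
                      qc_shuffles: int = 5000, seed: int = 0,
                      lag_s: float = 0.5) -> CellPipelineResult:
    """Full cellular analysis of a (simulated or loaded) two-photon session:
    registration, ROI extraction, neuropil correction, dF/F, receptive-field
    mapping with ANOVA screening, session QC against position-shuffled
    nulls, and per-direction coherence tuning.

    Cell position along the retinotopic axis is taken as the image row,
    matching the elevation mapping axis of the session's bar stimulus.
    """
    registered, shifts, _ = register_frames(session.stack)
    act = activity_map(registered)
    masks = segment_rois(act)
    soma, npil = extract_traces(registered, masks,
                                neuropil_radius_px=neuropil_radius_um / um_per_px)
    n_cells = soma.shape[0]
    frame_rate = session.stack.frame_rate
    centers = {p.label: p.centroid for p in regionprops(masks)}
    bar = session.bar_table
    loc_centers = np.sort(bar["location_deg"].unique())

    records = []
    for i in range(n_cells):
        corrected, alpha = neuropil_correct(soma[i], npil[i])
        try:
            dff, f0 = dff_cell(corrected)
        except ValueError:
            continue
        # bar responses: locations x repeats, onset-window mean minus baseline
        resp = np.full((loc_centers.size, bar["repeat"].nunique()), np.nan)
        for _, r in bar.iterrows():
            o, e = int(r["onset_frame"]), int(r["offset_frame"])
            if e + 3 > dff.size:
                continue
            li = int(np.searchsorted(loc_centers, r["location_deg"]))
            base = dff[max(o - 3, 0):o].mean() if o > 0 else 0.0
            resp[li, int(r["repeat"])] = dff[o:e + 3].mean() - base
        resp = np.nan_to_num(resp, nan=0.0)
        rf = map_receptive_field(resp, loc_centers)
        corrs, preferred, best = direction_coherence_tuning(
            dff, session.direction_segments, session.direction_traces,
            frame_rate=frame_rate, lag_s=lag_s)
        label = i + 1
        records.append(CellRecord(label, centers[label][0], centers[label][1],
                                  alpha, f0, rf, corrs, preferred, best))

    rows = [{"cell_id": r.cell_id, "row": r.row, "col": r.col,
             "alpha": r.alpha, "f0": r.f0, "rf_responsive": r.rf.responsive,
             "rf_p": r.rf.anova_p, "rf_center_deg": r.rf.center_deg,
             "rf_sigma_deg": r.rf.sigma_deg,
             "preferred_direction": r.preferred_direction,
             "best_correlation": r.best_correlation} for r in records]
    table = pd.DataFrame(rows)

    qc = None
    responsive = [r for r in records if r.rf.responsive]
    if len(responsive) >= 10:
        qc = session_qc(np.array([r.row for r in responsive]),
                        np.array([r.rf.center_deg for r in responsive]),
                        n_shuffle=qc_shuffles, seed=seed)
    return CellPipelineResult(table, records, masks, shifts, qc)
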