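"""Array containers, file round-trips (multi-page TIFF / NPZ), seeded
session configuration, and the end-to-end pipeline runner."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["FrameStack", "read_stack", "write_stack", "SessionConfig",
           "stage_rng", "run_pipeline"]


@dataclass
class FrameStack:
    """A T x H x W fluorescence movie with frame-rate metadata."""

    data: np.ndarray
    frame_rate: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must be T x H x W")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape


def write_stack(path, stack: FrameStack) -> None:
    """Write a stack as multi-page TIFF (.tif) or NPZ (.npz)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.data,
                         metadata={"frame_rate": stack.frame_rate})
    elif path.suffix == ".npz":
        np.savez(path, data=stack.data, frame_rate=stack.frame_rate)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")


def read_stack(path, frame_rate: float | None = None) -> FrameStack:
    """Read a multi-page TIFF or NPZ stack back into a :class:`FrameStack`.

    Mixed-shape TIFF pages raise with the offending page named.
    """
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            shapes = [p.shape for p in tif.pages]
            for i, s in enumerate(shapes):
                if s != shapes[0]:
                    raise ValueError(f"page {i} shape {s} != page 0 shape {shapes[0]}")
            data = tif.asarray()
            if data.ndim == 2:
                data = data[None]
            if frame_rate is None:
                meta = tif.shaped_metadata or tif.imagej_metadata
                if isinstance(meta, (list, tuple)) and meta:
                    meta = meta[0]
                frame_rate = float((meta or {}).get("frame_rate", 10.0))
        return FrameStack(data, frame_rate)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return FrameStack(z["data"], float(frame_rate or z["frame_rate"]))
    raise ValueError(f"unsupported stack format: {path.suffix}")


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage, derived
    deterministically from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())]))


@dataclass
class SessionConfig:
    """Everything the end-to-end synthetic run needs, with the study's
    default parameters. Presets: ``tiny`` (64 x 64 widefield sheet) and
    ``paper_like`` (200 x 200)."""

    master_seed: int = 0
    out_dir: str = "cohmap_out"
    # widefield sheet
    sheet_shape: tuple = (64, 64)
    n_areas: int = 7
    snr: float = 3.0
    tau_s: float = 1.5
    frame_rate: float = 10.0
    bar_cycles: int = 6
    coherence_block_frames: int = 50
    coherence_cycles: int = 3
    gain_intercept: float = 1.0
    gain_elevation_slope: float = -0.01
    # two-photon field
    twophoton_shape: tuple = (96, 96)
    n_cells: int = 20
    field_width_um: float = 425.0
    neuropil_alpha: float = 0.7
    kappa: float = 3.0

    @classmethod
    def tiny(cls, master_seed: int = 0, out_dir: str = "cohmap_out") -> "SessionConfig":
        return cls(master_seed=master_seed, out_dir=out_dir)

    @classmethod
    def paper_like(cls, master_seed: int = 0, out_dir: str = "cohmap_out") -> "SessionConfig":
        return cls(master_seed=master_seed, out_dir=out_dir,
                   sheet_shape=(200, 200), twophoton_shape=(256, 256),
                   n_cells=60)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sheet_shape"] = list(d["sheet_shape"])
        d["twophoton_shape"] = list(d["twophoton_shape"])
        return d


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: SessionConfig) -> dict:
    """Run the full synthetic study: stimulus synthesis, widefield
    retinotopy and area segmentation, coherent-motion correlation mapping
    with areal summaries and retinotopic-asymmetry statistics, a two-photon
    cellular session, and the statistics table.

    Writes maps (NPZ), tables (CSV), a QC/recovery report and a provenance
    JSON into ``config.out_dir`` and returns the artifact bundle as a dict.
    Fully deterministic under a fixed master seed.
    """
    from . import motion, retinotopy, stats, synthetic, twophoton
    from .stimulus import make_coherence_trace

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"partial": False, "failed_stages": []}
    report: dict = {}

    try:
        truth = synthetic.make_cortical_sheet(
            shape=tuple(config.sheet_shape), n_areas=config.n_areas,
            seed=int(stage_rng(config.master_seed, "sheet").integers(2**31)),
            gain_intercept=config.gain_intercept,
            gain_elevation_slope=config.gain_elevation_slope)

        # --- widefield retinotopy from four bar sweeps ---
        ret = retinotopy.recover_retinotopy(
            truth, seed=int(stage_rng(config.master_seed, "bars").integers(2**31)),
            snr=config.snr, tau=config.tau_s, frame_rate=config.frame_rate,
            n_cycles=config.bar_cycles)
        seg_labels, seg_signs = retinotopy.segment_areas(
            ret.sign_map, ret.azimuth, ret.elevation)
        names = retinotopy.label_areas(seg_labels, seg_signs)
        np.savez(out / "retinotopy.npz", azimuth=ret.azimuth,
                 elevation=ret.elevation, sign_map=ret.sign_map,
                 segmentation=seg_labels)
        area_table = pd.DataFrame(
            {"label": sorted(names), "name": [names[k] for k in sorted(names)],
             "sign": [seg_signs[k] for k in sorted(names)],
             "n_pixels": [int((seg_labels == k).sum()) for k in sorted(names)]})
        _df_to_csv(area_table, out / "areas.csv")
        report["n_patches_recovered"] = len(names)
        report["n_areas_planted"] = len(truth.area_names)
        v1 = truth.labels == 1
        report["median_azimuth_error_deg"] = float(np.nanmedian(
            np.abs(ret.azimuth - truth.azimuth)[v1]))
        report["median_elevation_error_deg"] = float(np.nanmedian(
            np.abs(ret.elevation - truth.elevation)[v1]))

        # --- RDK session: coherent-motion correlation mapping ---
        trace = make_coherence_trace(
            block_frames=config.coherence_block_frames, mode="blocked",
            seed=int(stage_rng(config.master_seed, "trace").integers(2**31)),
            n_cycles=config.coherence_cycles, gray_frames=20,
            frame_rate=config.frame_rate)
        stack, info = synthetic.simulate_widefield_session(
            truth, trace, session_kind="rdk",
            seed=int(stage_rng(config.master_seed, "rdk").integers(2**31)),
            snr=config.snr, tau=config.tau_s, n_trials=4)
        dff = retinotopy.compute_dff(stack)
        trial_avg = dff.data.reshape(info["n_trials"], info["frames_per_trial"],
                                     *truth.shape).mean(axis=0)
        trial_avg_dff = retinotopy.DFFStack(trial_avg, dff.baseline, dff.frame_rate)
        mmap = motion.coherent_motion_correlation_map(trial_avg_dff, trace)
        np.savez(out / "motion_maps.npz", coherent_motion_correlation=mmap)
        summary = motion.areal_summary(mmap, seg_labels, names)
        _df_to_csv(summary, out / "areal_summary.csv")
        mask = truth.labels > 0
        r_az, r_el = motion.retinotopic_asymmetry(
            mmap, truth.azimuth, truth.elevation, mask)
        report["asymmetry_r_azimuth"] = float(r_az)
        report["asymmetry_r_elevation"] = float(r_el)
        report["planted_gain_elevation_slope"] = config.gain_elevation_slope

        # --- two-photon cellular session ---
        truth2p = synthetic.make_twophoton_truth(
            shape=tuple(config.twophoton_shape), n_cells=config.n_cells,
            seed=int(stage_rng(config.master_seed, "cells_truth").integers(2**31)),
            alpha=config.neuropil_alpha, kappa=config.kappa)
        sess = synthetic.simulate_twophoton_session(
            truth2p, seed=int(stage_rng(config.master_seed, "cells_sim").integers(2**31)),
            frame_rate=config.frame_rate)
        cells = twophoton.run_cell_pipeline(sess, truth2p.um_per_px)
        _df_to_csv(cells.table, out / "cells.csv")
        report["n_cells_planted"] = truth2p.n_cells
        report["n_cells_recovered"] = len(cells.table)
        report["session_qc_pass"] = bool(cells.qc.passed) if cells.qc else None
        if len(cells.table) >= 4 and cells.table["preferred_direction"].notna().sum() >= 4:
            prefs = np.deg2rad(cells.table["preferred_direction"].dropna().to_numpy())
            report["hodges_ajne_p"] = float(twophoton.hodges_ajne(prefs))

        # --- stats table ---
        rows = []
        for name in summary["area"]:
            vals = mmap[(seg_labels == int(
                area_table.loc[area_table["name"] == name, "label"].iloc[0]))]
            vals = vals[np.isfinite(vals)]
            if vals.size >= 2 and np.std(vals) > 0:
                res = stats.one_sample_t(vals)
                rows.append({"comparison": f"{name} motion correlation vs 0",
                             "statistic": res.statistic, "df": res.df,
                             "p": res.p, "g": res.effect_size,
                             "n1": res.n[0], "n2": 0})
        thr = stats.bonferroni_threshold(0.05, max(len(rows), 1))
        tests = pd.DataFrame(rows)
        if len(tests):
            tests["significant_at_bonferroni"] = tests["p"] < thr
        _df_to_csv(tests, out / "stats.csv")
    except Exception as exc:  # pragma: no cover - partial-bundle path
        bundle["partial"] = True
        bundle["failed_stages"].append(repr(exc))

    bundle["report"] = report
    cfg = config.to_dict()
    cfg.pop("out_dir", None)  # keep provenance independent of where it lands
    provenance = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "master_seed": config.master_seed,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    bundle["out_dir"] = str(out)
    return bundle
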