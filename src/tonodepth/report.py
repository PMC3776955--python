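"""End-to-end orchestration and the quantitative summary table.

``run_pipeline`` chains the stages -- phantom synthesis, surface modelling,
voxel frequency responses, virtual penetrations, whole-structure summary --
writing every intermediate artifact (NIfTI volumes, OBJ/PLY meshes, CSV
tables, JSON summaries) into a working directory, and returns the summary
row.  ``table_stats`` aggregates rows of such summaries into the mean +- sd
column of the results table, with the significant/total area ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .penetration import (
    GradientSummary,
    PenetrationConfig,
    map_gradients,
    summarize_gradients,
)
from .phantom import (
    PhantomSpec,
    make_phantom_mask,
    make_session_design,
    plant_frequency_field,
    simulate_session,
)
from .response import (
    BootstrapConfig,
    compute_frequency_maps,
    extract_amplitudes,
    resample_to_mask,
)
from .surface import compute_depth_map, curvature_and_region, extract_surface

class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs, mirroring the stage parameters."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    penetration: PenetrationConfig = field(default_factory=PenetrationConfig)
    smoothing_iters: int = 20
    curvature_threshold: float = 0.05
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            phantom=self.phantom.replace(seed=seed),
            bootstrap=dataclasses.replace(self.bootstrap, seed=seed),
        )

    def as_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return clean(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def tupled(x):
            return tuple(tupled(v) for v in x) if isinstance(x, list) else x

        kw = {}
        if "phantom" in d:
            kw["phantom"] = PhantomSpec(**{k: tupled(v) for k, v in d["phantom"].items()})
        if "bootstrap" in d:
            kw["bootstrap"] = BootstrapConfig(**d["bootstrap"])
        if "penetration" in d:
            pen = dict(d["penetration"])
            if "depth_range_mm" in pen:
                pen["depth_range_mm"] = tuple(pen["depth_range_mm"])
            kw["penetration"] = PenetrationConfig(**pen)
        for k in ("smoothing_iters", "curvature_threshold", "seed"):
            if k in d:
                kw[k] = d[k]
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})


@dataclass
class PipelineResult:
    summary: GradientSummary
    table: pd.DataFrame  # map_gradients per-vertex table
    row: dict  # report-table row
    outdir: Path | None


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - stage-named re-raise
                raise PipelineStageError(name, e) from e

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run synth -> surface -> respond -> penetrate -> summarize.

    With ``outdir`` set, every declared artifact is written there (config
    echo with seed, masks and ground truth, session data and design table,
    meshes and vertex tables, frequency maps, the per-vertex gradient table,
    and the summary JSON).  Reruns with the same config and seed produce
    byte-identical summary JSON.
    """
    spec = config.phantom
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        io.save_json(out / "config.json", config.as_dict())

    @_stage("synth")
    def synth():
        func_mask = make_phantom_mask(spec)
        struct_mask = make_phantom_mask(spec, voxel_size_mm=spec.surface_voxel_size_mm)
        gt = plant_frequency_field(func_mask, spec)
        design = make_session_design(spec)
        data = simulate_session(gt, spec, design)
        if out is not None:
            io.save_volume(out / "mask.nii.gz", func_mask.mask, func_mask.voxel_size_mm)
            io.save_volume(out / "mask_structural.nii.gz", struct_mask.mask,
                           struct_mask.voxel_size_mm)
            io.save_volume(out / "gt_depth.nii.gz", gt.depth_field, spec.voxel_size_mm)
            io.save_volume(out / "gt_preferred_oct.nii.gz", gt.preferred_freq_field,
                           spec.voxel_size_mm)
            io.save_volume(out / "gt_labels.nii.gz", gt.patch_labels.astype(np.int16),
                           spec.voxel_size_mm)
            io.save_json(out / "gt_meta.json",
                         {"g_true": gt.g_true, "seed": spec.seed,
                          "spec": config.as_dict()["phantom"]})
            io.save_volume(out / "data.nii.gz",
                           np.moveaxis(data.to_volumes(), 0, -1).astype(np.float32),
                           spec.voxel_size_mm)
            design.table().to_csv(out / "design.csv", index=False)
        return func_mask, struct_mask, gt, data

    func_mask, struct_mask, gt, data = synth()

    @_stage("surface")
    def surface():
        surf = extract_surface(struct_mask.mask, struct_mask.voxel_size_mm,
                               smoothing_iters=config.smoothing_iters)
        curvature_and_region(surf, curvature_threshold=config.curvature_threshold)
        depthmap = compute_depth_map(struct_mask.mask, surf, struct_mask.voxel_size_mm)
        if out is not None:
            io.save_mesh(out / "surface", surf)
            io.save_vertex_table(out / "vertices.csv", surf)
            io.save_volume(out / "depth.nii.gz", depthmap.depth_mm,
                           struct_mask.voxel_size_mm)
        return surf, depthmap

    surf, depthmap = surface()

    @_stage("respond")
    def respond():
        # the depth analysis samples the functional data on the structural
        # grid the surface model lives on
        data_s = resample_to_mask(data, struct_mask)
        resp = extract_amplitudes(data_s)
        maps = compute_frequency_maps(resp, config.bootstrap)
        if out is not None:
            for name, arr in (("f_cent_oct", maps.f_cent), ("f_tune_oct", maps.f_tune),
                              ("hl_diff", maps.hl_diff), ("p_sound", maps.p_sound)):
                vol = np.full(struct_mask.mask.shape, np.nan)
                vol[tuple(data_s.voxel_indices.T)] = arr
                io.save_volume(out / f"{name}.nii.gz", vol,
                               struct_mask.voxel_size_mm)
            pd.DataFrame(
                {"i": data_s.voxel_indices[:, 0], "j": data_s.voxel_indices[:, 1],
                 "k": data_s.voxel_indices[:, 2], "f_cent_oct": maps.f_cent,
                 "f_tune_oct": maps.f_tune, "hl_diff": maps.hl_diff,
                 "p_sound": maps.p_sound, "ci68_width_oct": maps.ci68_width}
            ).to_csv(out / "voxel_maps.csv", index=False)
        return resp, maps

    resp, maps = respond()

    @_stage("penetrate")
    def penetrate():
        table = map_gradients(surf, depthmap, resp, config.penetration,
                              config.bootstrap, maps=maps)
        if out is not None:
            table.to_csv(out / "penetrations.csv")
        return table

    table = penetrate()

    @_stage("summarize")
    def summarize():
        summary = summarize_gradients(surf, table, config.penetration)
        row = {
            "sig_area_mm2": summary.sig_area_mm2,
            "trend_area_mm2": summary.trend_area_mm2,
            "total_area_mm2": summary.total_area_mm2,
            "mean_slope": summary.mean_slope,
            "sagittal_angle_deg": summary.sagittal_angle_deg,
            "axial_angle_deg": summary.axial_angle_deg,
            "mean_r2": summary.mean_r2,
            "mean_d0": summary.mean_d0,
        }
        if out is not None:
            io.save_json(out / "summary.json",
                         {"seed": config.seed, "summary": summary.as_dict(),
                          "row": row})
        return summary, row

    summary, row = summarize()
    return PipelineResult(summary=summary, table=table, row=row, outdir=out)


# ---------------------------------------------------------------------------
# report table


def half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at a given precision (display convention:
    e.g. 137.75 -> 138)."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def table_stats(rows: pd.DataFrame | list[dict]) -> dict:
    """Mean +- sample sd per report column, plus the pooled significant/total
    area ratio (integer percent, computed from the column sums)."""
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("need at least one row")
    out = {"n_rows": int(len(df)), "mean": {}, "sd": {}}
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            continue
        x = df[col].astype(float).values
        out["mean"][col] = float(np.mean(x))
        out["sd"][col] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if {"sig_area_mm2", "total_area_mm2"} <= set(df.columns):
        ratio = 100.0 * df["sig_area_mm2"].sum() / df["total_area_mm2"].sum()
        out["sig_total_ratio_pct"] = int(half_up(ratio, 0))
    return out


DISPLAY_PRECISION = {
    "sig_area_mm2": 0,
    "trend_area_mm2": 0,
    "total_area_mm2": 0,
    "mean_slope": 2,
    "sagittal_angle_deg": 0,
    "axial_angle_deg": 0,
    "mean_r2": 2,
    "mean_d0": 2,
}


def format_report(rows: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Printable results table: one column per phantom/subject row plus the
    mean +- sd column, at the display precision of each quantity."""
    df = pd.DataFrame(rows)
    stats = table_stats(df)
    cols = {}
    for i, (_, row) in enumerate(df.iterrows()):
        cols[f"run {i + 1}"] = {
            k: half_up(row[k], DISPLAY_PRECISION.get(k, 2)) for k in df.columns
        }
    cols["mean"] = {
        k: half_up(stats["mean"][k], DISPLAY_PRECISION.get(k, 2)) for k in df.columns
    }
    cols["sd"] = {
        k: half_up(stats["sd"][k], DISPLAY_PRECISION.get(k, 2)) for k in df.columns
    }
    return pd.DataFrame(cols)
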