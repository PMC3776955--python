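"""Virtual depth penetrations: cylinder probes, gradient fits, significance.

From every vertex of the analysis region a "virtual electrode penetration" is
made: the mean outward normal over the surrounding 0.6-mm manifold patch is
negated to give the inward direction, and a 1.2-mm-diameter cylinder is
extended along it over a 0-5 mm depth range.  The centroid frequency (or the
high-minus-low amplitude difference) of the member voxels is regressed on
their depth-map depth; a variable amount (0-1.5 mm) of superficial tissue is
removed before fitting, keeping the starting depth that gives the best
linear fit (minimum residual variance by default).  The
one-sided significance of a positive slope is the fraction of bootstrap
resamples (presentations resampled with replacement within condition) whose
refitted slope is non-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .response import (
    BootstrapConfig,
    FrequencyMaps,
    ResponseSamples,
    compute_frequency_maps,
    resample_weights,
)
from .surface import DepthMap, SurfaceMesh, manifold_patch, region_area


@dataclass(frozen=True)
class PenetrationConfig:
    """Geometry and fitting parameters of the depth-gradient analysis."""

    radius_mm: float = 0.6  # cylinder radius (1.2-mm diameter)
    depth_range_mm: tuple[float, float] = (0.0, 5.0)
    patch_radius_mm: float = 0.6  # manifold-patch radius for the mean normal
    d0_max_mm: float = 1.5  # deepest superficial cut searched
    d0_step_mm: float = 0.1
    min_points: int = 4
    value: str = "centroid"  # or "hl_diff"
    sig_p: float = 0.05
    trend_p: float = 0.16
    # voxels without a detectable sound response (one-sided bootstrap
    # sound-vs-quiet p at/above this) are excluded from fits: their moment
    # estimates are noise-dominated and biased toward mid-frequency.
    # None disables the filter.
    sound_p_threshold: float | None = 0.05
    # "best linear fit" criterion for the d0 search: "min_residual" picks the
    # starting depth minimizing the residual variance SSR/(n-2) (does not
    # reward span, so a flat superficial segment is actually trimmed);
    # "max_r2" picks the maximum R^2.
    d0_criterion: str = "min_residual"

    def d0_grid(self) -> np.ndarray:
        return np.arange(0.0, self.d0_max_mm + self.d0_step_mm / 2, self.d0_step_mm)


@dataclass
class Penetration:
    """One cylinder probe: inward direction, member voxels and their depths."""

    vertex_id: int
    origin: np.ndarray
    direction: np.ndarray  # inward unit vector
    voxel_rows: np.ndarray  # rows into the DepthMap flat arrays
    depths_mm: np.ndarray
    usable: bool = True

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_rows)


@dataclass
class DepthFit:
    """Linear depth-gradient fit for one penetration."""

    g: float  # slope (octaves/mm for centroid values)
    intercept: float
    d0: float  # superficial depth removed before fitting, mm
    r2: float
    p: float = np.nan  # one-sided bootstrap p (positive gradient)
    n_voxels: int = 0
    usable: bool = True


def build_penetration(
    surf: SurfaceMesh,
    depthmap: DepthMap,
    vertex_id: int,
    cfg: PenetrationConfig = PenetrationConfig(),
) -> Penetration:
    """Construct the cylinder probe rooted at a surface vertex.

    Direction is the normalized negative mean outward normal over the
    manifold patch; members are in-mask voxel centers whose perpendicular
    distance to the axis is <= the cylinder radius and whose axial projection
    lies within the depth range.  Each member carries its depth-map depth
    (which the fits use as the depth coordinate; the axial projection is only
    used for membership).
    """
    patch = manifold_patch(surf, vertex_id, cfg.patch_radius_mm)
    n = -surf.outward_normals[patch].mean(axis=0)
    norm = np.linalg.norm(n)
    origin = surf.vertices[vertex_id]
    if norm < 1e-9:
        return Penetration(vertex_id, origin, np.zeros(3), np.empty(0, int),
                           np.empty(0), usable=False)
    n = n / norm
    rel = depthmap.voxel_centers_mm - origin
    t = rel @ n
    perp2 = np.maximum((rel**2).sum(axis=1) - t**2, 0.0)
    lo, hi = cfg.depth_range_mm
    members = (
        (perp2 <= cfg.radius_mm**2 + 1e-9)
        & (t >= lo - 1e-9)
        & (t <= hi + 1e-9)
    )
    rows = np.flatnonzero(members)
    pen = Penetration(
        vertex_id=vertex_id,
        origin=origin,
        direction=n,
        voxel_rows=rows,
        depths_mm=depthmap.depth_flat[rows],
        usable=len(rows) > 0,
    )
    return pen


def _line_fit(x: np.ndarray, y: np.ndarray):
    xm, ym = x.mean(), y.mean()
    xc = x - xm
    denom = (xc**2).sum()
    if denom <= 0:
        return np.nan, np.nan, 0.0
    slope = (xc * (y - ym)).sum() / denom
    intercept = ym - slope * xm
    sst = ((y - ym) ** 2).sum()
    if sst <= 0:
        return slope, intercept, 0.0
    ssr = ((y - (intercept + slope * x)) ** 2).sum()
    return slope, intercept, 1.0 - ssr / sst


def fit_depth_gradient(
    pen: Penetration,
    values: np.ndarray,
    cfg: PenetrationConfig = PenetrationConfig(),
) -> DepthFit:
    """Best straight-line fit of value against depth after removing 0-1.5 mm
    of superficial tissue.

    For each candidate initial depth d0 on a 0.1-mm grid, voxels with depth
    >= d0 are fitted by least squares; the d0 giving the best fit (minimum
    residual variance by default, see ``PenetrationConfig.d0_criterion``),
    subject to at least ``min_points`` voxels, is kept; ties break toward
    smaller d0 so that more data are retained.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values) & np.isfinite(pen.depths_mm)
    depths = pen.depths_mm[finite]
    vals = values[finite]
    best = None
    best_score = np.inf
    for d0 in cfg.d0_grid():
        sel = depths >= d0 - 1e-9
        n = int(sel.sum())
        if n < cfg.min_points:
            continue
        slope, intercept, r2 = _line_fit(depths[sel], vals[sel])
        if not np.isfinite(slope):
            continue
        if cfg.d0_criterion == "max_r2":
            score = -r2
        else:  # residual variance, independent of the span of y
            sst = ((vals[sel] - vals[sel].mean()) ** 2).sum()
            score = sst * (1.0 - r2) / max(n - 2, 1)
        if best is None or score < best_score - 1e-12:
            best = DepthFit(g=slope, intercept=intercept, d0=float(d0), r2=r2,
                            n_voxels=n)
            best_score = score
    if best is None:
        return DepthFit(np.nan, np.nan, np.nan, np.nan, n_voxels=0, usable=False)
    return best


def _values_from_amplitudes(A_b: np.ndarray, f_oct: np.ndarray, mode: str) -> np.ndarray:
    """Per-voxel fit values from (B, n_cond, n_vox) resampled amplitudes."""
    if mode == "centroid":
        w = A_b - A_b.min(axis=1, keepdims=True)
        sw = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (f_oct[None, :, None] * w).sum(axis=1) / sw
    if mode == "hl_diff":
        return A_b[:, -1, :] - A_b[:, 0, :]
    raise ValueError(f"unknown value mode {mode!r}")


def bootstrap_slope_p(
    pen: Penetration,
    samples: np.ndarray,
    f_oct: np.ndarray,
    fit: DepthFit,
    cfg: PenetrationConfig = PenetrationConfig(),
    bootstrap: BootstrapConfig = BootstrapConfig(),
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided bootstrap p value of a positive depth gradient.

    ``samples`` is (n_conditions, n_reps, n_member_voxels): per-presentation
    quiet-referenced amplitudes of the penetration's voxels.  For each of B
    resamples the condition means are recomputed from presentations resampled
    with replacement, the voxel values rebuilt (min-subtraction inside each
    resample for centroid mode), and the line refitted at the point
    estimate's d0 (re-searching d0 per resample would bias p downward).
    p = (#slopes <= 0)/B, clamped to at least 1/(B+1).
    """
    if not (pen.usable and fit.usable):
        return np.nan
    if rng is None:
        rng = np.random.default_rng(bootstrap.seed)
    n_cond, n_reps, _ = samples.shape
    sel = pen.depths_mm >= fit.d0 - 1e-9
    x = pen.depths_mm[sel]
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom <= 0 or sel.sum() < 2:
        return np.nan
    B = bootstrap.B
    A_b = np.empty((B, n_cond, int(sel.sum())))
    sub = samples[:, :, sel]
    for c in range(n_cond):
        A_b[:, c, :] = resample_weights(rng, B, n_reps) @ sub[c]
    vals = _values_from_amplitudes(A_b, f_oct, cfg.value)  # (B, n_sel)
    ok = np.isfinite(vals).all(axis=1)
    vals = vals[ok]
    if len(vals) == 0:
        return np.nan
    slopes = ((vals - vals.mean(axis=1, keepdims=True)) * xc).sum(axis=1) / denom
    count = int((slopes <= 0).sum()) + int((~ok).sum())  # degenerate resamples count against
    return max(count / B, 1.0 / (B + 1))


def map_gradients(
    surf: SurfaceMesh,
    depthmap: DepthMap,
    resp: ResponseSamples,
    cfg: PenetrationConfig = PenetrationConfig(),
    bootstrap: BootstrapConfig = BootstrapConfig(),
    region: np.ndarray | None = None,
    maps: FrequencyMaps | None = None,
) -> pd.DataFrame:
    """One penetration, fit and bootstrap p per region vertex.

    Fit values come from the per-voxel frequency maps (centroid or high-low
    difference); voxels whose sound-vs-quiet p is at or above
    ``cfg.sound_p_threshold`` are excluded from fits.  Returns a table
    indexed by vertex id with columns g, p, r2, d0, n_voxels, nx/ny/nz
    (inward direction) and usable; unusable penetrations (grazing geometry,
    too few voxels) are recorded with NaN statistics.  Deterministic given
    inputs and the bootstrap seed.
    """
    if region is None:
        region = surf.region_mask
    if region is None:
        raise ValueError("no analysis region defined on the surface")
    vertex_ids = np.flatnonzero(region)
    if maps is None:
        maps = compute_frequency_maps(resp, bootstrap, ci=False)
    if cfg.value == "centroid":
        values_all = np.array(maps.f_cent, dtype=float, copy=True)
    else:
        values_all = np.array(maps.hl_diff, dtype=float, copy=True)
    if cfg.sound_p_threshold is not None:
        values_all[maps.p_sound >= cfg.sound_p_threshold] = np.nan
    seeds = np.random.SeedSequence(bootstrap.seed).spawn(len(vertex_ids))
    rows = []
    for vid, ss in zip(vertex_ids, seeds):
        pen = build_penetration(surf, depthmap, int(vid), cfg)
        if pen.usable:
            vals = values_all[pen.voxel_rows]
            keep = np.isfinite(vals)
            pen = Penetration(
                pen.vertex_id, pen.origin, pen.direction,
                pen.voxel_rows[keep], pen.depths_mm[keep],
                usable=bool(keep.any()),
            )
            vals = vals[keep]
        if pen.usable:
            fit = fit_depth_gradient(pen, vals, cfg)
        else:
            fit = DepthFit(np.nan, np.nan, np.nan, np.nan, usable=False)
        p = np.nan
        if pen.usable and fit.usable:
            sub = resp.sound_samples[:, :, pen.voxel_rows]
            p = bootstrap_slope_p(
                pen, sub, resp.f_oct, fit, cfg, bootstrap,
                rng=np.random.default_rng(ss),
            )
        rows.append(
            dict(vertex=int(vid), g=fit.g, p=p, r2=fit.r2, d0=fit.d0,
                 n_voxels=fit.n_voxels, nx=pen.direction[0], ny=pen.direction[1],
                 nz=pen.direction[2], usable=bool(pen.usable and fit.usable)),
        )
    return pd.DataFrame(rows).set_index("vertex")


def area_summary(surf: SurfaceMesh, vertex_ids, pvals, thresholds=(0.05, 0.16)) -> dict:
    """Surface area (mm^2) below each p threshold, from per-vertex areas."""
    vertex_ids = np.asarray(vertex_ids)
    pvals = np.asarray(pvals, dtype=float)
    out = {}
    for thr in thresholds:
        sel = vertex_ids[np.isfinite(pvals) & (pvals < thr)]
        out[thr] = region_area(surf, sel)
    return out


def mean_gradient_direction(directions, slopes, pvals, sig_threshold: float = 0.05):
    """Slope-weighted mean direction of significant penetrations, with angles.

    ``<n> = sum g_i n_i / sum g_i`` over penetrations with p below the
    threshold, normalized to unit length.  Angle convention: 0 deg points
    directly anterior (+y); positive sagittal angles rotate superior (+z),
    positive axial angles rotate to the right (+x).  Returns
    ``(n, sagittal_deg, axial_deg)`` or ``None`` when nothing is significant.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    slopes = np.asarray(slopes, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    sig = np.isfinite(pvals) & (pvals < sig_threshold) & np.isfinite(slopes)
    if not sig.any():
        return None
    g = slopes[sig]
    v = (g[:, None] * directions[sig]).sum(axis=0) / g.sum()
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        return None
    v = v / norm
    sagittal = float(np.degrees(np.arctan2(v[2], v[1])))
    axial = float(np.degrees(np.arctan2(v[0], v[1])))
    return v, sagittal, axial


@dataclass
class GradientSummary:
    """Whole-structure summary of the depth-gradient analysis (the per-subject
    column of the quantitative results table)."""

    total_area_mm2: float
    sig_area_mm2: float
    trend_area_mm2: float
    mean_slope: float
    sd_slope: float
    mean_r2: float
    sd_r2: float
    mean_d0: float
    sd_d0: float
    mean_direction: np.ndarray | None
    sagittal_angle_deg: float
    axial_angle_deg: float
    n_penetrations: int
    n_significant: int

    def as_dict(self) -> dict:
        d = {
            "total_area_mm2": self.total_area_mm2,
            "sig_area_mm2": self.sig_area_mm2,
            "trend_area_mm2": self.trend_area_mm2,
            "mean_slope": self.mean_slope,
            "sd_slope": self.sd_slope,
            "mean_r2": self.mean_r2,
            "sd_r2": self.sd_r2,
            "mean_d0": self.mean_d0,
            "sd_d0": self.sd_d0,
            "sagittal_angle_deg": self.sagittal_angle_deg,
            "axial_angle_deg": self.axial_angle_deg,
            "n_penetrations": self.n_penetrations,
            "n_significant": self.n_significant,
        }
        if self.mean_direction is not None:
            d["mean_direction"] = [float(x) for x in self.mean_direction]
        return d


def summarize_gradients(
    surf: SurfaceMesh,
    table: pd.DataFrame,
    cfg: PenetrationConfig = PenetrationConfig(),
) -> GradientSummary:
    """Areas, slope statistics over significant penetrations, and the mean
    gradient direction, from a :func:`map_gradients` table."""
    usable = table[table["usable"]]
    areas = area_summary(surf, usable.index.values, usable["p"].values,
                         thresholds=(cfg.sig_p, cfg.trend_p))
    total = region_area(surf, table.index.values)
    sig = usable[usable["p"] < cfg.sig_p]
    direction = mean_gradient_direction(
        usable[["nx", "ny", "nz"]].values, usable["g"].values, usable["p"].values,
        sig_threshold=cfg.sig_p,
    )
    if direction is None:
        vec, sag, axi = None, np.nan, np.nan
    else:
        vec, sag, axi = direction

    def _ms(x):
        x = np.asarray(x, dtype=float)
        if len(x) == 0:
            return np.nan, np.nan
        return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    mean_g, sd_g = _ms(sig["g"].values)
    mean_r2, sd_r2 = _ms(sig["r2"].values)
    mean_d0, sd_d0 = _ms(sig["d0"].values)
    return GradientSummary(
        total_area_mm2=total,
        sig_area_mm2=areas[cfg.sig_p],
        trend_area_mm2=areas[cfg.trend_p],
        mean_slope=mean_g, sd_slope=sd_g,
        mean_r2=mean_r2, sd_r2=sd_r2,
        mean_d0=mean_d0, sd_d0=sd_d0,
        mean_direction=vec,
        sagittal_angle_deg=sag,
        axial_angle_deg=axi,
        n_penetrations=int(len(usable)),
        n_significant=int(len(sig)),
    )


def blur_control(volumes: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian spatial smoothing of every presentation volume at a stated
    FWHM, for the control analysis that tests whether spatial structure
    survives deliberate resolution loss.  Input is (n_presentations, nx, ny,
    nz) (a single 3-D volume is also accepted)."""
    if fwhm_mm <= voxel_size_mm:
        raise ValueError("blur FWHM should exceed the voxel size")
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim == 3:
        return ndimage.gaussian_filter(volumes, sigma=sigma)
    return ndimage.gaussian_filter(volumes, sigma=(0.0, sigma, sigma, sigma))


def alpha_from_p(p) -> np.ndarray | float:
    """Overlay opacity from significance: opaque below p=0.05, transparent at
    p>=0.5, linear in log(p) between."""
    p = np.asarray(p, dtype=float)
    lo, hi = 0.05, 0.5
    with np.errstate(divide="ignore"):
        alpha = (np.log(hi) - np.log(p)) / (np.log(hi) - np.log(lo))
    out = np.clip(alpha, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out
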