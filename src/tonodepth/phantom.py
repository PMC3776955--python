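"""Synthetic midbrain phantom with a planted depth-wise tonotopic gradient.

The phantom stands in for the undeposited human data the analysis was designed
for: a brainstem slab carrying two collicular protrusions (spherical caps by
default), imaged with 1.2-mm isotropic functional voxels in a sparse-sampling
session (five bandpass-noise conditions log-spaced on 0.25--8 kHz plus a quiet
reference, five repeats per condition per ~6-min run, ~11 runs).  A linear
preferred-frequency-vs-depth law is planted in patchy sub-regions of the caps
below a superficial non-tonotopic rind, and per-presentation response
amplitudes are simulated at a stated thermal SNR.  Every quantity needed to
score recovery (analytic depth, planted preferred frequency, patch labels) is
exported as ground truth.

Frequencies are handled throughout in octaves relative to 1 kHz
(``f_oct = log2(f_kHz)``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

OCT_REF_KHZ = 1.0

# patch-label codes used in GroundTruth.patch_labels
LABEL_OUTSIDE = -1
LABEL_UNTUNED = 0
LABEL_RIND = 1
LABEL_TONOTOPIC = 2
LABEL_REVERSED = 3

LABEL_NAMES = {
    LABEL_OUTSIDE: "outside",
    LABEL_UNTUNED: "untuned",
    LABEL_RIND: "rind",
    LABEL_TONOTOPIC: "tonotopic",
    LABEL_REVERSED: "reversed",
}

QUIET_CONDITION = 5  # condition code of the silent reference period


def stimulus_frequencies(f_lo_khz: float, f_hi_khz: float, n: int) -> np.ndarray:
    """Center frequencies (kHz) of the stimulus set: a geometric progression.

    With the default protocol (0.25, 8, 5) adjacent frequencies are 1.25
    octaves apart and the set spans exactly 5 octaves.
    """
    if f_lo_khz <= 0 or f_hi_khz <= 0:
        raise ValueError("stimulus frequencies must be positive")
    if not f_lo_khz < f_hi_khz:
        raise ValueError("f_lo_khz must be below f_hi_khz")
    if n < 2:
        raise ValueError("need at least two stimulus frequencies")
    return np.geomspace(f_lo_khz, f_hi_khz, n)


def to_octaves(f_khz) -> np.ndarray:
    """Convert frequency in kHz to octaves re 1 kHz."""
    return np.log2(np.asarray(f_khz, dtype=float) / OCT_REF_KHZ)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom and its simulated session.

    Defaults follow the study conditions of the protocol being emulated:
    1.2-mm functional voxels, 0.7-mm structural (surface) voxels, thermal
    SNR 25, 11 runs x 5 repeats = 55 presentations per condition, evoked
    amplitudes of ~1% signal, and a planted depth gradient of 0.53
    octaves/mm beneath a 0.7-mm non-tonotopic rind.
    """

    grid_shape: tuple[int, int, int] = (28, 20, 18)
    voxel_size_mm: float = 1.2
    surface_voxel_size_mm: float = 0.7
    colliculus_radii_mm: tuple[tuple[float, float, float], ...] = (
        (4.2, 4.2, 4.2),
        (4.2, 4.2, 4.2),
    )
    cap_gap_mm: float = 2.4
    rind_thickness_mm: float = 0.7
    gradient_oct_per_mm: float = 0.53
    base_freq_oct: float = 0.5
    patch_fraction: float = 0.6
    reversed_patch_fraction: float = 0.0
    patch_scale_mm: float = 3.0
    snr: float = 25.0
    n_runs: int = 11
    reps_per_run: int = 5
    response_amp_pct: float = 1.0
    tuning_width_oct: float = 1.0
    undershoot_fraction: float = 0.0
    partial_volume_subsamples: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rind_thickness_mm <= 1.5):
            raise ValueError("rind_thickness_mm must lie in [0, 1.5] mm")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for name in ("patch_fraction", "reversed_patch_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_runs < 1 or self.reps_per_run < 1:
            raise ValueError("n_runs and reps_per_run must be >= 1")
        if self.voxel_size_mm <= 0 or self.surface_voxel_size_mm <= 0:
            raise ValueError("voxel sizes must be positive")
        if len(self.colliculus_radii_mm) != 2:
            raise ValueError("exactly two colliculi are expected")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_size_mm

    @property
    def presentations_per_condition(self) -> int:
        return self.n_runs * self.reps_per_run

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Cap:
    """One collicular protrusion: an upper half-ellipsoid seated on the slab top."""

    center_xy: tuple[float, float]
    radii: tuple[float, float, float]

    @property
    def is_sphere(self) -> bool:
        a, b, c = self.radii
        return a == b == c

    @property
    def empty(self) -> bool:
        return min(self.radii) <= 0

    def surface_area(self) -> float:
        """Analytic area of the exposed cap (exact for spheres, Thomsen
        approximation for general half-ellipsoids)."""
        a, b, c = self.radii
        if self.empty:
            return 0.0
        if self.is_sphere:
            return 2.0 * np.pi * a * a
        p = 1.6075
        s = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        return 2.0 * np.pi * s ** (1.0 / p)

    def volume(self) -> float:
        a, b, c = self.radii
        return (2.0 / 3.0) * np.pi * a * b * c


@dataclass(frozen=True)
class PhantomGeometry:
    """Analytic description of the phantom boundary, shared by the mask
    builder and the ground-truth depth computation."""

    slab_min: tuple[float, float, float]
    slab_max: tuple[float, float, float]  # slab_max[2] is the free-surface plane z_top
    caps: tuple[Cap, ...]

    @property
    def z_top(self) -> float:
        return self.slab_max[2]

    def analytic_volume(self) -> float:
        lo = np.asarray(self.slab_min)
        hi = np.asarray(self.slab_max)
        v = float(np.prod(hi - lo))
        return v + sum(c.volume() for c in self.caps)


def phantom_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Place the slab and the two caps inside the grid, validating fit."""
    ext = spec.extent_mm
    vs = spec.voxel_size_mm
    margin = 2.0 * vs
    slab_min = (margin, margin, vs)
    r1, r2 = (tuple(map(float, r)) for r in spec.colliculus_radii_mm)
    cmax = max(r1[2], r2[2])
    # snap the free-surface plane to a functional-voxel boundary so the
    # voxelized slab volume is exact
    z_top = np.floor((ext[2] - cmax - 2.0 * vs) / vs) * vs
    slab_max = (ext[0] - margin, ext[1] - margin, z_top)
    if slab_max[2] <= slab_min[2]:
        raise ValueError("colliculus radius exceeds grid along axis z")
    sep = r1[0] + r2[0] + spec.cap_gap_mm
    cy = ext[1] / 2.0
    c1 = (ext[0] / 2.0 - sep / 2.0, cy)
    c2 = (ext[0] / 2.0 + sep / 2.0, cy)
    caps = (Cap(c1, r1), Cap(c2, r2))
    for cap in caps:
        if cap.empty:
            continue
        (cx, cyy), (a, b, c) = cap.center_xy, cap.radii
        if cx - a < slab_min[0] or cx + a > slab_max[0]:
            raise ValueError("colliculus radius exceeds grid along axis x")
        if cyy - b < slab_min[1] or cyy + b > slab_max[1]:
            raise ValueError("colliculus radius exceeds grid along axis y")
        if z_top + c > ext[2] - vs:
            raise ValueError("colliculus radius exceeds grid along axis z")
    return PhantomGeometry(slab_min, slab_max, caps)


@dataclass
class TissueMask:
    """Binary tissue mask on a voxel grid, with physical voxel size.

    Axes are ordered (x=right, y=anterior, z=superior); voxel centers sit at
    ``(index + 0.5) * voxel_size_mm``.
    """

    mask: np.ndarray
    voxel_size_mm: float
    geometry: PhantomGeometry | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_indices(self) -> np.ndarray:
        return np.argwhere(self.mask)

    def voxel_centers_mm(self) -> np.ndarray:
        return (self.voxel_indices() + 0.5) * self.voxel_size_mm


def _voxel_center_grids(shape, vs):
    axes = [(np.arange(n) + 0.5) * vs for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def make_phantom_mask(spec: PhantomSpec, voxel_size_mm: float | None = None) -> TissueMask:
    """Voxelize the phantom: slab union two superior half-ellipsoid caps.

    A voxel is in the mask when its center lies inside the analytic geometry,
    so the voxelized volume converges to :meth:`PhantomGeometry.analytic_volume`.
    Deterministic given the spec.  ``voxel_size_mm`` overrides the functional
    voxel size, e.g. to build the higher-resolution structural mask the
    surface model is extracted from.
    """
    geom = phantom_geometry(spec)
    vs = float(voxel_size_mm if voxel_size_mm is not None else spec.voxel_size_mm)
    shape = tuple(int(np.floor(e / vs + 1e-9)) for e in spec.extent_mm)
    x, y, z = _voxel_center_grids(shape, vs)
    lo, hi = geom.slab_min, geom.slab_max
    mask = (
        (x >= lo[0]) & (x <= hi[0])
        & (y >= lo[1]) & (y <= hi[1])
        & (z >= lo[2]) & (z <= hi[2])
    )
    for cap in geom.caps:
        if cap.empty:
            continue
        (cx, cy), (a, b, c) = cap.center_xy, cap.radii
        inside = (
            ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - geom.z_top) / c) ** 2
            <= 1.0
        ) & (z >= geom.z_top)
        mask |= inside
    return TissueMask(mask=mask, voxel_size_mm=vs, geometry=geom)


def _cap_surface_samples(cap: Cap, z_top: float, spacing_mm: float = 0.1) -> np.ndarray:
    """Dense parametric sampling of a non-spherical cap surface (upper half)."""
    a, b, c = cap.radii
    rmax = max(cap.radii)
    n_th = max(8, int(np.ceil((np.pi / 2) * rmax / spacing_mm)))
    n_ph = max(16, int(np.ceil(2 * np.pi * rmax / spacing_mm)))
    th = np.linspace(0.0, np.pi / 2, n_th)
    ph = np.linspace(0.0, 2 * np.pi, n_ph, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    cx, cy = cap.center_xy
    pts = np.column_stack(
        [
            cx + a * np.sin(T).ravel() * np.cos(P).ravel(),
            cy + b * np.sin(T).ravel() * np.sin(P).ravel(),
            z_top + c * np.cos(T).ravel(),
        ]
    )
    return pts


def depth_to_free_surface(points: np.ndarray, geom: PhantomGeometry) -> np.ndarray:
    """Analytic depth: Euclidean distance to the superior free surface.

    The free surface is the exposed slab-top plane plus the cap surfaces.
    Exact for the plane and for spherical caps; non-spherical caps use a
    0.1-mm parametric surface sampling.  Slab side and bottom faces are
    deliberately not part of this depth definition (the planted field and the
    depth analysis both live near the superior surface).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = points.T
    h = z - geom.z_top
    best = np.full(len(points), np.inf)
    covered = np.zeros(len(points), dtype=bool)
    for cap in geom.caps:
        if cap.empty:
            continue
        (cx, cy), (a, b, c) = cap.center_xy, cap.radii
        dx, dy = x - cx, y - cy
        covered |= (dx / a) ** 2 + (dy / b) ** 2 < 1.0
        if cap.is_sphere:
            rho = np.hypot(dx, dy)
            rim = np.hypot(rho - a, h)
            best = np.minimum(best, rim)
            d3 = np.sqrt(dx**2 + dy**2 + h**2)
            inside = (h >= 0) & (d3 <= a)
            best = np.where(inside, np.minimum(best, a - d3), best)
        else:
            tree = cKDTree(_cap_surface_samples(cap, geom.z_top))
            d, _ = tree.query(points)
            best = np.minimum(best, d)
    plane = np.where((h < 0) & ~covered, -h, np.inf)
    return np.minimum(best, plane)


@dataclass
class GroundTruth:
    """Planted phantom parameters, for parameter-recovery scoring.

    ``preferred_freq_field`` is NaN wherever no preferred frequency is defined
    (outside the mask, in the rind, and in untuned patches).  Within tonotopic
    voxels it obeys exactly
    ``base_freq_oct + g_true * (depth - rind_thickness)`` (sign flipped in
    reversed patches).
    """

    spec: PhantomSpec
    geometry: PhantomGeometry
    depth_field: np.ndarray
    preferred_freq_field: np.ndarray
    patch_labels: np.ndarray
    domain_field: np.ndarray  # True inside the collicular columns
    g_true: float
    seed_dirs: tuple[np.ndarray, ...] = field(repr=False, default=())
    seed_labels: tuple[np.ndarray, ...] = field(repr=False, default=())

    def depth_at(self, points: np.ndarray) -> np.ndarray:
        return depth_to_free_surface(points, self.geometry)

    def column_label_at(self, points: np.ndarray) -> np.ndarray:
        """Patch identity of the surface column through each point, ignoring
        depth (so surface vertices can be classified)."""
        return _column_labels(
            np.atleast_2d(points), self.geometry, self.seed_dirs, self.seed_labels
        )[0]

    def in_domain_at(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies in a collicular column (inside a cap or in
        the tissue column beneath its footprint)."""
        return _column_labels(
            np.atleast_2d(points), self.geometry, self.seed_dirs, self.seed_labels
        )[1]


def _column_labels(points, geom, seed_dirs, seed_labels):
    """Patch label and collicular-domain membership per point."""
    x, y, z = np.asarray(points, dtype=float).T
    h = z - geom.z_top
    out = np.full(len(x), LABEL_UNTUNED, dtype=np.int8)
    in_domain = np.zeros(len(x), dtype=bool)
    for cap, dirs, labs in zip(geom.caps, seed_dirs, seed_labels):
        if cap.empty or len(dirs) == 0:
            continue
        (cx, cy), (a, b, _) = cap.center_xy, cap.radii
        dx, dy = x - cx, y - cy
        dom = (dx / a) ** 2 + (dy / b) ** 2 < 1.0
        in_domain |= dom
        if not dom.any():
            continue
        u = np.column_stack([dx[dom], dy[dom], np.maximum(h[dom], 0.0)])
        norms = np.linalg.norm(u, axis=1)
        u[norms > 0] /= norms[norms > 0, None]
        u[norms == 0] = (0.0, 0.0, 1.0)  # axis voxels below center -> pole patch
        nearest = np.argmax(u @ dirs.T, axis=1)
        out[dom] = labs[nearest]
    return out, in_domain


def plant_frequency_field(tissue: TissueMask, spec: PhantomSpec) -> GroundTruth:
    """Plant the depth-wise preferred-frequency law in patchy cap sub-regions.

    Depth is computed analytically from the phantom geometry (independent of
    the surface-model pipeline, which must later recover it).  Patches are a
    seeded Voronoi tiling of each cap by directions from the cap center, with
    an exact count ``round(patch_fraction * n_patches)`` marked tonotopic and,
    of those, ``round(reversed_patch_fraction * n_tonotopic)`` carrying a
    negated gradient.
    """
    if tissue.geometry is None:
        raise ValueError("tissue mask must carry phantom geometry")
    geom = tissue.geometry
    if spec.patch_fraction == 0:
        import warnings

        warnings.warn(
            "patch_fraction=0 plants no tonotopic patches; "
            "gradient-recovery tests will have nothing to recover",
            stacklevel=2,
        )
    rng = np.random.default_rng([int(spec.seed) % (2**31), 17])
    seed_dirs, seed_labels = [], []
    for cap in geom.caps:
        if cap.empty:
            seed_dirs.append(np.zeros((0, 3)))
            seed_labels.append(np.zeros(0, dtype=np.int8))
            continue
        patch_area = np.pi * (spec.patch_scale_mm / 2.0) ** 2
        n = max(3, int(round(cap.surface_area() / patch_area)))
        zz = rng.uniform(0.0, 1.0, n)
        ph = rng.uniform(0.0, 2 * np.pi, n)
        s = np.sqrt(1.0 - zz**2)
        dirs = np.column_stack([s * np.cos(ph), s * np.sin(ph), zz])
        labs = np.full(n, LABEL_UNTUNED, dtype=np.int8)
        order = rng.permutation(n)
        n_t = int(round(spec.patch_fraction * n))
        n_r = int(round(spec.reversed_patch_fraction * n_t))
        labs[order[:n_t]] = LABEL_TONOTOPIC
        labs[order[:n_r]] = LABEL_REVERSED
        seed_dirs.append(dirs)
        seed_labels.append(labs)

    shape = tissue.mask.shape
    idx = tissue.voxel_indices()
    centers = (idx + 0.5) * tissue.voxel_size_mm
    depth = depth_to_free_surface(centers, geom)
    col, dom = _column_labels(centers, geom, seed_dirs, seed_labels)

    labels = np.where(dom, col, LABEL_UNTUNED).astype(np.int8)
    labels[dom & (depth < spec.rind_thickness_mm)] = LABEL_RIND
    signed = np.where(
        labels == LABEL_TONOTOPIC, 1.0, np.where(labels == LABEL_REVERSED, -1.0, np.nan)
    )
    pref = (
        spec.base_freq_oct
        + signed * spec.gradient_oct_per_mm * (depth - spec.rind_thickness_mm)
    )

    depth_vol = np.full(shape, np.nan)
    pref_vol = np.full(shape, np.nan)
    lab_vol = np.full(shape, LABEL_OUTSIDE, dtype=np.int8)
    dom_vol = np.zeros(shape, dtype=bool)
    ii = tuple(idx.T)
    depth_vol[ii] = depth
    pref_vol[ii] = pref
    lab_vol[ii] = labels
    dom_vol[ii] = dom
    return GroundTruth(
        spec=spec,
        geometry=geom,
        depth_field=depth_vol,
        preferred_freq_field=pref_vol,
        patch_labels=lab_vol,
        domain_field=dom_vol,
        g_true=spec.gradient_oct_per_mm,
        seed_dirs=tuple(seed_dirs),
        seed_labels=tuple(seed_labels),
    )


@dataclass(frozen=True)
class SessionDesign:
    """Session structure: a monotonic cycle of five sounds plus quiet,
    repeated five times per run."""

    condition_sequence: np.ndarray  # condition code per presentation, 5=quiet
    run_index: np.ndarray
    center_freqs_khz: np.ndarray
    presentation_period_s: float = 12.0
    sound_duration_s: float = 2.85
    sound_gap_s: float = 0.3
    n_runs: int = 11
    reps_per_run: int = 5

    @property
    def cycle_period_s(self) -> float:
        return (len(self.center_freqs_khz) + 1) * self.presentation_period_s

    @property
    def n_presentations(self) -> int:
        return len(self.condition_sequence)

    @property
    def f_oct(self) -> np.ndarray:
        return to_octaves(self.center_freqs_khz)

    def table(self) -> pd.DataFrame:
        freqs = np.full(self.n_presentations, np.nan)
        sound = self.condition_sequence < QUIET_CONDITION
        freqs[sound] = self.center_freqs_khz[self.condition_sequence[sound]]
        return pd.DataFrame(
            {
                "run": self.run_index,
                "presentation": np.arange(self.n_presentations),
                "condition": self.condition_sequence,
                "center_freq_khz": freqs,
            }
        )


def make_session_design(spec: PhantomSpec, f_lo_khz=0.25, f_hi_khz=8.0, n_freqs=5) -> SessionDesign:
    freqs = stimulus_frequencies(f_lo_khz, f_hi_khz, n_freqs)
    cycle = np.arange(n_freqs + 1)  # monotonically increasing, then quiet
    per_run = np.tile(cycle, spec.reps_per_run)
    seq = np.tile(per_run, spec.n_runs)
    runs = np.repeat(np.arange(spec.n_runs), len(per_run))
    return SessionDesign(
        condition_sequence=seq,
        run_index=runs,
        center_freqs_khz=freqs,
        n_runs=spec.n_runs,
        reps_per_run=spec.reps_per_run,
    )


@dataclass
class SessionData:
    """Per-presentation response-amplitude data restricted to mask voxels.

    ``data[p, v]`` is the image intensity (percent-signal convention: baseline
    100) of mask voxel ``v`` at presentation ``p``.  ``frames`` optionally
    carries a per-acquisition series (4 frames per presentation) for
    exercising the preprocessing operators.
    """

    data: np.ndarray
    design: SessionDesign
    voxel_indices: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    baseline: float = 100.0
    frames: np.ndarray | None = None

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def to_volumes(self) -> np.ndarray:
        """Expand to dense (n_presentations, nx, ny, nz) volumes; voxels
        outside the mask are at baseline."""
        out = np.full((self.data.shape[0],) + tuple(self.grid_shape), self.baseline,
                      dtype=self.data.dtype)
        ii = tuple(self.voxel_indices.T)
        out[(slice(None),) + ii] = self.data
        return out

    @classmethod
    def from_volumes(cls, volumes, mask: TissueMask, design: SessionDesign,
                     baseline: float = 100.0) -> "SessionData":
        idx = mask.voxel_indices()
        data = volumes[(slice(None),) + tuple(idx.T)]
        return cls(
            data=np.ascontiguousarray(data),
            design=design,
            voxel_indices=idx,
            grid_shape=mask.mask.shape,
            voxel_size_mm=mask.voxel_size_mm,
            baseline=baseline,
        )


def noise_free_response(gt: GroundTruth, spec: PhantomSpec, design: SessionDesign) -> np.ndarray:
    """Evoked amplitude (percent signal above baseline) per condition and
    mask voxel, shape (n_conditions+1, n_voxels); the quiet row is zero.

    The planted field is continuous in space; each voxel's response is the
    partial-volume average of the local response over
    ``spec.partial_volume_subsamples ** 3`` points inside the voxel (1 =
    point-sample at the center).  Tuned tissue follows a Gaussian tuning
    curve in log2-frequency with sd ``tuning_width_oct`` around the local
    preferred frequency.  The superficial rind is responsive but carries no
    depth gradient: it is uniformly tuned to the base frequency (the low-pass
    response superficial tissue shows), so profiles along a penetration are
    constant through the rind and then rise.  Untuned patches respond with
    the full amplitude at every sound (responsive, not frequency selective).
    Tissue outside the collicular columns is not auditory-responsive.
    """
    idx = np.argwhere(~np.isnan(gt.depth_field))
    vs = gt.spec.voxel_size_mm
    k = max(1, int(spec.partial_volume_subsamples))
    offsets = (np.arange(k) + 0.5) / k  # sub-voxel fractions
    grid = np.stack(np.meshgrid(offsets, offsets, offsets, indexing="ij"), -1).reshape(-1, 3)
    f_oct = design.f_oct
    n_vox = len(idx)
    resp = np.zeros((len(f_oct) + 1, n_vox))
    for off in grid:
        pts = (idx + off) * vs
        depth = depth_to_free_surface(pts, gt.geometry)
        labels, dom = _column_labels(pts, gt.geometry, gt.seed_dirs, gt.seed_labels)
        rind = depth < spec.rind_thickness_mm
        pref = np.where(
            labels == LABEL_TONOTOPIC,
            spec.base_freq_oct
            + spec.gradient_oct_per_mm * (depth - spec.rind_thickness_mm),
            np.where(
                labels == LABEL_REVERSED,
                spec.base_freq_oct
                - spec.gradient_oct_per_mm * (depth - spec.rind_thickness_mm),
                np.nan,
            ),
        )
        pref = np.where(rind, spec.base_freq_oct, pref)
        tuned = dom & np.isfinite(pref)
        for i, f in enumerate(f_oct):
            r = np.where(dom, spec.response_amp_pct, 0.0)
            r[tuned] = spec.response_amp_pct * np.exp(
                -((f - pref[tuned]) ** 2) / (2.0 * spec.tuning_width_oct**2)
            )
            resp[i] += r
    resp[: len(f_oct)] /= len(grid)
    return resp


def simulate_session(
    gt: GroundTruth,
    spec: PhantomSpec,
    design: SessionDesign | None = None,
    seed: int | None = None,
    frames: bool = False,
    frames_per_presentation: int = 4,
) -> SessionData:
    """Simulate one sparse-sampling session over the phantom.

    ``snr`` is the temporal signal-to-noise of the acquired images, so each
    acquisition frame is ``baseline * (1 + response/100)`` plus Gaussian
    noise of sd ``baseline / snr``.  The sparse design collects
    ``frames_per_presentation`` image volumes during the flat-top of each
    evoked response (120 volumes per 30-presentation run at the default 4),
    and the primary data product -- one amplitude per presentation -- is
    their average, with noise sd ``baseline / snr / sqrt(frames)``.  With
    ``frames=True`` the frame-level series itself is attached (the
    presentation amplitudes are then exactly its per-presentation means).
    Identical seeds give bit-identical outputs.
    """
    if spec.snr <= 0:
        raise ValueError("snr must be positive")
    if design is None:
        design = make_session_design(spec)
    mask = ~np.isnan(gt.depth_field)
    idx = np.argwhere(mask)
    resp = noise_free_response(gt, spec, design)
    signal = resp[design.condition_sequence]  # (n_pres, n_vox)
    if spec.undershoot_fraction > 0:
        prev = np.empty_like(design.condition_sequence)
        prev[0] = QUIET_CONDITION
        prev[1:] = design.condition_sequence[:-1]
        signal = signal - spec.undershoot_fraction * resp[prev]
    baseline = 100.0
    sd = baseline / spec.snr
    rng = np.random.default_rng(int(spec.seed if seed is None else seed) % (2**31))
    frame_arr = None
    if frames:
        shape = (signal.shape[0], frames_per_presentation, signal.shape[1])
        frame_arr = baseline + signal[:, None, :] + rng.normal(0.0, sd, shape)
        data = frame_arr.mean(axis=1)
    else:
        data = baseline + signal + rng.normal(
            0.0, sd / np.sqrt(frames_per_presentation), signal.shape
        )
    return SessionData(
        data=data,
        design=design,
        voxel_indices=idx,
        grid_shape=gt.depth_field.shape,
        voxel_size_mm=spec.voxel_size_mm,
        baseline=baseline,
        frames=frame_arr,
    )
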