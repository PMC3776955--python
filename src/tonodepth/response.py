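"""Per-voxel frequency responses: preprocessing, amplitudes, moments, bootstrap.

Given presentation-level data and the session design, this module produces for
every voxel the response amplitude per stimulus condition (percent signal
relative to the quiet reference), the amplitude-weighted centroid frequency
``f_cent`` and tuning width ``f_tune``, the high-minus-low amplitude
difference, and bootstrap statistics (sound-vs-quiet p value, 68% confidence
interval of the centroid).

Frequency moments are computed in log2-frequency (octaves re 1 kHz): the
stimuli are logarithmically spaced and the gradients of interest are reported
in octaves, so the moment axis is logarithmic by construction.  The centroid
is the amplitude-weighted mean frequency after subtracting the minimum
amplitude (making the weights positive definite); the tuning width is the
square root of the corresponding second central moment so that it, too, is in
octaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import dct, idct

from .phantom import QUIET_CONDITION, SessionData, TissueMask


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling configuration: B resamples with replacement, percentile CI."""

    B: int = 1000
    seed: int = 0
    ci_level: float = 0.68

    def __post_init__(self):
        if self.B < 100:
            raise ValueError("B must be >= 100")
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def ci_percentiles(self) -> tuple[float, float]:
        half = 100.0 * (1.0 - self.ci_level) / 2.0
        return half, 100.0 - half


# ---------------------------------------------------------------------------
# preprocessing of frame-level series


def homomorphic_normalize(series: np.ndarray, smooth_fwhm_mm: float = 10.0,
                          voxel_size_mm: float = 1.2) -> np.ndarray:
    """Percent-signal normalization against a smoothed temporal-mean volume.

    Divides each voxel's time series by the spatially smoothed temporal mean
    (x100), removing slowly varying receive-gain fields while leaving
    temporal modulation intact.  Voxels whose smoothed mean is ~0 are masked
    to NaN.  ``series`` is (nx, ny, nz, t).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4 or series.shape[-1] < 2:
        raise ValueError("series must be 4-D with at least 2 frames")
    mean_vol = series.mean(axis=-1)
    sigma = smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    smooth = ndimage.gaussian_filter(mean_vol, sigma=sigma)
    out = np.full_like(series, np.nan)
    ok = np.abs(smooth) > 1e-9 * np.nanmax(np.abs(smooth))
    out[ok] = 100.0 * series[ok] / smooth[ok, None]
    return out


def highpass(series: np.ndarray, cutoff_cycles_per_run: float,
             stimulus_cycles_per_run: float = 5.0, axis: int = -1) -> np.ndarray:
    """Remove slow drifts below a cutoff (cycles/run) from a run's series.

    A discrete-cosine basis regression (the cosines with fewer than
    ``cutoff`` cycles over the run, plus the constant) is projected out and
    the mean is re-added as 100 by the percent-signal convention.  Refuses a
    cutoff at or above the stimulus frequency, which would destroy the signal
    of interest.
    """
    if cutoff_cycles_per_run >= stimulus_cycles_per_run:
        raise ValueError(
            f"cutoff {cutoff_cycles_per_run} cycles/run would remove the "
            f"stimulus frequency ({stimulus_cycles_per_run} cycles/run)"
        )
    series = np.asarray(series, dtype=float)
    x = np.moveaxis(series, axis, -1)
    n = x.shape[-1]
    coef = dct(x, type=2, norm="ortho", axis=-1)
    # DCT component k spans k/2 cycles over the run
    k = np.arange(n)
    drop = (k > 0) & (k / 2.0 < cutoff_cycles_per_run)
    low = coef.copy()
    low[..., ~drop] = 0.0
    trend = idct(low, type=2, norm="ortho", axis=-1)
    out = x - trend - x.mean(axis=-1, keepdims=True) + 100.0
    return np.moveaxis(out, -1, axis)


def resample_to_mask(data: SessionData, target_mask: TissueMask) -> SessionData:
    """Trilinear resampling of every presentation volume onto another grid.

    This mirrors transforming the functional data into the structural
    reference volume the surface model is built on: the depth analysis then
    samples tissue voxels at the structural resolution.  Neighboring resampled
    voxels share noise; downstream bootstraps resample presentations (not
    voxels), so that correlation is preserved within each resample.
    """
    idx_t = target_mask.voxel_indices()
    centers = (idx_t + 0.5) * target_mask.voxel_size_mm
    coords = (centers / data.voxel_size_mm - 0.5).T  # source index coordinates
    out = np.empty((data.data.shape[0], len(idx_t)))
    vol = np.full(data.grid_shape, float(data.baseline))
    ii = tuple(data.voxel_indices.T)
    for p in range(data.data.shape[0]):
        vol[ii] = data.data[p]
        out[p] = ndimage.map_coordinates(vol, coords, order=1, mode="nearest")
    return SessionData(
        data=out,
        design=data.design,
        voxel_indices=idx_t,
        grid_shape=target_mask.mask.shape,
        voxel_size_mm=target_mask.voxel_size_mm,
        baseline=data.baseline,
    )


# ---------------------------------------------------------------------------
# amplitudes


@dataclass
class ResponseSamples:
    """Quiet-referenced per-presentation amplitudes, grouped by condition.

    ``samples[c, r, v]`` is the amplitude (percent signal re the within-run
    quiet mean) of voxel ``v`` at repeat ``r`` of condition ``c``; the last
    condition row is the quiet presentations themselves.  ``A`` holds the
    mean amplitude per sound condition.
    """

    samples: np.ndarray  # (n_conditions+1, n_reps, n_voxels)
    f_oct: np.ndarray  # (n_conditions,) sound frequencies, octaves re 1 kHz

    @property
    def n_sound_conditions(self) -> int:
        return len(self.f_oct)

    @property
    def sound_samples(self) -> np.ndarray:
        return self.samples[: self.n_sound_conditions]

    @property
    def quiet_samples(self) -> np.ndarray:
        return self.samples[self.n_sound_conditions]

    @property
    def A(self) -> np.ndarray:
        """Mean amplitude per sound condition, (n_conditions, n_voxels)."""
        return self.sound_samples.mean(axis=1)


def extract_amplitudes(data: SessionData | np.ndarray, design=None) -> ResponseSamples:
    """Per-presentation amplitudes referenced to the within-run quiet mean.

    Accepts a :class:`~tonodepth.phantom.SessionData` (or a raw
    (n_presentations, n_voxels) array plus a design) whose rows are
    presentation-level amplitudes; when frame-level data are attached, each
    presentation's amplitude is the mean over its frames.  Every run must
    contain quiet presentations, which act as that run's reference.
    """
    if isinstance(data, SessionData):
        design = data.design
        arr = data.data if data.frames is None else data.frames.mean(axis=1)
    else:
        if design is None:
            raise ValueError("a design is required with raw arrays")
        arr = np.asarray(data, dtype=float)
    seq = design.condition_sequence
    runs = design.run_index
    n_cond = len(design.center_freqs_khz)
    quiet = seq == QUIET_CONDITION
    if not quiet.any():
        raise ValueError("design contains no quiet presentations")
    arr = np.asarray(arr, dtype=float)
    referenced = np.empty_like(arr)
    for r in np.unique(runs):
        in_run = runs == r
        q = in_run & quiet
        if not q.any():
            raise ValueError(f"run {r} has no quiet presentations")
        referenced[in_run] = arr[in_run] - arr[q].mean(axis=0)
    # group by condition; equal repeat counts are guaranteed by the design
    reps = int(quiet.sum())
    n_vox = arr.shape[1]
    samples = np.empty((n_cond + 1, reps, n_vox))
    for c in range(n_cond):
        samples[c] = referenced[seq == c]
    samples[n_cond] = referenced[quiet]
    return ResponseSamples(samples=samples, f_oct=design.f_oct)


# ---------------------------------------------------------------------------
# frequency moments


def centroid_frequency(A: np.ndarray, f_oct: np.ndarray) -> np.ndarray | float:
    """Amplitude-weighted centroid frequency, octaves re 1 kHz.

    Amplitudes are made positive definite by subtracting the per-voxel
    minimum, so the centroid is invariant to additive offsets (and to
    positive scaling).  All-equal amplitudes leave zero weights: the centroid
    is undefined and returned as NaN (flagged, excluded from maps).
    """
    A = np.asarray(A, dtype=float)
    f_oct = np.asarray(f_oct, dtype=float)
    scalar = A.ndim == 1
    A2 = A[:, None] if scalar else A
    w = A2 - A2.min(axis=0, keepdims=True)
    sw = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = (f_oct[:, None] * w).sum(axis=0) / sw
    fc = np.where(sw > 0, fc, np.nan)
    return float(fc[0]) if scalar else fc


def tuning_width(A: np.ndarray, f_oct: np.ndarray) -> np.ndarray | float:
    """Tuning width: square root of the min-subtracted second central moment
    of the amplitude response about the centroid, in octaves."""
    A = np.asarray(A, dtype=float)
    f_oct = np.asarray(f_oct, dtype=float)
    scalar = A.ndim == 1
    A2 = A[:, None] if scalar else A
    w = A2 - A2.min(axis=0, keepdims=True)
    sw = w.sum(axis=0)
    fc = centroid_frequency(A2, f_oct)
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = ((f_oct[:, None] - fc[None, :]) ** 2 * w).sum(axis=0) / sw
    ft = np.sqrt(np.where(sw > 0, m2, np.nan))
    return float(ft[0]) if scalar else ft


# ---------------------------------------------------------------------------
# bootstrap statistics


def bootstrap_distribution(samples: np.ndarray, cfg: BootstrapConfig):
    """B bootstrapped means of a 1-D sample, with the percentile interval.

    Returns ``(means, (lo, hi))`` where the interval covers ``cfg.ci_level``
    (16th/84th percentiles at the default 68%).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    n = len(samples)
    if n < 5:
        raise ValueError("need at least 5 samples to bootstrap")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.B, n))
    means = samples[idx].mean(axis=1)
    lo, hi = np.percentile(means, cfg.ci_percentiles)
    return means, (float(lo), float(hi))


def resample_weights(rng: np.random.Generator, B: int, n: int) -> np.ndarray:
    """(B, n) matrix of bootstrap-resample weights: row b holds the count of
    each of the n samples in resample b, divided by n, so that
    ``W @ samples`` is the vector of resampled means.  Exactly equivalent to
    drawing n indices with replacement and averaging, but BLAS-friendly."""
    idx = rng.integers(0, n, size=(B, n))
    W = np.zeros((B, n))
    np.add.at(W, (np.repeat(np.arange(B), n), idx.ravel()), 1.0 / n)
    return W


def sound_vs_quiet_p(resp_or_sound, quiet=None, cfg: BootstrapConfig = BootstrapConfig()):
    """One-sided bootstrap p for sound responses exceeding quiet.

    ``p`` is the fraction of resamples in which (mean sound - mean quiet)
    <= 0, clamped to at least 1/(B+1).  Accepts either a
    :class:`ResponseSamples` (vectorized over voxels, pooling all sound
    conditions) or two 1-D sample vectors.
    """
    scalar = not isinstance(resp_or_sound, ResponseSamples)
    if scalar:
        sound = np.asarray(resp_or_sound, dtype=float).reshape(-1, 1)
        quiet_s = np.asarray(quiet, dtype=float).reshape(-1, 1)
    else:
        resp = resp_or_sound
        sound = resp.sound_samples.reshape(-1, resp.samples.shape[2])
        quiet_s = resp.quiet_samples
    ns, nq = sound.shape[0], quiet_s.shape[0]
    if ns < 5 or nq < 5:
        raise ValueError("need at least 5 samples to bootstrap")
    rng = np.random.default_rng(cfg.seed)
    mean_s = resample_weights(rng, cfg.B, ns) @ sound
    mean_q = resample_weights(rng, cfg.B, nq) @ quiet_s
    counts = ((mean_s - mean_q) <= 0).sum(axis=0)
    p = np.maximum(counts / cfg.B, 1.0 / (cfg.B + 1))
    return float(p[0]) if scalar else p


def bootstrap_amplitudes(resp: ResponseSamples, cfg: BootstrapConfig) -> np.ndarray:
    """Resampled condition means, shape (B, n_conditions, n_voxels).

    Presentations are resampled with replacement within each condition; the
    same presentation indices are used for every voxel in a given resample,
    preserving the spatial covariance of each resampled map (each resample is
    a re-weighted session, as in session-level resampling).
    """
    rng = np.random.default_rng(cfg.seed)
    n_cond, n_reps, n_vox = resp.sound_samples.shape
    out = np.empty((cfg.B, n_cond, n_vox))
    for c in range(n_cond):
        out[:, c, :] = resample_weights(rng, cfg.B, n_reps) @ resp.sound_samples[c]
    return out


def centroid_ci(resp: ResponseSamples, cfg: BootstrapConfig, chunk: int = 2048):
    """Bootstrap 68% interval of the centroid frequency per voxel.

    The centroid (including its min-subtraction) is recomputed inside every
    resample; the same presentation resampling is shared by all voxels.
    Returns ``(lo, hi)`` arrays in octaves.  Voxels are processed in chunks
    to bound memory at large voxel counts.
    """
    rng = np.random.default_rng(cfg.seed)
    n_cond, n_reps, n_vox = resp.sound_samples.shape
    W = np.stack([resample_weights(rng, cfg.B, n_reps) for _ in range(n_cond)])
    lo = np.empty(n_vox)
    hi = np.empty(n_vox)
    for start in range(0, n_vox, chunk):
        sl = slice(start, min(start + chunk, n_vox))
        A_b = np.einsum("cbr,crv->bcv", W, resp.sound_samples[:, :, sl])
        w = A_b - A_b.min(axis=1, keepdims=True)
        sw = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fc = (resp.f_oct[None, :, None] * w).sum(axis=1) / sw
        lo[sl], hi[sl] = np.nanpercentile(fc, cfg.ci_percentiles, axis=0)
    return lo, hi


@dataclass
class FrequencyMaps:
    """Per-voxel frequency-response summaries (flat arrays over mask voxels)."""

    f_cent: np.ndarray  # centroid, octaves re 1 kHz
    f_tune: np.ndarray  # tuning width, octaves
    hl_diff: np.ndarray  # A(f_hi) - A(f_lo), percent signal
    p_sound: np.ndarray  # one-sided bootstrap p, sound > quiet
    ci68_lo: np.ndarray
    ci68_hi: np.ndarray
    f_oct: np.ndarray

    @property
    def ci68_width(self) -> np.ndarray:
        return self.ci68_hi - self.ci68_lo


def compute_frequency_maps(
    resp: ResponseSamples, cfg: BootstrapConfig, ci: bool = True
) -> FrequencyMaps:
    """All per-voxel maps in one pass: moments from the full-data amplitudes,
    bootstrap p and (optionally) the centroid CI from B resamples."""
    A = resp.A
    f_cent = centroid_frequency(A, resp.f_oct)
    f_tune = tuning_width(A, resp.f_oct)
    hl = A[-1] - A[0]
    p = sound_vs_quiet_p(resp, cfg=cfg)
    if ci:
        lo, hi = centroid_ci(resp, cfg)
    else:
        lo = np.full(A.shape[1], np.nan)
        hi = np.full(A.shape[1], np.nan)
    return FrequencyMaps(
        f_cent=f_cent, f_tune=f_tune, hl_diff=hl, p_sound=np.asarray(p),
        ci68_lo=lo, ci68_hi=hi, f_oct=resp.f_oct,
    )
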