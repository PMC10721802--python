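"""Voxel-level rs-fMRI metrics and temporal preprocessing.

Implements the three voxel-based connectivity/activity summaries used as
feature sources for MCI-vs-control classification:

* **fALFF** — fractional amplitude of low-frequency fluctuations: the share of
  a voxel's Fourier amplitude that falls inside the low-frequency band
  (default 0.008–0.09 Hz) relative to the whole positive-frequency spectrum.
* **LCOR** — local correlation: a Gaussian-distance-weighted average Pearson
  correlation of a voxel with its in-mask neighbours (kernel parameter 25 mm).
* **ICC** — intrinsic connectivity: a per-voxel summary of connectivity to all
  other in-mask voxels, either mean squared correlation ("power" variant) or
  the fraction of voxels correlated above a threshold ("degree" variant).

Temporal preprocessing mirrors a standard denoising stream: linear-detrend +
hard FFT band-pass, and ordinary-least-squares removal of nuisance regressors
(white matter / CSF means, motion proxies) with an implicit intercept.

fALFF is computed on confound-regressed but *unfiltered* series — the metric
is degenerate (≈ 1 everywhere) on band-limited data — while LCOR and ICC
expect filtered + regressed input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

logger = logging.getLogger("mcifmri")

MIN_TIMEPOINTS = 64

__all__ = [
    "Band",
    "BoldSeries",
    "VoxelMap",
    "bandpass_filter",
    "regress_confounds",
    "compute_falff",
    "compute_lcor",
    "compute_icc",
    "load_bold_nifti",
    "save_voxel_map",
    "load_confounds_tsv",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """Frequency band in Hz; default is the canonical low-frequency window."""

    low_hz: float = 0.008
    high_hz: float = 0.09

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band: need 0 <= low < high, got ({self.low_hz}, {self.high_hz})"
            )

    def validate_for(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if self.high_hz > nyquist + 1e-12:
            raise ValueError(
                f"band high edge {self.high_hz} Hz exceeds Nyquist {nyquist:.4f} Hz "
                f"for TR = {tr_seconds} s"
            )


@dataclass
class BoldSeries:
    """One subject's 4D BOLD signal: voxel grid x time, plus geometry."""

    data: np.ndarray  # (nx, ny, nz, T)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 2.0
    brain_mask: np.ndarray | None = None  # (nx, ny, nz) bool; None = all voxels

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x, y, z, t); got {self.data.ndim}D")
        if self.n_timepoints < MIN_TIMEPOINTS:
            raise ValueError(
                f"need at least {MIN_TIMEPOINTS} time points, got {self.n_timepoints}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError("brain_mask shape must match the voxel grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass
class VoxelMap:
    """One scalar per voxel inside the brain mask (fALFF, LCOR or ICC)."""

    values: np.ndarray  # (nx, ny, nz); zero outside mask
    metric: str  # "fALFF" | "LCOR" | "ICC"
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    _RANGES = {"fALFF": (0.0, 1.0), "LCOR": (-1.0, 1.0), "ICC": (0.0, 1.0)}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        inside = self.values[self.mask]
        if not np.all(np.isfinite(inside)):
            raise ValueError(f"{self.metric} map contains non-finite in-mask values")
        lo, hi = self._RANGES.get(self.metric, (-np.inf, np.inf))
        # tolerate float round-off at the range edges, then clip
        if inside.size and (inside.min() < lo - 1e-9 or inside.max() > hi + 1e-9):
            raise ValueError(
                f"{self.metric} values outside [{lo}, {hi}]: "
                f"range ({inside.min():.6g}, {inside.max():.6g})"
            )
        np.clip(self.values, lo, hi, out=self.values)
        self.values[~self.mask] = 0.0


# ---------------------------------------------------------------------------
# temporal preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(series: BoldSeries, band: Band = Band()) -> BoldSeries:
    """Hard FFT-domain band-pass after linear detrend; output is zero-mean.

    Frequency bins with ``low_hz <= f <= high_hz`` are retained, everything
    else (including DC) is zeroed, so in-band sinusoids pass essentially
    unattenuated and out-of-band components are removed.
    """
    band.validate_for(series.tr_seconds)
    t = series.n_timepoints
    detrended = _signal.detrend(series.data, axis=-1, type="linear")
    spec = np.fft.rfft(detrended, axis=-1)
    freqs = np.fft.rfftfreq(t, d=series.tr_seconds)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spec[..., ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=t, axis=-1)
    return replace(series, data=filtered)


def _as_design(confounds: np.ndarray | pd.DataFrame, t: int) -> tuple[np.ndarray, list[str]]:
    if isinstance(confounds, pd.DataFrame):
        names = [str(c) for c in confounds.columns]
        mat = confounds.to_numpy(dtype=np.float64)
    else:
        mat = np.asarray(confounds, dtype=np.float64)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"confound_{j}" for j in range(mat.shape[1])]
    if mat.shape[0] != t:
        raise ValueError(
            f"confound matrix has {mat.shape[0]} rows but the series has {t} time points"
        )
    design = np.column_stack([np.ones(t), mat])
    return design, ["intercept"] + names


def regress_confounds(series: BoldSeries, confounds: np.ndarray | pd.DataFrame) -> BoldSeries:
    """OLS residuals of every voxel's series on the confounds plus intercept."""
    design, names = _as_design(confounds, series.n_timepoints)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal does not reduce the rank: those are
        # the redundant (collinear) ones worth naming in the error
        redundant = [
            names[j]
            for j in range(design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(
            f"confound design is rank-deficient (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {redundant}"
        )
    flat = series.data.reshape(-1, series.n_timepoints).T  # (T, V)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    return replace(series, data=resid.T.reshape(series.data.shape))


# ---------------------------------------------------------------------------
# fALFF
# ---------------------------------------------------------------------------

def compute_falff(series: BoldSeries, band: Band = Band()) -> VoxelMap:
    """Fractional amplitude of low-frequency fluctuations per voxel.

    fALFF(v) = sum of |FFT| amplitude over in-band positive frequencies /
    sum over *all* positive frequencies (DC excluded). A zero-variance voxel
    gets 0 by convention (logged).
    """
    band.validate_for(series.tr_seconds)
    t = series.n_timepoints
    demeaned = series.data - series.data.mean(axis=-1, keepdims=True)
    amp = np.abs(np.fft.rfft(demeaned, axis=-1))
    freqs = np.fft.rfftfreq(t, d=series.tr_seconds)
    positive = freqs > 0
    in_band = positive & (freqs >= band.low_hz) & (freqs <= band.high_hz)
    num = amp[..., in_band].sum(axis=-1)
    den = amp[..., positive].sum(axis=-1)
    flat_voxels = den <= 0
    n_flat = int(np.count_nonzero(flat_voxels & series.brain_mask))
    if n_flat:
        logger.warning("fALFF: %d zero-variance in-mask voxel(s) set to 0", n_flat)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(flat_voxels, 0.0, num / np.where(flat_voxels, 1.0, den))
    return VoxelMap(
        values=values,
        metric="fALFF",
        mask=series.brain_mask,
        provenance={"band": (band.low_hz, band.high_hz), "tr_seconds": series.tr_seconds},
    )


# ---------------------------------------------------------------------------
# correlation-based metrics
# ---------------------------------------------------------------------------

def _standardize_time(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score along time; zero-variance voxels become all-zero (r := 0)."""
    mean = data.mean(axis=-1, keepdims=True)
    centred = data - mean
    sd = centred.std(axis=-1, keepdims=True)
    flat = sd[..., 0] <= 0
    sd = np.where(sd <= 0, 1.0, sd)
    z = centred / sd
    z[flat] = 0.0
    return z, flat


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def compute_lcor(
    series: BoldSeries,
    kernel_fwhm_mm: float = 25.0,
    kernel_is_sigma: bool = False,
    truncate_factor: float = 2.0,
) -> VoxelMap:
    """Local correlation: Gaussian-weighted mean correlation with neighbours.

    For voxel v, ``LCOR(v) = sum_u w(v,u) r(v,u) / sum_u w(v,u)`` over in-mask
    neighbours ``u != v`` within ``truncate_factor * kernel`` millimetres,
    where w is an isotropic Gaussian of the given FWHM (or sigma when
    ``kernel_is_sigma``) and r is the Pearson correlation of the time series.
    """
    vs = np.asarray(series.voxel_size_mm, dtype=float)
    if kernel_fwhm_mm <= vs.max():
        raise ValueError(
            f"kernel ({kernel_fwhm_mm} mm) must exceed the largest voxel dimension ({vs.max()} mm)"
        )
    sigma = kernel_fwhm_mm if kernel_is_sigma else _fwhm_to_sigma(kernel_fwhm_mm)
    radius_mm = truncate_factor * kernel_fwhm_mm

    z, flat = _standardize_time(series.data)
    n_flat = int(np.count_nonzero(flat & series.brain_mask))
    if n_flat:
        logger.warning("LCOR: %d zero-variance in-mask voxel(s); their correlations := 0", n_flat)
    t = series.n_timepoints
    mask = series.brain_mask.astype(np.float64)
    zm = z * mask[..., None]  # out-of-mask voxels contribute nothing

    shape = series.grid_shape
    max_off = [min(int(radius_mm // vs[a]), shape[a] - 1) for a in range(3)]

    num = np.zeros(shape)
    den = np.zeros(shape)
    for dx in range(-max_off[0], max_off[0] + 1):
        for dy in range(-max_off[1], max_off[1] + 1):
            for dz in range(-max_off[2], max_off[2] + 1):
                if dx == dy == dz == 0:
                    continue
                dist = math.sqrt((dx * vs[0]) ** 2 + (dy * vs[1]) ** 2 + (dz * vs[2]) ** 2)
                if dist > radius_mm:
                    continue
                w = math.exp(-0.5 * (dist / sigma) ** 2)
                shifted = _shift3d(zm, (dx, dy, dz))
                shifted_mask = _shift3d_mask(mask, (dx, dy, dz))
                r = np.einsum("xyzt,xyzt->xyz", zm, shifted) / t
                num += w * r
                den += w * shifted_mask
    if np.any((den <= 0) & series.brain_mask):
        raise ValueError("LCOR: some in-mask voxel has no in-mask neighbour inside the kernel radius")
    values = np.zeros(shape)
    inm = series.brain_mask
    values[inm] = num[inm] / den[inm]
    return VoxelMap(
        values=values,
        metric="LCOR",
        mask=series.brain_mask,
        provenance={
            "kernel_mm": kernel_fwhm_mm,
            "kernel_is_sigma": kernel_is_sigma,
            "truncate_factor": truncate_factor,
        },
    )


def _shift3d(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift a (x, y, z[, t]) array by an integer voxel offset, zero-padding."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for axis, off in enumerate(offset):
        n = arr.shape[axis]
        if off >= 0:
            src[axis] = slice(off, n)
            dst[axis] = slice(0, n - off)
        else:
            src[axis] = slice(0, n + off)
            dst[axis] = slice(-off, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shift3d_mask(mask: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    return _shift3d(mask, offset)


def compute_icc(
    series: BoldSeries,
    variant: str = "power",
    degree_threshold: float = 0.25,
    block_size: int = 2048,
) -> VoxelMap:
    """Intrinsic connectivity of every voxel to all other in-mask voxels.

    ``power`` (default): mean over u != v of r(v, u)^2, in [0, 1].
    ``degree``: fraction of other in-mask voxels with r(v, u) > threshold.
    Computed blockwise so memory stays bounded by ``block_size`` voxel rows.
    """
    if variant not in ("power", "degree"):
        raise ValueError(f"unknown ICC variant {variant!r}")
    coords = np.argwhere(series.brain_mask)
    v_count = coords.shape[0]
    if v_count < 2:
        raise ValueError("ICC needs at least 2 in-mask voxels")
    z, flat = _standardize_time(series.data)
    n_flat = int(np.count_nonzero(flat & series.brain_mask))
    if n_flat:
        logger.warning("ICC: %d zero-variance in-mask voxel(s); their correlations := 0", n_flat)
    zmat = z[series.brain_mask]  # (V, T)
    t = series.n_timepoints
    self_ok = ~flat[series.brain_mask]  # voxels whose self-correlation is 1

    out = np.empty(v_count)
    for start in range(0, v_count, block_size):
        stop = min(start + block_size, v_count)
        corr = zmat[start:stop] @ zmat.T / t  # (b, V)
        if variant == "power":
            total = np.einsum("bv,bv->b", corr, corr)
            total -= self_ok[start:stop].astype(float)  # remove r(v,v)^2
            out[start:stop] = np.clip(total / (v_count - 1), 0.0, 1.0)
        else:
            count = (corr > degree_threshold).sum(axis=1)
            count -= (self_ok[start:stop] & (1.0 > degree_threshold)).astype(int)
            out[start:stop] = count / (v_count - 1)

    values = np.zeros(series.grid_shape)
    values[series.brain_mask] = out
    return VoxelMap(
        values=values,
        metric="ICC",
        mask=series.brain_mask,
        provenance={"variant": variant, "degree_threshold": degree_threshold},
    )


# ---------------------------------------------------------------------------
# I/O helpers (NIfTI via nibabel, confounds as TSV)
# ---------------------------------------------------------------------------

def load_bold_nifti(path, brain_mask_path=None, tr_seconds: float | None = None) -> BoldSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    if tr_seconds is None:
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    mask = None
    if brain_mask_path is not None:
        mask = np.asarray(nib.load(str(brain_mask_path)).dataobj) > 0
    return BoldSeries(
        data=data,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        tr_seconds=tr_seconds,
        brain_mask=mask,
    )


def save_voxel_map(vmap: VoxelMap, path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vmap.values.astype(np.float32), affine), str(path))


def load_confounds_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
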