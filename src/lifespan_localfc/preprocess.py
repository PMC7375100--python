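"""Subject-level temporal preprocessing and motion quality control.

Implements the per-subject steps applied to a 4D resting-state run before any
local-connectivity statistic is computed: dropping of initial volumes,
construction and regression of nuisance signals (motion, motion derivatives,
linear trend, tissue means, optionally the global mean), zero-phase band-pass
filtering, Gaussian smoothing of statistic maps, and framewise-displacement
based motion QC (Power et al. convention, 50 mm head radius).

The canonical pipeline order is fixed:

    drop -> nuisance regression -> bandpass (lFCD branch only)
         -> statistic -> normalize -> smooth

The FOCA branch omits the band-pass step; its nuisance recipe also omits the
global-mean regressor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import nibabel as nib
import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .localfc import LocalFCMap

__all__ = [
    "VolumeSeries",
    "MotionTrace",
    "NuisanceSet",
    "drop_initial_volumes",
    "mean_fd",
    "exclude_by_fd",
    "build_nuisance",
    "regress_nuisance",
    "bandpass",
    "smooth",
    "detrend_keep_mean",
    "DEFAULT_HEAD_RADIUS_MM",
]

DEFAULT_HEAD_RADIUS_MM = 50.0


class EmptySeriesError(ValueError):
    """Raised when an operation would leave fewer timepoints than it needs."""


class InvalidBandError(ValueError):
    """Raised for a band-pass specification outside (0, Nyquist)."""


@dataclass
class VolumeSeries:
    """One subject's 4D signal grid with spatial metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, t)
        Voxel time series.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (NIfTI convention, mm).
    tr : float
        Repetition time in seconds.
    mask : ndarray of bool, shape (nx, ny, nz)
        Brain mask; operations treat out-of-mask voxels as absent.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        # float32 input is kept as-is (the pipeline's speed dtype);
        # everything else is promoted to float64
        self.data = np.asarray(self.data)
        if self.data.dtype != np.float32:
            self.data = self.data.astype(np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x,y,z,t), got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} != spatial shape {self.data.shape[:3]}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each spatial axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_sizes, self.tr))
        return img

    @classmethod
    def from_nifti(cls, path, mask, tr: float | None = None) -> "VolumeSeries":
        img = nib.load(str(path))
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        if isinstance(mask, (str,)) or hasattr(mask, "__fspath__"):
            mask = np.asarray(nib.load(str(mask)).get_fdata()) > 0.5
        return cls(np.asarray(img.get_fdata()), img.affine, tr, mask)


@dataclass
class MotionTrace:
    """Rigid-body motion parameters per timepoint.

    ``params`` is a (t, 6) array: 3 translations in mm then 3 rotations in
    radians (SPM rp_*.txt column order).
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"params must be (t, 6), got {self.params.shape}")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]

    def to_file(self, path) -> None:
        np.savetxt(path, self.params, fmt="%.10e")

    @classmethod
    def from_file(cls, path) -> "MotionTrace":
        return cls(np.loadtxt(path, ndmin=2))


@dataclass
class NuisanceSet:
    """Named nuisance regressors, one column per signal (no intercept)."""

    regressors: np.ndarray  # (t, k)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=np.float64)
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be 2D (t, k)")
        if len(self.labels) != self.regressors.shape[1]:
            raise ValueError("one label per column required")


def drop_initial_volumes(
    v: VolumeSeries, m: MotionTrace, n_drop: int
) -> tuple[VolumeSeries, MotionTrace]:
    """Remove the first ``n_drop`` frames from data and motion consistently.

    The leading frames of an EPI run are discarded to avoid T1 saturation;
    the default pipeline drops 5 of the 261 acquired volumes.
    """
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= v.n_timepoints:
        raise EmptySeriesError(
            f"dropping {n_drop} of {v.n_timepoints} volumes leaves an empty series"
        )
    if m.n_timepoints != v.n_timepoints:
        raise ValueError("motion trace length does not match data")
    return (
        replace(v, data=v.data[..., n_drop:]),
        MotionTrace(m.params[n_drop:]),
    )


def framewise_displacement(
    m: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-frame FD (mm): sum of absolute parameter changes, rotations
    converted to arc length on a sphere of ``head_radius`` mm."""
    if m.n_timepoints < 2:
        raise EmptySeriesError("FD undefined for fewer than 2 timepoints")
    d = np.diff(m.params, axis=0)
    d[:, 3:] *= head_radius
    return np.abs(d).sum(axis=1)


def mean_fd(m: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> float:
    """Mean framewise displacement of a run, the motion-QC scalar."""
    return float(framewise_displacement(m, head_radius).mean())


def exclude_by_fd(cohort, fd_column: str = "mean_fd", n_sd: float = 2.0):
    """Flag high-motion subjects: mean FD two or more group SDs above the mean.

    Returns a copy of the cohort table with an ``included`` boolean column.
    Group mean and SD (sample SD, ddof=1) are computed over *all* subjects
    before any exclusion. In the degenerate zero-variance group nobody is
    excluded: the rule targets outliers and such a group has none.
    """
    cohort = cohort.copy()
    if len(cohort) == 0:
        cohort["included"] = np.array([], dtype=bool)
        return cohort
    fd = np.asarray(cohort[fd_column], dtype=float)
    if np.any(np.isnan(fd)):
        raise ValueError("mean FD must be filled for all subjects")
    sd = fd.std(ddof=1) if len(fd) > 1 else 0.0
    if sd > 0:
        cohort["included"] = fd < fd.mean() + n_sd * sd
    else:
        cohort["included"] = np.ones(len(fd), dtype=bool)
    return cohort


def _linear_trend(t: int) -> np.ndarray:
    # unit-range ramp; scaling is irrelevant to the projection
    return np.linspace(-0.5, 0.5, t)


def build_nuisance(
    v: VolumeSeries,
    m: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    recipe: str,
) -> NuisanceSet:
    """Assemble the nuisance design for one statistic branch.

    recipe ``"lfcd"``: 12 motion parameters (6 + backward-difference
    derivatives with a leading zero row), linear trend, global mean, white
    matter mean, CSF mean (16 columns). recipe ``"foca"``: the same without
    the global mean (15 columns). Constant-zero columns (e.g. a motionless
    trace) are flagged with a warning and dropped; the regression always adds
    its own intercept.
    """
    if recipe not in ("lfcd", "foca"):
        raise ValueError(f"unknown nuisance recipe {recipe!r}")
    t = v.n_timepoints
    if m.n_timepoints != t:
        raise ValueError("motion trace length does not match data")

    cols: list[np.ndarray] = []
    labels: list[str] = []
    motion_names = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    for j, name in enumerate(motion_names):
        cols.append(m.params[:, j])
        labels.append(name)
    deriv = np.vstack([np.zeros((1, 6)), np.diff(m.params, axis=0)])
    for j, name in enumerate(motion_names):
        cols.append(deriv[:, j])
        labels.append(name + "_deriv")
    cols.append(_linear_trend(t))
    labels.append("linear_trend")
    if recipe == "lfcd":
        cols.append(v.data[v.mask].mean(axis=0))
        labels.append("global_mean")
    wm_mask = np.asarray(wm_mask, dtype=bool)
    csf_mask = np.asarray(csf_mask, dtype=bool)
    for tissue_mask, name in ((wm_mask, "wm_mean"), (csf_mask, "csf_mean")):
        if not tissue_mask.any():
            raise ValueError(f"{name} tissue mask is empty")
        cols.append(v.data[tissue_mask].mean(axis=0))
        labels.append(name)

    X = np.column_stack(cols)
    zero = np.all(X == 0, axis=0)
    if zero.any():
        dropped = [labels[j] for j in np.flatnonzero(zero)]
        warnings.warn(f"dropping constant-zero nuisance columns: {dropped}")
        X = X[:, ~zero]
        labels = [lab for lab, z in zip(labels, zero) if not z]
    return NuisanceSet(X, labels)


def regress_nuisance(v: VolumeSeries, n: NuisanceSet) -> VolumeSeries:
    """Residualize every in-mask voxel on [intercept | nuisance regressors].

    Rank-deficient designs are handled by dropping collinear columns (with a
    warning); out-of-mask voxels are zeroed.
    """
    t = v.n_timepoints
    if n.regressors.shape[0] != t:
        raise ValueError("regressor rows must match timepoints")
    X = np.column_stack([np.ones(t), n.regressors])
    names = ["intercept", *n.labels]

    # drop collinear columns greedily, keeping the earliest independent set
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"rank-deficient nuisance design; dropping {dropped}")
        X = X[:, keep]

    Y = v.data[v.mask]  # (n_vox, t)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    out = np.zeros_like(v.data)
    out[v.mask] = resid.T
    return replace(v, data=out)


def bandpass(v: VolumeSeries, low: float, high: float) -> VolumeSeries:
    """Zero-phase band-pass via a hard frequency-domain mask.

    Retains Fourier components with ``low <= f <= high`` (Hz); the DC
    component is always removed, so a constant series maps to zero. The
    default band for the lFCD branch is 0.01-0.08 Hz.
    """
    nyquist = 1.0 / (2.0 * v.tr)
    if not (0 <= low < high):
        raise InvalidBandError(f"need 0 <= low < high, got ({low}, {high})")
    if high >= nyquist:
        raise InvalidBandError(f"high={high} Hz >= Nyquist {nyquist:.4f} Hz")
    t = v.n_timepoints
    freqs = np.fft.rfftfreq(t, d=v.tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False
    spec = np.fft.rfft(v.data, axis=-1)
    spec[..., ~keep] = 0
    out = np.fft.irfft(spec, n=t, axis=-1)
    out[~v.mask] = 0.0
    return replace(v, data=out)


def detrend_keep_mean(v: VolumeSeries) -> VolumeSeries:
    """Remove the per-voxel linear trend but restore the temporal mean.

    Used for the tSNR gate, which needs the signal mean that full nuisance
    residualization would destroy.
    """
    t = v.n_timepoints
    X = np.column_stack([np.ones(t), _linear_trend(t)])
    Y = v.data[v.mask].T  # (t, n_vox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = np.zeros_like(v.data)
    out[v.mask] = (resid + Y.mean(axis=0)).T
    return replace(v, data=out)


def smooth(m: "LocalFCMap", fwhm: float) -> "LocalFCMap":
    """Gaussian-smooth a statistic map within its mask.

    ``fwhm`` is in mm and converted per-axis to voxel units via the affine
    (sigma = FWHM / (2 sqrt(2 ln 2))). Convolution is mask-renormalized:
    the masked image and the mask are smoothed separately and divided, so a
    constant in-mask image stays constant and edges are not dimmed.
    """
    from scipy.ndimage import gaussian_filter

    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return replace(m, smoothed_fwhm=0.0)
    voxel_sizes = np.sqrt((np.asarray(m.affine)[:3, :3] ** 2).sum(axis=0))
    sigma_vox = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_sizes
    masked = np.where(m.mask, m.values, 0.0)
    num = gaussian_filter(masked, sigma=sigma_vox, mode="constant", cval=0.0)
    den = gaussian_filter(m.mask.astype(float), sigma=sigma_vox, mode="constant", cval=0.0)
    out = np.zeros_like(masked)
    inside = m.mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return replace(m, values=out, smoothed_fwhm=float(fwhm))
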