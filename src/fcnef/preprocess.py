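"""Nuisance construction, motion QC, denoising, filtering, and smoothing.

These steps are shared by the online per-trial pipeline and the offline
resting-state pipeline; the two differ only in (a) how high-motion volumes
are handled (spike regressors online, frame removal offline) and (b) the
Butterworth pass band (0.008-0.3 Hz online, 0.008-0.1 Hz offline).

Conventions fixed here:

* framewise displacement follows Power's formula: the sum of absolute
  backward differences of the three translations plus the head radius
  (50 mm by default) times the sum of absolute rotation differences;
* nuisance regressors are the six motion parameters plus mean signals of
  the whole brain, CSF and grey matter, plus backward-difference
  derivatives of all of them (first element 0), plus one unit indicator
  column per high-motion volume when spike regressors are requested;
* band-pass filtering uses a second-order Butterworth filter applied
  forward and backward (zero phase);
* nuisance regression always includes an intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import InputError, ParameterError
from .io_config import MotionParams, VolumeSeries

__all__ = [
    "NuisanceSet",
    "compute_fd",
    "build_nuisance",
    "regress_out",
    "bandpass",
    "scrub",
    "gaussian_smooth",
]

#: Order in which tissue-mean regressors are assembled.
TISSUE_ORDER = ("global", "csf", "gm")

MOTION_LABELS = ("mot_tx", "mot_ty", "mot_tz", "mot_rx", "mot_ry", "mot_rz")


@dataclass
class NuisanceSet:
    """A time x regressor design matrix with per-column labels."""

    design: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        if self.design.ndim != 2:
            raise InputError("nuisance design must be 2D (time x regressor)")
        if self.design.shape[1] != len(self.labels):
            raise InputError("one label per design column required")

    @property
    def n_volumes(self) -> int:
        return self.design.shape[0]


def _motion_array(motion) -> np.ndarray:
    if isinstance(motion, MotionParams):
        return motion.values
    arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise InputError(f"motion must be (n, 6), got {arr.shape}")
    return arr


def compute_fd(motion, head_radius_mm: float = 50.0) -> np.ndarray:
    """Per-volume framewise displacement in mm (Power's formula).

    ``FD[0] = 0``; for t > 0,
    ``FD[t] = sum |d translation| + head_radius * sum |d rotation|``.
    Rotations must be in radians so the head radius converts them to arc
    length on a sphere of the given radius.
    """
    arr = _motion_array(motion)
    if arr.shape[0] < 1:
        raise InputError("motion must have at least one row")
    if not np.isfinite(arr).all():
        raise InputError("motion parameters contain non-finite values")
    if head_radius_mm <= 0:
        raise ParameterError("head_radius_mm must be positive")
    diffs = np.abs(np.diff(arr, axis=0))
    fd = np.zeros(arr.shape[0])
    fd[1:] = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return fd


def _backward_difference(x: np.ndarray) -> np.ndarray:
    d = np.zeros_like(x)
    d[1:] = x[1:] - x[:-1]
    return d


def build_nuisance(motion, tissue_means: dict[str, np.ndarray] | None = None,
                   include_derivatives: bool = True,
                   spike_volumes=()) -> NuisanceSet:
    """Assemble the nuisance design matrix.

    Parameters
    ----------
    motion : MotionParams or (n, 6) array
    tissue_means : mapping with keys among {"global", "csf", "gm"}
        Mean tissue signals; omitted keys simply produce fewer columns.
    include_derivatives : bool
        Append backward-difference derivatives of every base column.
    spike_volumes : iterable of int
        Volume indices that receive a unit indicator column each (the
        online handling of high-motion frames).
    """
    arr = _motion_array(motion)
    n = arr.shape[0]
    cols = [arr]
    labels = list(MOTION_LABELS)
    tissue_means = tissue_means or {}
    unknown = set(tissue_means) - set(TISSUE_ORDER)
    if unknown:
        raise InputError(f"unknown tissue keys: {sorted(unknown)}")
    for key in TISSUE_ORDER:
        if key in tissue_means:
            series = np.asarray(tissue_means[key], dtype=float).reshape(-1)
            if series.shape[0] != n:
                raise InputError(
                    f"tissue series '{key}' length {series.shape[0]} != {n}"
                )
            cols.append(series[:, None])
            labels.append(f"tissue_{key}")
    base = np.hstack(cols)
    if include_derivatives:
        base = np.hstack([base, _backward_difference(base)])
        labels = labels + [f"d_{lab}" for lab in labels]
    spike_volumes = sorted(int(v) for v in spike_volumes)
    for v in spike_volumes:
        if not 0 <= v < n:
            raise InputError(f"spike volume {v} outside series of length {n}")
        col = np.zeros((n, 1))
        col[v, 0] = 1.0
        base = np.hstack([base, col])
        labels.append(f"spike_{v}")
    # drop constant-zero columns (e.g. zero motion) so regression stays sane
    keep = ~np.all(base == 0, axis=0)
    return NuisanceSet(design=base[:, keep],
                       labels=tuple(l for l, k in zip(labels, keep) if k))


def regress_out(signal_ts: np.ndarray, nuisance) -> np.ndarray:
    """Residualize a signal against the nuisance design (plus intercept).

    ``signal_ts`` may be 1D (time,) or 2D (time, channels).  Exact
    duplicate columns are dropped before fitting; if the design is still
    rank-deficient a warning is raised and a pseudo-inverse fit is used.
    The residual is orthogonal to every retained regressor.
    """
    y = np.asarray(signal_ts, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    X = nuisance.design if isinstance(nuisance, NuisanceSet) else np.asarray(
        nuisance, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError(
            f"design rows {X.shape} must match signal length {y.shape[0]}"
        )
    X = np.hstack([np.ones((y.shape[0], 1)), X])
    # drop exact duplicate columns
    _, unique_idx = np.unique(X.round(12), axis=1, return_index=True)
    X = X[:, np.sort(unique_idx)]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "rank-deficient nuisance design; using pseudo-inverse fit",
            RuntimeWarning, stacklevel=2,
        )
        beta = np.linalg.pinv(X) @ y
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid[:, 0] if squeeze else resid


def bandpass(signal_ts: np.ndarray, tr_seconds: float, low_hz: float,
             high_hz: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (axis 0).

    The filter is applied forward and backward (``filtfilt``), which
    squares the magnitude response and cancels phase distortion; the DC
    component is rejected by the high-pass edge.
    """
    if tr_seconds <= 0:
        raise ParameterError("tr_seconds must be positive")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 < low_hz < high_hz < nyquist):
        raise ParameterError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyquist})"
        )
    y = np.asarray(signal_ts, dtype=float)
    b, a = signal.butter(order, [low_hz, high_hz], btype="band",
                         fs=1.0 / tr_seconds)
    try:
        return signal.filtfilt(b, a, y, axis=0)
    except ValueError as exc:
        raise InputError(f"series too short to band-pass filter: {exc}") from exc


def scrub(series: np.ndarray, fd: np.ndarray, threshold_mm: float
          ) -> tuple[np.ndarray, np.ndarray]:
    """Remove frames whose FD exceeds the threshold (offline handling).

    Returns the censored series and the kept frame indices, in original
    order.  Raises if no frame survives.
    """
    y = np.asarray(series, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if fd.shape[0] != y.shape[0]:
        raise InputError("FD length must match series length")
    kept = np.flatnonzero(fd <= threshold_mm)
    if kept.size == 0:
        raise InputError("scrubbing removed every frame; no data survives")
    return y[kept], kept


def gaussian_smooth(volume_series, fwhm_mm: float,
                    voxel_size_mm=None):
    """Per-volume 3D Gaussian spatial smoothing.

    ``sigma = FWHM / (2 sqrt(2 ln 2)) / voxel_size`` per axis; reflective
    boundaries preserve the total image sum to within a fraction of a
    percent.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ParameterError("fwhm_mm must be >= 0")
    if isinstance(volume_series, VolumeSeries):
        data = volume_series.data
        voxel = volume_series.voxel_size_mm
    else:
        data = np.asarray(volume_series, dtype=float)
        if voxel_size_mm is None:
            raise ParameterError("voxel_size_mm required for raw arrays")
        voxel = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    if data.ndim != 4:
        raise InputError("expected a 4D (x, y, z, t) array")
    if fwhm_mm == 0:
        out = data.copy()
    else:
        sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel
        out = np.empty_like(data)
        for t in range(data.shape[3]):
            out[..., t] = ndimage.gaussian_filter(
                data[..., t], sigma=sigma_vox, mode="reflect")
    if isinstance(volume_series, VolumeSeries):
        return VolumeSeries(out, volume_series.affine,
                            volume_series.tr_seconds,
                            volume_series.n_discarded_leading)
    return out
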