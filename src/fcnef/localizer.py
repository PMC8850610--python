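"""Block-design GLM localizer: t-contrasts, masked peak, sphere ROIs.

The localizer identifies, for each participant, the voxel where executive
control (2-back > rest) or default-mode (rest > 1-back + 2-back) activity
peaks inside an anatomical mask, and builds an 8 mm sphere ROI around that
peak.  The 3-back condition is excluded from contrasts because it is too
noisy when participants cannot keep up with the task.

Implementation choices (the published protocol leaves these open):

* condition regressors are boxcars convolved with the canonical
  double-gamma HRF (nilearn's Glover model);
* family-wise-error control is Bonferroni over in-mask voxels;
* suprathreshold clusters use 18-neighbour connectivity and must contain at
  least ``min_cluster_voxels`` voxels (10 by default);
* equal-t peak ties break to the lowest linear voxel index in scan order;
* conditions are modeled without orthogonalization by default; sequential
  orthogonalization (each column against its predecessors) is available
  behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from nilearn.glm.first_level import compute_regressor
from scipy import ndimage, stats

from .errors import InputError, ValidationError
from .io_config import VolumeSeries

__all__ = [
    "CONDITIONS",
    "Block",
    "DesignSpec",
    "GLMResult",
    "RoiSphere",
    "build_design_matrix",
    "fit_glm",
    "t_contrast",
    "peak_within_mask",
    "make_sphere_roi",
    "extract_roi_timeseries",
]

#: Valid block conditions of the n-back localizer.
CONDITIONS = ("rest", "back0", "back1", "back2", "back3")


@dataclass(frozen=True)
class Block:
    """One task block: condition name, onset and duration in seconds."""

    condition: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r}; valid: {CONDITIONS}"
            )
        if self.onset < 0:
            raise ValidationError("block onset must be >= 0")
        if self.duration <= 0:
            raise ValidationError("block duration must be positive")


@dataclass(frozen=True)
class DesignSpec:
    """A block sequence plus the subset of conditions to model."""

    blocks: tuple[Block, ...]
    conditions_to_model: tuple[str, ...] = ("rest", "back1", "back2")

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "conditions_to_model",
                           tuple(self.conditions_to_model))
        for cond in self.conditions_to_model:
            if cond not in CONDITIONS:
                raise ValidationError(f"unknown condition {cond!r}")
        spans = sorted((b.onset, b.onset + b.duration) for b in self.blocks)
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0 - 1e-9:
                raise ValidationError(
                    f"overlapping blocks: [{s0}, {e0}) and starting {s1}"
                )

    def end_seconds(self) -> float:
        return max((b.onset + b.duration for b in self.blocks), default=0.0)


def _orthogonalize_sequential(X: np.ndarray) -> np.ndarray:
    """Orthogonalize each column against all earlier columns (in order)."""
    out = X.copy()
    for j in range(1, X.shape[1]):
        prev = out[:, :j]
        beta, *_ = np.linalg.lstsq(prev, out[:, j], rcond=None)
        out[:, j] = out[:, j] - prev @ beta
    return out


def build_design_matrix(design: DesignSpec, tr_seconds: float,
                        n_volumes: int, motion=None,
                        orthogonalize: bool = False
                        ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Boxcar-convolved condition columns (+ optional motion regressors).

    Each modeled condition contributes one column: its block boxcar
    convolved with the canonical double-gamma HRF and sampled at the scan
    times.  Motion regressors, when given, are appended unconvolved as
    regressors of no interest.
    """
    if tr_seconds <= 0:
        raise ValidationError("tr_seconds must be positive")
    if design.end_seconds() > n_volumes * tr_seconds + 1e-9:
        raise ValidationError("design extends past the acquired volumes")
    frame_times = np.arange(n_volumes) * tr_seconds
    cols, labels = [], []
    for cond in design.conditions_to_model:
        blocks = [b for b in design.blocks if b.condition == cond]
        if not blocks:
            raise ValidationError(f"no blocks for modeled condition {cond!r}")
        exp_condition = np.array([
            [b.onset for b in blocks],
            [b.duration for b in blocks],
            [1.0] * len(blocks),
        ])
        reg, _ = compute_regressor(exp_condition, "glover", frame_times,
                                   con_id=cond)
        cols.append(reg[:, 0])
        labels.append(cond)
    X = np.column_stack(cols)
    if orthogonalize:
        X = _orthogonalize_sequential(X)
    if motion is not None:
        mot = np.asarray(getattr(motion, "values", motion), dtype=float)
        if mot.shape[0] != n_volumes:
            raise InputError("motion rows must match n_volumes")
        X = np.hstack([X, mot])
        labels += [f"motion_{i}" for i in range(mot.shape[1])]
    return X, tuple(labels)


@dataclass
class GLMResult:
    """Voxel-wise OLS fit of a design matrix to a 4D series."""

    beta: np.ndarray            # (n_regressors + 1, x, y, z); last col = const
    sigma2: np.ndarray          # (x, y, z) residual variance
    dof: int
    xtx_inv: np.ndarray         # (k, k) for the full design incl. intercept
    labels: tuple[str, ...]
    shape: tuple[int, int, int]


def _series_data(volume_series) -> tuple[np.ndarray, tuple[int, int, int]]:
    if isinstance(volume_series, VolumeSeries):
        data = volume_series.data
    else:
        data = np.asarray(volume_series, dtype=float)
    if data.ndim != 4:
        raise InputError("expected a 4D (x, y, z, t) series")
    shape = data.shape[:3]
    return data.reshape(-1, data.shape[3]).T, shape  # (t, v)


def fit_glm(volume_series, design_matrix: np.ndarray,
            labels: tuple[str, ...] | None = None) -> GLMResult:
    """Ordinary least squares per voxel; an intercept is always appended."""
    Y, shape = _series_data(volume_series)
    X = np.asarray(design_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise InputError("design rows must match the number of volumes")
    if labels is None:
        labels = tuple(f"x{i}" for i in range(X.shape[1]))
    Xc = np.hstack([X, np.ones((X.shape[0], 1))])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [labels[j] for j in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(Xc, j, axis=1))
               == np.linalg.matrix_rank(Xc)]
        raise InputError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(Xc, Y, rcond=None)
    resid = Y - Xc @ beta
    dof = Y.shape[0] - rank
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return GLMResult(
        beta=beta.reshape(Xc.shape[1], *shape),
        sigma2=sigma2.reshape(shape),
        dof=dof,
        xtx_inv=np.linalg.inv(Xc.T @ Xc),
        labels=tuple(labels) + ("const",),
        shape=shape,
    )


def t_contrast(glm: GLMResult, contrast) -> np.ndarray:
    """Voxel-wise t statistic ``c'b / sqrt(s2 c'(X'X)^-1 c)``.

    The contrast vector addresses the modeled regressors (without the
    intercept); a zero appended for the intercept completes it.
    """
    c = np.asarray(contrast, dtype=float).reshape(-1)
    k = glm.beta.shape[0]
    if c.size == k - 1:
        c = np.concatenate([c, [0.0]])
    if c.size != k:
        raise ValidationError(
            f"contrast length {c.size} does not match {k - 1} regressors"
        )
    if np.all(c == 0):
        raise ValidationError("contrast must have at least one nonzero weight")
    effect = np.tensordot(c, glm.beta, axes=1)
    var_scale = float(c @ glm.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(glm.sigma2 * var_scale)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def peak_within_mask(t_volume: np.ndarray, mask: np.ndarray, dof: int,
                     alpha_fwe: float = 0.05, min_cluster_voxels: int = 10
                     ) -> tuple[int, int, int] | None:
    """Maximum-t voxel surviving Bonferroni FWE and the cluster-size rule.

    Voxels must exceed the one-sided Bonferroni threshold over in-mask
    voxels and belong to an 18-connected suprathreshold component of at
    least ``min_cluster_voxels`` voxels inside the mask.  Returns the peak
    voxel coordinate, or ``None`` if nothing survives.  Ties break to the
    lowest linear index in scan order.
    """
    t = np.asarray(t_volume, dtype=float)
    m = np.asarray(mask).astype(bool)
    if t.shape != m.shape:
        raise InputError("t volume and mask shapes differ")
    n_mask = int(m.sum())
    if n_mask == 0:
        raise InputError("empty mask")
    threshold = stats.t.isf(alpha_fwe / n_mask, dof)
    supra = (t > threshold) & m
    if not supra.any():
        return None
    structure = ndimage.generate_binary_structure(3, 2)  # 18-connectivity
    labels, n_lab = ndimage.label(supra, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(t), labels, range(1, n_lab + 1))
    keep = supra & np.isin(labels, 1 + np.flatnonzero(
        np.asarray(sizes) >= min_cluster_voxels))
    if not keep.any():
        return None
    masked_t = np.where(keep, t, -np.inf)
    idx = np.unravel_index(int(np.argmax(masked_t)), t.shape)
    return tuple(int(i) for i in idx)


@dataclass
class RoiSphere:
    """A spherical ROI: center voxel, mm center, radius and member voxels."""

    center_voxel: tuple[int, int, int]
    center_mm: np.ndarray
    radius_mm: float
    voxels: np.ndarray          # (n, 3) int voxel coordinates
    source_mask: str = ""

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]


def make_sphere_roi(center_voxel, radius_mm: float, shape,
                    affine: np.ndarray, source_mask: str = "") -> RoiSphere:
    """All voxels whose centers lie within ``radius_mm`` of the center voxel.

    Distances are Euclidean in mm (through the affine); the sphere is
    clipped at grid edges and always contains its center.
    """
    center_voxel = tuple(int(c) for c in center_voxel)
    shape = tuple(int(s) for s in shape)
    if len(center_voxel) != 3 or len(shape) != 3:
        raise InputError("center and shape must be 3D")
    if not all(0 <= c < s for c, s in zip(center_voxel, shape)):
        raise InputError(f"center {center_voxel} outside grid {shape}")
    affine = np.asarray(affine, dtype=float)
    if radius_mm < 0:
        raise InputError("radius_mm must be >= 0")

    def to_mm(vox: np.ndarray) -> np.ndarray:
        return vox @ affine[:3, :3].T + affine[:3, 3]

    center_mm = to_mm(np.asarray(center_voxel, dtype=float))
    # bounding box in voxels (worst-case isotropic bound via smallest zoom)
    zooms = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    half = np.ceil(radius_mm / zooms).astype(int) + 1
    lo = np.maximum(np.asarray(center_voxel) - half, 0)
    hi = np.minimum(np.asarray(center_voxel) + half + 1, shape)
    grid = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(to_mm(grid.astype(float)) - center_mm, axis=1)
    voxels = grid[dist <= radius_mm + 1e-9]
    return RoiSphere(center_voxel=center_voxel, center_mm=center_mm,
                     radius_mm=radius_mm, voxels=voxels,
                     source_mask=source_mask)


def extract_roi_timeseries(volume_series, roi: RoiSphere) -> np.ndarray:
    """Per-volume mean signal over the ROI's member voxels."""
    data = volume_series.data if isinstance(volume_series, VolumeSeries) \
        else np.asarray(volume_series, dtype=float)
    if data.ndim != 4:
        raise InputError("expected a 4D (x, y, z, t) series")
    if roi.n_voxels == 0:
        raise InputError("empty ROI")
    vx = roi.voxels
    if (vx >= np.asarray(data.shape[:3])).any() or (vx < 0).any():
        raise InputError("ROI voxels outside volume grid")
    return data[vx[:, 0], vx[:, 1], vx[:, 2], :].mean(axis=0)
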