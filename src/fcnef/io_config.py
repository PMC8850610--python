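"""File readers/writers and the validated pipeline configuration.

Every numeric default of the processing chain lives in
:class:`PipelineConfig`: the two Butterworth pass bands (0.008-0.3 Hz for
the online per-trial pipeline, 0.008-0.1 Hz for offline resting-state
connectivity), the 0.5 mm framewise-displacement threshold, the 8 mm ROI
sphere radius, the 50 mm head radius used to convert rotations to arc
displacement, the 10 leading steady-state volumes discarded from every run,
the 2 s hemodynamic discard at induction onset, the +/- 2 SD outlier rule,
and the Normal(50, 30.3) sham-feedback distribution.

On-disk conventions
-------------------
* volumes and masks: NIfTI-1 (via nibabel), data laid out (x, y, z, t);
* motion parameters: whitespace-delimited text, six columns in the order
  3 translations (mm) then 3 rotations; rotations are stored internally in
  radians and converted on read when the file is declared to be in degrees;
* cohort questionnaire tables: CSV, long format, one row per
  participant x day with a fixed day vocabulary;
* configuration: YAML mapping of the PipelineConfig fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InputError, ParameterError, ValidationError

__all__ = [
    "PipelineConfig",
    "VolumeSeries",
    "MotionParams",
    "DAY_LABELS",
    "COHORT_COLUMNS",
    "read_volume_series",
    "write_volume_series",
    "read_motion_params",
    "write_motion_params",
    "read_cohort_table",
    "write_cohort_table",
    "validate_cohort",
    "read_roi_timeseries",
    "write_roi_timeseries",
]

#: Fixed vocabulary of measurement days, in chronological order.
DAY_LABELS = (
    "Day0",
    "FCNefDay1",
    "FCNefDay2",
    "FCNefDay3",
    "FCNefDay4",
    "Post1m",
    "Post2m",
)

#: Required columns of a cohort table.
COHORT_COLUMNS = (
    "participant_id",
    "experiment_id",
    "day",
    "BDI",
    "RRS_depression",
    "RRS_brooding",
    "RRS_reflection",
    "STAI2",
    "rs_fc",
)


@dataclass
class PipelineConfig:
    """All tunable numeric defaults of the pipeline in one place.

    The defaults are the values used throughout the neurofeedback protocol;
    change them only to explore variants.
    """

    tr_seconds: float = 1.0
    online_band: tuple[float, float] = (0.008, 0.3)
    resting_band: tuple[float, float] = (0.008, 0.1)
    fd_threshold_mm: float = 0.5
    roi_radius_mm: float = 8.0
    sphere_head_radius_mm: float = 50.0
    steady_state_discard_volumes: int = 10
    hemodynamic_discard_seconds: float = 2.0
    outlier_k_sd: float = 2.0
    sham_mean: float = 50.0
    sham_sd: float = 30.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        for name in ("online_band", "resting_band"):
            band = tuple(float(x) for x in getattr(self, name))
            if len(band) != 2:
                raise ParameterError(f"{name} must be a (low, high) pair")
            low, high = band
            if not (0 < low < high):
                raise ParameterError(f"{name}: need 0 < low < high, got {band}")
            if high >= nyquist:
                raise ParameterError(
                    f"{name}: high edge {high} Hz is at or above Nyquist "
                    f"{nyquist} Hz for TR {self.tr_seconds}s"
                )
            setattr(self, name, band)
        for name in ("fd_threshold_mm", "roi_radius_mm", "sphere_head_radius_mm",
                     "outlier_k_sd", "sham_sd"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.steady_state_discard_volumes < 0:
            raise ParameterError("steady_state_discard_volumes must be >= 0")
        if self.hemodynamic_discard_seconds < 0:
            raise ParameterError("hemodynamic_discard_seconds must be >= 0")
        self.steady_state_discard_volumes = int(self.steady_state_discard_volumes)
        self.rng_seed = int(self.rng_seed)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["online_band"] = list(self.online_band)
        d["resting_band"] = list(self.resting_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("online_band", "resting_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class VolumeSeries:
    """A 4D BOLD series: data laid out (x, y, z, t) plus geometry and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    n_discarded_leading: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise InputError("need at least one volume")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValidationError("affine must be invertible")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        if self.n_discarded_leading < 0:
            raise ValidationError("n_discarded_leading must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm derived from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class MotionParams:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise FormatError(
                f"motion parameters must be (n, 6), got {self.values.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume_series(path: str | Path, config: PipelineConfig | None = None
                       ) -> VolumeSeries:
    """Load a 4D NIfTI file, dropping the leading steady-state volumes.

    TR is taken from the NIfTI header when present (4th zoom), otherwise
    from ``config.tr_seconds``.  The number of dropped leading volumes is
    recorded in ``n_discarded_leading``.
    """
    config = config or PipelineConfig()
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D series, got {data.ndim}D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else config.tr_seconds
    discard = config.steady_state_discard_volumes
    if data.shape[3] <= discard:
        raise InputError(
            f"{path}: {data.shape[3]} volumes but {discard} to discard"
        )
    return VolumeSeries(
        data=data[..., discard:],
        affine=np.asarray(img.affine, dtype=float),
        tr_seconds=tr,
        n_discarded_leading=discard,
    )


def write_volume_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a VolumeSeries as NIfTI-1 with TR recorded in the header."""
    img = nib.Nifti1Image(series.data, series.affine)
    zooms = list(img.header.get_zooms())
    zooms = zooms[:3] + [series.tr_seconds]
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Motion parameters
# ---------------------------------------------------------------------------

def read_motion_params(path: str | Path, rotations_in_degrees: bool = False
                       ) -> MotionParams:
    """Read a 6-column motion-parameter text file.

    Assumed column order (SPM ``rp_*.txt`` convention): three translations
    in mm followed by three rotations.  Rotations are stored in radians;
    pass ``rotations_in_degrees=True`` if the file records degrees.
    """
    try:
        values = np.loadtxt(str(path), ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot parse motion file {path}: {exc}") from exc
    if values.shape[1] != 6:
        raise FormatError(
            f"{path}: expected 6 columns, got {values.shape[1]}"
        )
    if rotations_in_degrees:
        values = values.copy()
        values[:, 3:] = np.deg2rad(values[:, 3:])
    return MotionParams(values)


def write_motion_params(motion: MotionParams, path: str | Path) -> None:
    np.savetxt(str(path), motion.values, fmt="%.10g", delimiter="\t")


# ---------------------------------------------------------------------------
# ROI time series (pre-extracted signals, one column per ROI)
# ---------------------------------------------------------------------------

def read_roi_timeseries(path: str | Path) -> np.ndarray:
    """Read a whitespace/tab-delimited time x ROI numeric table."""
    try:
        values = np.loadtxt(str(path), ndmin=2)
    except Exception as exc:
        raise FormatError(f"cannot parse time-series file {path}: {exc}") from exc
    return values


def write_roi_timeseries(series: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), np.asarray(series, dtype=float), fmt="%.10g",
               delimiter="\t")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a long-format cohort table.

    Checks the required columns, the fixed day vocabulary, experiment ids
    in {1, 2}, rs_fc within [-1, 1], and uniqueness of (participant, day).
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    out = table.loc[:, list(COHORT_COLUMNS)].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    out["experiment_id"] = out["experiment_id"].astype(int)
    out["day"] = out["day"].astype(str)
    bad_exp = set(out["experiment_id"]) - {1, 2}
    if bad_exp:
        raise ValidationError(f"experiment_id must be 1 or 2, got {sorted(bad_exp)}")
    bad_days = set(out["day"]) - set(DAY_LABELS)
    if bad_days:
        raise ValidationError(f"unknown day labels: {sorted(bad_days)}")
    for col in ("BDI", "RRS_depression", "RRS_brooding", "RRS_reflection",
                "STAI2", "rs_fc"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    if (out["rs_fc"].abs() > 1).any():
        raise ValidationError("rs_fc values must lie in [-1, 1]")
    dup = out.duplicated(subset=["participant_id", "day"])
    if dup.any():
        pairs = out.loc[dup, ["participant_id", "day"]].values.tolist()
        raise InputError(f"duplicate (participant, day) rows: {pairs}")
    return out.reset_index(drop=True)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read cohort CSV {path}: {exc}") from exc
    return validate_cohort(table)


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(table).to_csv(path, index=False)
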