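"""Synthetic inputs for every pipeline stage.

No public dataset accompanies the protocol this package implements, so
this module generates the inputs the pipeline needs with known ground
truth: two-ROI BOLD sessions with a planted Pearson correlation, nuisance
structure and motion spikes; block-design localizer runs with planted
activation blobs; and questionnaire cohorts with a planted linear
FC-change -> symptom-change relationship.

Generative model
----------------
The latent ROI pair is a bivariate Gaussian AR(1) process: innovations are
drawn with the target correlation (Cholesky of the 2x2 correlation
matrix) and filtered with a common AR coefficient, which leaves the
stationary cross-correlation equal to the innovation correlation.  Shared
nuisance components (global / CSF / grey-matter means, modeled as smooth
AR(1) series) are added to both ROIs with configurable amplitudes, plus a
linear drift and optional independent measurement noise.  Head motion is
a small random walk; motion spikes are single-frame translation steps
that exceed the 0.5 mm framewise-displacement threshold at exactly the
requested volumes.

Cohorts plant ``symptom_change = intercept + beta * fc_change`` (plus an
additive experiment-2 shift and Gaussian residual); Day0 and Day4 rows
are emitted consistently with the planted changes.  Default cohort
conditions mirror the study: 19 participants split 9/10 across two
experiments, Day-0 BDI near 14.3 +/- 5.1, Day-0 resting FC near
0.01 +/- 0.05, and a mean FC change of about -0.07.

All generators are deterministic per (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_config import MotionParams, VolumeSeries, validate_cohort
from .localizer import Block, DesignSpec, build_design_matrix
from .preprocess import build_nuisance, NuisanceSet
from .session_model import (
    SegmentIndex,
    TrialSchedule,
    segment_session,
    session_length_volumes,
)

__all__ = [
    "SignalSpec",
    "CohortSpec",
    "SimulatedPair",
    "SessionBundle",
    "LocalizerBundle",
    "BlobSpec",
    "simulate_roi_pair",
    "simulate_session",
    "simulate_localizer_run",
    "simulate_cohort",
    "default_localizer_design",
]


@dataclass(frozen=True)
class SignalSpec:
    """Statistical structure of a simulated two-ROI BOLD recording."""

    target_r: float = -0.1
    noise_sd: float = 0.0
    drift_amplitude: float = 1.0
    nuisance_amplitudes: dict = field(
        default_factory=lambda: {"global": 1.0, "csf": 0.5, "gm": 0.8})
    spike_volumes: tuple[int, ...] = ()
    autocorrelation: float = 0.3

    def __post_init__(self) -> None:
        if abs(self.target_r) >= 1:
            raise ParameterError("|target_r| must be < 1")
        if not 0 <= self.autocorrelation < 1:
            raise ParameterError("autocorrelation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        object.__setattr__(self, "spike_volumes",
                           tuple(int(v) for v in self.spike_volumes))


def _ar1(n: int, phi: float, rng: np.random.Generator,
         innovations: np.ndarray | None = None) -> np.ndarray:
    e = rng.standard_normal(n) if innovations is None else innovations
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1 - phi ** 2) if phi > 0 else e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def _correlated_pair(n: int, r_per_volume: np.ndarray, phi: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Bivariate AR(1) latent pair with per-volume innovation correlation.

    For constant r the stationary cross-correlation equals r because both
    series share the AR coefficient.
    """
    e = rng.standard_normal((n, 2))
    r = np.asarray(r_per_volume, dtype=float)
    # per-volume Cholesky of [[1, r], [r, 1]]
    e2 = r * e[:, 0] + np.sqrt(1 - r ** 2) * e[:, 1]
    x = np.column_stack([
        _ar1(n, phi, rng, innovations=e[:, 0]),
        _ar1(n, phi, rng, innovations=e2),
    ])
    return x / np.sqrt(1.0 / (1 - phi ** 2)) if phi > 0 else x


def _simulate_motion(n: int, spike_volumes, rng: np.random.Generator
                     ) -> MotionParams:
    """Random-walk head motion (FD well below 0.5 mm) plus spike steps."""
    steps = np.empty((n, 6))
    steps[:, :3] = rng.normal(0.0, 0.005, size=(n, 3))      # mm
    steps[:, 3:] = rng.normal(0.0, 0.0001, size=(n, 3))     # rad
    steps[0] = 0.0
    for v in spike_volumes:
        if not 0 < v < n:
            raise ParameterError(f"spike volume {v} outside (0, {n})")
        steps[v, 0] += 1.0  # permanent 1 mm x-translation step
    return MotionParams(np.cumsum(steps, axis=0))


def _nuisance_series(n: int, keys, rng: np.random.Generator) -> dict:
    return {k: _ar1(n, 0.95, rng) for k in keys}


@dataclass
class SimulatedPair:
    """A simulated two-ROI recording with its confound ground truth."""

    roi1: np.ndarray
    roi2: np.ndarray
    motion: MotionParams
    tissue_means: dict
    nuisance: NuisanceSet
    target_r: float | np.ndarray


def _assemble_pair(n_volumes: int, r_per_volume, spec: SignalSpec,
                   rng: np.random.Generator) -> SimulatedPair:
    latent = _correlated_pair(n_volumes, r_per_volume,
                              spec.autocorrelation, rng)
    motion = _simulate_motion(n_volumes, spec.spike_volumes, rng)
    tissue = _nuisance_series(n_volumes, spec.nuisance_amplitudes, rng)
    shared = np.zeros(n_volumes)
    for key, amp in spec.nuisance_amplitudes.items():
        shared = shared + amp * tissue[key]
    drift = spec.drift_amplitude * np.linspace(0.0, 1.0, n_volumes)
    noise = rng.normal(0.0, spec.noise_sd, size=(n_volumes, 2)) \
        if spec.noise_sd > 0 else np.zeros((n_volumes, 2))
    roi1 = latent[:, 0] + shared + drift + noise[:, 0]
    roi2 = latent[:, 1] + shared + drift + noise[:, 1]
    nuisance = build_nuisance(motion, tissue, include_derivatives=True)
    return SimulatedPair(roi1=roi1, roi2=roi2, motion=motion,
                         tissue_means=tissue, nuisance=nuisance,
                         target_r=r_per_volume)


def simulate_roi_pair(n_volumes: int, spec: SignalSpec | None = None,
                      seed: int = 0) -> SimulatedPair:
    """Simulate a stationary two-ROI recording with planted correlation."""
    spec = spec or SignalSpec()
    if n_volumes < 10:
        raise ParameterError("n_volumes must be >= 10")
    rng = np.random.default_rng(seed)
    return _assemble_pair(n_volumes, np.full(n_volumes, spec.target_r),
                          spec, rng)


@dataclass
class SessionBundle:
    """A full simulated neurofeedback session."""

    roi1: np.ndarray
    roi2: np.ndarray
    segments: SegmentIndex
    motion: MotionParams
    tissue_means: dict
    nuisance: NuisanceSet
    schedule: TrialSchedule
    tr_seconds: float
    per_trial_target_r: tuple[float, ...]


def simulate_session(schedule: TrialSchedule | None = None,
                     per_trial_target_r=None,
                     spec: SignalSpec | None = None,
                     seed: int = 0,
                     tr_seconds: float = 1.0) -> SessionBundle:
    """Simulate one session: rest then trials, each trial's induction
    period carrying its own planted correlation (zero elsewhere)."""
    schedule = schedule or TrialSchedule()
    spec = spec or SignalSpec()
    if per_trial_target_r is None:
        per_trial_target_r = (spec.target_r,) * schedule.n_trials
    per_trial_target_r = tuple(float(r) for r in per_trial_target_r)
    if len(per_trial_target_r) != schedule.n_trials:
        raise ParameterError(
            f"need one target r per trial ({schedule.n_trials}), "
            f"got {len(per_trial_target_r)}"
        )
    if any(abs(r) >= 1 for r in per_trial_target_r):
        raise ParameterError("|target_r| must be < 1 for every trial")
    n_volumes = session_length_volumes(schedule, tr_seconds)
    segments = segment_session(schedule, tr_seconds, n_volumes)
    r_per_volume = np.zeros(n_volumes)
    for trial, r in zip(segments.trials, per_trial_target_r):
        # plant the correlation over the whole induction period, including
        # the hemodynamically discarded lead-in
        start = trial.equals[1]
        r_per_volume[start: trial.induction_used[1]] = r
    rng = np.random.default_rng(seed)
    pair = _assemble_pair(n_volumes, r_per_volume, spec, rng)
    return SessionBundle(
        roi1=pair.roi1, roi2=pair.roi2, segments=segments,
        motion=pair.motion, tissue_means=pair.tissue_means,
        nuisance=pair.nuisance, schedule=schedule, tr_seconds=tr_seconds,
        per_trial_target_r=per_trial_target_r,
    )


# ---------------------------------------------------------------------------
# Localizer runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobSpec:
    """A planted activation blob responding to one condition."""

    center: tuple[int, int, int]
    condition: str
    radius_mm: float = 4.0


@dataclass
class LocalizerBundle:
    """A simulated localizer run with its planted ground truth."""

    volumes: VolumeSeries
    design: DesignSpec
    design_matrix: np.ndarray
    design_labels: tuple[str, ...]
    blobs: tuple[BlobSpec, ...]


def default_localizer_design(n_blocks: int = 8, block_seconds: float = 30.0,
                             rest_seconds: float = 30.0) -> DesignSpec:
    """A compact n-back-style block design: alternating rest and task
    blocks (back1/back2 alternating) opening with a rest block."""
    blocks = []
    t = 0.0
    task_cycle = ("back1", "back2")
    for i in range(n_blocks):
        blocks.append(Block("rest", t, rest_seconds))
        t += rest_seconds
        blocks.append(Block(task_cycle[i % 2], t, block_seconds))
        t += block_seconds
    blocks.append(Block("rest", t, rest_seconds))
    return DesignSpec(tuple(blocks))


def simulate_localizer_run(design: DesignSpec | None = None,
                           blobs=(),
                           effect_size: float = 1.0,
                           seed: int = 0,
                           shape=(14, 14, 14),
                           voxel_size_mm: float = 2.0,
                           tr_seconds: float = 1.0,
                           noise_sd: float = 1.0) -> LocalizerBundle:
    """Simulate a 4D localizer run with planted blobs.

    Voxels inside each blob carry that blob's condition regressor
    (boxcar convolved with the HRF, unit-normalized) scaled by
    ``effect_size`` and a Gaussian spatial profile peaked at the blob
    center (sigma = radius / 2), so at high SNR the strongest response is
    at the planted center; every voxel receives independent Gaussian
    noise.
    """
    design = design or default_localizer_design()
    blobs = tuple(blobs)
    shape = tuple(int(s) for s in shape)
    n_volumes = int(np.ceil(design.end_seconds() / tr_seconds))
    X, labels = build_design_matrix(design, tr_seconds, n_volumes)
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, noise_sd, size=shape + (n_volumes,))
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    for blob in blobs:
        if not all(0 <= c < s for c, s in zip(blob.center, shape)):
            raise ParameterError(f"blob center {blob.center} outside grid")
        if blob.condition not in labels:
            raise ParameterError(
                f"blob condition {blob.condition!r} not modeled: {labels}"
            )
        reg = X[:, labels.index(blob.condition)]
        reg = reg / np.sqrt((reg ** 2).mean())  # unit RMS
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape],
                                 indexing="ij")
        dist = voxel_size_mm * np.sqrt(
            (ii - blob.center[0]) ** 2 + (jj - blob.center[1]) ** 2
            + (kk - blob.center[2]) ** 2)
        member = dist <= blob.radius_mm
        sigma = blob.radius_mm / 2.0
        profile = np.exp(-dist[member] ** 2 / (2.0 * sigma ** 2))
        data[member] += effect_size * profile[:, None] * reg
    volumes = VolumeSeries(data=data, affine=affine, tr_seconds=tr_seconds)
    return LocalizerBundle(volumes=volumes, design=design, design_matrix=X,
                           design_labels=labels, blobs=blobs)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Planted population structure of a questionnaire cohort."""

    n_participants: int = 19
    beta: float = 20.0
    intercept: float = -1.5
    residual_sd: float = 2.0
    experiment_effect: float = 0.0
    fc_change_distribution: tuple[float, float] = (-0.07, 0.10)
    seed: int = 0
    follow_up: bool = True   # emit Post1m/Post2m rows for experiment 2

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ParameterError("n_participants must be >= 2")
        if self.residual_sd < 0:
            raise ParameterError("residual_sd must be >= 0")
        if self.fc_change_distribution[1] < 0:
            raise ParameterError("fc change sd must be >= 0")


# Day-0 questionnaire levels (mean, sd): BDI per the screening population;
# RRS factor and STAI2 levels chosen as plausible subclinical values.
_DAY0_LEVELS = {
    "BDI": (14.3, 5.1),
    "RRS_depression": (30.0, 6.0),
    "RRS_brooding": (11.0, 3.0),
    "RRS_reflection": (10.0, 3.0),
    "STAI2": (48.0, 8.0),
}

# How strongly each outcome's change tracks the FC change, as a fraction
# of the primary (BDI) slope: the brooding factor partially tracks it,
# the depression factor weakly, reflection and trait anxiety not at all.
_OUTCOME_SLOPE_FRACTION = {
    "BDI": 1.0,
    "RRS_depression": 0.5,
    "RRS_brooding": 0.4,
    "RRS_reflection": 0.0,
    "STAI2": 0.0,
}


def simulate_cohort(spec: CohortSpec | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort table plus its ground-truth record.

    Each participant gets a Day0 row and a FCNefDay4 row whose difference
    realizes ``intercept + beta * fc_change (+ experiment shift) + noise``
    for the BDI; the other outcomes use scaled-down slopes.  Experiment-2
    participants additionally get Post1m/Post2m rows when ``follow_up``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    n_exp1 = n // 2
    rows = []
    truth_participants = []
    fc_mu, fc_sd = spec.fc_change_distribution
    for i in range(n):
        pid = f"P{i + 1:02d}"
        exp = 1 if i < n_exp1 else 2
        day0 = {k: rng.normal(*v) for k, v in _DAY0_LEVELS.items()}
        fc0 = float(np.clip(rng.normal(0.01, 0.05), -0.95, 0.95))
        horizons = ["FCNefDay4"]
        if spec.follow_up and exp == 2:
            horizons += ["Post1m", "Post2m"]
        rows.append({"participant_id": pid, "experiment_id": exp,
                     "day": "Day0", **day0, "rs_fc": fc0})
        truth = {"participant_id": pid, "experiment_id": exp,
                 "rs_fc_day0": fc0, "changes": {}}
        for day in horizons:
            fc_change = float(rng.normal(fc_mu, fc_sd))
            fc_later = float(np.clip(fc0 + fc_change, -1.0, 1.0))
            fc_change = fc_later - fc0  # respect the [-1, 1] bound exactly
            row = {"participant_id": pid, "experiment_id": exp, "day": day,
                   "rs_fc": fc_later}
            changes = {}
            for outcome, frac in _OUTCOME_SLOPE_FRACTION.items():
                eps = float(rng.normal(0.0, spec.residual_sd)) \
                    if spec.residual_sd > 0 else 0.0
                shift = spec.experiment_effect if exp == 2 else 0.0
                delta = (spec.intercept + frac * spec.beta * fc_change
                         + shift + eps)
                row[outcome] = day0[outcome] + delta
                changes[outcome] = delta
            changes["rs_fc"] = fc_change
            truth["changes"][day] = changes
            rows.append(row)
        truth_participants.append(truth)
    table = validate_cohort(pd.DataFrame(rows))
    ground_truth = {
        "beta": spec.beta,
        "intercept": spec.intercept,
        "residual_sd": spec.residual_sd,
        "experiment_effect": spec.experiment_effect,
        "outcome_slope_fraction": dict(_OUTCOME_SLOPE_FRACTION),
        "participants": truth_participants,
        "seed": spec.seed,
    }
    return table, ground_truth
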