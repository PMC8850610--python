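"""Per-trial FC scoring: baselines, the 0-100 score map, sham feedback.

The scoring chain works in Fisher z space.  On the sham day, per-trial
DLPFC-PCC correlations are Fisher-transformed, averaged (sample SD, n-1),
and transformed back: the back-transformed mean is the participant's
baseline correlation, and the back-transformed mean -/+ one SD give the
score-100 and score-0 anchors.  A trial at the baseline scores 50; at or
below baseline minus one SD it scores 100; at or above baseline plus one
SD it scores 0.  More anticorrelation (more negative FC) therefore means a
higher score.  Between the anchors the score interpolates linearly in z
(the published mapping states only the three anchor points; linear-in-z is
this package's choice, and r-space anchors are available behind the
``anchor_space`` switch).

Sham feedback is a raw draw from Normal(50, 30.3); the displayed value is
clamped to [0, 100] but the raw draw is retained so the generating
parameters stay recoverable from saved scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateBaselineError,
    DegenerateCorrelationError,
    ParameterError,
)
from .io_config import PipelineConfig
from .preprocess import NuisanceSet, bandpass, regress_out
from .session_model import SegmentIndex, TrialSchedule

__all__ = [
    "BaselineFC",
    "TrialScore",
    "ShamDraw",
    "fisher_z",
    "inverse_fisher",
    "trial_fc",
    "compute_baseline",
    "score_trial",
    "sham_score",
    "run_fcnef_session",
]


def fisher_z(r):
    """Fisher r-to-z transform, ``z = atanh(r)``; requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ParameterError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Inverse Fisher transform, ``r = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BaselineFC:
    """Sham-day baseline statistics in Fisher z space plus score anchors."""

    mean_z: float
    sd_z: float
    lower_anchor_r: float   # score-100 anchor (baseline minus one SD)
    upper_anchor_r: float   # score-0 anchor (baseline plus one SD)
    n_trials_used: int
    anchor_space: str = "z"

    @property
    def mean_r(self) -> float:
        return float(np.tanh(self.mean_z))

    @property
    def lower_anchor_z(self) -> float:
        return float(np.arctanh(self.lower_anchor_r))

    @property
    def upper_anchor_z(self) -> float:
        return float(np.arctanh(self.upper_anchor_r))


@dataclass(frozen=True)
class TrialScore:
    """One trial's FC value and its mapped feedback score."""

    trial_index: int
    r: float
    z: float
    score: float
    sham: bool = False
    raw_score: float | None = None   # unclamped sham draw when sham is True


@dataclass(frozen=True)
class ShamDraw:
    """A sham feedback draw: the raw Normal(50, 30.3) value and its
    display value clamped to [0, 100]."""

    raw: float
    display: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        raise DegenerateCorrelationError(
            "zero-variance signal; correlation undefined"
        )
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def trial_fc(roi1: np.ndarray, roi2: np.ndarray,
             induction_window: tuple[int, int],
             rest_window: tuple[int, int],
             nuisance: NuisanceSet | np.ndarray | None,
             config: PipelineConfig | None = None) -> float:
    """Per-trial functional connectivity of a session-long ROI pair.

    Pipeline: subtract each ROI's rest-period mean, residualize against
    the nuisance design, band-pass with the online band (0.008-0.3 Hz),
    then Pearson-correlate over the trial's induction-use window.
    """
    config = config or PipelineConfig()
    roi1 = np.asarray(roi1, dtype=float)
    roi2 = np.asarray(roi2, dtype=float)
    r0, r1 = rest_window
    i0, i1 = induction_window
    if i1 - i0 < 3:
        raise ParameterError("induction window must span at least 3 volumes")
    pair = np.column_stack([
        roi1 - roi1[r0:r1].mean(),
        roi2 - roi2[r0:r1].mean(),
    ])
    if nuisance is not None:
        pair = regress_out(pair, nuisance)
    pair = bandpass(pair, config.tr_seconds, *config.online_band)
    return _pearson(pair[i0:i1, 0], pair[i0:i1, 1])


def compute_baseline(trial_rs, anchor_space: str = "z") -> BaselineFC:
    """Baseline FC statistics from the sham day's per-trial correlations.

    ``anchor_space='z'`` (default): anchors are ``tanh(mean_z -/+ sd_z)``.
    ``anchor_space='r'``: the SD is instead taken over the raw correlation
    values and applied around the back-transformed mean.
    """
    rs = np.asarray(list(trial_rs), dtype=float)
    if rs.size < 2:
        raise DegenerateBaselineError("need at least two sham trials")
    z = fisher_z(rs)
    mean_z = float(z.mean())
    sd_z = float(z.std(ddof=1))
    if sd_z == 0:
        raise DegenerateBaselineError("zero variance across sham trials")
    if anchor_space == "z":
        lower = float(np.tanh(mean_z - sd_z))
        upper = float(np.tanh(mean_z + sd_z))
    elif anchor_space == "r":
        mean_r = float(np.tanh(mean_z))
        sd_r = float(rs.std(ddof=1))
        lower = max(mean_r - sd_r, -1.0 + 1e-12)
        upper = min(mean_r + sd_r, 1.0 - 1e-12)
    else:
        raise ParameterError("anchor_space must be 'z' or 'r'")
    return BaselineFC(mean_z=mean_z, sd_z=sd_z, lower_anchor_r=lower,
                      upper_anchor_r=upper, n_trials_used=int(rs.size),
                      anchor_space=anchor_space)


def score_trial(r: float, baseline: BaselineFC) -> float:
    """Map a trial correlation to the 0-100 feedback score.

    50 at the baseline, 100 at or below the lower anchor, 0 at or above
    the upper anchor, linear in z between anchors; nonincreasing in r.
    """
    if baseline.sd_z <= 0:
        raise DegenerateBaselineError("degenerate baseline")
    z = fisher_z(float(r))
    if z <= baseline.mean_z:
        span = baseline.mean_z - baseline.lower_anchor_z
        score = 50.0 + 50.0 * (baseline.mean_z - z) / span
    else:
        span = baseline.upper_anchor_z - baseline.mean_z
        score = 50.0 - 50.0 * (z - baseline.mean_z) / span
    return float(np.clip(score, 0.0, 100.0))


def sham_score(rng: np.random.Generator,
               config: PipelineConfig | None = None) -> ShamDraw:
    """One sham feedback draw from Normal(50, 30.3)."""
    config = config or PipelineConfig()
    raw = float(rng.normal(config.sham_mean, config.sham_sd))
    return ShamDraw(raw=raw, display=float(np.clip(raw, 0.0, 100.0)))


def run_fcnef_session(bundle, baseline: BaselineFC | None,
                      schedule: TrialSchedule | None = None,
                      config: PipelineConfig | None = None,
                      sham: bool = False,
                      rng: np.random.Generator | None = None
                      ) -> tuple[list[TrialScore], float]:
    """Score every trial of a session; returns the scores and their mean.

    ``bundle`` must expose ``roi1``, ``roi2``, ``segments``
    (:class:`SegmentIndex`) and ``nuisance`` (a design or None) — the
    shape produced by :func:`fcnef.synthetic_data.simulate_session`.  With
    ``sham=True`` the reported scores are random Normal(50, 30.3) draws
    (clamped for display) and require a seeded ``rng``; the true per-trial
    correlations are still computed and recorded.
    """
    config = config or PipelineConfig()
    segments: SegmentIndex = bundle.segments
    if sham and rng is None:
        raise ParameterError("sham scoring requires a seeded rng")
    if not sham and baseline is None:
        raise ParameterError("real feedback requires a baseline")
    scores: list[TrialScore] = []
    for i, trial in enumerate(segments.trials):
        r = trial_fc(bundle.roi1, bundle.roi2, trial.induction_used,
                     segments.rest_used, bundle.nuisance, config)
        if sham:
            draw = sham_score(rng, config)
            scores.append(TrialScore(i, r, fisher_z(r), draw.display,
                                     sham=True, raw_score=draw.raw))
        else:
            scores.append(TrialScore(i, r, fisher_z(r),
                                     score_trial(r, baseline)))
    mean_score = float(np.mean([s.score for s in scores]))
    return scores, mean_score
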