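"""Group-level analysis: resting FC, change scores, models, LOO prediction.

The group chain relates each participant's change in resting-state
DLPFC-PCC connectivity (later day minus Day 0) to their change in symptom
scores over the same interval: a linear model of symptom change on FC
change (optionally with an experiment main effect and interaction), a
likelihood-ratio test comparing the two, and a leave-one-out analysis that
predicts each held-out participant's symptom change from a model fit to
the others.

With a single change score per participant these models have no
replicated grouping factor, so the mixed-effects formulation reduces to an
ordinary linear model; the repeated-measures variant (task score across
training days) keeps a true random intercept per participant.  Maximum
likelihood (not REML) is used wherever models are compared by
likelihood-ratio test or AIC, and AIC counts the residual variance as an
estimated parameter (``AIC = 2k - 2 logLik``).

Outlier handling follows the +/- 2 SD rule: a single pass over the
dependent variable's change scores, mean and (sample) SD computed once
over all values, strict inequality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InputError, ParameterError
from .io_config import DAY_LABELS, PipelineConfig
from .preprocess import bandpass, build_nuisance, compute_fd, regress_out, scrub

__all__ = [
    "ModelFit",
    "LRTResult",
    "LooResult",
    "resting_fc",
    "change_scores",
    "exclude_outliers",
    "fit_change_model",
    "likelihood_ratio_test",
    "loo_predict",
    "correlate_changes",
    "repeated_measures_task_model",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("BDI", "RRS_depression", "RRS_brooding", "RRS_reflection", "STAI2")
HORIZONS = ("FCNefDay4", "Post1m", "Post2m")


# ---------------------------------------------------------------------------
# Offline resting-state FC
# ---------------------------------------------------------------------------

def resting_fc(roi1, roi2, motion, tissue_means,
               config: PipelineConfig | None = None) -> float:
    """Resting-state FC of a ROI pair through the offline pipeline.

    Pipeline: residualize against the full nuisance design (motion,
    tissue means, derivatives), remove frames with FD > 0.5 mm, band-pass
    0.008-0.1 Hz, then Pearson-correlate the surviving series.
    """
    config = config or PipelineConfig()
    pair = np.column_stack([np.asarray(roi1, float), np.asarray(roi2, float)])
    nuisance = build_nuisance(motion, tissue_means, include_derivatives=True)
    pair = regress_out(pair, nuisance)
    fd = compute_fd(motion, config.sphere_head_radius_mm)
    pair, kept = scrub(pair, fd, config.fd_threshold_mm)
    if kept.size < 3:
        raise InputError("fewer than 3 volumes survive scrubbing")
    pair = bandpass(pair, config.tr_seconds, *config.resting_band)
    r = np.corrcoef(pair[:, 0], pair[:, 1])[0, 1]
    if not np.isfinite(r):
        raise InputError("degenerate resting series; correlation undefined")
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Change scores
# ---------------------------------------------------------------------------

def change_scores(cohort: pd.DataFrame, horizon: str = "FCNefDay4"
                  ) -> pd.DataFrame:
    """Per-participant change scores: horizon-day value minus Day 0 value.

    Participants missing either row are dropped with a logged warning.
    Returns one row per participant with ``delta_*`` columns.
    """
    if horizon not in DAY_LABELS or horizon == "Day0":
        raise ParameterError(f"horizon must be one of {HORIZONS}")
    day0 = cohort[cohort["day"] == "Day0"].set_index("participant_id")
    later = cohort[cohort["day"] == horizon].set_index("participant_id")
    common = day0.index.intersection(later.index)
    missing = set(day0.index).symmetric_difference(later.index)
    if missing:
        logger.warning("dropping participants missing Day0 or %s rows: %s",
                       horizon, sorted(missing))
    if len(common) == 0:
        raise InputError(f"no participant has both Day0 and {horizon} rows")
    out = pd.DataFrame({
        "participant_id": common,
        "experiment_id": day0.loc[common, "experiment_id"].values,
        "horizon": horizon,
    })
    for col in OUTCOMES + ("rs_fc",):
        out[f"delta_{col}"] = (later.loc[common, col].values
                               - day0.loc[common, col].values)
    return out.reset_index(drop=True)


def exclude_outliers(values, k: float = 2.0) -> np.ndarray:
    """Boolean inclusion mask: keep x with ``|x - mean| <= k * SD``.

    Mean and sample SD are computed once over all values (single pass, no
    iteration); zero variance keeps everything.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InputError("need at least 3 values for outlier screening")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    return np.abs(x - x.mean()) <= k * sd


# ---------------------------------------------------------------------------
# Linear models on change scores
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted linear model with the quantities the analysis reports."""

    params: pd.Series
    bse: pd.Series
    anova: pd.DataFrame          # index: term; columns: F, df_num, df_den, p
    llf: float
    aic: float
    formula: str
    n_used: int
    outcome: str
    results: object = field(repr=False, default=None)   # statsmodels results

    @property
    def n_params(self) -> int:
        return len(self.params)


def _design(cs: pd.DataFrame, outcome: str, interaction: bool
            ) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    ycol = f"delta_{outcome}"
    if ycol not in cs.columns:
        raise ParameterError(f"unknown outcome {outcome!r}")
    y = cs[ycol].to_numpy(dtype=float)
    fc = cs["delta_rs_fc"].to_numpy(dtype=float)
    cols = [np.ones_like(fc), fc]
    names = ["const", "delta_rs_fc"]
    formula = f"delta_{outcome} ~ delta_rs_fc"
    if interaction:
        exp2 = (cs["experiment_id"].to_numpy() == 2).astype(float)
        cols += [exp2, fc * exp2]
        names += ["experiment2", "delta_rs_fc:experiment2"]
        formula += " * experiment"
    return y, np.column_stack(cols), names, formula


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("collinear design; cannot fit change model")
    res = sm.OLS(y, X).fit()
    return res


def _term_anova(y: np.ndarray, X: np.ndarray, names: list[str],
                res) -> pd.DataFrame:
    """Drop-one-term F tests (marginal, treatment coding)."""
    ssr_full = float(res.ssr)
    df_den = int(res.df_resid)
    rows = []
    for j, name in enumerate(names):
        if name == "const":
            continue
        Xr = np.delete(X, j, axis=1)
        res_r = sm.OLS(y, Xr).fit()
        q = 1
        F = ((res_r.ssr - ssr_full) / q) / (ssr_full / df_den)
        p = stats.f.sf(F, q, df_den)
        rows.append({"term": name, "F": float(F), "df_num": q,
                     "df_den": df_den, "p": float(p)})
    return pd.DataFrame(rows).set_index("term")


def fit_change_model(change_scores_df: pd.DataFrame, outcome: str = "BDI",
                     include_experiment_interaction: bool = False,
                     outlier_k: float | None = None) -> ModelFit:
    """Linear model of a symptom change on the resting-FC change.

    With ``include_experiment_interaction`` the design gains an
    experiment-2 main effect and its interaction with the FC change.
    ``outlier_k`` applies the +/- k SD screen to the dependent variable's
    change scores before fitting.
    """
    cs = change_scores_df
    if len(cs) < 4:
        raise InputError("need at least 4 change-score records")
    if outlier_k is not None:
        keep = exclude_outliers(cs[f"delta_{outcome}"].to_numpy(), outlier_k)
        cs = cs.loc[keep].reset_index(drop=True)
    y, X, names, formula = _design(cs, outcome,
                                   include_experiment_interaction)
    res = _ols(y, X, names)
    k = X.shape[1] + 1  # + residual variance
    return ModelFit(
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        anova=_term_anova(y, X, names, res),
        llf=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        formula=formula,
        n_used=len(cs),
        outcome=outcome,
        results=res,
    )


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float


def likelihood_ratio_test(fit_full: ModelFit, fit_reduced: ModelFit
                          ) -> LRTResult:
    """Likelihood-ratio test of two nested ML fits on the same data."""
    if fit_full.n_used != fit_reduced.n_used:
        raise InputError("models were fit on different numbers of records")
    if not set(fit_reduced.params.index) <= set(fit_full.params.index):
        raise InputError("reduced model is not nested in the full model")
    df = fit_full.n_params - fit_reduced.n_params
    chi2 = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    return LRTResult(chi2=float(chi2), df=int(df),
                     p=float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0)


@dataclass
class LooResult:
    """Leave-one-out predictions and their agreement with the data."""

    table: pd.DataFrame          # participant_id, actual, predicted
    r: float
    p: float


def loo_predict(change_scores_df: pd.DataFrame, outcome: str = "BDI"
                ) -> LooResult:
    """Leave-one-out prediction of each participant's symptom change.

    For each participant the base model (change ~ FC change) is refit on
    the remaining n-1 records and the held-out change is predicted from
    that participant's FC change; reports the Pearson correlation between
    actual and predicted changes.
    """
    cs = change_scores_df.reset_index(drop=True)
    if len(cs) < 5:
        raise InputError("need at least 5 records for leave-one-out")
    y_all = cs[f"delta_{outcome}"].to_numpy(dtype=float)
    fc_all = cs["delta_rs_fc"].to_numpy(dtype=float)
    preds = np.empty(len(cs))
    for i in range(len(cs)):
        mask = np.arange(len(cs)) != i
        X = np.column_stack([np.ones(mask.sum()), fc_all[mask]])
        res = sm.OLS(y_all[mask], X).fit()
        preds[i] = res.params[0] + res.params[1] * fc_all[i]
    r, p = stats.pearsonr(y_all, preds)
    table = pd.DataFrame({
        "participant_id": cs["participant_id"],
        "actual": y_all,
        "predicted": preds,
    })
    return LooResult(table=table, r=float(r), p=float(p))


def correlate_changes(change_scores_df: pd.DataFrame, outcome: str = "BDI"
                      ) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between the FC change and a
    symptom change across participants."""
    cs = change_scores_df
    if len(cs) < 3:
        raise InputError("need at least 3 pairs")
    x = cs["delta_rs_fc"].to_numpy(dtype=float)
    y = cs[f"delta_{outcome}"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise InputError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Repeated-measures task-score model
# ---------------------------------------------------------------------------

def repeated_measures_task_model(task_scores: pd.DataFrame) -> ModelFit:
    """Mixed model of session task score on training day.

    ``task_scores`` needs columns ``participant_id``, ``day`` (numeric,
    e.g. 1-4) and ``score``.  Fits ``score ~ day`` with a random intercept
    per participant by maximum likelihood and reports the Wald test of the
    day effect.
    """
    required = {"participant_id", "day", "score"}
    if not required <= set(task_scores.columns):
        raise InputError(f"task_scores needs columns {sorted(required)}")
    days_per = task_scores.groupby("participant_id")["day"].nunique()
    if (days_per < 2).any() or task_scores["day"].nunique() < 2:
        raise InputError("need at least two days per participant")
    day = task_scores["day"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(task_scores)), day])
    model = sm.MixedLM(task_scores["score"].to_numpy(dtype=float), X,
                       groups=task_scores["participant_id"].to_numpy())
    res = model.fit(reml=False)
    names = ["const", "day"]
    wald_z = res.params[1] / res.bse[1]
    p = 2 * stats.norm.sf(abs(wald_z))
    anova = pd.DataFrame([{"term": "day", "F": float(wald_z ** 2),
                           "df_num": 1, "df_den": int(res.nobs - 2),
                           "p": float(p)}]).set_index("term")
    k = 4  # intercept, slope, random-intercept variance, residual variance
    return ModelFit(
        params=pd.Series(res.params[:2], index=names),
        bse=pd.Series(res.bse[:2], index=names),
        anova=anova,
        llf=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        formula="score ~ day + (1 | participant)",
        n_used=int(res.nobs),
        outcome="task_score",
        results=res,
    )
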