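"""Trial performance scoring and learning-curve regression.

Every trial is reduced to a penalty-based fitness score: an ideal trial,
consisting solely of Guide and other non-wall-contact primitives, scores 1;
each wall-contacting primitive instance subtracts its penalty
(ControlledBounce 0.03, RandomBounce 0.06, RollAlongWall 0.12,
RollToWall 0.09 by default).  Longer trials are not penalised for length —
only the primitives count.

Learning is quantified by simple linear regression of score on the pooled
observation index (trial counter across the whole session), reported with
the full inferential block: coefficient standard errors, t statistics, the
model F test, R-squared and the 95% confidence band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import WALL_CONTACT_LABELS, PenaltyTable
from .segmentation import PrimitiveSegmentation

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltyTable", "TrialScore", "RegressionResult",
    "score_trial", "day_accuracy", "fit_ols", "learning_curves",
]


@dataclass(frozen=True)
class TrialScore:
    """Penalty score plus the precision metrics of one trial."""

    score: float
    n_contacts: int
    contact_time_ratio: float
    completed: bool
    n_segments: int

    def __post_init__(self) -> None:
        if self.score > 1 + 1e-12:
            raise ValueError("score cannot exceed 1")
        if not (0 <= self.contact_time_ratio <= 1):
            raise ValueError("contact_time_ratio must be within [0, 1]")


def score_trial(segmentation: PrimitiveSegmentation,
                penalties: Optional[PenaltyTable] = None,
                completed: bool = True) -> TrialScore:
    """Score = 1 minus the summed penalties of the trial's segments.

    No clipping is applied: heavily penalised trials may score below 0
    (logged).  ``n_contacts`` counts wall-contact segments and
    ``contact_time_ratio`` is the fraction of trial time spent in them.
    """
    penalties = penalties or PenaltyTable()
    total_pen = 0.0
    n_contacts = 0
    contact_time = 0.0
    for seg in segmentation.segments:
        total_pen += penalties[seg.label]
        if seg.label in WALL_CONTACT_LABELS:
            n_contacts += 1
            contact_time += seg.duration
    t0, t1 = segmentation.span
    trial_time = t1 - t0
    score = 1.0 - total_pen
    if score < 0:
        logger.info("trial %s scored below zero (%.3f)",
                    segmentation.trial_id, score)
    if not segmentation.segments:
        logger.info("empty segmentation %s scored as ideal",
                    segmentation.trial_id)
    ratio = contact_time / trial_time if trial_time > 0 else 0.0
    return TrialScore(score=score, n_contacts=n_contacts,
                      contact_time_ratio=min(ratio, 1.0),
                      completed=completed,
                      n_segments=len(segmentation.segments))


def day_accuracy(trials: Sequence) -> float:
    """Fraction of trials executed to the end (reached the target).

    ``trials`` may be TrialScore objects, objects with a ``completed``
    attribute, or plain booleans.
    """
    flags = [bool(getattr(t, "completed", t)) for t in trials]
    if not flags:
        raise ValueError("day_accuracy requires at least one trial")
    return sum(flags) / len(flags)


@dataclass
class RegressionResult:
    """Simple OLS fit y = beta0 + beta1 * x with full inference.

    ``t1 = beta1/se1`` and ``F = t1**2`` hold exactly (simple regression);
    p-values use the t / F distributions with n - 2 degrees of freedom.
    """

    beta0: float
    beta1: float
    se0: float
    se1: float
    t0: float
    t1: float
    p0: float
    p1: float
    F: float
    p_F: float
    R2: float
    adjR2: float
    RMSE: float
    n: int
    x: np.ndarray = field(repr=False)
    ci95_lower: np.ndarray = field(repr=False)
    ci95_upper: np.ndarray = field(repr=False)

    def predict(self, x) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)

    def summary(self) -> str:
        return (
            f"y ~ 1 + x1  (n = {self.n})\n"
            f"  intercept  {self.beta0:.5g}  (SE = {self.se0:.5g}, "
            f"tStat = {self.t0:.4g}, p = {self.p0:.3g})\n"
            f"  x1         {self.beta1:.5g}  (SE = {self.se1:.5g}, "
            f"tStat = {self.t1:.4g}, p = {self.p1:.3g})\n"
            f"  F = {self.F:.4g} (p = {self.p_F:.3g}), "
            f"R2 = {self.R2:.3f} (adj {self.adjR2:.3f}), RMSE = {self.RMSE:.3g}"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": [self.beta0, self.beta1],
             "SE": [self.se0, self.se1],
             "tStat": [self.t0, self.t1],
             "p": [self.p0, self.p1]},
            index=["intercept", "x1"])


def fit_ols(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Closed-form simple OLS of y on x.

    beta1 = Sxy/Sxx, beta0 = ybar - beta1*xbar; residual variance is
    SSE/(n-2); RMSE = sqrt(SSE/(n-2)); R2 = 1 - SSE/SST; the 95% CI band
    at each x uses the usual mean-response standard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("fit_ols needs n >= 3 paired observations")
    xbar, ybar = x.mean(), y.mean()
    dx = x - xbar
    Sxx = float(dx @ dx)
    if Sxx <= 0:
        raise ValueError("degenerate design: x is constant")
    beta1 = float(dx @ (y - ybar)) / Sxx
    beta0 = ybar - beta1 * xbar
    resid = y - (beta0 + beta1 * x)
    SSE = float(resid @ resid)
    SST = float((y - ybar) @ (y - ybar))
    df = n - 2
    s2 = SSE / df
    RMSE = math.sqrt(s2)
    se1 = math.sqrt(s2 / Sxx)
    se0 = math.sqrt(s2 * (1.0 / n + xbar ** 2 / Sxx))
    # a perfect fit has zero residual variance; report infinite t (p = 0)
    t0 = beta0 / se0 if se0 > 0 else math.copysign(math.inf, beta0)
    t1 = beta1 / se1 if se1 > 0 else (
        math.copysign(math.inf, beta1) if beta1 != 0 else 0.0)
    F = t1 ** 2
    p0 = 2 * stats.t.sf(abs(t0), df)
    p1 = 2 * stats.t.sf(abs(t1), df)
    p_F = stats.f.sf(F, 1, df)
    R2 = 1.0 - SSE / SST if SST > 0 else 1.0
    adjR2 = 1.0 - (1.0 - R2) * (n - 1) / df
    tcrit = stats.t.ppf(0.975, df)
    se_mean = np.sqrt(s2 * (1.0 / n + dx ** 2 / Sxx))
    yhat = beta0 + beta1 * x
    return RegressionResult(
        beta0=beta0, beta1=beta1, se0=se0, se1=se1, t0=t0, t1=t1,
        p0=p0, p1=p1, F=F, p_F=p_F, R2=R2, adjR2=adjR2, RMSE=RMSE, n=n,
        x=x, ci95_lower=yhat - tcrit * se_mean, ci95_upper=yhat + tcrit * se_mean)


def learning_curves(scores: pd.DataFrame,
                    grouping: str = "pooled") -> Dict[str, RegressionResult]:
    """Learning-curve regressions over a tidy score table.

    Parameters
    ----------
    scores:
        DataFrame with at least columns ``score`` and ``day``; rows must be
        in trial order.  The pooled fit regresses score on the pooled
        observation index 0..n-1; per-day fits use the within-day index.
    grouping:
        ``"pooled"`` or ``"per-day"``.

    Returns
    -------
    dict mapping ``"pooled"`` or ``"day<k>"`` to RegressionResult.  Days
    with fewer than 3 trials are skipped with a warning.
    """
    if grouping not in ("pooled", "per-day"):
        raise ValueError("grouping must be 'pooled' or 'per-day'")
    out: Dict[str, RegressionResult] = {}
    if grouping == "pooled":
        y = scores["score"].to_numpy(dtype=float)
        out["pooled"] = fit_ols(np.arange(len(y), dtype=float), y)
        return out
    for day, grp in scores.groupby("day", sort=True):
        y = grp["score"].to_numpy(dtype=float)
        if len(y) < 3:
            logger.warning("day %s has fewer than 3 trials; skipped", day)
            continue
        out[f"day{day}"] = fit_ols(np.arange(len(y), dtype=float), y)
    return out
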