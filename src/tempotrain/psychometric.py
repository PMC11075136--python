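"""Psychometric model of keyword recognition under time compression.

A listener's probability of repeating a keyword correctly is modelled as a
decreasing logistic function of the time-compression ratio (percent duration
removed; faster speech is harder).  The quantity of interest is the
50%-correct compression ratio — the time-compression threshold — extracted
from a block of adaptive-track trials by maximum-likelihood fitting of this
curve to the keyword counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit


class InvalidParameterError(ValueError):
    """Psychometric parameters outside their admissible range."""


class EmptyTrialsError(ValueError):
    """A fit was requested on an empty block."""


class DegenerateDesignError(ValueError):
    """The block visited too few distinct levels to identify a 2-parameter fit."""


#: plausible range the fitted threshold is clamped to (% compression)
THRESHOLD_BOUNDS = (-50.0, 150.0)
#: admissible slope range for the optimizer (per %-compression)
SLOPE_BOUNDS = (0.01, 2.0)
#: optimizer start value for the slope
SLOPE_START = 0.1


@dataclass(frozen=True)
class PsychometricCurve:
    """Decreasing logistic curve for keyword-correct probability.

    Parameters
    ----------
    threshold_c50
        Compression ratio (%) at which keyword-correct probability is 0.5
        (exactly, when ``lapse`` is 0).
    slope
        Logistic steepness per percent compression; must be positive.
    lapse
        Upper-asymptote shortfall in [0, 0.1]: even at very slow speech the
        listener tops out at ``1 - lapse``.
    """

    threshold_c50: float
    slope: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise InvalidParameterError(f"slope must be positive, got {self.slope}")
        if not 0.0 <= self.lapse <= 0.1:
            raise InvalidParameterError(f"lapse must be in [0, 0.1], got {self.lapse}")


def _prob(curve: PsychometricCurve, level) -> np.ndarray | float:
    """Curve evaluation without the stimulus-range precondition (internal)."""
    return (1.0 - curve.lapse) * expit(-curve.slope * (np.asarray(level, float) - curve.threshold_c50))


def prob_keyword_correct(curve: PsychometricCurve, level) -> np.ndarray | float:
    """Probability of a single keyword being repeated correctly at ``level``.

    ``level`` is a compression ratio strictly inside (0, 100); scalars and
    arrays are accepted.
    """
    lv = np.asarray(level, dtype=float)
    if np.any(lv <= 0.0) or np.any(lv >= 100.0):
        raise ValueError(f"compression level must lie in (0, 100), got {level}")
    out = _prob(curve, lv)
    return float(out) if np.isscalar(level) or np.ndim(level) == 0 else out


@dataclass(frozen=True)
class BlockFit:
    """Result of fitting one adaptive block.

    ``fallback_used`` marks blocks where the likelihood surface was
    degenerate (no 50% crossing, or optimizer failure) and the threshold is
    the reversal average instead of the MLE.
    """

    curve: PsychometricCurve
    converged: bool
    fallback_used: bool
    log_likelihood: float
    n_trials: int

    @property
    def threshold(self) -> float:
        return self.curve.threshold_c50

    def as_dict(self) -> dict:
        return {
            "threshold": self.curve.threshold_c50,
            "slope": self.curve.slope,
            "lapse": self.curve.lapse,
            "converged": self.converged,
            "fallback_used": self.fallback_used,
            "log_likelihood": self.log_likelihood,
            "n_trials": self.n_trials,
        }


def reversal_average(trials: Sequence) -> float:
    """Fallback threshold estimator: mean of reversal levels.

    Falls back to the mean of all visited levels when fewer than two
    reversals occurred.
    """
    rev = [t.level for t in trials if t.is_reversal]
    if len(rev) >= 2:
        return float(np.mean(rev))
    return float(np.mean([t.level for t in trials]))


def _neg_loglik(params, levels, successes, totals, lapse):
    c50, slope = params
    p = (1.0 - lapse) * expit(-slope * (levels - c50))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -float(np.sum(successes * np.log(p) + (totals - successes) * np.log1p(-p)))


def fit_block(
    trials: Sequence,
    *,
    lapse: float = 0.0,
    scoring: str = "keyword",
    keywords_per_sentence: int = 5,
    correct_majority: int = 3,
) -> BlockFit:
    """Fit the logistic curve to a block of trials and extract the threshold.

    ``trials`` is any sequence of records exposing ``level``, ``n_correct``
    and ``is_reversal`` (see :class:`tempotrain.staircase.TrialRecord`).

    scoring
        ``"keyword"`` (default): each of the 5 keywords is a Bernoulli draw,
        binomial likelihood on the counts.  ``"sentence"``: the trial is
        scored as a single binary outcome, correct iff at least
        ``correct_majority`` keywords were repeated; the fitted curve is then
        the sentence-correct probability and the threshold its 50% point
        (equal to the keyword 50% point for independent keywords).
    """
    if len(trials) == 0:
        raise EmptyTrialsError("cannot fit an empty block")
    if scoring not in ("keyword", "sentence"):
        raise ValueError(f"unknown scoring convention: {scoring!r}")

    levels = np.array([t.level for t in trials], dtype=float)
    counts = np.array([t.n_correct for t in trials], dtype=float)
    if scoring == "keyword":
        successes, totals = counts, np.full_like(counts, keywords_per_sentence)
    else:
        successes = (counts >= correct_majority).astype(float)
        totals = np.ones_like(counts)

    if np.unique(levels).size < 2:
        raise DegenerateDesignError(
            "all trials at a single level: 2-parameter fit is unidentifiable"
        )

    def _fallback() -> BlockFit:
        thr = reversal_average(trials)
        curve = PsychometricCurve(thr, SLOPE_START, lapse)
        ll = -_neg_loglik((thr, SLOPE_START), levels, successes, totals, lapse)
        return BlockFit(curve, converged=False, fallback_used=True,
                        log_likelihood=ll, n_trials=len(trials))

    # No 50% crossing: responses never straddle the majority criterion, so
    # the MLE threshold runs away to a bound.  Use the reversal average.
    frac = successes / totals
    if np.all(frac >= 0.5) or np.all(frac < 0.5):
        return _fallback()

    x0 = (float(np.mean(levels)), SLOPE_START)
    res = minimize(
        _neg_loglik,
        x0,
        args=(levels, successes, totals, lapse),
        method="L-BFGS-B",
        bounds=[THRESHOLD_BOUNDS, SLOPE_BOUNDS],
    )
    if not res.success or not np.isfinite(res.x[0]):
        return _fallback()

    c50 = float(np.clip(res.x[0], *THRESHOLD_BOUNDS))
    curve = PsychometricCurve(c50, float(res.x[1]), lapse)
    return BlockFit(curve, converged=True, fallback_used=False,
                    log_likelihood=-float(res.fun), n_trials=len(trials))
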