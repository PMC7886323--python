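"""Relative-fitness estimation from pairwise competition time courses.

Fitness is the slope of ln(count_a / count_b) against generation — the
difference in Malthusian parameters between the two competitors, in units
of per generation.  Frequency-dependent selection is detected by analysing
each sampling interval independently: the interval's fitness is regressed
on the starting frequency of competitor a, and a significantly positive
slope with a zero-crossing inside (0, 1) marks a bistable equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simcore.sim_types import CompetitionTimecourse


class BoundaryOutcomeError(ValueError):
    """A competitor fixed or was lost: no slope is defined.

    Raised when fewer than two timepoints have both counts positive; the
    ``outcome`` attribute reports which competitor reached the boundary and
    at which generation.
    """

    def __init__(self, outcome: str, generation: int):
        self.outcome = outcome
        self.generation = generation
        super().__init__(f"{outcome} at generation {generation}")


@dataclass
class FitnessEstimate:
    s_hat: float  # per generation, for competitor a relative to b
    stderr: float | None  # absent with exactly two timepoints
    n_timepoints: int
    orientation: str = "a_vs_b"


@dataclass
class IntervalEstimate:
    f0: float  # frequency of competitor a at the interval start
    s_hat: float  # per generation
    gen_start: int
    gen_end: int


@dataclass
class FreqDependence:
    slope: float  # d s / d f0
    intercept: float
    classification: str  # positive | negative | none
    f_star: float | None  # bistable equilibrium frequency, if any
    alpha: float
    p_value: float


def _usable_window(tc: CompetitionTimecourse):
    """Timepoints up to (excluding) the first zero count."""
    usable = []
    for tp in tc.timepoints:
        if tp.count_a <= 0 or tp.count_b <= 0:
            break
        usable.append(tp)
    return usable


def log_ratio_slope(tc: CompetitionTimecourse) -> FitnessEstimate:
    """OLS slope of ln(count_a/count_b) on generation over the usable window.

    Zero-count timepoints terminate the usable window (no pseudocounts); if
    fewer than two usable timepoints remain, a :class:`BoundaryOutcomeError`
    reports fixation/loss instead of a slope.
    """
    usable = _usable_window(tc)
    if len(usable) < 2:
        first_bad = tc.timepoints[len(usable)]
        outcome = "a_lost" if first_bad.count_a <= 0 else "a_fixed"
        raise BoundaryOutcomeError(outcome, first_bad.generation)
    gens = np.array([tp.generation for tp in usable], dtype=float)
    logratio = np.log([tp.count_a / tp.count_b for tp in usable])
    if len(usable) == 2:
        s = float((logratio[1] - logratio[0]) / (gens[1] - gens[0]))
        return FitnessEstimate(s, None, 2)
    res = stats.linregress(gens, logratio)
    return FitnessEstimate(float(res.slope), float(res.stderr), len(usable))


def interval_fitness(
    tc: CompetitionTimecourse,
) -> tuple[list[IntervalEstimate], list[tuple[int, int]]]:
    """Per-interval fitness: each consecutive timepoint pair independently.

    Returns (estimates, flagged) where ``flagged`` lists the (gen_start,
    gen_end) of intervals excluded because a count was zero.
    """
    if len(tc.timepoints) < 2:
        raise ValueError("need at least two timepoints")
    estimates, flagged = [], []
    for a, b in zip(tc.timepoints[:-1], tc.timepoints[1:]):
        if min(a.count_a, a.count_b, b.count_a, b.count_b) <= 0:
            flagged.append((a.generation, b.generation))
            continue
        dg = b.generation - a.generation
        s = (np.log(b.count_a / b.count_b) - np.log(a.count_a / a.count_b)) / dg
        estimates.append(
            IntervalEstimate(
                f0=a.count_a / a.sample_size,
                s_hat=float(s),
                gen_start=a.generation,
                gen_end=b.generation,
            )
        )
    return estimates, flagged


def frequency_dependence(
    intervals: list[IntervalEstimate], alpha: float = 0.01
) -> FreqDependence:
    """Regress per-interval fitness on starting frequency.

    Classification is positive/negative when the slope's two-sided t-test
    rejects at ``alpha`` with the corresponding sign, else none.  For a
    positive classification the fitted zero crossing -intercept/slope is
    reported as the bistable equilibrium f* when it lies in (0, 1).
    """
    if len(intervals) < 3:
        raise ValueError("need at least 3 intervals")
    f0 = np.array([iv.f0 for iv in intervals])
    s = np.array([iv.s_hat for iv in intervals])
    if np.allclose(f0, f0[0]):
        raise ValueError("all starting frequencies identical: no contrast")
    res = stats.linregress(f0, s)
    slope, intercept = float(res.slope), float(res.intercept)
    p = float(res.pvalue)
    if np.isnan(p):
        # zero residual variance: an exact fit; classify by the slope itself
        p = 0.0 if abs(slope) > 1e-12 else 1.0
    classification = "none"
    if p < alpha:
        classification = "positive" if slope > 0 else "negative"
    f_star = None
    if classification == "positive":
        crossing = -intercept / slope
        if 0.0 < crossing < 1.0:
            f_star = float(crossing)
    return FreqDependence(slope, intercept, classification, f_star, alpha, p)


def pooled_estimate(estimates: list[FitnessEstimate]) -> float:
    """Unweighted mean of per-competition fitness estimates."""
    if not estimates:
        raise ValueError("no estimates to pool")
    return float(np.mean([e.s_hat for e in estimates]))
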