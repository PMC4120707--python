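"""Cue-weight algebra for gaze-direction perception.

The points of subjectively direct gaze are regressed on head orientation;
the slope ``m`` of that line determines the relative weighting of eye
deviation E and head orientation H in the percept
``G = (1 / (1 - m)) E + (m / (m - 1)) H``, with the two weights
constrained to sum to one. A negative head weight is a repulsive effect.

Fitting the slope separately for the whole-head (``m_WH``) and eye-region
(``m_ER``) conditions lets the whole-head percept be decomposed into the
eye-region route and a direct head route:
``G_WH = ((1 - m_ER) / (1 - m_WH)) G_ER + ((m_WH - m_ER) / (m_WH - 1)) H``,
again with weights summing to one. A positive direct weight means head
orientation attracts perceived gaze when the head context is visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_SINGULAR_TOL = 1e-12


@dataclass
class CueWeightEstimate:
    """Regression slope and the implied eye/head weights for one condition."""

    condition: str
    slope_m: float
    intercept_deg: float
    w_eye: float
    w_head: float


@dataclass
class DualRouteDecomposition:
    """Whole-head weights split into eye-region route vs direct head route."""

    m_wh: float
    m_er: float
    w_er_route: float
    w_direct: float


@dataclass
class GroupTest:
    """One-sample t test against a null mean, with Cohen's d = mean / SD."""

    mean: float
    t_statistic: float
    df: int
    p_value: float
    cohen_d: float


def fit_slope(head_orientations_deg, direct_gaze_points_deg) -> tuple[float, float]:
    """OLS line through the direct-gaze points: returns (slope m, intercept)."""
    x = np.asarray(head_orientations_deg, dtype=float)
    y = np.asarray(direct_gaze_points_deg, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct head orientations")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def weights_from_slope(m: float) -> tuple[float, float]:
    """Eye and head weights (1/(1-m), m/(m-1)) implied by slope ``m``.

    The pair sums to one exactly; ``m = 1`` (head fully determines the
    direct-gaze point) is a singularity.
    """
    if abs(m - 1.0) < _SINGULAR_TOL:
        raise ZeroDivisionError("slope m = 1: cue weights are undefined")
    w_eye = 1.0 / (1.0 - m)
    w_head = m / (m - 1.0)
    return float(w_eye), float(w_head)


def cue_weight_estimate(
    condition: str, head_orientations_deg, direct_gaze_points_deg
) -> CueWeightEstimate:
    """Slope regression plus weight conversion for one condition."""
    m, intercept = fit_slope(head_orientations_deg, direct_gaze_points_deg)
    w_eye, w_head = weights_from_slope(m)
    return CueWeightEstimate(condition, m, intercept, w_eye, w_head)


def decompose(m_wh: float, m_er: float) -> DualRouteDecomposition:
    """Split the whole-head percept into eye-region and direct head routes.

    ``w_er_route = (1 - m_ER) / (1 - m_WH)`` weights the eye-region
    signal; ``w_direct = (m_WH - m_ER) / (m_WH - 1)`` weights head
    orientation as a direct cue. The two sum to one. ``w_direct`` is
    positive exactly when the repulsive shift is smaller with the head
    visible than with it occluded.
    """
    if abs(m_wh - 1.0) < _SINGULAR_TOL:
        raise ZeroDivisionError("slope m_WH = 1: decomposition is undefined")
    w_er_route = (1.0 - m_er) / (1.0 - m_wh)
    w_direct = (m_wh - m_er) / (m_wh - 1.0)
    return DualRouteDecomposition(float(m_wh), float(m_er), float(w_er_route), float(w_direct))


def group_t_test(per_subject_values, null_mean: float = 0.0) -> GroupTest:
    """Two-sided one-sample t test across subjects, with Cohen's d."""
    values = np.asarray(per_subject_values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two subjects")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across subjects: t is undefined")
    res = stats.ttest_1samp(values, popmean=null_mean)
    mean = float(values.mean())
    return GroupTest(
        mean=mean,
        t_statistic=float(res.statistic),
        df=len(values) - 1,
        p_value=float(res.pvalue),
        cohen_d=(mean - null_mean) / float(sd),
    )
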