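"""Trinomial categorization model of direct-gaze judgments.

The internal representation of a gaze stimulus at eye deviation ``g`` is
Gaussian with mean ``g`` and SD ``sigma_rep``; a response is "left" when
the sample falls below criterion ``b_L``, "right" above ``b_R``, and
"direct" in between — the probability of each category is the area of
the Gaussian over the corresponding interval. Fitting the three
parameters (b_L, b_R, sigma_rep) to the left/direct/right counts per eye
deviation by maximum product-multinomial likelihood yields, per head
orientation:

- the *peak* of perceptually direct gaze, the criterion midpoint
  ``(b_L + b_R) / 2``;
- the *width* of the cone of direct gaze, ``b_R - b_L`` (inverse
  specificity);
- ``sigma_rep`` (inverse sensitivity).

Two model-free measures accompany the fit: the *centroid* of the direct
responses (proportion-direct-weighted mean eye deviation, robust at
small trial counts) and the overall proportion of direct responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

_P_FLOOR = 1e-12

COUNT_COLUMNS = ["eye_deviation_deg", "n_left", "n_direct", "n_right"]


def category_probabilities(g_deg, b_l: float, b_r: float, sigma: float):
    """(p_left, p_direct, p_right) for stimuli at ``g_deg``.

    p_left = Phi((b_L - g)/sigma), p_right = 1 - Phi((b_R - g)/sigma),
    p_direct the remaining Gaussian mass between the criteria.
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not b_l < b_r:
        raise ValueError("left criterion must lie below the right criterion")
    g = np.asarray(g_deg, dtype=float)
    p_left = ndtr((b_l - g) / sigma)
    cdf_r = ndtr((b_r - g) / sigma)
    return p_left, cdf_r - p_left, 1.0 - cdf_r


@dataclass
class CategoryModelFit:
    """MLE of the two criteria and the sensory noise, with derived measures."""

    boundary_left_deg: float
    boundary_right_deg: float
    sigma_rep_deg: float
    log_likelihood: float
    n_trials: int

    def __post_init__(self) -> None:
        if not self.boundary_left_deg < self.boundary_right_deg:
            raise ValueError("fit invariant violated: b_L >= b_R")
        if not self.sigma_rep_deg > 0:
            raise ValueError("fit invariant violated: sigma <= 0")

    @property
    def peak_deg(self) -> float:
        """Peak direction of perceptually direct gaze (criterion midpoint)."""
        return 0.5 * (self.boundary_left_deg + self.boundary_right_deg)

    @property
    def width_deg(self) -> float:
        """Width of the cone of direct gaze (criterion separation)."""
        return self.boundary_right_deg - self.boundary_left_deg


def counts_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Tabulate left/direct/right counts per eye deviation for one cell."""
    tab = (
        trials.groupby("eye_deviation_deg")["response"]
        .value_counts()
        .unstack(fill_value=0)
    )
    for full, short in (("left", "L"), ("direct", "D"), ("right", "R")):
        col = full if full in tab.columns else (short if short in tab.columns else None)
        tab[f"n_{full}"] = tab[col] if col is not None else 0
    out = tab.reset_index()[COUNT_COLUMNS].copy()
    out[["n_left", "n_direct", "n_right"]] = out[
        ["n_left", "n_direct", "n_right"]
    ].astype(int)
    return out


def log_likelihood(counts: pd.DataFrame, b_l: float, b_r: float, sigma: float) -> float:
    """Product-multinomial log likelihood of the counts under the model."""
    g = counts["eye_deviation_deg"].to_numpy(dtype=float)
    n = counts[["n_left", "n_direct", "n_right"]].to_numpy(dtype=float)
    p = np.column_stack(category_probabilities(g, b_l, b_r, sigma))
    return float(np.sum(n * np.log(np.maximum(p, _P_FLOOR))))


def _moment_init(counts: pd.DataFrame) -> tuple[float, float, float]:
    """Moment-based starting values: peak, width and sigma from the data."""
    g = counts["eye_deviation_deg"].to_numpy(dtype=float)
    n = counts[["n_left", "n_direct", "n_right"]].to_numpy(dtype=float)
    span = max(np.ptp(g), 1.0)
    totals = n.sum(axis=1)
    with np.errstate(invalid="ignore"):
        p_direct = np.divide(n[:, 1], totals, out=np.zeros_like(totals), where=totals > 0)
    if p_direct.sum() > 0:
        peak0 = float(np.sum(g * p_direct) / p_direct.sum())
        width0 = float(max(span * p_direct.mean(), span / 20.0))
    else:
        peak0, width0 = float(np.median(g)), span / 20.0
    sigma0 = span / 6.0
    return peak0, width0, sigma0


def fit_category_model(
    counts: pd.DataFrame, n_starts: int = 8, seed: int = 0
) -> CategoryModelFit:
    """Maximum-likelihood fit of (b_L, b_R, sigma_rep) to one counts table.

    The criteria are parameterized as midpoint +/- half-width with the
    width and sigma on a log scale, so the invariants b_L < b_R and
    sigma > 0 hold by construction. ``n_starts`` L-BFGS-B runs from
    jittered moment-based starting values guard against local optima.

    Raises on fewer than three usable eye-deviation levels, on data
    showing a single response category, and on total non-convergence
    (the best candidate is attached to the exception). Data with no
    direct responses at all trigger a boundary-collapse warning.
    """
    counts = counts.loc[counts[["n_left", "n_direct", "n_right"]].sum(axis=1) > 0]
    if len(counts) < 3:
        raise ValueError("need at least three eye-deviation levels with trials")
    cat_totals = counts[["n_left", "n_direct", "n_right"]].sum(axis=0)
    if (cat_totals > 0).sum() < 2:
        raise ValueError("need at least two observed response categories")
    if cat_totals["n_direct"] == 0:
        warnings.warn(
            "no direct responses anywhere: criteria may collapse onto each other",
            stacklevel=2,
        )

    g_arr = counts["eye_deviation_deg"].to_numpy(dtype=float)
    n_arr = counts[["n_left", "n_direct", "n_right"]].to_numpy(dtype=float)

    def nll(theta):
        peak, log_w, log_s = theta
        half = 0.5 * np.exp(log_w)
        sigma = np.exp(log_s)
        p_left = ndtr((peak - half - g_arr) / sigma)
        cdf_r = ndtr((peak + half - g_arr) / sigma)
        p = np.column_stack([p_left, cdf_r - p_left, 1.0 - cdf_r])
        return -float(np.sum(n_arr * np.log(np.maximum(p, _P_FLOOR))))

    peak0, width0, sigma0 = _moment_init(counts)
    rng = np.random.default_rng(seed)
    span = max(np.ptp(counts["eye_deviation_deg"].to_numpy(dtype=float)), 1.0)
    best = None
    converged = False
    for start in range(n_starts):
        x0 = np.array([peak0, np.log(width0), np.log(sigma0)])
        if start > 0:
            x0 += rng.normal(0.0, [span / 8.0, 0.4, 0.4])
        res = minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    peak, log_w, log_s = best.x
    half = 0.5 * float(np.exp(log_w))
    fit = CategoryModelFit(
        boundary_left_deg=float(peak - half),
        boundary_right_deg=float(peak + half),
        sigma_rep_deg=float(np.exp(log_s)),
        log_likelihood=-float(best.fun),
        n_trials=int(counts[["n_left", "n_direct", "n_right"]].to_numpy().sum()),
    )
    if not converged:
        err = RuntimeError("category-model fit did not converge from any start")
        err.best_candidate = fit  # type: ignore[attr-defined]
        raise err
    return fit


def centroid_direct(eye_deviations_deg, proportion_direct) -> float:
    """Proportion-direct-weighted mean eye deviation.

    A model-free locator of subjectively direct gaze that is less
    sensitive to trial count than the fitted peak. Returns NaN when no
    direct responses were recorded.
    """
    g = np.asarray(eye_deviations_deg, dtype=float)
    p = np.asarray(proportion_direct, dtype=float)
    total = p.sum()
    if total <= 0:
        warnings.warn("no direct responses: centroid undefined", stacklevel=2)
        return float("nan")
    return float(np.sum(g * p) / total)


def proportion_direct_overall(trials: pd.DataFrame) -> float:
    """Fraction of direct responses among all trials of one cell."""
    if len(trials) == 0:
        raise ValueError("no trials")
    return float(trials["response"].isin(["direct", "D"]).mean())


def fit_category_table(
    trials: pd.DataFrame,
    level: str = "subject",
    n_starts: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the model per condition x head orientation and tabulate.

    ``level="subject"`` fits every subject separately; ``level="group"``
    pools counts across subjects. The output is the tidy estimates table
    (one row per fit: peak, width, sigma, centroid, proportion direct,
    log likelihood) that downstream ANOVA-style analyses consume.
    """
    if level not in ("subject", "group"):
        raise ValueError("level must be 'subject' or 'group'")
    work = trials.copy()
    if level == "group":
        work["subject"] = "group"
    rows = []
    keys = ["subject", "condition", "head_orientation_deg"]
    for (subject, condition, head), cell in work.groupby(keys):
        counts = counts_from_trials(cell)
        fit = fit_category_model(counts, n_starts=n_starts, seed=seed)
        totals = counts[["n_left", "n_direct", "n_right"]].sum(axis=1).to_numpy()
        p_direct = counts["n_direct"].to_numpy() / totals
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "head_orientation_deg": head,
                "boundary_left_deg": fit.boundary_left_deg,
                "boundary_right_deg": fit.boundary_right_deg,
                "sigma_deg": fit.sigma_rep_deg,
                "peak_deg": fit.peak_deg,
                "width_deg": fit.width_deg,
                "centroid_deg": centroid_direct(counts["eye_deviation_deg"], p_direct),
                "prop_direct": proportion_direct_overall(cell),
                "loglik": fit.log_likelihood,
            }
        )
    return pd.DataFrame(rows)
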