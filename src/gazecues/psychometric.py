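"""Psychometric analysis of trinomial gaze judgments.

Responses are recoded (left = 0, direct = 0.5, right = 1) and averaged
into a proportion-rightward score per eye deviation. For each head
orientation the score is fitted with a two-parameter logistic
``psi(x) = 1 / (1 + exp(-(x - alpha) / beta))`` by weighted nonlinear
least squares; the location ``alpha`` is the 50% point, i.e. the eye
deviation of subjectively direct gaze (the PSE). Percentile-bootstrap
confidence intervals are obtained by resampling trials within each
eye-deviation cell.

Least squares (with weights equal to the number of trials per level) is
used rather than a binomial likelihood because the 0.5 recoding of
"direct" responses makes the score a trinomial mixture, not a Bernoulli
outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

_RECODE = {
    "left": 0.0,
    "direct": 0.5,
    "right": 1.0,
    "L": 0.0,
    "D": 0.5,
    "R": 1.0,
}

GROUP_KEYS = ["condition", "head_orientation_deg", "eye_deviation_deg"]


def recode(response: str) -> float:
    """Recode a categorical gaze response: left = 0, direct = 0.5, right = 1."""
    try:
        return _RECODE[response]
    except KeyError:
        raise ValueError(f"unknown response label: {response!r}") from None


def add_recoded_scores(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the trial table with a ``score`` column."""
    out = trials.copy()
    out["score"] = out["response"].map(_RECODE)
    if out["score"].isna().any():
        bad = out.loc[out["score"].isna(), "response"].unique()
        raise ValueError(f"unknown response labels: {list(bad)}")
    return out


def proportion_scores(
    trials: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Aggregate trials into proportion-rightward and proportion-direct.

    Groups by subject x condition x head orientation x eye deviation
    (columns present in ``trials``) and returns one row per cell with
    ``n_trials``, ``prop_rightward`` (mean recoded score) and
    ``prop_direct`` (fraction of "direct" responses).
    """
    scored = add_recoded_scores(trials)
    if by is None:
        by = [c for c in ["subject", *GROUP_KEYS] if c in scored.columns]
    scored["is_direct"] = scored["score"] == 0.5
    agg = (
        scored.groupby(by, as_index=False)
        .agg(
            n_trials=("score", "size"),
            prop_rightward=("score", "mean"),
            prop_direct=("is_direct", "mean"),
        )
        .sort_values(by)
        .reset_index(drop=True)
    )
    return agg


@dataclass
class PsychometricFit:
    """One logistic fit: location alpha (the PSE) and scale beta."""

    alpha_deg: float
    beta_deg: float
    head_orientation_deg: float = np.nan
    ci_low_deg: float = np.nan
    ci_high_deg: float = np.nan
    n_trials_per_level: float = np.nan


def logistic(x, alpha: float, beta: float):
    return expit((np.asarray(x, dtype=float) - alpha) / beta)


def fit_logistic(
    eye_deviations,
    proportions,
    counts=None,
    xtol: float = 1e-12,
) -> PsychometricFit:
    """Weighted least-squares logistic fit of proportion-rightward.

    ``counts`` (trials per level) enter as weights; omit for equal
    weighting. Raises if fewer than three distinct eye-deviation levels
    are given, if the proportions are constant, or if the fitted slope is
    negative (the score must increase with rightward eye deviation).
    Data saturated at 0/1 everywhere produce a boundary-fit warning with
    alpha clamped to the sampled range.
    """
    x = np.asarray(eye_deviations, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least three distinct eye-deviation levels")
    if np.ptp(p) == 0:
        raise ValueError("proportions are constant; the 50% point is undefined")
    w = np.ones_like(p) if counts is None else np.sqrt(np.asarray(counts, dtype=float))
    if np.polyfit(x, p, 1, w=w)[0] < 0:
        raise ValueError(
            "decreasing trend: proportion-rightward must increase with eye deviation"
        )

    span = np.ptp(x)
    alpha0 = float(x[np.argmin(np.abs(p - 0.5))])
    beta0 = span / 5.0

    def residuals(theta):
        return w * (logistic(x, theta[0], theta[1]) - p)

    sol = least_squares(
        residuals, x0=[alpha0, beta0], xtol=xtol, ftol=xtol, gtol=xtol, method="lm"
    )
    alpha, beta = sol.x
    if beta <= 0:
        raise ValueError(
            "fitted logistic is decreasing (beta <= 0); "
            "proportion-rightward must increase with eye deviation"
        )
    if alpha < x.min() or alpha > x.max():
        warnings.warn(
            "boundary fit: 50% point outside the sampled range; alpha clamped",
            stacklevel=2,
        )
        alpha = float(np.clip(alpha, x.min(), x.max()))
    n_level = np.nan if counts is None else float(np.mean(counts))
    return PsychometricFit(float(alpha), float(beta), n_trials_per_level=n_level)


def _fit_cell(cell: pd.DataFrame) -> PsychometricFit:
    return fit_logistic(
        cell["eye_deviation_deg"], cell["prop_rightward"], cell["n_trials"]
    )


def bootstrap_direct_point(
    trials: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the PSE of one data cell.

    ``trials`` holds every trial of one subject x condition x head
    orientation. Trials are resampled with replacement *within* each
    eye-deviation cell (stratified), proportions recomputed, and the
    logistic refitted; the interval is the percentile range of the
    resampled alphas. Raises if more than 20% of resample fits fail.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scored = add_recoded_scores(trials)
    groups = {
        float(g): sub["score"].to_numpy()
        for g, sub in scored.groupby("eye_deviation_deg")
    }
    levels = np.array(sorted(groups))
    rng = np.random.default_rng(seed)
    alphas = []
    failures = 0
    for _ in range(n_boot):
        props = np.empty(len(levels))
        counts = np.empty(len(levels))
        for i, lev in enumerate(levels):
            scores = groups[lev]
            take = rng.integers(0, len(scores), size=len(scores))
            props[i] = scores[take].mean()
            counts[i] = len(scores)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_logistic(levels, props, counts, xtol=1e-8)
            alphas.append(fit.alpha_deg)
        except ValueError:
            failures += 1
    if failures > 0.2 * n_boot:
        label = trials.iloc[0].to_dict() if len(trials) else {}
        cell = {k: label.get(k) for k in ("subject", "condition", "head_orientation_deg")}
        raise RuntimeError(f"bootstrap failed for more than 20% of resamples in cell {cell}")
    tail = (100.0 - ci) / 2.0
    lo, hi = np.percentile(alphas, [tail, 100.0 - tail])
    return float(lo), float(hi)


def fit_psychometric_table(
    trials: pd.DataFrame,
    level: str = "subject",
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one logistic per condition x head orientation.

    ``level="subject"`` fits each subject separately; ``level="group"``
    pools recoded scores across subjects before fitting (the
    group-average analysis). With ``n_boot > 0`` a bootstrap 95% interval
    for alpha is attached to every fit.

    Returns a tidy table: subject, condition, head_orientation_deg,
    alpha_deg, beta_deg, ci_low_deg, ci_high_deg, n_trials.
    """
    if level not in ("subject", "group"):
        raise ValueError("level must be 'subject' or 'group'")
    work = trials.copy()
    if level == "group":
        work["subject"] = "group"
    props = proportion_scores(work)
    rows = []
    boot_seed = np.random.SeedSequence(seed)
    keys = ["subject", "condition", "head_orientation_deg"]
    for (subject, condition, head), cell in props.groupby(keys):
        fit = _fit_cell(cell)
        ci_low = ci_high = np.nan
        if n_boot > 0:
            sub_trials = work[
                (work["subject"] == subject)
                & (work["condition"] == condition)
                & (work["head_orientation_deg"] == head)
            ]
            child = int(boot_seed.spawn(1)[0].generate_state(1)[0] % (2**31))
            ci_low, ci_high = bootstrap_direct_point(sub_trials, n_boot, seed=child)
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "head_orientation_deg": head,
                "alpha_deg": fit.alpha_deg,
                "beta_deg": fit.beta_deg,
                "ci_low_deg": ci_low,
                "ci_high_deg": ci_high,
                "n_trials": int(cell["n_trials"].sum()),
            }
        )
    return pd.DataFrame(rows)
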