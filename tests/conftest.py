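"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from gazecues.design import DesignSpec
from gazecues.observer import ObserverParams, PopulationSpec


@pytest.fixture
def main_spec() -> DesignSpec:
    """The default main-experiment design (1,080 trials, 6 blocks)."""
    return DesignSpec(seed=123)


@pytest.fixture
def study_observer() -> ObserverParams:
    """A single observer in the study regime: repulsive eye route,
    attractive direct route, small leftward bias."""
    return ObserverParams(
        w_eye_route_head=-0.25,
        w_direct_head=0.15,
        bias_deg=-1.0,
        sigma_rep_deg=3.0,
        boundary_left_deg=-4.0,
        boundary_right_deg=4.0,
        lapse_rate=0.0,
    )


@pytest.fixture
def study_population() -> PopulationSpec:
    """The simulated study population: 20 observers, eye-route head
    weight -0.25 +/- 0.05, direct head weight 0.15 +/- 0.05."""
    return PopulationSpec(n_observers=20, seed=2024)


def make_condition_design(
    condition: str,
    head_orientations=(-30.0, -15.0, 0.0, 15.0, 30.0),
    eye_deviations=(-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0),
    trials_per_cell: int = 1,
    subject: int = 0,
) -> pd.DataFrame:
    """Flat (unblocked) factorial design for one condition — a convenience
    for tests that need many repetitions of each cell."""
    rows = [
        {
            "subject": subject,
            "block": 1,
            "trial_index": i,
            "condition": condition,
            "identity": 1,
            "head_orientation_deg": h,
            "eye_deviation_deg": e,
        }
        for i, (h, e, _r) in enumerate(
            itertools.product(head_orientations, eye_deviations, range(trials_per_cell))
        )
    ]
    return pd.DataFrame(rows)


def grid_search_category_fit(
    counts: pd.DataFrame,
    b_grid: np.ndarray,
    sigma_grid: np.ndarray,
) -> tuple[float, float, float, float]:
    """Brute-force oracle for the trinomial categorization model.

    Enumerates every (b_L, b_R, sigma) triple with b_L < b_R on the given
    grids, evaluates the product-multinomial log likelihood with
    scipy.stats.norm directly (independent of the package's objective),
    and returns the best (b_L, b_R, sigma, loglik).
    """
    g = counts["eye_deviation_deg"].to_numpy(dtype=float)
    n = counts[["n_left", "n_direct", "n_right"]].to_numpy(dtype=float)
    best = (np.nan, np.nan, np.nan, -np.inf)
    for sigma in sigma_grid:
        # cdf[i, j] = P(sample < b_grid[i]) at level j
        cdf = norm.cdf((b_grid[:, None] - g[None, :]) / sigma)
        for i, j in itertools.combinations(range(len(b_grid)), 2):
            p = np.column_stack([cdf[i], cdf[j] - cdf[i], 1.0 - cdf[j]])
            ll = float(np.sum(n * np.log(np.maximum(p, 1e-12))))
            if ll > best[3]:
                best = (float(b_grid[i]), float(b_grid[j]), float(sigma), ll)
    return best


def simulate_counts(
    b_l: float, b_r: float, sigma: float, trials_per_level: int, rng: np.random.Generator,
    levels=(-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0),
) -> pd.DataFrame:
    """Multinomial draws from the trinomial model, via norm.cdf (oracle side)."""
    rows = []
    for g in levels:
        p_left = norm.cdf((b_l - g) / sigma)
        p_right = 1.0 - norm.cdf((b_r - g) / sigma)
        p = [p_left, 1.0 - p_left - p_right, p_right]
        n = rng.multinomial(trials_per_level, p)
        rows.append(
            {"eye_deviation_deg": g, "n_left": n[0], "n_direct": n[1], "n_right": n[2]}
        )
    return pd.DataFrame(rows)
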