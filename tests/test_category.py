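"""Trinomial categorization model: probabilities, MLE, derived measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from conftest import grid_search_category_fit, simulate_counts
from gazecues.category import (
    category_probabilities,
    centroid_direct,
    counts_from_trials,
    fit_category_model,
    log_likelihood,
    proportion_direct_overall,
)

LEVELS = np.array([-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0])


def expected_counts(b_l, b_r, sigma, n_per_level, levels=LEVELS) -> pd.DataFrame:
    """Deterministic counts proportional to the exact category areas."""
    p_l, p_d, p_r = category_probabilities(levels, b_l, b_r, sigma)
    return pd.DataFrame(
        {
            "eye_deviation_deg": levels,
            "n_left": np.round(n_per_level * p_l).astype(int),
            "n_direct": np.round(n_per_level * p_d).astype(int),
            "n_right": np.round(n_per_level * p_r).astype(int),
        }
    )


class TestCategoryProbabilities:
    def test_direct_area_for_unit_criteria(self):
        """Criteria one sigma either side of the stimulus: the direct area
        is the central normal mass 2*Phi(1) - 1."""
        sigma = 3.0
        _, p_direct, _ = category_probabilities(0.0, -sigma, sigma, sigma)
        assert p_direct == pytest.approx(2 * norm.cdf(1) - 1, abs=1e-12)

    def test_noiseless_limit_inside_cone(self):
        p = category_probabilities(1.0, -4.0, 4.0, 1e-9)
        assert p == pytest.approx((0.0, 1.0, 0.0), abs=1e-12)

    def test_symmetry_at_peak(self):
        p_l, _, p_r = category_probabilities(1.0, -3.0, 5.0, 2.5)
        assert p_l == pytest.approx(p_r, abs=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            category_probabilities(0.0, -4.0, 4.0, 0.0)
        with pytest.raises(ValueError):
            category_probabilities(0.0, 4.0, -4.0, 1.0)

    @given(
        g=st.floats(-30, 30),
        peak=st.floats(-10, 10),
        width=st.floats(0.1, 20),
        sigma=st.floats(0.1, 10),
    )
    @settings(max_examples=500, deadline=None)
    def test_probabilities_sum_to_one(self, g, peak, width, sigma):
        p = category_probabilities(g, peak - width / 2, peak + width / 2, sigma)
        assert sum(p) == pytest.approx(1.0, abs=1e-12)


class TestFitCategoryModel:
    def test_large_sample_recovery(self):
        """Counts generated exactly from (b_L = -4, b_R = 4, sigma = 3) at
        1e5 trials per level recover the parameters within 0.1."""
        counts = expected_counts(-4.0, 4.0, 3.0, 100_000)
        fit = fit_category_model(counts)
        assert fit.boundary_left_deg == pytest.approx(-4.0, abs=0.1)
        assert fit.boundary_right_deg == pytest.approx(4.0, abs=0.1)
        assert fit.sigma_rep_deg == pytest.approx(3.0, abs=0.1)
        assert fit.peak_deg == pytest.approx(0.0, abs=0.1)
        assert fit.width_deg == pytest.approx(8.0, abs=0.2)

    def test_mirror_symmetry(self):
        """Negating eye deviation and swapping left/right counts mirrors the
        fitted criteria and leaves sigma unchanged."""
        rng = np.random.default_rng(4)
        counts = simulate_counts(-6.0, 2.0, 3.0, 200, rng)
        mirrored = pd.DataFrame(
            {
                "eye_deviation_deg": -counts["eye_deviation_deg"],
                "n_left": counts["n_right"],
                "n_direct": counts["n_direct"],
                "n_right": counts["n_left"],
            }
        )
        fit = fit_category_model(counts)
        mfit = fit_category_model(mirrored)
        assert mfit.boundary_left_deg == pytest.approx(-fit.boundary_right_deg, abs=1e-3)
        assert mfit.boundary_right_deg == pytest.approx(-fit.boundary_left_deg, abs=1e-3)
        assert mfit.sigma_rep_deg == pytest.approx(fit.sigma_rep_deg, abs=1e-3)

    def test_mle_beats_grid_oracle(self):
        """On 20 random instances the MLE's log likelihood is at least the
        best of a brute-force 21x21x21 grid, and the parameters agree with
        the grid optimum within one grid step."""
        rng = np.random.default_rng(99)
        b_grid = np.linspace(-10.0, 10.0, 21)
        sigma_grid = np.linspace(0.5, 10.5, 21)
        for _ in range(20):
            b_l = rng.uniform(-8.0, -1.0)
            b_r = rng.uniform(1.0, 8.0)
            # sigma at or above half the level spacing keeps all three
            # parameters identifiable from 5-degree-spaced levels
            sigma = rng.uniform(2.0, 6.0)
            counts = simulate_counts(b_l, b_r, sigma, 50, rng)
            fit = fit_category_model(counts)
            gb_l, gb_r, gsigma, gll = grid_search_category_fit(counts, b_grid, sigma_grid)
            assert fit.log_likelihood >= gll - 1e-6
            assert abs(fit.boundary_left_deg - gb_l) <= np.diff(b_grid)[0]
            assert abs(fit.boundary_right_deg - gb_r) <= np.diff(b_grid)[0]
            assert abs(fit.sigma_rep_deg - gsigma) <= np.diff(sigma_grid)[0]

    def test_counts_from_trials_roundtrip(self):
        trials = pd.DataFrame(
            {
                "eye_deviation_deg": [0.0, 0.0, 0.0, 5.0, 5.0],
                "response": ["left", "direct", "right", "direct", "direct"],
            }
        )
        counts = counts_from_trials(trials)
        row0 = counts.set_index("eye_deviation_deg").loc[0.0]
        assert (row0[["n_left", "n_direct", "n_right"]] == [1, 1, 1]).all()
        assert counts.set_index("eye_deviation_deg").loc[5.0, "n_direct"] == 2

    def test_preconditions(self):
        counts = expected_counts(-4.0, 4.0, 3.0, 100).iloc[:2]
        with pytest.raises(ValueError, match="three eye-deviation"):
            fit_category_model(counts)
        one_category = pd.DataFrame(
            {
                "eye_deviation_deg": LEVELS,
                "n_left": 0,
                "n_direct": 10,
                "n_right": 0,
            }
        )
        with pytest.raises(ValueError, match="two observed"):
            fit_category_model(one_category)

    def test_no_direct_responses_warns(self):
        counts = pd.DataFrame(
            {
                "eye_deviation_deg": LEVELS,
                "n_left": (LEVELS < 0).astype(int) * 10,
                "n_direct": 0,
                "n_right": (LEVELS >= 0).astype(int) * 10,
            }
        )
        with pytest.warns(UserWarning, match="collapse"):
            fit_category_model(counts)

    def test_log_likelihood_matches_direct_formula(self):
        counts = expected_counts(-4.0, 4.0, 3.0, 30)
        ll = log_likelihood(counts, -3.0, 5.0, 2.0)
        manual = 0.0
        for _, row in counts.iterrows():
            p = category_probabilities(row["eye_deviation_deg"], -3.0, 5.0, 2.0)
            for n_cat, p_cat in zip(
                row[["n_left", "n_direct", "n_right"]], p
            ):
                manual += n_cat * np.log(max(p_cat, 1e-12))
        assert ll == pytest.approx(manual, abs=1e-9)


class TestDirectResponseMeasures:
    def test_centroid_symmetric(self):
        assert centroid_direct([-5.0, 0.0, 5.0], [0.2, 0.6, 0.2]) == pytest.approx(0.0)

    def test_centroid_point_mass(self):
        assert centroid_direct([-5.0, 0.0, 5.0], [0.0, 0.0, 0.7]) == pytest.approx(5.0)

    def test_centroid_undefined_without_direct(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(centroid_direct([-5.0, 5.0], [0.0, 0.0]))

    @pytest.mark.parametrize(
        "responses, expected",
        [
            (["direct"] * 4, 1.0),
            (["left", "right"], 0.0),
            (["direct"] * 27 + ["left"] * 40 + ["right"] * 41, 0.25),
        ],
    )
    def test_proportion_direct(self, responses, expected):
        trials = pd.DataFrame({"response": responses})
        assert proportion_direct_overall(trials) == pytest.approx(expected)
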