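"""Generative dual-route observer: percepts, responses, simulation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_condition_design
from gazecues.category import category_probabilities
from gazecues.design import generate_main_design
from gazecues.observer import (
    ObserverParams,
    PopulationSpec,
    perceive,
    respond,
    sample_population,
    simulate_experiment,
    simulate_trials,
)
from gazecues.psychometric import fit_psychometric_table
from gazecues.weights import fit_slope


def obs(**kwargs) -> ObserverParams:
    defaults = dict(
        w_eye_route_head=0.0,
        w_direct_head=0.0,
        bias_deg=0.0,
        sigma_rep_deg=3.0,
        boundary_left_deg=-4.0,
        boundary_right_deg=4.0,
        lapse_rate=0.0,
    )
    defaults.update(kwargs)
    return ObserverParams(**defaults)


class TestPerceive:
    def test_zero_head_weights_give_veridical_eyes(self):
        p = perceive(obs(), 5.0, 30.0, "whole_head", noise_draw=0.0)
        assert p.g_perceived_deg == pytest.approx(5.0)

    def test_repulsive_eye_route(self):
        """w = -0.25, E = 0, H = 30: the eye-region signal is repelled to -7.5."""
        p = perceive(obs(w_eye_route_head=-0.25), 0.0, 30.0, "eye_region", 0.0)
        assert p.g_eye_region_deg == pytest.approx(-7.5)
        assert p.g_perceived_deg == pytest.approx(-7.5)

    def test_direct_route_attraction_cancels_repulsion(self):
        """With d = 0.2 the direct pull exactly cancels the eye-route push:
        G = 0.8 * (-7.5) + 0.2 * 30 = 0."""
        o = obs(w_eye_route_head=-0.25, w_direct_head=0.2)
        p = perceive(o, 0.0, 30.0, "whole_head", 0.0)
        assert p.g_eye_region_deg == pytest.approx(-7.5)
        assert p.g_perceived_deg == pytest.approx(0.0)

    def test_direct_route_inactive_without_head_context(self):
        o = obs(w_eye_route_head=-0.25, w_direct_head=0.2)
        for condition in ("eye_region", "eyes_only"):
            p = perceive(o, 0.0, 30.0, condition, 0.0)
            assert p.g_perceived_deg == pytest.approx(-7.5)

    def test_noise_scales_with_sigma(self):
        p = perceive(obs(sigma_rep_deg=2.0), 0.0, 0.0, "whole_head", 1.5)
        assert p.g_perceived_deg == pytest.approx(3.0)

    def test_vectorized_matches_scalar(self):
        o = obs(w_eye_route_head=-0.3, w_direct_head=0.1, bias_deg=-1.0)
        e = np.array([-5.0, 0.0, 5.0])
        h = np.array([30.0, -15.0, 0.0])
        cond = np.array(["whole_head", "eye_region", "whole_head"])
        vec = perceive(o, e, h, cond, np.zeros(3))
        for i in range(3):
            s = perceive(o, e[i], h[i], cond[i], 0.0)
            assert vec.g_perceived_deg[i] == pytest.approx(s.g_perceived_deg)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            obs(sigma_rep_deg=0.0)
        with pytest.raises(ValueError):
            obs(boundary_left_deg=4.0, boundary_right_deg=-4.0)
        with pytest.raises(ValueError):
            obs(lapse_rate=1.0)


class TestRespond:
    @pytest.mark.parametrize(
        "g, expected", [(0.0, "direct"), (-10.0, "left"), (10.0, "right")]
    )
    def test_criterion_rule(self, g, expected):
        assert respond(obs(), g, np.random.default_rng(0)) == expected

    def test_full_lapse_is_uniform(self):
        """lapse_rate = 1 - eps makes responses near-uniform over categories."""
        o = obs(lapse_rate=0.999999)
        rng = np.random.default_rng(42)
        out = respond(o, np.full(10_000, 20.0), rng)
        freq = pd.Series(out).value_counts(normalize=True)
        assert freq.max() - freq.min() < 0.05
        assert set(freq.index) == {"left", "direct", "right"}

    def test_frequencies_match_trinomial_probabilities(self):
        """Monte-Carlo respond frequencies converge to the analytic category
        probabilities (total-variation distance < 0.02 at 10,000 draws)."""
        o = obs(sigma_rep_deg=3.0)
        rng = np.random.default_rng(7)
        for g in (-6.0, 0.0, 3.0):
            percepts = g + o.sigma_rep_deg * rng.standard_normal(10_000)
            out = pd.Series(respond(o, percepts, rng))
            emp = np.array([(out == r).mean() for r in ("left", "direct", "right")])
            exact = np.array(category_probabilities(g, -4.0, 4.0, 3.0))
            assert 0.5 * np.abs(emp - exact).sum() < 0.02


class TestSimulateExperiment:
    def test_trial_count_and_determinism(self, study_population, main_spec):
        designs = [generate_main_design(main_spec, i) for i in range(20)]
        trials = simulate_experiment(study_population, designs)
        assert len(trials) == 21_600
        again = simulate_experiment(study_population, designs)
        pd.testing.assert_frame_equal(trials, again)

    def test_noiseless_limit_is_deterministic_in_stimulus(self):
        o = obs(w_eye_route_head=-0.25, sigma_rep_deg=1e-9)
        design = make_condition_design("eye_region", trials_per_cell=3)
        trials = simulate_trials(o, design, np.random.default_rng(0))
        per_cell = trials.groupby(["head_orientation_deg", "eye_deviation_deg"])[
            "response"
        ].nunique()
        assert (per_cell == 1).all()

    def test_design_count_mismatch_rejected(self, study_population, main_spec):
        designs = [generate_main_design(main_spec, i) for i in range(3)]
        with pytest.raises(ValueError, match="design"):
            simulate_experiment(study_population, designs)

    def test_population_sampling_respects_invariants(self):
        spec = PopulationSpec(
            n_observers=50,
            sds={"sigma_rep_deg": 2.0, "lapse_rate": 0.05},
            seed=3,
        )
        for o in sample_population(spec):
            assert o.sigma_rep_deg > 0
            assert 0 <= o.lapse_rate < 1


class TestAnalyticSlopes:
    """The simulator's PSE moves linearly in head orientation with the
    closed-form slope; an attractive direct route flattens it."""

    def _fitted_slope(self, o: ObserverParams, condition: str) -> float:
        design = make_condition_design(condition, trials_per_cell=150)
        trials = simulate_trials(o, design, np.random.default_rng(11))
        fits = fit_psychometric_table(trials, level="subject")
        return fit_slope(fits["head_orientation_deg"], fits["alpha_deg"])[0]

    def test_eye_route_slope(self):
        """w = -0.25, d = 0: slope of the PSE on H is -w/(1-w) = 0.2."""
        o = obs(w_eye_route_head=-0.25, bias_deg=-1.0)
        assert self._fitted_slope(o, "eye_region") == pytest.approx(0.2, abs=0.02)

    def test_direct_route_reduces_slope(self):
        o = obs(w_eye_route_head=-0.25, w_direct_head=0.15, bias_deg=-1.0)
        m_wh = self._fitted_slope(o, "whole_head")
        m_er = self._fitted_slope(o, "eye_region")
        assert m_wh == pytest.approx(o.expected_slope("whole_head"), abs=0.02)
        assert m_wh < m_er

    def test_pse_matches_analytic_value(self):
        o = obs(w_eye_route_head=-0.25, w_direct_head=0.15, bias_deg=-1.0)
        design = make_condition_design("whole_head", trials_per_cell=150)
        trials = simulate_trials(o, design, np.random.default_rng(5))
        fits = fit_psychometric_table(trials, level="subject")
        for _, row in fits.iterrows():
            expected = o.expected_direct_gaze_point(
                "whole_head", row["head_orientation_deg"]
            )
            assert row["alpha_deg"] == pytest.approx(expected, abs=0.3)
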