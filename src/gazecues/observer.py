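"""Generative dual-route observer for trinomial gaze judgments.

The observer combines the eye-deviation cue E and the head-orientation
cue H in two stages, each with weights constrained to sum to one:

1. *Eye-region route* (always active). The visible eye region carries a
   head-contaminated gaze signal,
   ``G_ER = (1 - w) * E + w * H + bias``, where ``w`` is the eye-route
   head weight. Empirically ``w < 0``: rotating the head shifts the iris
   within the visible eye opening, so the signal is *repelled* from the
   head.

2. *Direct route* (only when the head context is visible). The final
   percept re-combines the eye-region signal with head orientation as a
   direct, attractive cue: ``G = (1 - d) * G_ER + d * H`` with direct
   weight ``d >= 0``. When the head is occluded (eye-region or eyes-only
   displays) ``G = G_ER``.

Gaussian sensory noise with standard deviation ``sigma_rep_deg`` is added
once, at the percept stage, and the noisy percept is categorized against
two criteria: left of ``boundary_left_deg`` -> "left", right of
``boundary_right_deg`` -> "right", otherwise "direct".

Closed-form consequences used throughout the tests: the point of
subjectively direct gaze moves linearly in H with slope
``m_ER = -w / (1 - w)`` when the head is hidden and
``m_WH = -((1 - d) w + d) / ((1 - d)(1 - w))`` when it is visible, and
the dual-route decomposition of (m_WH, m_ER) returns exactly ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

RESPONSES = ("left", "direct", "right")

#: Conditions in which the head context is visible to the observer.
HEAD_VISIBLE_CONDITIONS = frozenset({"whole_head"})


@dataclass
class ObserverParams:
    """Generative parameters of one dual-route observer.

    Parameters
    ----------
    w_eye_route_head
        Signed head weight inside the eye-region route (repulsive when
        negative). Unitless.
    w_direct_head
        Head weight of the direct route, active only when the head
        context is visible. Unitless, expected >= 0.
    bias_deg
        Constant response bias of the eye-region signal, degrees
        (negative = leftward).
    sigma_rep_deg
        SD of the Gaussian sensory noise on the percept, degrees.
    boundary_left_deg, boundary_right_deg
        Category criteria separating left / direct / right, degrees.
    lapse_rate
        Probability of a uniformly random response.
    """

    w_eye_route_head: float = -0.25
    w_direct_head: float = 0.15
    bias_deg: float = -1.0
    sigma_rep_deg: float = 3.0
    boundary_left_deg: float = -4.0
    boundary_right_deg: float = 4.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_rep_deg > 0:
            raise ValueError("sigma_rep_deg must be positive")
        if not self.boundary_left_deg < self.boundary_right_deg:
            raise ValueError("boundary_left_deg must lie below boundary_right_deg")
        if not 0 <= self.lapse_rate < 1:
            raise ValueError("lapse_rate must lie in [0, 1)")

    def expected_slope(self, condition: str) -> float:
        """Analytic slope of the direct-gaze point against head orientation."""
        w = self.w_eye_route_head
        m_er = -w / (1.0 - w)
        if condition not in HEAD_VISIBLE_CONDITIONS:
            return m_er
        d = self.w_direct_head
        return -((1.0 - d) * w + d) / ((1.0 - d) * (1.0 - w))

    def expected_direct_gaze_point(self, condition: str, head_orientation_deg: float) -> float:
        """Eye deviation whose mean percept hits the criterion midpoint."""
        midpoint = 0.5 * (self.boundary_left_deg + self.boundary_right_deg)
        w, d = self.w_eye_route_head, self.w_direct_head
        if condition in HEAD_VISIBLE_CONDITIONS:
            # (1-d)[(1-w)E + wH + bias] + dH = midpoint
            num = midpoint - (1.0 - d) * (w * head_orientation_deg + self.bias_deg) - d * head_orientation_deg
            return num / ((1.0 - d) * (1.0 - w))
        return (midpoint - w * head_orientation_deg - self.bias_deg) / (1.0 - w)


@dataclass
class PerceptSample:
    """Intermediate eye-region signal and the final perceived direction."""

    g_eye_region_deg: float
    g_perceived_deg: float


def perceive(
    obs: ObserverParams,
    eye_deviation_deg,
    head_orientation_deg,
    condition,
    noise_draw=0.0,
) -> PerceptSample:
    """Map a stimulus and a standard-normal deviate to a percept.

    Accepts scalars or equal-length arrays; ``condition`` may be a single
    string or an array of condition labels.
    """
    e = np.asarray(eye_deviation_deg, dtype=float)
    h = np.asarray(head_orientation_deg, dtype=float)
    z = np.asarray(noise_draw, dtype=float)
    w = obs.w_eye_route_head
    g_er = (1.0 - w) * e + w * h + obs.bias_deg
    if np.isscalar(condition) or isinstance(condition, str):
        head_visible = condition in HEAD_VISIBLE_CONDITIONS
    else:
        head_visible = np.isin(np.asarray(condition), list(HEAD_VISIBLE_CONDITIONS))
    d = obs.w_direct_head
    g_mean = np.where(head_visible, (1.0 - d) * g_er + d * h, g_er)
    g = g_mean + obs.sigma_rep_deg * z
    if g_er.ndim == 0:
        return PerceptSample(float(g_er), float(g))
    return PerceptSample(g_er, g)


def respond(obs: ObserverParams, percept, rng: np.random.Generator):
    """Categorize a percept as left / direct / right.

    With probability ``lapse_rate`` the response is uniform over the
    three categories; otherwise the noisy perceived direction is compared
    against the two criteria. ``percept`` may be a
    :class:`PerceptSample`, a scalar, or an array of perceived directions.
    """
    g = percept.g_perceived_deg if isinstance(percept, PerceptSample) else percept
    g = np.asarray(g, dtype=float)
    scalar = g.ndim == 0
    g = np.atleast_1d(g)
    idx = np.ones(g.shape, dtype=np.int64)  # default "direct"
    idx[g < obs.boundary_left_deg] = 0
    idx[g > obs.boundary_right_deg] = 2
    if obs.lapse_rate > 0:
        lapse = rng.random(g.shape) < obs.lapse_rate
        idx[lapse] = rng.integers(0, 3, size=int(lapse.sum()))
    out = np.array(RESPONSES, dtype=object)[idx]
    return str(out[0]) if scalar else out


def _default_sds() -> dict[str, float]:
    return {
        "w_eye_route_head": 0.05,
        "w_direct_head": 0.05,
        "bias_deg": 0.5,
        "sigma_rep_deg": 0.0,
        "boundary_left_deg": 0.0,
        "boundary_right_deg": 0.0,
        "lapse_rate": 0.0,
    }


@dataclass
class PopulationSpec:
    """Between-subject distribution of observer parameters.

    Each :class:`ObserverParams` field is drawn independently from a
    Gaussian with the given mean and SD, truncated (by rejection) to the
    field's valid domain. The defaults reproduce the study regime: a
    repulsive eye-route head weight of -0.25 +/- 0.05, a direct head
    weight of 0.15 +/- 0.05, a small leftward bias, sensory noise of 3°
    and criteria at +/-4°.
    """

    n_observers: int = 20
    means: ObserverParams = field(default_factory=ObserverParams)
    sds: dict[str, float] = field(default_factory=_default_sds)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("n_observers must be positive")
        if any(v < 0 for v in self.sds.values()):
            raise ValueError("population SDs must be non-negative")


def sample_population(spec: PopulationSpec) -> list[ObserverParams]:
    """Draw ``n_observers`` parameter sets from the population."""
    rng = np.random.default_rng(spec.seed)
    observers = []
    names = [f.name for f in fields(ObserverParams)]
    for _ in range(spec.n_observers):
        for _attempt in range(1000):
            draw = {
                name: rng.normal(getattr(spec.means, name), spec.sds.get(name, 0.0))
                for name in names
            }
            try:
                observers.append(ObserverParams(**draw))
                break
            except ValueError:
                continue
        else:  # pragma: no cover - requires pathological spec
            raise RuntimeError("could not sample valid observer parameters")
    return observers


def simulate_trials(
    obs: ObserverParams, design: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate one observer's responses to every row of a design table."""
    z = rng.standard_normal(len(design))
    percept = perceive(
        obs,
        design["eye_deviation_deg"].to_numpy(),
        design["head_orientation_deg"].to_numpy(),
        design["condition"].to_numpy(),
        z,
    )
    out = design.copy()
    out["response"] = respond(obs, percept.g_perceived_deg, rng)
    return out


def simulate_experiment(
    population: PopulationSpec | list[ObserverParams],
    designs: list[pd.DataFrame],
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a full experiment: one design table per observer.

    ``population`` is either a :class:`PopulationSpec` (observers are
    sampled from it, and its seed drives all randomness) or an explicit
    list of :class:`ObserverParams` (then ``seed`` must be given).
    Returns the concatenated trial table with a ``response`` column.
    """
    if isinstance(population, PopulationSpec):
        observers = sample_population(population)
        seed = population.seed if seed is None else seed
    else:
        observers = population
        if seed is None:
            raise ValueError("seed is required with an explicit observer list")
    if len(observers) != len(designs):
        raise ValueError(
            f"{len(observers)} observers but {len(designs)} designs; need one design per observer"
        )
    streams = np.random.SeedSequence(seed).spawn(len(observers))
    tables = [
        simulate_trials(obs, design, np.random.default_rng(stream))
        for obs, design, stream in zip(observers, designs, streams)
    ]
    return pd.concat(tables, ignore_index=True)
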