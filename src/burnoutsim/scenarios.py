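"""Persona scenarios and trajectory pattern analytics.

Three personas, differing only in seven parameters (two caps, two initial
levels, three switches), are simulated for 100 weeks from an identical
well-rested starting state:

* **P1 — burnout and learning from it**: medium goal relevance and
  expected consequences, all switches on.  Crashes once, learns, and
  settles at a sustainable level.
* **P2 — burnout and no learning**: high goal relevance and expected
  consequences, all switches off.  Trapped in a cycle of burnout
  episodes, regulated only by the limits of the body.
* **P3 — under pressure but coping**: medium initial levels but static
  caps on both variables.  Never enters a burnout episode and keeps
  self-efficacy stable.

Pattern analytics operationalize these descriptions: burnout episodes are
intervals where stress activation crosses an onset threshold and stays
elevated (with hysteresis) for a minimum duration, and a run is classified
as ``coping`` (no episode), ``single_episode_with_learning`` (one episode
followed by settling), or ``cyclic`` (recurring episodes or an episode
with no return to stability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .burnout import BurnoutParams, build_burnout_model, initial_burnout_state
from .engine import (
    ParameterError,
    RunConfig,
    TrajectorySet,
    ValidationError,
    run_simulation,
)
from .simplified import detect_settling_week

__all__ = [
    "PersonaSpec",
    "PatternReport",
    "EpisodeThresholds",
    "PERSONA_IDS",
    "REPORTED_VARIABLES",
    "persona_params",
    "run_persona",
    "count_episodes",
    "classify_trajectory",
]

#: The six variables reported by every persona run.
REPORTED_VARIABLES = (
    "demands",
    "mental_effort",
    "cognitive_and_emotional_functions",
    "self_efficacy",
    "capacity_for_effort",
    "stress_activation",
)

#: The seven persona-level parameters (everything else is shared).
PERSONA_FIELDS = (
    "maximum_expected_consequences",
    "maximum_work_goal_relevance",
    "work_goal_relevance0",
    "expected_consequences0",
    "switch_allow_expected_consequences_to_change",
    "switch_allow_work_goal_relevance_to_change",
    "switch_learning",
)


@dataclass(frozen=True)
class PersonaSpec:
    """A persona: an id, a label, and its seven parameter overrides."""

    id: str
    label: str
    overrides: dict[str, float]

    def __post_init__(self):
        unknown = set(self.overrides) - set(PERSONA_FIELDS)
        if unknown:
            raise ValidationError(
                f"persona overrides restricted to the scenario-table parameters; "
                f"got {sorted(unknown)}"
            )

    def params(self, base: BurnoutParams | None = None) -> BurnoutParams:
        base = base if base is not None else BurnoutParams()
        return replace(base, **self.overrides)


_PERSONAS = {
    "P1": PersonaSpec(
        id="P1",
        label="Burnout and learning from it",
        overrides={
            "maximum_expected_consequences": 1.0,
            "maximum_work_goal_relevance": 1.0,
            "work_goal_relevance0": 0.6,
            "expected_consequences0": 0.6,
            "switch_allow_expected_consequences_to_change": 1,
            "switch_allow_work_goal_relevance_to_change": 1,
            "switch_learning": 1,
        },
    ),
    "P2": PersonaSpec(
        id="P2",
        label="Burnout and no learning",
        overrides={
            "maximum_expected_consequences": 1.0,
            "maximum_work_goal_relevance": 1.0,
            "work_goal_relevance0": 0.9,
            "expected_consequences0": 0.9,
            "switch_allow_expected_consequences_to_change": 0,
            "switch_allow_work_goal_relevance_to_change": 0,
            "switch_learning": 0,
        },
    ),
    "P3": PersonaSpec(
        id="P3",
        label="Under pressure but coping",
        overrides={
            "maximum_expected_consequences": 0.5,
            "maximum_work_goal_relevance": 0.7,
            "work_goal_relevance0": 0.6,
            "expected_consequences0": 0.6,
            "switch_allow_expected_consequences_to_change": 1,
            "switch_allow_work_goal_relevance_to_change": 1,
            "switch_learning": 1,
        },
    ),
}

PERSONA_IDS = tuple(_PERSONAS)


def persona_params(persona_id: str) -> PersonaSpec:
    """The published parameterization of one persona (P1, P2 or P3)."""
    try:
        return _PERSONAS[persona_id]
    except KeyError:
        raise ValidationError(
            f"unknown persona '{persona_id}'; expected one of {', '.join(_PERSONAS)}"
        ) from None


def run_persona(spec: PersonaSpec | str,
                config: RunConfig | None = None) -> TrajectorySet:
    """Simulate one persona (default: 100 weeks at dt = 0.125).

    All personas start from the identical initial state; only the seven
    persona parameters differ.  The returned trajectory records every
    model variable, including the six reported ones.
    """
    if isinstance(spec, str):
        spec = persona_params(spec)
    if config is None:
        config = RunConfig(horizon=100.0, dt=0.125)
    params = spec.params()
    model = build_burnout_model(params)
    return run_simulation(model, config, initial_burnout_state(params))


# --------------------------------------------------------------------------
# Episodes and classification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EpisodeThresholds:
    """Hysteresis thresholds defining a burnout episode on stress.

    An episode opens when stress activation rises above ``onset`` and
    closes when it falls below ``release``; only intervals of at least
    ``min_duration`` weeks count.  The hysteresis band avoids chatter on
    noisy crossings.
    """

    onset: float = 0.65
    release: float = 0.4
    min_duration: float = 4.0

    def __post_init__(self):
        if not self.onset > self.release:
            raise ParameterError(
                f"onset ({self.onset}) must exceed release ({self.release})"
            )
        if self.min_duration < 0:
            raise ParameterError("min_duration must be nonnegative")


def count_episodes(stress_series, times, onset_threshold: float = 0.65,
                   release_threshold: float = 0.4,
                   min_duration: float = 4.0) -> list[tuple[float, float]]:
    """Maximal high-stress intervals under hysteresis thresholds.

    Returns ``(onset week, end week)`` pairs: each interval starts when
    stress crosses above the onset threshold and ends when it drops below
    the release threshold (or at the end of the record); intervals shorter
    than ``min_duration`` are discarded.
    """
    thresholds = EpisodeThresholds(onset_threshold, release_threshold, min_duration)
    stress = np.asarray(stress_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if stress.shape != times.shape:
        raise ValidationError("stress series and times must have equal length")
    episodes: list[tuple[float, float]] = []
    start: float | None = None
    for t, s in zip(times, stress):
        if start is None:
            if s > thresholds.onset:
                start = t
        elif s < thresholds.release:
            if t - start >= thresholds.min_duration:
                episodes.append((float(start), float(t)))
            start = None
    if start is not None and times[-1] - start >= thresholds.min_duration:
        episodes.append((float(start), float(times[-1])))
    return episodes


@dataclass
class PatternReport:
    """Result of classifying one trajectory."""

    episodes: list[tuple[float, float]]
    episode_count: int
    label: str
    settling_week: float | None


def classify_trajectory(traj: TrajectorySet,
                        thresholds: EpisodeThresholds | None = None,
                        settling_band: float = 0.02) -> PatternReport:
    """Classify a persona trajectory into one of three patterns.

    ``coping``: no burnout episode.  ``single_episode_with_learning``:
    exactly one episode, followed by settling of all six reported series
    (within ``settling_band`` of their final values) after the episode
    begins.  ``cyclic``: two or more episodes, or a single episode with no
    return to stability.
    """
    thresholds = thresholds or EpisodeThresholds()
    missing = [v for v in REPORTED_VARIABLES if v not in traj.series]
    if missing:
        raise ValidationError(f"trajectory lacks reported series: {', '.join(missing)}")
    episodes = count_episodes(
        traj["stress_activation"], traj.times,
        thresholds.onset, thresholds.release, thresholds.min_duration,
    )
    horizon = float(traj.times[-1])
    settling = detect_settling_week(
        traj.subset(REPORTED_VARIABLES), band=settling_band
    )
    settling_week = None if settling >= horizon else settling
    if len(episodes) == 0:
        label = "coping"
    elif len(episodes) == 1 and settling_week is not None \
            and settling_week >= episodes[0][0]:
        label = "single_episode_with_learning"
    else:
        label = "cyclic"
    return PatternReport(
        episodes=episodes,
        episode_count=len(episodes),
        label=label,
        settling_week=settling_week,
    )
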