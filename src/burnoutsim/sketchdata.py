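"""Synthetic retrospective burnout sketches and phase segmentation.

Recovered burnout patients, asked to sketch "graphs over time" of how they
perceived their episode, consistently produce a three-phase shape:

* **build-up** -- demands creep from low to high, effort follows, the need
  for recovery stays deceptively low for a long time and then rises
  steeply, while available resources stay low or dwindle;
* **crash** -- a peak in perceived demands and effort followed by a sudden
  drop, accompanied by a stress peak and a drop in perceived efficacy;
* **recovery** -- a plateau of lowered (but not absent) activity lasting
  one month to a year, then a gradual return of demands and effort.

No such sketch collection is publicly available, so this module generates
*synthetic* stand-ins: seed-controlled archetype records with exactly the
seven perceived tracks (amount of demands, effort, perceived efficacy,
appropriateness of resources, engagement, need for recovery, stress
responses) and three event timelines (interventions, work developments,
private developments), built from piecewise-linear segments plus optional
Gaussian noise, with the ground-truth phase boundaries attached.  Two
crash mechanisms are emulated: plain ``exhaustion``, and
``reward_withheld`` (effort invested but the expected reward does not
arrive), which additionally depresses engagement for a prolonged period.

The companion detector segments a sketch back into the three phases, and
:func:`compare_sim_to_sketch` scores how well a simulated trajectory
reproduces the qualitative shape of a sketch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .engine import TrajectorySet, ValidationError
from .simplified import detect_peak_week

__all__ = [
    "TRACK_NAMES",
    "TIMELINE_NAMES",
    "MECHANISMS",
    "ScenarioSketch",
    "PhaseAnnotation",
    "generate_sketch",
    "detect_phases",
    "sketch_features",
    "sketch_from_trajectory",
    "compare_sim_to_sketch",
    "compare_sketches",
    "DEFAULT_VARIABLE_MAPPING",
]

#: The seven perceived variables of the sketch task, in canonical order.
TRACK_NAMES = (
    "amount of demands",
    "effort",
    "perceived efficacy",
    "appropriateness of resources",
    "engagement",
    "need for recovery",
    "stress responses",
)

#: The three event timelines of the sketch template.
TIMELINE_NAMES = ("interventions", "work developments", "private developments")

MECHANISMS = ("exhaustion", "reward_withheld")

#: Simulated variable providing each sketch track, where one exists.
DEFAULT_VARIABLE_MAPPING = {
    "amount of demands": "demands",
    "effort": "mental_effort",
    "perceived efficacy": "self_efficacy",
    "stress responses": "stress_activation",
}

WEEKS_PER_MONTH = 52.0 / 12.0


@dataclass
class PhaseAnnotation:
    """Ordered, contiguous phases of a sketch with per-phase confidence."""

    phases: list[tuple[str, float, float]]
    confidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        allowed = {"build-up", "crash", "recovery"}
        names = [p[0] for p in self.phases]
        for name, start, end in self.phases:
            if name not in allowed:
                raise ValidationError(f"unknown phase name '{name}'")
            if end < start:
                raise ValidationError(f"phase '{name}' has end < start")
        for (_, _, e0), (_, s1, _) in zip(self.phases, self.phases[1:]):
            if abs(e0 - s1) > 1e-9:
                raise ValidationError("phases must be contiguous")
        canonical = [n for n in ("build-up", "crash", "recovery") if n in names]
        if names != canonical:
            raise ValidationError(f"phases out of canonical order: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.phases)

    def boundaries(self) -> dict[str, tuple[float, float]]:
        return {name: (start, end) for name, start, end in self.phases}


@dataclass
class ScenarioSketch:
    """A retrospective sketch record on a monthly grid.

    ``times`` are months since the start of the sketched span; every track
    value lies in [0, 1] (low/mid/high).  ``timelines`` holds labeled
    events/intervals; ``truth`` carries the generator's phase boundaries
    when the sketch is synthetic.
    """

    times: np.ndarray
    tracks: dict[str, np.ndarray]
    timelines: dict[str, list[dict]]
    mechanism: str = "exhaustion"
    truth: PhaseAnnotation | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if tuple(self.tracks) != TRACK_NAMES and set(self.tracks) != set(TRACK_NAMES):
            raise ValidationError(
                f"a sketch requires exactly the 7 tracks {TRACK_NAMES}; "
                f"got {tuple(self.tracks)}"
            )
        if set(self.timelines) != set(TIMELINE_NAMES):
            raise ValidationError(
                f"a sketch requires exactly the 3 timelines {TIMELINE_NAMES}"
            )
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism '{self.mechanism}'")
        clean = {}
        for name in TRACK_NAMES:
            arr = np.asarray(self.tracks[name], dtype=float)
            if arr.shape != self.times.shape:
                raise ValidationError(f"track '{name}' length mismatch")
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValidationError(f"track '{name}' leaves [0, 1]")
            clean[name] = np.clip(arr, 0.0, 1.0)
        self.tracks = clean

    @property
    def span_months(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "tracks": {k: v.tolist() for k, v in self.tracks.items()},
            "timelines": self.timelines,
            "mechanism": self.mechanism,
            "truth": None if self.truth is None else {
                "phases": [list(p) for p in self.truth.phases],
                "confidence": self.truth.confidence,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSketch":
        truth = d.get("truth")
        return cls(
            times=np.asarray(d["times"], dtype=float),
            tracks={k: np.asarray(v, dtype=float) for k, v in d["tracks"].items()},
            timelines={k: list(v) for k, v in d["timelines"].items()},
            mechanism=d.get("mechanism", "exhaustion"),
            truth=None if truth is None else PhaseAnnotation(
                phases=[tuple(p) for p in truth["phases"]],
                confidence=dict(truth.get("confidence", {})),
            ),
        )

    @classmethod
    def from_json(cls, source: str) -> "ScenarioSketch":
        return cls.from_dict(json.loads(source))


def _segments(grid: np.ndarray, points: list[tuple[float, float]]) -> np.ndarray:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return np.interp(grid, xs, ys)


def generate_sketch(seed: int, span_years: float = 2.0,
                    mechanism: str = "exhaustion",
                    noise_sd: float = 0.0) -> ScenarioSketch:
    """Generate one synthetic retrospective sketch.

    The archetype embeds the three phases: the crash peak lands at a
    seed-dependent point in the middle of the span, the sudden drop takes
    one or two months, and the recovery plateau lasts one month to a year
    (capped at half the remaining span).  With ``noise_sd = 0`` every
    track is piecewise monotone between its breakpoints; Gaussian noise of
    the given standard deviation is added per grid point otherwise.
    Reproducible: the same arguments always yield the same sketch, with
    ground-truth phase boundaries attached as ``truth``.
    """
    if not 1.0 <= span_years <= 10.0:
        raise ValidationError(f"span_years must lie in [1, 10], got {span_years}")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    if mechanism not in MECHANISMS:
        raise ValidationError(f"unknown mechanism '{mechanism}'")
    rng = np.random.default_rng(seed)
    n_months = int(round(span_years * 12))
    grid = np.arange(n_months + 1, dtype=float)
    end = float(grid[-1])

    # breakpoints snapped to whole months so archetype extrema sit on the grid
    peak = float(round(rng.uniform(0.45, 0.60) * end))
    drop_len = float(rng.integers(1, 3))
    crash_end = min(peak + drop_len, end - 2.0)
    max_plateau = max(1.0, (end - crash_end) / 2.0)
    plateau = float(round(rng.uniform(1.0, min(12.0, max_plateau))))
    rise_start = crash_end + plateau
    nfr_turn = peak - float(rng.uniform(3.0, 6.0))  # late steep rise onset

    lo = float(rng.uniform(0.10, 0.20))       # demand starting level
    hi = float(rng.uniform(0.90, 1.00))       # crash-peak level
    floor = float(rng.uniform(0.15, 0.25))    # plateau activity level
    back = float(rng.uniform(0.45, 0.60))     # end-of-recovery return level

    tracks = {
        "amount of demands": _segments(grid, [
            (0.0, lo), (0.4 * peak, 0.5), (peak, hi),
            (crash_end, floor), (rise_start, floor), (end, back),
        ]),
        "effort": _segments(grid, [
            (0.0, 0.55), (0.5 * peak, 0.7), (peak, hi),
            (crash_end, floor), (rise_start, floor), (end, back),
        ]),
        "perceived efficacy": _segments(grid, [
            (0.0, 0.75), (0.7 * peak, 0.7), (peak, 0.55),
            (crash_end, 0.2), (rise_start, 0.25), (end, 0.65),
        ]),
        "appropriateness of resources": _segments(grid, [
            (0.0, 0.45), (peak, 0.2), (crash_end, 0.2),
            (rise_start, 0.3), (end, 0.45),
        ]),
        "need for recovery": _segments(grid, [
            (0.0, 0.2), (max(0.0, nfr_turn), 0.25), (peak, 0.9),
            (crash_end, 0.95), (rise_start, 0.6), (end, 0.3),
        ]),
        "stress responses": _segments(grid, [
            (0.0, 0.25), (0.6 * peak, 0.45), (peak, 0.95),
            (crash_end, 0.75), (rise_start, 0.4), (end, 0.25),
        ]),
    }
    if mechanism == "reward_withheld":
        # a significant engagement drop with prolonged low values
        tracks["engagement"] = _segments(grid, [
            (0.0, 0.8), (peak, 0.75), (crash_end, 0.1),
            (end - 1.0, 0.15), (end, 0.25),
        ])
    else:
        tracks["engagement"] = _segments(grid, [
            (0.0, 0.8), (peak, 0.7), (crash_end, 0.4),
            (rise_start, 0.45), (end, 0.65),
        ])
    tracks = {name: tracks[name] for name in TRACK_NAMES}

    if noise_sd > 0:
        for name in TRACK_NAMES:
            tracks[name] = np.clip(
                tracks[name] + rng.normal(0.0, noise_sd, size=grid.shape), 0.0, 1.0
            )

    timelines = {
        "interventions": [
            {"label": "sick leave and professional help",
             "start": round(crash_end, 1), "end": round(rise_start, 1)},
        ],
        "work developments": [
            {"label": "new role with growing responsibilities",
             "start": 0.0, "end": round(peak, 1)},
        ],
        "private developments": [
            {"label": "period of extra private strain",
             "start": round(0.3 * peak, 1), "end": round(0.8 * peak, 1)},
        ],
    }
    truth = PhaseAnnotation(
        phases=[
            ("build-up", 0.0, peak),
            ("crash", peak, crash_end),
            ("recovery", crash_end, end),
        ],
        confidence={"build-up": 1.0, "crash": 1.0, "recovery": 1.0},
    )
    return ScenarioSketch(times=grid, tracks=tracks, timelines=timelines,
                          mechanism=mechanism, truth=truth)


# --------------------------------------------------------------------------
# Phase detection
# --------------------------------------------------------------------------


def _smooth3(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return x.copy()
    out = x.copy()
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    return out


def detect_phases(sketch: ScenarioSketch, drop_window_frac: float = 0.3,
                  min_drop_frac: float = 0.25) -> PhaseAnnotation:
    """Segment a sketch into build-up / crash / recovery.

    The crash is located at the maximal joint (demands + effort) peak; the
    crash end is the first point after the peak at which the joint signal
    has shed most of its eventual fall within a trailing window.  If the
    joint signal never drops by at least ``min_drop_frac`` of its range
    (e.g. constant tracks), a single low-confidence build-up phase is
    returned.
    """
    joint = (sketch.tracks["amount of demands"] + sketch.tracks["effort"]) / 2.0
    t = sketch.times
    rng_ = float(joint.max() - joint.min())
    k = int(np.argmax(joint))
    window = max(2, int(round(drop_window_frac * len(t))))
    tail = joint[k + 1:k + 1 + window]
    if rng_ < 1e-6 or len(tail) == 0:
        return PhaseAnnotation(
            phases=[("build-up", float(t[0]), float(t[-1]))],
            confidence={"build-up": 0.1},
        )
    floor = float(tail.min())
    drop = joint[k] - floor
    if drop < min_drop_frac * rng_:
        return PhaseAnnotation(
            phases=[("build-up", float(t[0]), float(t[-1]))],
            confidence={"build-up": 0.2},
        )
    # crash ends once the joint signal is within 15% of the local floor
    threshold = floor + 0.15 * drop
    j = k + 1
    while j < k + 1 + len(tail) and joint[j] > threshold:
        j += 1
    j = min(j, len(t) - 1)
    confidence = float(min(1.0, drop / rng_))
    return PhaseAnnotation(
        phases=[
            ("build-up", float(t[0]), float(t[k])),
            ("crash", float(t[k]), float(t[j])),
            ("recovery", float(t[j]), float(t[-1])),
        ],
        confidence={"build-up": confidence, "crash": confidence,
                    "recovery": confidence},
    )


def sketch_features(sketch: ScenarioSketch) -> dict[str, float]:
    """Deterministic scalar features of one sketch.

    Peak months of the headline tracks, magnitude of the post-peak drop in
    demands and in perceived efficacy, the recovery-plateau length in
    months, and the lag between the need-for-recovery upturn and the
    crash peak.
    """
    t = sketch.times
    demands = sketch.tracks["amount of demands"]
    effort = sketch.tracks["effort"]
    efficacy = sketch.tracks["perceived efficacy"]
    nfr = sketch.tracks["need for recovery"]

    demands_peak = detect_peak_week(demands, t)
    effort_peak = detect_peak_week(effort, t)
    stress_peak = detect_peak_week(sketch.tracks["stress responses"], t)

    annotation = detect_phases(sketch)
    bounds = annotation.boundaries()
    if "crash" in bounds:
        crash_start, crash_end = bounds["crash"]
        after = t >= crash_end
        demands_drop = float(demands.max() - demands[after].min())
        efficacy_drop = float(efficacy[t <= crash_start].max() - efficacy[after].min())
        post = _smooth3(effort[after])
        tpost = t[after]
        floor = float(post.min())
        # plateau ends where effort starts climbing again (slope per month)
        rising = np.where(np.diff(post) > 0.01)[0]
        if len(rising):
            plateau_end = float(tpost[rising[0]])
        else:
            above = tpost[post > floor + 0.1]
            plateau_end = float(above[0]) if len(above) else float(t[-1])
        plateau_months = max(0.0, plateau_end - crash_end)
    else:
        demands_drop = 0.0
        efficacy_drop = 0.0
        plateau_months = 0.0
        crash_start = float(t[-1])
    early = nfr[: max(2, len(nfr) // 4)]
    upturn_mask = nfr > float(early.mean()) + 0.2
    nfr_upturn = float(t[upturn_mask][0]) if upturn_mask.any() else float(t[-1])
    return {
        "demands_peak_month": float(demands_peak),
        "effort_peak_month": float(effort_peak),
        "stress_peak_month": float(stress_peak),
        "demands_drop": demands_drop,
        "efficacy_drop": efficacy_drop,
        "plateau_months": plateau_months,
        "need_for_recovery_upturn_month": nfr_upturn,
        "upturn_to_crash_lag_months": float(crash_start) - nfr_upturn,
    }


# --------------------------------------------------------------------------
# Simulation/sketch comparison
# --------------------------------------------------------------------------


def sketch_from_trajectory(traj: TrajectorySet,
                           mapping: dict[str, str] | None = None,
                           mechanism: str = "exhaustion") -> ScenarioSketch:
    """Render a simulated trajectory as a sketch record.

    Mapped simulation series are resampled onto a monthly grid; sketch
    tracks without a simulated counterpart are filled with neutral or
    proxy values (need for recovery from exhaustion symptoms, engagement
    from motivation, when available).
    """
    mapping = dict(DEFAULT_VARIABLE_MAPPING if mapping is None else mapping)
    missing = [v for v in mapping.values() if v not in traj.series]
    if missing:
        raise ValidationError(
            f"trajectory lacks mapped series: {', '.join(sorted(set(missing)))}"
        )
    span_weeks = float(traj.times[-1] - traj.times[0])
    n_months = max(2, int(round(span_weeks / WEEKS_PER_MONTH)))
    months = np.arange(n_months + 1, dtype=float)
    weeks_at = traj.times[0] + months * (span_weeks / n_months)

    def resample(series: np.ndarray) -> np.ndarray:
        return np.clip(np.interp(weeks_at, traj.times, series), 0.0, 1.0)

    tracks: dict[str, np.ndarray] = {}
    for track, var in mapping.items():
        tracks[track] = resample(traj[var])
    proxies = {
        "need for recovery": "symptoms_of_exhaustion",
        "engagement": "motivation_to_meet_demands",
    }
    for track in TRACK_NAMES:
        if track in tracks:
            continue
        proxy = proxies.get(track)
        if proxy is not None and proxy in traj.series:
            tracks[track] = resample(traj[proxy])
        else:
            tracks[track] = np.full_like(months, 0.5)
    return ScenarioSketch(
        times=months,
        tracks={name: tracks[name] for name in TRACK_NAMES},
        timelines={name: [] for name in TIMELINE_NAMES},
        mechanism=mechanism,
    )


def _normalized_peaks(sketch: ScenarioSketch, names) -> list[float]:
    span = sketch.span_months or 1.0
    return [
        (detect_peak_week(sketch.tracks[n], sketch.times) - sketch.times[0]) / span
        for n in names
    ]


def compare_sketches(a: ScenarioSketch, b: ScenarioSketch) -> float:
    """Similarity of two sketches in [0, 1] (symmetric; 1 for identical).

    Aggregates three subscores: phase presence and order agreement, the
    ordering of the peaks of the headline tracks, and the co-timing of the
    crash peak as a fraction of the span.
    """
    pa, pb = detect_phases(a), detect_phases(b)
    s_phase = 1.0 if pa.names == pb.names else (
        0.5 if ("crash" in pa.names) == ("crash" in pb.names) else 0.0
    )

    names = ("amount of demands", "effort", "perceived efficacy", "stress responses")
    peaks_a = _normalized_peaks(a, names)
    peaks_b = _normalized_peaks(b, names)
    agree = total = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            total += 1
            if np.sign(peaks_a[i] - peaks_a[j]) == np.sign(peaks_b[i] - peaks_b[j]):
                agree += 1
    s_peaks = agree / total

    ba, bb = pa.boundaries(), pb.boundaries()
    if "crash" in ba and "crash" in bb:
        ca = (ba["crash"][0] - a.times[0]) / (a.span_months or 1.0)
        cb = (bb["crash"][0] - b.times[0]) / (b.span_months or 1.0)
        s_timing = max(0.0, 1.0 - abs(ca - cb) / 0.25)
    elif "crash" not in ba and "crash" not in bb:
        s_timing = 1.0
    else:
        s_timing = 0.0

    return float((s_phase + s_peaks + s_timing) / 3.0)


def compare_sim_to_sketch(traj: TrajectorySet, sketch: ScenarioSketch,
                          mapping: dict[str, str] | None = None) -> float:
    """Score in [0, 1] for how well a simulation reproduces a sketch.

    The trajectory is rendered as a sketch (see
    :func:`sketch_from_trajectory`) and compared with
    :func:`compare_sketches`; a sketch rendered from the trajectory itself
    scores exactly 1.
    """
    return compare_sketches(sketch_from_trajectory(traj, mapping), sketch)
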