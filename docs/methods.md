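# Methods

## Scope and modeling stance

`burnoutsim` implements a quantitative system-dynamics account of
occupational burnout: the development of chronic stress under escalating
demands, the crash into exhaustion, and the two roads out of it —
learning to regulate one's goals, or relapsing for want of that learning.
All behavioral quantities are dimensionless levels on [0, 1], with the
reading low = 0, medium = 0.5, high = 1.  Time is measured in weeks.

The package is a *reconstruction*: the causal structure (variables, edge
polarities, the five named loops, the three persona parameter rows, the
three-phase retrospective pattern) is fixed by published qualitative
material, but no equation set or parameter table for the full model is
publicly available.  Every functional form here is therefore the simplest
member of its class that respects the declared polarities and reproduces
the qualitative trajectory patterns; each form is isolated behind a named
function so alternatives can be swapped and re-tested.

## The engine

A model is a `ModelGraph`: variables with roles (stock / flow /
auxiliary / constant), expression-string equations for flows and
auxiliaries, per-stock inflow/outflow lists, piecewise-linear
`TableFunction` lookups (clamped outside their breakpoints), and a signed
causal edge set.

* **Integration** is explicit Euler with `dt = 0.125` weeks by default.
  The weekly phenomena modeled here have time constants of 1–12 weeks, so
  0.125 weeks resolves the fastest dynamics 8-fold; the test suite checks
  first-order convergence (endpoint error slope 1.0 ± 0.1 in log₂–log₂)
  and that persona classifications are invariant under halving dt.
  Higher-order integrators are out of scope by design: Euler is the
  field's convention and the models' table functions have corners.
* **Evaluation order**: auxiliaries and flows must be acyclic once stocks
  are treated as sources; they are evaluated in topological order with an
  alphabetical tie-break, so evaluation is reproducible regardless of
  declaration order.  Every feedback loop must therefore pass through at
  least one stock — algebraic loops are rejected with the offending cycle
  named.
* **Bounded stocks** are clamped to [0, 1] after each step.  Clamping
  rather than rate-limiting keeps the update rule transparent;
  the bound suite verifies the clamp never hides runaway dynamics (levels
  sit strictly inside the band almost everywhere).
* **Adjustment primitives**: `first_order_smooth_step` (perception
  smoothing of an exogenous signal) and `goal_seek_step` (a stock chasing
  an endogenous target) share the arithmetic
  `x + dt·(target − x)/τ`; both match the continuous exponential to
  1 × 10⁻³ at `dt = τ/100`.  A warning is emitted for `dt > τ/4`.
* **Loop enumeration** runs on the declared causal edge set — a
  *projection* of the equations in which the implicit self-balancing
  first-order loop of every goal-seeking stock is not drawn, matching how
  causal loop diagrams are drawn in practice.  Polarity is the parity of
  negative edges on the cycle; cycles are canonicalized to their
  lexicographically smallest rotation and enumerated via networkx, with
  an independent DFS enumerator serving as the test oracle.
* **Edge-sign consistency**: each declared edge is checked by perturbing
  its source ±10⁻³ at a reference state, re-evaluating the auxiliaries
  downstream, and comparing the sign of the response of the target (its
  equation, or its net flow for stocks).  A zero partial derivative — the
  momentarily inactive branch of a `min`, a gate that is closed at the
  reference state — is treated as *consistent*: weak monotonicity cannot
  contradict a declared sign.  Only a nonzero opposite-signed derivative
  fails.

## The simplified model

Four variables: a capacity-for-effort stock (constant recovery inflow,
load outflow proportional to effort), effort `= min(demands, f(capacity))`,
performance proportional to effort, and a demand stock goal-seeking
toward `performance × gain`.  The availability curve `f` is a concave
5-point table (`f(0)=0, f(1)=1`) that is nearly flat at high capacity and
declines sharply once reserves are low.

The packaged reference parameterization (recovery 0.1125/wk, load
coefficient 0.25 per unit effort, pressure gain 1.5, demand adjustment
time 6 wk, from capacity 1.0 and demands 0.1) was calibrated once against
the two qualitative anchors of the reference scenario — an effort peak
shortly *after week 24* and settling into equilibrium *around week 52* —
and then frozen.  At the default step it peaks in week 26.1, settles
(joint ±2% band on capacity, demands and effort) in week 49.8, and ends
at capacity 0.25.  The settling detector measures each series' deviation
from its final value against `band × (max − min)` of that series; range
normalization makes the criterion meaningful for decaying series and
lets constant series settle at t₀.

## The full burnout model

Ten stocks, fourteen auxiliaries, thirteen flows, four processes.

**Regulating demands.**  Indicated demand =
`task_load × requirements_per_task × (1 + hindrance_gain × hindrances)`,
clamped to 1.  The demand stock goal-seeks toward the larger of the
indicated demand and `performance × 1.8` (good performance raises
expectations — the engine of the *pressure to do more* loop).  Task load
is anchored by what is at stake:
`base × (EC + (1 − EC)·performance) × (1 − route2·(1 − EC)·(0.5 + perceived gap))`
where EC is expected consequences.  Someone with high EC keeps receiving
work regardless of their recent performance; someone with low EC sees
task load track performance down after a collapse and can hand work over
when a gap opens (coping route 2).  Requirements per task carry the
symmetric structure in work-goal relevance (route 3: lowering one's own
bar).  Route 1 — simply working harder — emerges from the drive term
below.

**Regulating effort.**  Motivation = work-goal relevance × expected
consequences (multiplicative, so either being zero gates effort to
zero).  Drive = `min(1, motivation·(1 + 3·motivation·perceived_gap))`:
motivated people push harder when they perceive themselves falling
short.  Mental effort =
`min(demands × g(drive), f(perceived capacity)) × (1 − 0.9·forced_rest)`
with `g` a steep willingness curve — its steepness in the mid-range is
what turns small differences in stakes into different dynamic regimes,
the sensitive dependence the persona comparison is about.  Performance =
effort × cognitive functions; the gap is the unmet part of demands;
self-efficacy smooths `1 − gap`.

**Impacts on body and mind.**  Stress gains with effort and (while
engaged) with the gap, saturating as it approaches 1, and decays at a
rate proportional to recovery (`1 − effort`: effort crowds recovery
out).  Capacity drains in proportion to effort and stress and refills
through recovery.  Cognitive and emotional functions erode while stress
exceeds the exhaustion-onset threshold (0.6) and repair only slowly below
it.  Two mechanisms here are essential to the observed dynamics and are
deliberate design choices:

1. *Perceived capacity is a smoothed stock* (time constant 6 wk), not an
   instantaneous reading — people notice their depletion late, consistent
   with treating perceptions as first-order smoothed quantities.  The
   delay this inserts into the *limits of the body* balancing loop is
   what lets the no-learning persona overshoot and oscillate; with
   instantaneous perception every parameterization we examined relaxes
   into a featureless equilibrium.
2. *A hysteretic forced-rest state* operationalizes the crash tipping
   point — the moment further effort becomes impossible.  When capacity
   falls below 0.45 the rest state engages (effort drops to a 10%
   residual); it releases only once capacity has rebuilt past 0.7.  The
   two-threshold (Schmitt-trigger) form is the discrete idealization of a
   collapse-and-reengage cycle; a single threshold stalls in the dead
   zone between partial rest and partial recovery.

**Burnout symptoms and learning.**  Symptoms of exhaustion smooth
`1 − capacity` (4 wk).  Crossing the learning trigger (0.45) sets a
permanent memory; while symptoms are declining — the recovery phase — a
persona whose learning switch is on adjusts work-goal relevance and
expected consequences toward learned sustainable levels (0.4), each only
if its own change switch allows, over a 4-week learning time.  With all
three switches off both variables are bit-constant for the whole run.

**Personas.**  The three parameter rows are used exactly as published;
the only adaptation is that an initial value above its cap (P3's
expected consequences, 0.6 against a cap of 0.5) starts at the cap, since
a cap that the initial state violates is not a cap.  All other
parameters are shared.  The shared set was calibrated once against the
three qualitative patterns — P1 one episode then stable, P2 a cycle of
episodes, P3 no episode with stable self-efficacy — and frozen; at the
defaults P1 peaks at stress 0.72 with one episode (weeks 25–50), P2
cycles with five episodes about 19 weeks apart, and P3 peaks at 0.43.

**Episode definition.**  A burnout episode is an excursion of stress
activation above 0.65 that persists until stress falls below 0.40, with a
4-week minimum duration; the hysteresis band prevents chatter.  These
thresholds are an analytic convention calibrated with the shared
parameter set (P1's structural stress ceiling is ≈ 0.72, P3's ≈ 0.43, so
0.65 separates the regimes with ~10% margins on either side), not an
empirical clinical cutoff.  Classification: `coping` (no episode),
`single_episode_with_learning` (one episode followed by settling of the
six reported series within ±2% of their final values), `cyclic`
(anything else).

## The synthetic sketch generator

The generator emulates the retrospective "graphs over time" task: seven
perceived tracks on a monthly grid over a 1–10-year span (default 2
years), three labeled event timelines, and the three-phase archetype —
rising demands and effort, a deceptive lull then steep rise in the need
for recovery, a crash peak with a 1–2-month drop, a recovery plateau of
1–12 months, then gradual return.  The `reward_withheld` mechanism
additionally drops engagement sharply and holds it low through recovery.
Tracks are piecewise-linear between seed-jittered breakpoints (snapped to
whole months so archetype extrema sit on the grid) with optional Gaussian
per-point noise, clamped to [0, 1]; ground-truth phase boundaries ride
along with each sketch.

What the generator does *not* emulate: real sketches are hand-drawn, with
idiosyncratic shapes, recall bias, non-stationary noise, and spans chosen
by the participant; tracks here are mutually consistent by construction,
whereas real respondents can sketch contradictory tracks.  A detector
that passes the round-trip suite is therefore shown to invert *this
archetype family* under moderate noise — evidence of internal
consistency, not of field validity on clinical data.

The phase detector locates the crash at the maximal joint
(demands + effort) peak, ends it where the joint signal has shed 85% of
its fall within a trailing window, and labels the spans before and after
as build-up and recovery.  If the joint signal never drops by a quarter
of its range, a single low-confidence build-up phase is returned
(constant tracks contain no crash).  Over 100 seeds at noise SD 0.05 the
round trip recovers all three phases in order with crash-boundary error
≤ 5% of the span in at least 90 cases (typically 100).

The simulation–sketch similarity score averages three symmetric
subscores — phase-sequence agreement, pairwise ordering of the four
mapped track peaks, and crash co-timing as a fraction of span — and is 1
exactly for a sketch rendered from the trajectory itself.  The second
crash mechanism's quantitative counterpart inside the dynamic model is
out of scope: engagement and appropriateness-of-resources exist only as
sketch tracks, not as model variables.

## Numerical and interface conventions

* Determinism: simulation is a pure function of (model, config, initial);
  repeated runs are bit-identical, and the CLI writes SHA-256 manifests
  so any run can be replayed and diffed.
* Trajectory CSV uses 17-significant-digit formatting and round-trip
  float parsing, so write → read is lossless.
* CLI precedence is defaults < config file < explicit flags — an
  explicit flag always wins, because a config file silently overriding a
  typed flag is a usability trap.
* The DOT export is plain text written and parsed by this package (the
  round-trip test checks counts, not layout); rendering requires any
  standard Graphviz installation.

## Known limitations

* The full model is one defensible closure of a qualitative structure;
  other closures (different willingness curves, additive demand
  composition, stochastic shocks) could produce the same three persona
  labels with different interiors.  The persona margins quoted above are
  properties of the frozen defaults, not robust identified quantities.
* Willingness-curve steepness places P1 and P3 on opposite sides of the
  escalation boundary at motivations 0.36 vs 0.30 — sensitive dependence
  is the point of the comparison, but it means small shared-parameter
  changes require recalibration.
* Learning is monotone and permanent (no forgetting, no partial
  relapse for P1); exogenous interventions, team effects and
  physiological submodels are out of scope.
* Exact replication of any externally produced trajectory is not
  attempted: no solver, step size, or full parameter table exists to
  replicate against, so the anchors checked are qualitative and
  week-level.
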