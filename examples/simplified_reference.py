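"""The overshoot-and-collapse reference scenario of the simplified model.

Runs the frozen four-variable capacity/effort/demands model from a
well-rested, low-demand start and prints the two trajectory anchors:
the week effort peaks (the tipping point into exhaustion) and the week
the system settles into its degraded equilibrium.
"""

from burnoutsim import detect_peak_week, detect_settling_week, reference_run

run = reference_run()
traj = run.traj

peak = detect_peak_week(traj["effort"], traj.times)
settle = detect_settling_week(
    traj.subset(["capacity_for_effort", "demands", "effort"]), band=0.02
)

print(f"effort peaks in week        {peak:.1f}")
print(f"system settles in week      {settle:.1f}")
print(f"initial capacity for effort {traj['capacity_for_effort'][0]:.2f}")
print(f"final capacity for effort   {traj['capacity_for_effort'][-1]:.2f}")

# The peak marks the moment accumulated load outruns recovery: beyond it
# the person can no longer meet the risen demands and effort collapses.
# The equilibrium capacity far below its starting value is the cost of
# letting the reinforcing demand spiral run unchecked.
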