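"""Enumerate and name the feedback loops of the full burnout model.

Builds the model graph, lists the five named feedback loops with their
polarities, checks every declared edge sign against a numerical
perturbation, and writes the causal loop diagram (nodes grouped by the
four processes) as Graphviz DOT.
"""

from burnoutsim import (
    BurnoutParams,
    build_burnout_model,
    check_edge_signs,
    enumerate_feedback_loops,
    export_cld,
    initial_burnout_state,
    verify_named_loops,
)
from burnoutsim.burnout import PROCESS_MAP

params = BurnoutParams()
model = build_burnout_model(params)

named = verify_named_loops(model)
print(f"simple feedback loops (length <= 8): {len(enumerate_feedback_loops(model, 8))}")
print("named loops:")
for name, loop in named.items():
    tag = "R" if loop.polarity == "reinforcing" else "B"
    print(f"  [{tag}] {name}: {' -> '.join(loop.cycle)}")

check_edge_signs(model, initial_burnout_state(params))
print("all declared edge polarities consistent with numerical perturbation")

path = export_cld(model, "burnout_model.dot", processes=PROCESS_MAP, loops=named)
print(f"causal loop diagram written to {path}")

# A reinforcing (R) loop amplifies whatever it is fed -- the "pressure to
# do more" spiral.  The balancing (B) loops are the system's brakes: the
# body's limits, demand regulation, and learning after a burnout episode.
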