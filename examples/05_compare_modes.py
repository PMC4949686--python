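"""With vs without the shape constraint on one interacting stack.

The same phantom stack is tracked twice: once with the collision mechanism
active and once in baseline mode (multi-phase exclusion only). The baseline
typically passes a target between trackers or squeezes one to extinction
during coalescence; the shape constraint keeps both plants on their own
roots.
"""

import warnings

from rhizotrace import (
    SimConfig,
    TrackParams,
    evaluate,
    run,
    seeds_from_truth,
    simulate_stack,
)

warnings.filterwarnings("ignore", category=UserWarning)

stack, truth = simulate_stack(SimConfig(n_slices=150), seed=4)
seeds = seeds_from_truth(truth)
print(f"{len(truth.interaction_log)} contact episode(s) in {stack.depth} slices")

for constraint in (True, False):
    label = "shape constraint ON " if constraint else "shape constraint OFF"
    volume, report = run(stack, seeds, TrackParams(shape_constraint=constraint))
    m = evaluate(volume, truth)
    lost = f", lost plants {m.lost_plants}" if m.lost_plants else ""
    print(f"{label}: accuracy {m.overall_accuracy:.1%}, "
          f"swap slices {m.swap_count}{lost}, interactions kept "
          f"{sum(i['success'] for i in m.interactions)}/{len(m.interactions)}")
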