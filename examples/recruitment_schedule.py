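"""Build the weaned-cub recruitment schedule and redistribute a cub cull.

Fox cubs are born in spring but only enter the lampable ("observable")
population once weaned and active away from the earth. The schedule w_t
spreads that entry over the two-week steps of the year; cubs culled at
breeding earths are redistributed over the same steps so they are not
removed from the model before they exist.
"""

import numpy as np

from foxdepletion import ConceptionModel, build_weaning_schedule, redistribute_cub_cull
from foxdepletion.calendars import step_grid

sched = build_weaning_schedule(ConceptionModel())
print("recruitment weights by step of year (nonzero):")
for step in range(sched.support[0], sched.support[1] + 1):
    print(f"  step {step:2d} (weeks {2*step-1}-{2*step}): w = {sched.w[step-1]:.3f}")
print(f"support: steps {sched.support[0]}-{sched.support[1]}, sum = {sched.w.sum():.6f}")

# an estate removed 9 cubs at earths in spring 1998 (recorded in one step);
# the model spreads them across the year's recruitment window
years, steps = step_grid(1998, 26)
observed = np.zeros(26)
observed[sched.support[0] - 1] = 9.0
spread = redistribute_cub_cull(observed, sched, years, steps)
print("\nredistributed cub cull (9 cubs):")
print(np.round(spread[spread > 0], 2), "-> total", spread.sum())
print("The annual total is conserved exactly; each step receives w_t x 9.")
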