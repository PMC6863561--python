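"""Refit one estate under alternative structural and prior assumptions.

Each variant patches one assumption - seasonal instead of constant
immigration, cub recruitment shifted two weeks, an alternative mortality or
birth-rate prior, different carrying-capacity bounds, or an alternative
process-error treatment - and the comparison table reports how posterior
medians and reconstructed density move relative to the reference fit.
"""

import foxdepletion as fx
from foxdepletion.analysis_metrics import sensitivity_suite
from foxdepletion.inference import MCMCConfig

sched = fx.build_weaning_schedule(fx.ConceptionModel())
truth = fx.OperatingTruth(params=fx.ModelParams(
    N0=2.0, K=4.0, v=0.2, r=3.18, M=0.34 / 26, d=0.45))
effort = fx.generate_effort(
    fx.EffortPattern(weekly_hours=(1.0, 0.7, 0.35, 1.0), years=4), seed=17)
series, _ = fx.simulate_estate(truth, effort, sched, seed=18)

res = sensitivity_suite(
    series, sched, MCMCConfig.profile("standard", seed=11),
    variants=["seasonal_immigration", "recruit_earlier", "recruit_later",
              "M_body_mass", "r_vague"])
print(res.comparison.round(3))
print("\ndensity_delta_pct is the mean relative change of posterior-median "
      "density against the reference fit; estimates robust to an "
      "assumption show small deltas confined to the perturbed parameter.")
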