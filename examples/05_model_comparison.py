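"""Constant vs saturable adsorption: likelihood-ratio comparison.

Fits both device sub-models in stage 2 (sharing one stage-1 fit) on a
study simulated with saturable adsorption, and applies the ΔOFV > 3.84
decision rule.
"""

from dataclasses import replace

import numpy as np

from adsorbkin import (
    builtin_design,
    compare_models,
    default_population,
    simulate_study,
    stage2_fit,
    two_stage_fit,
)
from adsorbkin.datasets import Port
from adsorbkin.pkmodels import AdsorptionConstantParams

times = tuple(np.round(np.arange(0.0, 6.01, 0.5), 6))
design = replace(
    builtin_design("G2_CYA"),
    n_intervention=12,
    n_control=4,
    sampling_times={Port.inlet: times, Port.outlet: times},
)
pop_sat = default_population("CYA")
dataset = simulate_study(design, pop_sat, seed=11)

stage1, fit_sat = two_stage_fit(dataset, pop_sat)
pop_const = replace(pop_sat, adsorption=AdsorptionConstantParams(k_constant=0.3))
fit_const = stage2_fit(dataset, pop_const, stage1)

decision = compare_models(fit_const, fit_sat)
print(f"constant-extraction OFV : {fit_const.ofv:10.2f}")
print(f"saturable OFV           : {fit_sat.ofv:10.2f}")
print(f"delta OFV               : {decision.delta_ofv:10.2f}  (threshold {decision.threshold})")
print(f"preferred sub-model     : {decision.preferred}")
print()
print("A delta far above 3.84 for one extra parameter: the data demand the")
print("saturable (linearly decreasing) adsorption kinetics.")
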