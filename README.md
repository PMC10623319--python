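# adsorbkin

Population pharmacokinetics of drug removal by extracorporeal
hemoadsorption cartridges.

Hemoperfusion devices (polymer-bead cartridges inserted into an
extracorporeal blood circuit) are used to clear cytokines in critically
ill and transplant patients — exactly the patients who depend on
immunosuppressant drugs. `adsorbkin` quantifies how much drug such a
cartridge inadvertently removes, for pharmacometricians and
transplant-pharmacology researchers. It implements:

* **Direct clearance across the device** from paired inlet/outlet
  samples: CL = ((Cᵢ − Cₒ)/Cᵢ)·FL with plasma flow
  FL = blood flow × (1 − hematocrit), and elimination rate E = CL·Cᵢ.
* **Compartmental models with a device pathway.** One-compartment
  first-order absorption with lag (oral drugs, apparent CL/F and V/F) or
  a two-compartment IV model, plus an extra clearance pathway from the
  central compartment while the circuit session runs, either

  * constant extraction: CL_dev = blood_flow · k_constant, or
  * saturable (linear-decrease): CL_dev(t) = CL_max · (1 − A_dev(t)/A_max),

  where A_dev(t) is the amount already bound and A_max the cartridge
  capacity.
* **Nonlinear mixed-effects estimation** (log-normal inter-individual
  variability, port-specific proportional — or combined — residual
  error) via a Laplace approximation to the marginal likelihood, with
  the two-stage strategy used in device studies: fit systemic
  disposition with the device ignored, then freeze everything except
  clearance and estimate the adsorption sub-model. Nested sub-models are
  compared on the NONMEM-convention objective function (ΔOFV > 3.84 per
  extra parameter) and AIC.
* **A synthetic-study generator** reproducing a sheep hemoperfusion
  design (5 intervention + 3 sham-control animals per oral-drug group,
  twice-daily dosing to target troughs, a 6-h circuit session at
  120 mL/min and 33% hematocrit, paired inlet/outlet sampling), so the
  full estimation chain can be exercised and validated without animal
  data.

## Worked example

```python
from dataclasses import replace
import numpy as np
from adsorbkin import (builtin_design, default_population, simulate_study,
                       two_stage_fit)
from adsorbkin.datasets import Port

times = tuple(np.round(np.arange(0.0, 6.01, 0.5), 6))
design = replace(builtin_design("G2_CYA"), n_intervention=12, n_control=4,
                 sampling_times={Port.inlet: times, Port.outlet: times})
pop = default_population("CYA")          # saturable truth: 2.80 L/h, 1.15 mg
dataset = simulate_study(design, pop, seed=11)
stage1, stage2 = two_stage_fit(dataset, pop)
for name in stage2.estimated_names:
    print(name, round(stage2.estimates[name], 3))
```

prints

```
CL_F 557.422
CL_max 2.731
A_max 1.2
sigma_prop_post 0.216
```

i.e. from 16 simulated animals the two-stage fit recovers the cartridge's
maximum clearance (2.73 vs 2.80 L/h generating truth) and capacity
(1.20 vs 1.15 mg); the apparent systemic clearance (557 vs 500 L/h) and
the 20% outlet assay CV come back alongside. The `examples/` directory
holds one short script per capability (direct clearance, simulation,
trajectory + cartridge load, two-stage fitting, model comparison).

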