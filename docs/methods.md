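# Methods

## The problem

An adsorption cartridge in an extracorporeal circuit removes drug from
the blood flowing through it. Two questions matter clinically: how large
is the device clearance, and how much drug can the cartridge bind in
total? Both are answered here at two levels — a model-free computation
from paired samples drawn immediately before (inlet) and after (outlet)
the cartridge, and a population compartmental model in which the device
is an additional, possibly saturable, clearance pathway.

## Direct (model-free) clearance

For a paired sample (Cᵢ, Cₒ) the device clearance is the extraction
ratio times the plasma flow,

    CL = ((Cᵢ − Cₒ)/Cᵢ) · FL,    FL = blood_flow · (1 − hematocrit),

and the elimination rate is E = CL·Cᵢ. Units: circuit flows are quoted
in mL/min (pump setting; 120 mL/min ≡ 7.2 L/h), concentrations
internally in mg/L, so E = CL·Cᵢ/1000 in mg/min. Clearances computed
from noisy pairs may be negative (outlet above inlet); they are kept and
flagged, not truncated, because truncation biases any downstream median.
The "negligible clearance" classifier uses the absolute value of the
*signed* median extraction ratio against a 5%-of-FL threshold; the
signed median lets symmetric assay noise cancel. The 5% cutoff is a
package convention (flagged as such in the output) — the underlying
qualitative judgement has no published numeric criterion — and with 20%
per-sample noise the classifier needs a few hundred pairs to separate
zero extraction from the threshold reliably.

## Structural models

Orally dosed drugs use a one-compartment model with first-order
absorption, an optional absorption lag ALAG, and apparent parameters
CL/F and V/F (bioavailability in sheep is unknown and unidentifiable
from these data). Methylprednisolone, given IV, uses a two-compartment
model (CL, V1, V2, Q; micro-constants k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2 internally). Systemic elimination is linear throughout.

The device adds a clearance pathway from the central compartment that is
active only while the circuit session runs:

* constant: CL_dev = blood_flow · k_constant (the extraction constant
  multiplies blood flow as conventionally written; a `flow_basis`
  switch selects plasma flow instead),
* saturable: CL_dev(t) = CL_max · (1 − A_dev(t)/A_max), the clearance
  decaying linearly in the bound amount A_dev(t) and vanishing at the
  capacity A_max.

During simulation the instantaneous device clearance is capped at the
plasma flow FL: a flow-limited device cannot clear more plasma than
passes through it. Estimation leaves CL_max itself unconstrained, so an
estimate above FL is reportable (its plausibility is judged against the
flow, not forced). The outlet concentration is the inlet times
(1 − CL_dev/FL), which makes the paired-sample formula above an exact
inverse — a property the tests pin down.

The model states are amounts (mg): depot, central, peripheral, the
running cartridge load, and the cumulative systemically eliminated
amount, so total dosed-in drug is conserved (checked to < 1e-6 relative
at every output time). In the apparent (oral) parameterisation the
bookkeeping amounts are dose-scale; the cartridge load integral
∫CL_dev·C dt is nevertheless in true mg because the concentration is.

## Numerics

The reference solver (`solve_profile`) integrates piecewise with LSODA
(rtol 1e-8, atol 1e-10 mg), restarting at every dose entry and session
boundary. Absorption lag is implemented by event-time shifting — an
oral dose enters the depot exactly at dose time + ALAG — rather than by
discontinuity detection, for exactness.

The estimation hot path uses a specialised predictor: before the
session no device pathway exists and the models are linear, so the
state at session start is evaluated in closed form (superposition of
lagged Bateman / exponential terms); within the session a fixed-step
classical Runge–Kutta scheme (default maximum step 0.1 h during
fitting, grid broken at every dose entry, lag onset, session boundary
and observation time) integrates the nonlinear device coupling,
compiled with numba and vectorised across subjects. Agreement with the
reference route is ≲ 1e-6 relative for the oral drugs; for
methylprednisolone the flow cap introduces a kink that bounds accuracy
near 1e-4 — three orders below the 20% assay noise.

Time origin: record times are hours from the study origin (first
run-in dose), so all times are non-negative; the session start for the
oral groups is 168 h (after a 7-day run-in) and 0 for the single-dose
groups. Port-level sampling times are stored relative to session start.

## Population model and estimation

Structural parameters are log-normal across subjects:
pᵢ = p_typ · exp(ηᵢ), ηᵢ ~ N(0, ω²), with inter-individual variability
on clearance (and on V/F for tacrolimus). Residual error is
proportional with separate CVs for pre-cartridge (systemic, inlet) and
post-cartridge samples; methylprednisolone adds an additive component
(combined model).

The marginal likelihood is approximated by Laplace: per subject the
empirical-Bayes mode of η is found by a safeguarded Newton search
(finite-difference gradient/Hessian, vectorised across subjects by
stacking the stencil into one predictor call), and the OFV is

    OFV = Σᵢ [ h(η̂ᵢ) + log det(½ ∇²h(η̂ᵢ)) ],

with h the 2π-free −2 log joint. Dropping the 2π constants matches the
NONMEM convention, so ΔOFV between nested fits is on the chi-square
scale. A test utility integrates the 1-D marginal exactly by adaptive
quadrature and pins the Laplace error below 0.1 OFV units on small
studies.

Population parameters are log-transformed and optimised by Nelder–Mead
(parameter tolerance 1e-6 relative, OFV tolerance 1e-4, ≤ 500
iterations per dimension). Standard errors come from a
central-difference Hessian of the marginal −2LL at the optimum
(covariance = 2·H⁻¹, delta method back to the natural scale); reported
confidence intervals are Wald on the natural scale (log-scale optional),
and a singular Hessian yields absent SEs rather than fabricated ones.
Eta shrinkage is 100·(1 − SD(η̂)/ω) with the ddof-1 sample SD.

**Two-stage strategy.** Stage 1 ignores the device: the systemic model
is fitted to control and pre-cartridge observations only. Stage 2 keeps
every stage-1 parameter fixed except clearance, switches the adsorption
sub-model on, and estimates its parameters together with clearance and
the post-cartridge residual CV. Starting values: stage-1 clearance from
the naive-pooled dose rate over mean concentration (volume from an
assumed 12-h half-life); stage-2 CL_max from the median early-session
paired-sample clearance, A_max from the per-subject trapezoidal
integral of E(t) over the session. Model selection requires
ΔOFV strictly greater than 3.84 per extra parameter, with AIC as a
secondary criterion; parameters with RSE > 50% should be read as weakly
identifiable. KA and ALAG are fixed at their configured values in the
default fits — the circuit-session sampling window carries almost no
information about the absorption phase — and `estimated_flags` turns
them on where a design supports it.

## The synthetic-study generator

The generator emulates the standardized animal design: per oral-drug
group 5 intervention + 3 sham-control sheep, twice-daily oral dosing
(tacrolimus 10 mg, cyclosporin 600 mg, mycophenolate 1 g, everolimus
3 mg — the minima of the protocol dose ranges), a 7-day run-in so the
session starts near steady state, a 6-h session at 120 mL/min blood
flow and 33% hematocrit, paired inlet/outlet samples at 0, 30, 90, 250
and 330 min (single-port sham samples for controls), and for
methylprednisolone IV dosing (1 × 1.5 g, or 2 × 1 g with the second
dose at 1.5 h) sampled at 10–180 min. The antibody group (basiliximab,
20 mg IV, 3 animals, no controls) and prednisolone carry no adsorption
pathway — their device clearance is negligible.

Generating truths for the device sub-model are the published sheep
estimates (A_max/CL_max: tacrolimus 0.040 mg/4.02 L/h, cyclosporin
1.15/2.80, mycophenolate 4.17/3.71, everolimus 0.0163/3.23,
methylprednisolone 53.4 mg/8.21 L/h; lags 15.3/4.7/4.1 h). Systemic
disposition typical values are *synthetic conventions* — not reported
estimates — chosen once so that steady-state troughs sit inside the
protocol target bands (e.g. tacrolimus CL/F 115 L/h, V/F 2500 L gives a
6.9 ng/mL typical trough inside the 6–8 ng/mL band). Default
variabilities: ω = 0.3 (~30% CV) on clearance (and V/F for tacrolimus),
residual CVs 0.20 pre and post, additive SD 0.5 mg/L for
methylprednisolone. Randomness uses one master seed with per-subject
substreams, so enlarging an arm never perturbs existing subjects.

What the generator does **not** emulate: assay-specific error shapes or
limits of quantification (observations are taken as reported; no BLQ
handling), inter-occasion variability, covariates, drug–drug
interactions on absorption, circuit dead volume or tubing adsorption,
and any pharmacodynamics. Passing recovery tests therefore show that
the estimator inverts its own generative assumptions at the study's
design, not that real sheep data are this well behaved.

## Problem sizes used in validation

The validation suite balances statistical resolution against desk-scale
runtimes: model-discrimination and recovery studies use 50 subjects
with 15-min paired sampling (50 replicates for recovery);
likelihood-ratio calibration under a constant-adsorption truth uses 100
replicates of the animal-scale design (5+3 subjects, 30-min sampling);
the Laplace-vs-quadrature check runs on 3-subject studies. The
two-eta (tacrolimus) recovery check runs at n=20 on a single replicate.

## Known limitations

* The Laplace approximation is least accurate for very sparse designs
  (few observations per subject) — exactly where the quadrature oracle
  test guards it.
* Nelder–Mead is robust but slow for many simultaneous parameters; the
  two-stage split keeps each stage low-dimensional.
* With proportional residual error the OFV optimum on noise-free data
  is not exactly the generating parameter set (the log-variance term
  contributes); self-consistency checks therefore use a fixed additive
  error model.
* The constant-extraction sub-model is the A_max → ∞ boundary of the
  saturable one; under a constant truth the ΔOFV null distribution is a
  boundary mixture, so the saturable extension "wins" in ≈2–5% of
  replicates at the 3.84 threshold, not the nominal 5%.
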