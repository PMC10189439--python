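# Methods

This note documents the models behind `lysisflow`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Similarity scaling

Kinematic similarity between a target vessel and the bench loop is
enforced by matching the Reynolds group G_Re = Q̄/(Dν) and the Womersley
group G_Wo = D²f/ν. Any convention constant in Re = 4Q/(πDν) or
α = (D/2)√(2πf/ν) cancels in the matching condition, so matching the
groups is equivalent to matching Re and α themselves; the reported
profile uses the conventions above. Only cycle-averaged Re is matched —
matching transient systolic/diastolic Re would require a programmable
flow source the lumped pump law cannot represent.

With the peristaltic constraint Q̄_m = k·f_m the three equations reduce
to a cubic with the unique positive root D_m = (k·G_Wo/G_Re)^⅓; f_m and
Q̄_m follow by substitution. Both group residuals are recomputed from
the returned operating point and asserted ≤ 1e-9 relative.

Defaults and parameters that matter:

- **Pump volume per cycle** k = 25 mL, from the nominal law
  Q̄ = (1 L/min)·f/40 with f read in cycles/min. The empirical bench
  calibration (187 RPM ↔ 913 s⁻¹ wall shear) is *not* consistent with
  this law for any integer roller count, so the two are exposed as
  independent configuration: `PumpLaw.volume_per_cycle` for the
  similarity solver and `shear_from_rpm` (proportional, anchored at a
  measured RPM/shear pair) for speed calibration.
- **Tubing bore**: 5/32 in is 3.96875 mm by exact conversion; the
  constant `TUBING_ID_5_32_IN = 3.9688 mm` (4-digit engineering value)
  is used in the shear formulas, a 0.002% difference.
- **Chandler loop shear** assumes the fluid slug is held by gravity
  while the tube rotates, so the mean wall-relative velocity equals the
  drum surface speed 2πR·rpm/60; curvature (Dean-flow) corrections are
  out of scope. At 40 RPM, R = 5.5 cm, 5/32-in tubing this gives
  464 s⁻¹.
- **Entrance length** uses the standard laminar correlation
  L_e = 0.06·Re·D. For plasma viscosities 1.1–1.5·10⁻⁶ m²/s at the
  398 s⁻¹ condition L_e stays below the 36-cm clot position.
- **Laminar-only scope**: all relations assume Poiseuille flow;
  operations warn (not fail) above Re = 2100.
- Internal units are strictly SI; the config/CLI layer converts from
  clinical units (mmHg = 133.322 Pa, in = 25.4 mm exact, L/min, µM).

A note on the elevated reservoir: an 8-cm head of plasma is ρgh ≈
6 mmHg of hydrostatic pressure, while bench practice reports ~12 mmHg
mean operating pressure at the downstream sensor — the difference is
supplied by the pump through the resistive network, not by the head.
`hydrostatic_dp` computes only the physics.

## Loop simulator

No circuit description of the physical loop exists, so the simulator is
the *minimal* lumped model that reproduces dampening behaviour: a
single pressure node (pump outlet + dampener) with isothermal gas
compliance C = V_a/P_ref, discharging through Hagen–Poiseuille
resistances (upstream segment; downstream segment multiplied by a
scalar clot-occlusion factor ≥ 1) into a constant-pressure reservoir:

    C·dP₁/dt = Q_pump(t) − (P₁ − P_res)/R_total

Sensor A sits after the upstream segment, sensor B between the clot
and the return line, so P_A = P₁ − R_up·Q_out and
P_B = P_res + R_down·Q_out. The measured pulse amplitudes
(4/20/40 mmHg at 60/5/1 mL dampener air) are treated as a *qualitative
ordering* target only: reproducing them quantitatively would require
roller geometry and tubing inertance values that are not available.
The model's validated behaviours are (i) exact steady state under
constant flow, (ii) small-signal agreement with the analytic RC filter
gain 1/√(1+(2πfRC)²) to 2%, (iii) strictly increasing amplitude as air
volume drops, (iv) volume conservation over a steady cycle.

Numerics: fixed-step RK4; dt must satisfy dt ≤ 1/(200f); integration
starts at the steady operating point and the first half of the
simulation is discarded as transient anyway; non-finite states raise
an integration error naming dt. Systolic/diastolic are per-cycle
extrema means with cycles delimited by rising zero crossings of the
detrended signal; a constant trace reports zero amplitude and NaN
period. Default absolute reference pressure for the gas compliance is
772 mmHg (atmosphere + 12 mmHg operating mean). Whether the quoted
1/5/60 mL syringe figures are air or liquid volumes is ambiguous; they
are interpreted as trapped air volumes and are configurable.

Pump shapes: full-wave rectified sine (peristaltic rollers), constant,
on/off gated with amplitude 1/duty (heartbeat bot at ~1 Hz), and a
small-signal sinusoid used for filter validation. All shapes
time-average exactly to the programmed mean flow.

## Trace kinetics

The generator is phenomenological, not mechanistic: a lag (default
10 min — linear phases develop about 10 min after drug addition),
a linear release phase at slope s, saturation at the releasable total
S_max, additive baseline B₀ and background drift b, i.i.d. Gaussian
noise (default σ = 0.5 RFU, chosen to visually match bench scatter),
and a constant multiplicative quench factor (1−q) on released signal
(hemoglobin/self-quenching; time-varying quench dynamics are out of
scope). Preset slopes encode the observed condition means: 0.43 / 0.53
/ 0.73 / 1.17 RFU/min for 0/40/200/1000 ng/mL tPa at constant shear;
ratio-only conditions (pulsatile +19%, heartbeat +63%) anchor their
dampened baseline at 1.00 RFU/min because only the ratios, not the
baselines, were reported. Default S_max = 150 RFU keeps 60-min runs in
the linear phase. `digestion_pct` is defined as released / releasable
fluorescence × 100 (no standard definition exists).

The analyser scans every window of length ≥ 20 min starting after a
10-min exclusion with OLS. Among windows with r² ≥ 0.95 it selects the
one maximising the noise-penalised slope, score = slope − 6·SE(slope),
and reports that window's OLS slope; if nothing reaches r² ≥ 0.95 the
max-r² window is used. On noiseless data SE = 0, so the rule is exactly
"steepest well-fitting window" and recovers generator slopes to
rounding while never starting before the lag. The SE penalty exists
because a plain argmax of slope over thousands of overlapping noisy
windows is upward-biased (≈+6% for the shallowest preset at
σ = 0.5 RFU); with the penalty the selection bias is below 1% for all
presets, and the mean recovered slope over 20 replicate seeds sits
within 5% of the generator value, the recovery level the acceptance
checks assert. The penalty weight 6 is deliberately heavy — selection
should be driven by robustness (long windows), with slope deciding only
between comparably precise candidates.

Calibration: 0.1 nM FITC-fibrinogen per RFU (fluorometer gain),
fibrinogen molar mass 340 kDa, default 50 mL circulating volume. The
mass release rate is nM/min × 10⁻⁹ mol/L × MW(g/mol) × V(L) × 10⁶
µg/g. Reported bench correlation coefficients between mass loss and
fluorescence rise (0.91/0.78/0.81 across digestion modalities) depend
on unpublished per-clot raw data; `pearson_r` provides the statistic
but those values are context, not reproduction targets.

## Composition analysis

The synthetic section is a per-pixel class map (RBC / fibrin / WBC /
background) drawn from a spatially correlated RBC-probability field:
p(x) = sigmoid(logit(p₀) + h·g(x)) with g a unit-variance Gaussian
random field of ~1 mm correlation length (Gaussian-filtered white
noise, wrap-around boundaries). The `heterogeneity` parameter h is the
SD of the local log-odds; h = 0 is the homogeneous binomial limit
(5-ROI COV < 0.05 at default resolution). The presets
`well_mixed` (h = 0.62) and `control` (h = 2.30) were calibrated by
simulation so the mean 5-ROI COV lands near the levels observed for
well-mixed (~0.18) and poorly mixed (~0.49) clots. Non-RBC pixels
split 80/5/15 between fibrin, WBC and background — a plausible fibrin-
dominated remainder, not a measured one.

Defaults: 10 × 10 mm section at 20 µm/pixel, five 2 × 2 mm ROIs,
sample (n−1) SD in COV = SD/mean (the estimator is not standardised in
practice; the population-SD choice would shrink COV by √(5/4) ≈ 1.12).
ROIs are uniformly placed and constrained pairwise non-overlapping
(rejection sampling; geometric error if they cannot fit). Coordinates
are 0-based, top-left origin, half-open intervals. Rendering uses a
fixed palette (dark red / pink / blue / off-white) and classification
of rendered images is nearest-palette-colour, exact by construction on
synthetic renders; real H&E stain variation, nucleus detection and WBC
differentials are out of scope, so passing these tests demonstrates
the *metrics* are correct, not that real-slide segmentation would be.

`cov_from_summary` applies the same SD/mean definition to printed
mean ± SD summaries (e.g. the fluorometer step-injection repeatability
62.8 ± 7.4 → COV 11.8%).

## Reagents

Mixing arithmetic only: spike concentration native/r (default 3 mg/mL
native fibrinogen, 340 kDa — the standard literature value, exposed in
the plan), molarity exo(g/L)/MW; recalcification volume
v = target·V/(stock − target), exact including self-dilution. Dilution
of other blood components by the spike volume is neglected (a vehicle
control handles it experimentally). The CaCl₂ stock concentration is
an input — it is not standardised.

## What the synthetic generators do not show

Synthetic traces share the noise model, not the biochemistry: there is
no tPa/plasminogen reaction kinetics, no RBC-release burst, no
clot-rupture events. Synthetic sections have exact labels and a clean
palette. Tests passing on these fixtures validate the analysis chain
(estimators, geometry, calibration algebra) — they do not validate the
platform against new wet-lab data.

## Problem sizes

Simulations in the test suite run 40–60 pulse periods at 400–500 steps
per period (scalar RK4); trace analyses use 60-min, 121-sample traces
with 20 replicate seeds; histology fixtures are 500 × 500 px. These
sizes put every quantity well inside its tolerance while keeping the
whole suite around ten seconds.
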