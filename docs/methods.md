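# Methods

This note documents the models, parameter choices and numerical decisions
behind glucoloop, what the synthetic generators do and do not emulate,
and the known limitations.

## Endpoint extraction

A chronoamperometric current decays toward a diffusion-limited
quasi-plateau; the raw tables the package ships report a single current
per concentration without stating how it was reduced from the 30 s
recording. The package's rule is the time-weighted (trapezoid) mean of
the piecewise-linear interpolant over exactly the final 10% of the time
span (t ∈ [27, 30] s at the nominal duration). Averaging over a window,
rather than taking the last sample, suppresses measurement noise by
roughly √n of the tail samples (~31 at the default 10 Hz) and is
insensitive to whether a sample lands on the window boundary; the
tail-fraction is a parameter (`tail_fraction`, default 0.1). Whether the
printed values were endpoint, mean or peak currents is unknowable from
the source data; the round-trip tests only require internal consistency
of the blank subtraction, which holds regardless.

Units: all table currents are interpreted as μA. This is an assumption,
supported by the potentiostat's ±10 μA measurement range and by every
printed magnitude being ≤ 9.98.

## Fixture corrections

Two cells of the packaged raw table deviate from the printed source, both
flagged in the loader's provenance records:

- sensor 3 at 50 μM prints a positive raw current (+3) while its printed
  blank-subtracted response is 6.98; since −3.00 − (−9.98) = 6.98 the
  fixture stores −3.00 (sign-corrected);
- the raw table's ninth column header repeats "100 μM"; it is read as
  1000 μM, matching the derived table's header.

Both CSVs are SHA-256 checksummed at load; tampering raises an integrity
error.

## Calibration model

The default realization of the "sigmoidal" concentration-response shape
is a four-parameter logistic (4PL) on x = log10(concentration), the
standard model for saturating immuno/enzymatic assays. Fitting is
ordinary least squares via `scipy.optimize.curve_fit` with a fixed,
deterministic initialization (asymptotes from the observed extreme
responses, inflection at the median log-concentration, slope sign from
the linear trend), so identical tables always give identical curves.

Two exclusion rules run before/around the fit, both logged on the curve:

1. points that break the declining trend past the response peak by more
   than 0.5 μA are excluded up front (e.g. sensor 3's upturn at 1600 μM:
   2.33 → 3.56 μA cannot belong to a monotone branch);
2. at most one further point whose residual exceeds 3× the robust
   residual SD (1.4826·MAD) is dropped and the curve refitted.

Non-monotone data are therefore never silently averaged into a monotone
curve. A monotone PCHIP interpolant is available (`monotone_interpolant`)
for sensors the 4PL fits poorly.

**Monotone range and inverse prediction.** The usable branch is the
concentration sub-range where |df/dx| ≥ a slope threshold (default
1e-3 μA per decade, evaluated on a 512-point grid; the 4PL derivative is
unimodal so the region is contiguous). Inversion uses `brentq` on that
branch. Responses above/below the branch's response span return boundary
projections flagged `below_range` / `above_range`, or `saturated` when at
the lower asymptote (within 0.05 μA). Estimates are never extrapolated
beyond the fitted concentration span scaled by [0.5, 2] — the data give
no basis for extrapolation bounds, so this guard is the package's own
choice. Confidence intervals propagate the fit covariance plus residual
variance through the inverse by the first-order delta method and are
documented as approximate.

**Usable-slope gate.** The five shipped sensors are nearly flat below
~400 μM (the 10–400 μM responses span ~0.3 μA, within noise). An
inversion there is numerically defined but scientifically meaningless: a
0.02 μA perturbation moves the estimate across the whole plateau. The
curve-level threshold (1e-3) keeps such regions formally invertible, but
`estimate_concentration` accepts a caller-side `min_slope`, and the
closed loop requires 0.5 μA/decade: estimates where the curve is flatter
are flagged `ambiguous_nonmonotone` and produce logged NO_ACTION
decisions. Without this gate, endpoint noise produces spurious therapy
triggers at true concentrations well below threshold.

## Decision engine

"Surpassing 400 μM" is read as strictly greater-than; the boundary case
(exactly 400) does not trigger and is pinned by test. The cooldown
default of 1800 s prevents re-dosing on persistent hyperglycemia — the
source system's re-trigger behavior is undocumented, so this is a policy
default, not a claim. Blood-glucose bounds (hypo < 70, hyper >
130 mg/dL) are carried as documented constants only: no sweat-to-blood
mapping exists in the source data, so decisions compare sweat estimates
directly against the sweat threshold. The wire protocol to the release
circuit is a line-delimited JSON message (`htrc_command`), byte-stable
for fixed inputs.

## Thermal release circuit

**Electrical.** The 9 × 330 Ω ladder is taken as parallel across a 5 V
rail: per branch P = V²/R ≈ 75.8 mW (under the ½ W rating), total
≈ 0.682 W. The series alternative dissipates only ~8.4 mW — three orders
short of what heating a patch to 40 °C requires — so parallel is the only
physically coherent reading, and the supply voltage (unstated in the
source) is set to the 5 V logic rail the named microcontroller provides.
Modulation by the pass transistor is modelled as slow PWM (duty cycle on
a 1 s control period); average power scales linearly with duty.
Per-resistor dissipation is checked against the rating at construction
and again per duty request (clamp or raise, configurable).

**Plant.** Lumped capacitance: dT/dt = P/C_th − (T − ambient)/τ, explicit
Euler at dt ≤ 1 s (default 0.5 s; halving dt moves a 600 s endpoint by
< 0.05 °C). Defaults C_th = 5 J/°C, τ = 110 s, ambient 25 °C were chosen
so the full-duty steady state, ambient + P·τ/C_th, is exactly 40.0 °C:
the heater is sized to land the surface at the top of the gelatin window,
and the controller's role is to guard against overheating rather than to
chop a grossly overpowered heater. (A heavier/leakier plant — e.g.
C_th = 20 J/°C with τ = 120 s — cannot exceed ~29 °C at 0.68 W and can
never reach the transition window at all; the safety test grid covers
such cells and asserts only the safety bound there.)

**Sensing and control.** The temperature readout models a linear
10 mV/°C sensor quantized by a 12-bit ADC over 5 V (≈ 0.12 °C per count)
with additive Gaussian noise (default SD 0.1 °C); an NTC thermistor path
via the Steinhart–Hart equation is provided as an alternative and agrees
with the linear sensor within 0.5 °C over 30–45 °C when cross-calibrated.
Control is hysteresis (bang-bang): full duty below setpoint − band, off
above setpoint, unchanged inside the dead band. Defaults are setpoint
40 °C and band 0.5 °C, i.e. on below 39.5 °C, off above 40 °C — the upper
half of the 37–40 °C transition window. A wide band (e.g. 2 °C) makes the
loop limit-cycle across 38–40 °C with a time-mean near the band center
(~39 °C); the narrow band keeps the dwell at 39.5–40 °C so the plateau
mean rounds to 40 °C, maximizing thermal activation of the patch while
never exceeding 41 °C. The ADC resolution was chosen so quantization
(0.12 °C) does not swamp the dead band.

**Release.** Payload release is first-order,
df/dt = a(T)·k·(1 − f), with activation a(T) ramping linearly from 0 at
37 °C to 1 at 40 °C and k = 1/600 s⁻¹ (≈ 63% released after 10 min at
full activation). The kinetic law and rate are this package's model of
"viscosity diminishes → controlled diffusion"; no release-rate data exist
in the source. The update uses expm1 so zero activation changes nothing
exactly, and the fraction is non-decreasing by construction.

## Closed loop

`run_closed_loop` senses through the full chain at each sampling instant:
it synthesizes a 30 s CA trace whose plateau is the sensor blank plus the
fitted response at the true scenario concentration (Gaussian current
noise, default SD 0.05 μA), extracts the endpoint, blank-subtracts,
inverts the curve with the 0.5 μA/decade gate, and feeds the estimate to
the decision engine. The first trigger starts the thermal simulation with
a derived seed. Runs are pure functions of (config, seed); the event log
embeds the config hash and seed for provenance.

## Synthetic generators

- **Traces**: i(t) = plateau + A·exp(−t/τ_tr)/√(t + t₀) + N(0, σ), with
  t₀ = 0.1 s regularizing the diffusion-like 1/√t singularity and
  τ_tr = 2 s cutting the transient off well before the endpoint window
  (so a noiseless trace's endpoint equals its plateau to < 0.01 μA).
  Currents are clipped to the ±10 μA instrument range, which only affects
  the early transient. Noise is homoscedastic Gaussian; no drift or
  flicker components.
- **Panels**: per-concentration traces whose plateaus default to the
  packaged fixture row, so a zero-noise panel reproduces the printed
  table to within 0.01 μA.
- **OGTT cohorts**: per-subject independent Gaussian draws around group
  profiles, truncated at a 40 mg/dL physiological floor. The 0 h and 1 h
  group means/SDs are the reported values (control 188±46 → 340±100,
  sitagliptin 163±25 → 305±60, dapagliflozin 183±50 → 207±36 mg/dL); the
  2 h and 3 h values are *not* reported anywhere and are invented as a
  linear return toward baseline (2 h midway, 3 h at baseline), matching
  the qualitative "returned to normal after 3 h". Reported per-group AUC
  values therefore cannot be reproduced desk-side and are not claimed.

What passing tests show — and do not. The generators emulate the
structure of the data (plateau levels, noise magnitudes, group means),
not real sweat physiology: no sensor drift, temperature sensitivity,
sweat-rate or lag effects, and no within-subject correlation across OGTT
time points. Tests passing on synthetic data demonstrate the algorithms'
correctness under the stated models, not field performance of a physical
device.

## Problem sizes and determinism

Default study sizes: 30 s traces at 10 Hz (301 samples); 600 s thermal
runs at dt = 0.5 s; 20-seed thermal replication; 200-replicate
inversion Monte-Carlo; OGTT cohorts of n = 1000 per group for
mean-recovery checks and n = 10 for the worked example. All randomness
flows through `numpy.random.default_rng` seeds; identical inputs give
byte-identical outputs across runs and platforms.

## Limitations

- The calibration plateau below ~400 μM makes low concentrations
  unquantifiable with these sensors; the package flags rather than fixes
  this.
- The thermal plant is single-node: no spatial gradients across the 5 × 1
  cm² patch grid, no transistor or PCB transients.
- Confidence intervals on inverse predictions are first-order
  approximations and degrade near the asymptotes (where they are wide by
  construction).
- OGTT statistics beyond AUC/mean/SD (ANOVA, t-tests) are routine scipy
  wrappers, provided for convenience only.
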