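# Methods

`afloop` simulates left-ventricular (LV) function under the rhythm
disturbances of atrial fibrillation (AF) with a lumped-parameter (0D)
four-chamber heart coupled to a closed-loop systemic and pulmonary
circulation, and runs a paired 2×2×2 in-silico trial — heart rate
(61 vs 94 bpm) × rhythm regularity (regular vs AF-like irregular) ×
atrial contraction (effective vs disabled) — on a calibrated cohort of
ten virtual patients.

## The heart model

**Chambers.** Each chamber (LA, LV, RA, RV) is an equivalent thin-walled
sphere with cavity volume `V`, unstressed volume `v_ref` and wall volume
`v_wall`. Fiber stretch is `λ = (V/v_ref)^(1/3)`. Cavity pressure is

```
P(V) = k_passive · (exp(α·(V/v_ref − 1)) − 1)  +  (2/3) · σ(t, λ) · v_wall / V
```

The first term is an exponential end-diastolic pressure–volume relation
(EDPVR), gently negative below `v_ref`; the second is the Laplace law
`2σh/r` for a sphere (`h = v_wall / 4πr²`), converting active wall
tension `σ` (kPa) to pressure (mm Hg).

**Active tension.** A reduced Land-type model: a single activation gate
`a` obeys `da/dt = k_on·s·(1−a) − k_off·(1−s)·a` with Hill drive
`s = Ca^n / (Ca^n + ca50_eff^n)`, and developed tension is
`σ = T_ref · a · g(λ)`. Length dependence (the Frank–Starling
mechanism) enters twice: the ascending-limb scale
`g(λ) = clip(1 + β·(λ−1), 0, 2.5)` and a milder calcium sensitisation
`ca50_eff = ca50 · max(0.45, 1 − 0.08·β·(λ−1))`. The slope `β` must
exceed ~3 for a spherical chamber to have positive volume-stiffness
while contracting (pressure carries a 1/V factor and V ~ λ³); the
ventricular default β = 14 additionally produces an end-systolic
elastance of a few mm Hg/mL, so end-systolic volume is only mildly
afterload-sensitive, as in intact ventricles. The sensitisation slope is
kept small deliberately: a steep slope pushes `ca50_eff` below diastolic
calcium at end-diastolic stretch and produces spurious resting tone that
destroys preload reserve. Setting `contraction_enabled = False` forces
`σ ≡ 0`, which is how ineffective (fibrillating) atrial contraction is
modelled.

**Calcium.** Each activation starts a prescribed two-exponential
transient rising from the diastolic level `c_dia` (0.1 µM) to a peak at
`t_peak` and decaying with `tau_decay`; ventricular: 50/85 ms, atrial:
35/75 ms. Rate dependence enters through amplitude *restitution*: the
transient is scaled by `f(rr) = rr^k / (rr^k + rr_half^k)` of the
preceding R-R interval, a monotone sigmoid saturating to 1 for long
diastolic intervals. Ventricular restitution is shallow
(`rr_half = 0.15 s`) — force falls only slightly at 94 bpm; atrial
restitution is steeper (`rr_half = 0.50 s`, slope 6.5), so the atrial
kick weakens substantially after short diastolic intervals.

**Circulation.** Four resistive diode valves (flow only down the
pressure gradient) connect the chambers through four linear-compliance
compartments (systemic/pulmonary, arterial/venous) with series
resistances. Total blood volume is fixed; preload and afterload on every
chamber are emergent. Atria activate one atrio-ventricular delay
(0.16 s, configurable) before their ventricles. None of these values are
patient data — they are package reference values for a 117-mL-EDV adult,
chosen so a calibrated heart operates at 90–140/60–90 mm Hg aortic
pressure with LVEF in the mid-50s at 61 bpm, with a pulse pressure,
ejection duration and venous time constants in plausible adult ranges.
Chamber geometry (`v_ref`, `v_wall`) scales linearly with the patient's
target EDV; vascular properties do not.

**Integration.** Explicit fixed-step Heun (RK2), dt = 1 ms by default.
Volume conservation is exact by construction (every flow leaves one
compartment and enters another); a step-halving test bounds the
discretisation error on stroke volume below 0.5%. Activation gates are
clamped to [0, 1]; non-finite states raise a diagnostic error.

## Virtual cohort and calibration

The synthetic cohort emulates an imaging-derived AF population: per
patient, target LV EDV ~ Normal(117, 30²) mL truncated to [60, 220]
(truncation shifts the true mean to ≈119 mL and SD to ≈28 mL — the
parent parameters are kept as the sampling law), sex assigned by exact
count (round(0.6·n) male), age and BMI as inert metadata. Generation is
a pure function of (n, seed, spec).

Calibration fits four parameters per patient — total blood volume,
systemic resistance, a ventricular contractility scale and a ventricular
passive-stiffness scale — so that regular sinus rhythm at 61 bpm
satisfies: aortic systolic 90–140 mm Hg, diastolic 60–90 mm Hg,
LVEF > 50%, EDV within 5% of target. The fit is a damped coordinate
descent (blood volume ← EDV error; stiffness ← pre-A-wave LV EDP toward
8.5 mm Hg; resistance ← mean aortic pressure toward 88 mm Hg;
contractility ← EF toward 54%, a mid-normal set-point *inside* the
window), with a Nelder–Mead fallback on the summed squared window
violations. A calibration run settles 12 beats so the slow
venous-reservoir modes equilibrate; the end state is stored as the
patient's baseline operating point. Every scenario simulation starts
from that state — the trial's short 5- and 12-beat protocols presume a
hemodynamically settled patient, and the large venous reservoirs hold
chronic pressures approximately fixed across an acute rhythm change.

## Trial protocol and statistics

Regular arms run 5 beats and analyse the final beat; irregular arms run
3 warm-up plus 9 analysed beats. Irregular R-R intervals are drawn from
a lognormal law with coefficient of variation 0.24, truncated to
[0.3, 2.0] s by rejection. One sequence per rate level is shared by the
whole cohort and across atrial-contraction arms (the trial design uses
exactly two irregular rhythms), and each drawn block is rescaled so the
mean of the diastolic intervals feeding the analysed beats equals the
regular arm's cycle length exactly — the regular rates are defined as
the averages of the irregular sequences, so paired regular/irregular
contrasts isolate rhythm *shape* from mean rate.

Per beat, EDV is the LV volume at the instant of ventricular activation
(so filling and restitution attribute to the correct beat in irregular
rhythms), ESV the minimum over that beat's window, and aortic
systolic/diastolic pressures the window extrema. Endpoints are LVSV and
LVEF — final-beat values for regular arms, means over the 9 analysed
beats for irregular arms.

The cohort summary reports scenario means ± SD, per-patient percent LVSV
change and absolute LVEF change (percentage points) versus untreated AF
(rapid irregular, no atrial contraction), each with both the cohort SD
and the SEM of paired differences (the source convention is ambiguous,
so both are emitted under explicit column names). Paired t tests compare
the four labelled management arms against untreated AF with Bonferroni
correction over that family (m = 4) at α = .01. Zero-variance
conventions: identical pairs give p = 1; a constant nonzero shift gives
p = 0.

## Numerical and design choices

- dt = 1 ms Heun; activation events are snapped to the step grid.
- Valves are resistive diodes without inertance or regurgitation.
- No pericardium, no direct septal coupling, no baroreflex: chamber
  interaction is carried by the closed loop only.
- `beat_metrics` defaults to window-maximum EDV for generic traces; the
  simulator uses window-start EDV (see above).
- Degenerate inputs: zero-cv distributions produce exactly constant
  intervals; a constant volume trace yields SV = 0, EF = 0.
- The Nelder–Mead fallback and all sampling are seeded/deterministic;
  rerunning any pipeline stage with the same configuration is
  bit-identical.

## What the synthetic data do and do not capture

The generator reproduces the marginal demographics and EDV spread of a
small AF cohort and AF-like R-R interval statistics. It does not carry
image-derived anatomy, fibre architecture, per-patient
electrophysiology, or any demographic→physiology coupling (age, sex and
BMI have no hemodynamic effect), and all patients share the same
material parameters up to the four calibrated scales. Consequently the
cohort's EF dispersion (SD well below 1 percentage point) is far
narrower than clinical EF spread — paired within-patient contrasts are
meaningful; between-patient variance is not.

## Known limitations

- **Irregularity and the atrial kick.** In the source trial an
  irregular rhythm at physiological mean rate removes essentially the
  whole atrial-kick benefit (LVSV −13.7% with atrial contraction, while
  irregularity without atrial contraction is cost-free). This model
  reproduces the *direction* but only ~1% of the magnitude. The cause is
  structural: with a monotone single-interval restitution curve, the
  mean kick over a symmetric interval distribution approximately equals
  the kick at the mean interval, and any curve steep enough to cancel it
  would also kill the kick at the *rapid regular* rate (0.64 s, shorter
  than nearly all irregular-61 intervals), grossly inflating the rate
  effect. Cancelling the kick under irregularity while preserving it at
  fast regular rates requires multi-beat calcium memory in the atrial
  myocyte (CaMKII-type rate adaptation), which is outside this package's
  phenomenological restitution abstraction. The two affected endpoints
  (irregularity LVSV drop; the EF contrast of sinus-rhythm-with-
  irregularity versus AF) are therefore under-reproduced, and the
  acceptance suite reports them as failures rather than hiding them.
- LV end-diastolic and pulmonary venous pressures sit at the high end of
  the physiological range (diastolic-dysfunction-like), a side effect of
  the stiff EDPVR needed for a robust atrial-kick contribution.
- Ejection is somewhat shorter and more impulsive than a real LV
  outflow profile; valve dynamics are quasi-static.
- Only two heart-rate levels are simulated, and ectopic beats are not
  modelled.
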