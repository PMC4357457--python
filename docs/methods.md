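# Methods

## Model structure

The circulation is a closed hydraulic loop of eight storage compartments:
left atrium (la), left ventricle (lv), right atrium (ra), right ventricle
(rv), systemic arteries (sas), systemic veins (svn), pulmonary arteries
(pas) and pulmonary veins (pvn).  Volumes are the primary states; every
pressure is derived algebraically from volume, which makes total blood
volume a *linear invariant* of the vector field — conservation is then a
property of the equations, not of the solver, and both Runge–Kutta and
multistep methods preserve it to round-off.

* Chambers: P = [E_min + a(t)(E_max − E_min)](V − V_un).  The activation
  a(t) resets at every RR onset, rises as sin² to 1 at `act_peak_frac·T_sys`
  and relaxes as cos² to 0 at `T_sys = tsys_k·√RR`; the square-root law
  shortens systole less than the beat, so the systolic *fraction* grows at
  fast rates and diastolic filling time is disproportionately eroded — the
  central rate-dependence of the experiment.  An asymmetric pulse (peak at
  ~63% of systole) is used because a symmetric pulse makes the early
  elastance rise so fast that ejection degenerates into a single
  unphysiological flow spike (>1500 mL/s) with mid-systolic valve closure
  and reopening.
* Atria are passive: constant elastance at all times, the loss of atrial
  kick that defines fibrillating mechanics here.  Both ventricles share
  the activation clock.
* Vessels: P = (V − V_un)/C, connected by linear resistances
  (systemic arteries→veins→right atrium; pulmonary arteries→veins→left
  atrium).
* Valves: rectifying diodes with series resistance R and inertance L on
  all four branches: L·dQ/dt = ΔP − R·Q while the valve conducts (Q > 0 or
  ΔP > 0); a shut valve's flow state relaxes to zero (time constant 2 ms).
  Mass transfer uses the rectified flow max(Q, 0), so no regurgitation is
  possible by construction.  The inertances matter physiologically: mitral
  inflow momentum lets diastolic filling overshoot the pressure equilibrium
  (the E-wave), which is (a) how the end-diastolic LV pressure can exceed
  the pulmonary-venous pressure, and (b) a key mechanism limiting filling
  when diastole is short.

## Numerical integration

The diode switching makes the right-hand side non-smooth.  Adaptive
implicit multistep codes (LSODA/BDF/Radau) either fail outright or crawl on
this field — their Newton iterations and error estimators assume a smooth
Jacobian across steps; a sigmoid-regularised valve law was tried and made
the system so stiff near closure that LSODA needed minutes per handful of
beats.  The default integrator is therefore a compiled classical RK4 with
fixed step `dt = 2e-4 s`, comfortably resolving the fastest mode (the 2 ms
valve-relaxation) and the valve transitions; explicit methods are
indifferent to the switching.  Design safeguards:

* Step robustness: halving `dt` changes the 100-beat mean stroke volume by
  < 0.5% (tested).
* Independent route: any scipy `solve_ivp` method can be selected through
  `SolverOptions.method`; a test integrates the same regular-rhythm run
  with adaptive RK45 at rtol 1e-8 and requires LV-volume agreement within
  0.05 mL.
* Conservation: total-volume drift is checked after every run
  (tolerance 1e-6 relative; observed ~1e-13 over 5000 beats) and raises an
  error if exceeded.

Each beat is integrated on its own activation clock and sampled on a
uniform 200-point grid; warm-up beats (default 20, run at the sequence
mean RR) flush the initial condition and are discarded before analysis.

## Event detection and indices

Valve events are read from the *unrectified* flow states: a closure is a
downward zero crossing, located by linear interpolation between samples.
End-systole is the last aortic closure in the beat (early ejection can
ring against the arterial impedance); end-diastole is the first mitral
closure in the beat — the closure that seals the ventricle as its
contraction begins — or the beat onset if the valve was already shut.
Beats whose aortic valve never opens are flagged non-ejecting, excluded
from ejection statistics and reported as a count (none occur at the study
conditions; they appear only at extreme tachycardia).

Stroke work is the absolute shoelace area of the sampled LV
pressure–volume path with the loop closed by a chord; 1 mmHg·mL =
1.33322e-4 J.  PE uses the end-systolic/end-diastolic formula with
V_un = 5 mL.  Per-minute indices (CO, RPP, TTI/min, PVA/min) are formed
per beat with the instantaneous rate 60/RR and then averaged; with
irregular rhythm this exceeds the product of the means (Jensen's
inequality), and the per-beat convention is the one consistent with the
reported index tables (e.g. mean RPP exceeds mean systolic pressure times
the nominal rate).

## RR generator

`exgauss_from_moments` solves μ_g, σ_g, τ from the target mean and cv; the
Gaussian/exponential variance split is not identified by those two moments,
so it is exposed as `tau_fraction` (default 0.5, an equal split).  The
split mainly shapes the right tail; the simulated indices depend on it
weakly compared to cv itself.  Sampling rejects draws below the 0.3 s
refractoriness floor from a single seeded stream (bit-reproducible); since
truncation would otherwise inflate the mean (+2% at 130 bpm) and deflate
cv (0.218 vs 0.240), the underlying distribution is pre-adjusted by a
fixed-point iteration on its first two moments so the floored distribution
matches the targets essentially exactly.  cv = 0 is supported as a
degenerate regular-rhythm mode and is used for periodic-steady-state and
calibration checks.

## Parameter set and calibration

The packaged set (`src/afsim/data/default_params.yaml`, clinical units)
was calibrated in two stages: by hand until a regular rhythm at 70 bpm
lies in textbook-normal ranges (EF 55–70%, systolic arterial pressure
100–130 mmHg, left atrial pressure ~10 mmHg), then by a randomized
coordinate search against the reference per-rate index table under the AF
conditions (cv = 0.24), with held-out-seed validation.  The parameters
that matter most, with defaults:

| parameter | default | units | role |
|---|---|---|---|
| lv_emax / lv_emin | 2.11 / 0.099 | mmHg/mL | LV contractility / diastolic stiffness |
| tsys_k | 0.510 | s^1/2 | systole duration T_sys = k√RR |
| act_peak_frac | 0.626 | – | position of peak activation within systole |
| mi_r, mi_l | 0.0115, 6e-4 | mmHg·s/mL, mmHg·s²/mL | mitral filling resistance/inertia |
| ao_r, ao_l | 0.0106, 1.6e-3 | 〃 | aortic impedance (ejection damping) |
| sa_c, r_sys | 1.51, 1.31 | mL/mmHg, mmHg·s/mL | arterial windkessel |
| total_volume | 4680 | mL | mean circulatory filling (preload) |

Sensitivity in brief: `tsys_k` and `act_peak_frac` set the mean LV
pressure and TTI and the P_lv rise with rate; the mitral/tricuspid
inertances set how steeply stroke volume falls with rate (E-wave
truncation); `ao_l`/`ao_r` set closure timing (hence end-systolic
pressure/volume and PE) and ejection pressure (hence SW); `sa_c·r_sys`
sets the diastolic arterial decay and the 50 bpm pulse pressure.

## What the synthetic data does and does not emulate

The RR generator reproduces the marginal AF interval distribution
(right-skewed, cv 0.24) but draws beats independently — no long-range
correlations, circadian drift or autonomic modulation.  The circulation
has no baroreflex, no coronary circulation, no respiratory coupling, no
valve disease, and a denervated, comorbidity-free heart; contractility and
vascular tone are rate-independent.  Passing tests therefore demonstrate
the *isolated* hemodynamic effect of mean ventricular rate under those
assumptions, not a prediction for any individual patient, and exercise
states (inotropic/chronotropic co-activation) are outside the model's
domain.  The analytic beat fixtures (rectangles, ellipses, planted valve
events, Gaussian summary streams) exist purely to pin the index
arithmetic; they are deliberately non-physiological.

## Problem sizes

The study conditions are 5000 analyzed beats per rate; the test suite runs
the two extreme rates at that full size (shared session fixtures) and the
five-rate directionality sweep at 500 beats per rate, where all fourteen
reference signs already reproduce and means agree with the 5000-beat runs
within a few standard errors.  A 5000-beat rate takes ~10 s (compiled
path) on one CPU.

## Known limitations

* The absolute index values depend on a calibrated parameter set; the
  percent-variation structure across rates is the robust surface, the
  absolute means carry calibration uncertainty of a few percent.
* The diode valve has no leaflet dynamics or regurgitation; closure
  timing (and hence end-systolic readings) inherits the inertance choice.
* The global time-average and the per-beat-mean conventions for
  beat-mean pressures differ by ~3% under irregular rhythm; the per-beat
  convention is used throughout.
* Fixed-step integration trades adaptive error control for robustness to
  valve switching; the step-halving and cross-solver tests bound the
  residual error.
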