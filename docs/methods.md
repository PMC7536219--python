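# Methods

`tiltsim` simulates the short-term autonomic control of circulation during a
passive head-up tilt test and computes the observables used to characterize
it: heart rate, per-beat systolic/diastolic pressure, LF/HF spectral powers
of the RR tachogram, and the total percent of phase synchronization
(S index) between the ~0.1 Hz components of heart rate and arterial
pressure.

## Model

The model is a lumped, beat-resolved delay-differential system.  Its core
assumption is that the low-frequency (~0.1 Hz, "Mayer-wave") rhythms of
heart rate and vascular tone are generated by **self-excited** time-delay
feedback loops in the sympathetic arm — not by passive resonance — and that
the two loops are anatomically separated: the aortic/carotid baroreflex
drives heart rate and contractility, while lower-body arterial
baroreceptors drive peripheral vascular tone.

State variables and equations (all activities/concentrations in arbitrary
units, pressures in mmHg, times in seconds):

* **Sinus node.** A phase oscillator `dphi/dt = f_s f_p / T0`; a beat fires
  when `phi` crosses 1.  `T0 = 1.1 s` is the intrinsic (denervated) period.
  The sympathetic chronotropic factor saturates in cardiac noradrenaline,
  `f_s = 1 + k_fs c_c / (1 + c_c / c_sat_s) >= 1`; the vagal factor is
  `f_p = 1 - k_fp (1 - exp(-v_p / v_sat_p)) <= 1`.
* **Arterial pressure.** During the systolic upstroke (duration
  `tau_sys = 0.125 s`) pressure follows the smooth pulse
  `p = DAP + s·x·e^(1-x)` with `x` the phase fraction, peaking at
  `SAP = DAP + s`.  Contractility
  `s = S_max (1 - exp(-(s0 + k_sc c_c + k_sT T_prev)/S_max))` grows with
  cardiac noradrenaline and with the previous cycle length (Starling-like
  filling).  Diastole is a windkessel runoff `dp/dt = -p/(R C_wk)` with
  `R = R0 + k_R sqrt(c_v)` — a concave uptake law whose calibrated slope is
  deliberately shallow (the reference means pin R at 0.80 supine vs 0.77
  upright while `c_v` falls three-fold).
* **Baroreceptors (two sites).** Warner form, sensitive to pressure and its
  rate: `v_b = max(0, k_bp (p_site - p0) + k_bd dp/dt)`, with `dp/dt` taken
  from the model's own analytic expressions (smoothed systolic upstroke,
  windkessel decay), never from numerical differencing.  The lower-body
  site feels `p + p_hst_lower sin(alpha)/sin(alpha_test)`; the carotid site
  feels `p - p_hst_upper sin(alpha)/sin(alpha_test)`.  Both hydrostatic
  terms vanish supine (`alpha = 0`); the paired signs represent the blood
  column shifting toward the lower body on tilting.
* **Central afferent integration.** The sympathetic loops receive the
  baroreceptor activity through a first-order smoothing stage with time
  constant `T0` (about one cardiac cycle).  Without it, the pulsatile
  afferent signal (swinging several units at heart rate) dithers the loop
  nonlinearities and suppresses their limit cycles; central neurons
  integrating the phasic afferent volley is the physiological reading of
  this stage.  The vagal branch receives the raw phasic signal.
* **Sympathetic loops.** Each loop relaxes toward a saturating (logistic)
  function of its delayed inputs,
  `tau dv/dt = -v + G sigma(a - k_self v(t-theta) - k_baro n_b(t-theta) + k_resp r)`.
  The delayed self-inhibition makes each isolated loop a stable ~0.1 Hz
  limit-cycle oscillator (heart loop delay 3.3 s, vessel loop 3.6 s — the
  slight detuning produces intermittent rather than rigid locking between
  the loops).  Baroreceptor input *inhibits* the loops, so tilting (which
  lowers carotid and raises lower-body baroreceptor activity) raises
  heart-loop and lowers vessel-loop activity.
* **Vagal branch.** Instantaneous (no acetylcholine state, its kinetics
  being much faster than everything else modelled):
  `v_p = max(0, k_pb_u v_b (1 + k_pr r) + k_pb_l v_b^l)`.  Baroreceptor
  drive *excites* the vagal branch.  The respiratory gating is
  multiplicative, so respiratory sinus arrhythmia scales with vagal tone
  and HF power falls in the upright posture, as in real tilt responses.
* **Noradrenaline.** Linear kinetics per compartment,
  `dc/dt = -c/tau + k v(t - theta)` (release delay 1.65 s), so the steady
  state is exactly `k·tau·v` under constant drive.
* **Respiration.** A constant-amplitude sinusoid whose frequency is redrawn
  at every breath onset as `f_br + xi`, `xi ~ N(0, sigma2_xi)`; draws below
  0.05 Hz are rejected and redrawn.  Defaults `f_br = 0.25 Hz`,
  `sigma(xi) = 0.04 Hz` are typical adult spontaneous-breathing statistics.
  This is the model's **only** stochastic input; with `sigma2_xi = 0` every
  run is fully deterministic.

### Sign convention

Descriptions of this system sometimes state that baroreceptor activation
excites the sympathetic arm and depresses the vagal arm.  The reference
operating points this package is calibrated to imply the opposite (and
textbook) signs — sympathetic activity moves against its baroreceptor
input across the posture change, vagal activity moves with it — and the
implementation follows those signs throughout.

### Parameters

47 named coefficients, shipped in `tiltsim/data/default_params.yaml` with a
provenance tag and box constraint each: 14 `fixed` structural constants
(intrinsic period, systole duration, compliance, loop delays and relaxation
times, release delays, saturation scales, reference tilt angle, the unused
lower-baroreceptor-to-vagal gain), 31 `fitted` coefficients (every gain,
set point, offset and decay time the fitting procedure may move), and 2
`from_data` respiration statistics.  The shipped fitted values were
produced by a least-squares calibration of the free-running model against
reference posture-pair operating points for all eleven state variables;
only the 31 fitted-tagged entries ever move during fitting.

## Numerical scheme

Fixed-step integration, `dt = 0.01 s`.  The four slow ODE states (two loop
activities, two noradrenaline concentrations) and the two afferent
smoothing states advance by explicit Euler; activities and concentrations
are clipped at zero after each step (threshold nonlinearity of neural
firing / concentrations).  Pressure is advanced **exactly** within each
step — the systolic pulse is an analytic expression and the diastolic decay
an exponential with the resistance held over the step — so frozen-R
diastolic segments reproduce the closed form to floating-point accuracy.
Delay terms are read from full-history buffers with linear interpolation at
fractional lags; pre-history is the constant initial state.  The beat
threshold crossing is located by linear interpolation inside the step,
giving sub-`dt` beat times (RR intervals are not quantized to the grid,
which would otherwise distort HF power).  Halving `dt` moves the mean RR
interval by well under 0.5 %.  A beat arriving before the previous systole
ends simply starts the new upstroke from the instantaneous pressure; a
non-finite state or a runaway heart rate aborts the run with the first
offending variable named.  Each run draws its respiration from one seeded
generator; ensembles use seeds `seed0 + i`, and paired supine/upright runs
share the seed so posture is the only difference within a pair.

## Tilt protocol and problem sizes

The simulated protocol mirrors the human one (10 min rest, 10 min supine
recording, tilt to 80°, 5 min exclusion, 10 min upright recording) but
replaces the rest/exclusion stages with a discarded equilibration window.
Runs start from a near-operating-point state and discard 300 s by default;
lengthening the discard four-fold moves the reported means by < 0.2 %, and
a conservative two-hour discard remains available via
`TiltProtocol(transient_s=7200)`.  Ensemble summaries in the tests and the
acceptance script use 20 paired realizations with 600 s recording windows —
sizes chosen so the full analysis reruns in seconds while ensemble means
are stable to well under a percent across seed choices.

## Analysis stack

* **Tachogram.** Beat-wise RR intervals are cubic-spline interpolated onto
  a uniform 4 Hz grid.  RR is kept in seconds internally and converted to
  ms for spectral indexes.
* **LF/HF.** Welch averaged modified periodogram: Hann window, 100 s
  segments, 50 % overlap, per-segment mean removal; LF = integral of the
  PSD over 0.04–0.15 Hz, HF over 0.15–0.40 Hz, in ms²; records shorter than
  300 s are rejected (the 0.04 Hz edge cannot be resolved).
* **Phase.** Zero-phase Butterworth band-pass 0.05–0.15 Hz, then the
  analytic-signal (Hilbert) phase, unwrapped.
* **Pressure decimation.** Stored pressure (50 Hz) is low-passed
  (zero-phase Butterworth, 1 Hz) before interpolation to 4 Hz; without
  this, cardiac harmonics alias into the analysis bands and destroy the
  RR–pressure phase relationship.
* **S index.** Plateaus of the unwrapped phase difference are found with a
  sliding 13 s linear fit; a sample is a plateau candidate when the local
  |slope| < 0.01 rad/s, candidate runs shorter than 13 s are discarded, and
  two band-center periods (20 s) at each record end are excluded as filter
  transients.  S is the plateau time divided by the accounted duration, in
  percent.  The window/threshold/minimum-duration defaults are calibrated
  choices, not literature values: `scripts/sync_null_calibration.py`
  re-derives their operating point, showing S = 0 for independent
  band-limited noise and for pairs detuned by ≥ 0.02 Hz, and S ≈ 100 for
  locked pairs at the fixture noise level.  Tightening the slope threshold
  can only shrink S (monotonicity by construction).

## Fitting

The objective is the sum over the five indexes (mean HR in beats/min — the
beats-per-minute convention is a deliberate choice, mean SAP, mean DAP, LF,
HF) of squared relative mismatches against targets; the search stops when
the objective drops below 0.05, at which point each index is within ~10 %
of its target.  The optimizer is a normalized-gradient descent with
variable step: forward finite differences (step 10⁻³ of each box width) in
box-scaled coordinates, step halved on a rejected trial and grown 1.5× on
acceptance, terminating on step underflow at 10⁻⁸ of the initial step.
Only fitted-tagged coefficients move and all iterates respect the box
constraints.  Objective evaluations reuse a common seed list so
finite-difference gradients are not drowned by respiration noise, and a
trial point whose integration fails scores a large penalty (10³) instead of
crashing the search.  Because the human ensemble index targets are not
available to this package, the default targets for fitting experiments are
generated by the model itself (the `model-targets` fixture); the shipped
parameter-recovery experiment perturbs five fitted coefficients by ±20 %
and verifies the descent returns the objective below 0.05 — an
index-surface recovery, with no claim that individual coefficients are
identifiable.

## Synthetic data generator

The fixture generator produces the oracle inputs for the analysis stack:
phase-locked pairs, detuned (drifting) pairs, piecewise-locked pairs with a
known locked fraction, single-tone tachograms, and model-generated index
targets, each with a ground-truth sidecar.  These fixtures emulate the
*analytic* structure of real RR/PPG pairs (band-limited oscillations,
additive observation noise, known locking) but none of the physiological
nuisance of real recordings: no artefacts or ectopic beats, no amplitude
modulation, no nonstationary drift, stationary Gaussian noise at a fixed
level (0.05 of unit amplitude, keeping the oracle sharp).  Passing the
oracle suites therefore certifies the estimators' correctness on clean
signals, not their robustness to real-world recording pathology.

## Known limitations

* The model targets ensemble-average behaviour of a healthy group; it is
  not calibrated for individual subjects, and its realization-to-realization
  spread (driven only by respiration noise) is much smaller than
  between-subject spread in real data.
* Constant-amplitude respiration and the absence of cardiopulmonary
  feedback inflate RR–pressure phase locking; the simulated S index is
  accordingly high (~80 % supine, ~92 % upright in the shipped
  configuration) and should be read as an upper bound.
* The vessel-chain operating points cannot be matched exactly under linear
  noradrenaline kinetics (the reference means imply posture-dependent
  gain); the calibration splits the discrepancy, leaving `v_s^l` and `c_v`
  about 5 % from their nominal values in both postures.
* The peripheral-resistance response to tilt has the wrong physiological
  sign by construction (R falls ~4 % upright instead of rising): with
  vascular tone controlled solely by the lower-body loop, rising lower-body
  pressure can only withdraw sympathetic drive.  This is a structural
  property of the two-loop separation, reproduced deliberately.
* Humoral regulation, microcirculation, intracardiac mechanisms
  (Bowditch/Bayliss), central command, and ECG waveform morphology are out
  of scope; the heart contributes beat times and per-beat pressures only.
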