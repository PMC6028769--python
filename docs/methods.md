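# Methods

## The model

`hipsccm` implements a whole-cell electrophysiology model of the
spontaneously beating, ventricular-like human iPSC-derived cardiomyocyte
(hiPSC-CM) — the 2018 member of the Paci model family.  The cell is two
well-mixed compartments (cytosol, 8800 µm³; sarcoplasmic reticulum,
583.73 µm³) behind a 98.7 pF membrane carrying the currents fitted on
hiPSC-CM patch-clamp data: I_Na, I_NaL, I_CaL, I_f, I_to, I_Kr, I_Ks, I_K1,
the Na⁺/K⁺ pump, the Na⁺/Ca²⁺ exchanger, the sarcolemmal Ca²⁺ pump and two
background currents.  Intracellular K⁺ is fixed at 150 mM; Na⁺, cytosolic
Ca²⁺ and SR Ca²⁺ evolve with rapid-buffering corrections.  The state vector
has 23 components: Vm, 16 gates (including the legacy SR-release
inactivation gate `g`, retained from the predecessor formulation but
decoupled from the release flux — kept so the state layout matches the
published 23-ODE model), three ryanodine-receptor (RyR) gates, and the three
concentrations.

The distinguishing piece is the SR Ca²⁺ release.  Instead of the older
voltage-triggered (L-type-gate-coupled) release, the flux is gated by
cytosolic Ca²⁺ itself:

    I_rel = I_rel,max · RyR_CaSR(Ca_SR) · RyR_o · RyR_c · (Ca_SR − Ca_i)

with `RyR_CaSR = 1 − 1/(1 + exp((Ca_SR − 0.3)/0.1))` a luminal-load factor,
an open gate `RyR_o` (sigmoid in Ca_i, increasing), a closed/inactivation
gate `RyR_c` (sigmoid in Ca_i, decreasing) and an adaptation gate `RyR_a`
that shifts both half-activations toward the prevailing Ca_i.  Because the
release senses Ca_i rather than the I_CaL gate, spontaneous diastolic
release — and with it delayed afterdepolarizations (DADs) through inward
Na⁺/Ca²⁺-exchange current — becomes possible.

### Units

Internally: volts, seconds, mM, A/F (the model family's convention).  The
RyR half-activations, adaptation constants and slopes are stored in µM
exactly as published and the gate equations compare them against
`1000 · Ca_i`; this is numerically identical to a mM convention but keeps
the printed decimals intact in the config files.  Biomarkers are reported
in mV, ms, V/s, Hz.

### Parameters

Two packaged sets (`src/hipsccm/data/*.yaml`):

* `paci2018-optimized` — the published optimized values (SERCA maximum
  0.5113 mM/s, I_rel,max 62.5434 mM/s, the five RyR constants, exchanger and
  pump maxima, SERCA half-saturation, SR leak, and the exchanger
  outward-enhancement factor α).
* `paci2013-baseline` — the pre-optimization values plus the RyR seeds.
  The seeds follow the "atrial source rescaled to 1/10" rule where that is
  consistent with the published ±20 % optimization box; for the open/closed
  half-activations and I_rel,max, whose rescaled source values would leave
  the published optimum unreachable, round seed values whose box contains
  the optimum are used instead.  (Two published optimized values —
  I_NaCa,max at 65.5 % and K_up at 127.7 % of their printed originals — in
  fact violate the stated ±20 % constraint; the packaged sets keep the
  printed values verbatim and the unit tests document the exception.)

RyR slopes (0.0082 / 0.003 / 0.001 µM) and gate time constants (1 s /
18.75 ms / 87.5 ms) are fixed named constants from the atrial source
formulation; an alternative (5 / 15 ms) time-constant pair from that source
was evaluated and rejected because it grossly distorts the Ca²⁺-transient
decay.

## Simulation engine

`scipy.integrate.solve_ivp` with LSODA (Adams/BDF switching; BDF available
via `method=`), rtol 1e-7 and atol 1e-9 by default.  Pacing splits the
integration at every stimulus edge so the solver never steps across a
discontinuity; within a segment the stimulus is constant.  The stimulus is a
rectangular pulse, 5 ms by default (the duration is not a published
quantity; it is exposed on `Protocol`), with the amplitude in pA converted
to A/F through the membrane capacitance.  The right-hand side is JIT
compiled with numba when available; the pure-NumPy kernel is the reference
implementation and the test suite asserts both agree to 1e-13.

Long pre-runs store no trajectory; analysis windows are sampled on a uniform
0.1 ms grid (upstroke velocity needs sub-ms sampling).  A packaged steady
state (spontaneous and 1 Hz-paced, each the product of an 800 s pre-run) is
shipped and regenerated with `hipsccm steady-state`; biomarkers at 800 s and
2400 s agree to <0.1 %, so the 800 s convention is a true limit cycle for
every purpose here.

Deliberate protocol choices (all config-exposed):

* Current-block experiments: 1 Hz pacing, 800 s pre-run, 400 s drug phase,
  biomarkers on a 20 s window (the published protocol states the 400 s
  timing but not the window length).
* If a deeply Na⁺-blocked arm follows only every other stimulus at the
  published 750 pA amplitude, the result carries an explicit capture flag
  and biomarkers are computed on the elicited APs; capture needs a takeoff
  within ~3 mV of threshold in this implementation, so the 2:1 pattern at
  the two highest TTX doses is reported rather than hidden.
* Environment changes (K_o, Ca_o, Na_o) are instantaneous steps; rates are
  measured over a 100 s window after a 300 s settling phase.  The K_o = 8 mM
  arm converges slowly (Na⁺ re-equilibration); its quasi-steady drop is
  ~7 %, smaller than the published 11 % (see Limitations).

## Biomarkers

Eight AP biomarkers (APA, MDP, CL, Vmax, APD10/30/90, Triangulation — with
APD40/50/70/80 computed internally) and six Ca²⁺-transient biomarkers
(DURATION, TPEAK, RT1050, RT1090, DT9010, FREQ), each measured per event and
averaged over all complete events in the window.  The publication does not
state operational definitions, so this package fixes them:

* APDx runs from the maximum-dV/dt instant to the crossing of x %
  repolarization on the span peak-to-MDP, linearly interpolated.
* CL is the interval between successive maximum-dV/dt instants; Vmax the
  peak dV/dt of the upstroke; APA peak minus MDP.
* Triangulation = (APD30 − APD40)/(APD70 − APD80); > 1.5 classifies
  ventricular-like.
* Ca²⁺-transient amplitude runs from the preceding diastolic minimum to the
  peak; RTxy/DT9010 are amplitude-fraction crossing intervals on the
  rising/decaying limb; DURATION spans the 10 %-amplitude up-crossing to
  the 10 %-amplitude down-crossing; TPEAK the 10 %-up-crossing to the peak;
  FREQ is the reciprocal mean peak interval.  All fraction-based Ca²⁺
  biomarkers are well defined on uncalibrated fluorescence signals.

DAD detection: the diastolic interval between two APs (from the end of
repolarization to the next takeoff, bounded by crossings of a −40 mV
diastolic level) is scanned for local maxima with prominence above 1 mV;
bumps reaching −20 mV are classified triggered APs, as are full APs whose
cycle is shorter than 0.65 of a reference cycle length.  For paced traces a
separate metric detrends each diastole with a 300 ms moving average before
measuring bump prominence, so release-locked deflections are separated from
the smooth pacemaker depolarization.  All thresholds are keyword arguments.

## Parameter optimization

The cost is the published weighted SD-band form: each biomarker contributes
`w·(|b_exp − b_sim| − SD)/SD` when it lies outside mean ± SD, zero inside;
weights are 2 for MDP and CL, 1 otherwise.  A candidate evaluation settles
the model 300 s from the packaged steady state (the full protocol uses
800 s; a limit-cycle drift check — CL drift < 1 % across the window —
guards the shortcut), extracts the 14 biomarkers from a 30 s window and
reports the cost; lost spontaneous activity yields a flagged penalty of 1e3.
A further-shortened variant (100 s settle, 20 s window, rtol 1e-5) passes
the same drift check (< 0.1 % cycle-length drift) and agrees with the full
objective to < 0.1 % at the optimized point; the routine descent test uses
it, and both variants reach cost zero from the seeds.

Nelder-Mead is unconstrained, so the ±20 % bounds are enforced through a
per-parameter sigmoid reparameterization (any real coordinate maps inside
the box); an additive-penalty mode is provided for comparison.  The initial
simplex perturbs each coordinate by ~7 % of the parameter value — the
scipy default simplex is degenerate at the transform's origin.  Because the
cost is nonnegative and its zero set has positive volume, the driver stops
at the first zero-cost evaluation.  From the packaged seeds the descent
reaches cost zero in ~130 evaluations with every multiplier inside
[0.8, 1.2].

Note an inherent wrinkle: the published optimized APD30 (241.8 ms) lies
3.2 ms outside its own experimental band (180 ± 58.6 ms), so the cost at
the published optimum is small but nonzero — with this package's
conventions, 0.23.  The zero-cost statement therefore holds for the
optimizer's own terminal point, not for the published parameter vector.

## Synthetic waveforms

`hipsccm.fixtures` generates rectangular, triangular and
piecewise-exponential event trains with closed-form biomarkers (e.g. a
linear decay crosses 90 → 10 % of the amplitude in 0.8 of the ramp time;
the exponential decay is truncated and renormalized at 7 time constants so
the signal is exactly baseline between events and every crossing has an
analytic time).  Gaussian noise is optional and seeded.  These fixtures
validate the biomarker extractors to < 0.5 ms / 0.1 mV independently of the
ODE model; they emulate waveform geometry only — no channel noise,
photobleaching or baseline drift — so passing them certifies the
*measurement* code, not the model.

## Problem sizes and runtime

Spontaneous steady state: 800 s pre-run + 20 s window (≈ 11 APs analyzed).
Block arms: shared paced pre-run, 400 s drug, 20 s window.  Rate arms:
300 s settle + 100 s window.  Optimization: 150–300 s settling per
evaluation.  With the numba kernel the full validation suite runs in
minutes on one CPU.

## Known limitations

* Biomarker values depend on operational conventions at the few-percent
  level.  With the conventions above, CL, MDP, APA, FREQ, Vmax and APD90
  agree with the published simulated column to ≤ 2–3 %, but the published
  APD10/APD30 are ~9 ms shorter than any reference convention tested here
  reproduces, triangulation is 2.77 vs 3.0, and the Ca²⁺ kinetics run
  ~3–4 % slow (DT9010 381 vs 367.6 ms).  These residuals are consistent
  with differences in unpublished measurement tooling and in model
  constants that were never printed alongside the main results.
* The hypercalcemia run reproduces the published phenomenology — a
  DAD series, an anticipated (triggered) beat, and a transition to faster
  Ca²⁺ cycling — but the internal timeline differs: the full release
  reactivation fires within the first ~5 s after the Ca_o step rather than
  at ~30 s, and subsequent DAD series recur with a ~17 s period.
* Under the immature-RyR variant, 70–90 % exchanger block abolishes DADs
  (as published), but 50 % block shrinks rather than enlarges the
  release-locked Vm deflection — the published amplitude increase at 50 %
  block does not reproduce under any detection convention tried, although
  the accompanying diastolic Ca²⁺ accumulation (~0.06 µM mean) matches the
  published value.
* The hyperkalemia dose-response is flatter than published at K_o = 8 mM
  (−7 % vs −11 %); the 16 and 20 mM arms agree.
* No contraction, no spatial Ca²⁺ microdomains, no stochastic RyR gating,
  no temperature dependence — all outside the model's scope by design.
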