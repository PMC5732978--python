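# Methods

## Scope and model

`ipsctailor` tailors a ventricular-type human iPSC-cardiomyocyte action
potential model to a specific cell line (and to individual cells within
it) using only linear scaling of maximum conductances, then predicts
drug-induced changes to action potential duration (APD) under
Hill-equation conductance block.

The baseline electrophysiology is a hand transcription of the ventricular
variant of the Paci et al. (2013) iPSC-CM model (18 states: membrane
potential, 14 gating variables, cytosolic Na+ and Ca2+, SR Ca2+; twelve
membrane currents: I_Na, I_CaL, I_K1, I_Kr, I_Ks, I_to, I_f, I_NaCa,
I_NaK, I_pCa and two background currents). The transcription lives in
`ipsctailor/_paci2013.py` in the model's native units (V, s, mM, A/F);
public interfaces use mV/ms. Because no CellML importer is available in
this environment, the transcription is validated behaviorally rather than
against a reference integrator: the free-running model is spontaneously
active (~0.6 Hz) with a ventricular-like AP, every gating variable stays
in [0, 1] over a 60 s simulation, and the default integration agrees with
an independent tight-tolerance re-integration of the same equations to
within 0.5 mV on AP peak and minimum diastolic potential.

Every conductance/permeability g_max,i is multiplied by a dimensionless
scale factor s_i (default 1). Temperature is a model parameter; it enters
all reversal potentials and every voltage-dependent factor written in
terms of F/RT (the L-type Ca driving term, the I_Kr activation midpoint,
and the I_NaK / I_NaCa exponentials). Clamp simulations run at 298 K
(room-temperature recordings); paced AP and dose-response simulations run
at the model's native 310 K. The source experiments state the clamp
temperature only; the choice of 310 K for pacing is this package's
decision (the optical recordings it emulates were at 35 +/- 2 degC).

## Voltage-clamp simulation

Three whole-cell step protocols are built in:

| protocol | holding | steps | duration | interval | grid |
|---|---|---|---|---|---|
| sodium  | -80 mV | -60..+60 mV / 10 mV | 20 ms  | 5 s  | 0.1 ms |
| calcium | -80 mV | -40..+40 mV / 10 mV | 200 ms | 5 s  | 0.1 ms |
| outward | -80 mV | -40..+50 mV / 10 mV | 500 ms | 10 s | 1 ms   |

During clamp simulation the membrane potential is held at the command
value and intracellular concentrations are clamped to the pipette values
(dialysis); each sweep starts from the holding-potential steady state
(gates relaxed until the state derivative norm is below 1e-6/s). The
5-10 s inter-step intervals of the experiments justify treating sweeps as
independent, so the intervals themselves are not integrated. The holding
potential of the calcium and outward protocols is stated only for the
sodium protocol in the source; -80 mV is assumed for all three.

Solution mapping (mM): sodium/outward experiments use pipette Na 10,
K 110 (KCl + KF), free Ca ~0 (20 mM EGTA, no added calcium); bath Na 150,
K 4, Ca 1.2. The calcium experiment uses a Cs/TEA pipette and an NMDG
bath: all potassium currents (I_K1, I_Kr, I_Ks, I_to, I_f) are placed in
`blocked_currents`, pipette Na 8.2 (from Na2-ATP/Na-GTP), bath Na ~0,
Ca 2. Concentrations are floored at 1e-6 mM inside the reversal-potential
code so ion-free solutions remain finite. Ba2+ is not modeled and no
kinetics are shifted.

The first 10 ms after every commanded potential change are masked
(capacitance-artifact window), mirroring the analysis of real recordings.
Simulated traces carry no artifact, so simulation-only analyses (the
sodium peak-composition check, peak-IV scaling) read the full window via
`peak_iv(..., respect_mask=False)`; the masked fast I_Na transient would
otherwise be invisible under a 10 ms mask on 20 ms steps. Leak correction
subtracts I_leak = V/R_leak (pA), converted to A/F with the cell
capacitance (default 30 pF).

Because potential and concentrations are clamped, the gating trajectory is
independent of the scale factors and each component trace is *exactly*
linear in its scale factor. This is the property that turns conductance
estimation into a linear problem; it is enforced by tests at 1e-8
relative.

## Conductance estimation

**Inward currents.** s_Na and s_CaL are the ratios of measured to
simulated extremal peak current on the protocol's peak-IV relation
(kinetics untouched). On the cell line this package targets these came
out 0.69 (I_Na) and 0.80 (I_CaL); the package reproduces those factors
exactly on proportionally constructed IVs.

**Outward decomposition.** The lumped outward-protocol recording is
modeled as a non-negative weighted sum of the eight unit-scale simulated
component currents (I_Na, I_CaL, I_K1, I_Kr, I_Ks, I_to, I_f, I_NaCa)
over the unmasked samples of all ten sweeps, equally weighted. The
production optimizer is CMA-ES over log-scale factors (non-negativity by
construction), initialized at a seed-perturbed NNLS solution with initial
step 0.5 log-units. Since the SSE objective is an exact quadratic in s,
`scipy.optimize.nnls` provides an independent closed-form oracle; tests
require agreement to 1e-3 relative L2 and the implementation typically
agrees to ~1e-8. The CMA-ES implementation itself
(`ipsctailor/_cmaes.py`) is the standard (mu/mu_w, lambda) strategy with
cumulative step-size adaptation; termination is by stagnation of the
*transformed* scale vector (every coordinate moving less than 1e-8 of the
vector's magnitude over a trailing window), because coordinates of absent
components drift toward the log-space boundary and never satisfy a plain
tol-x. Ten fits from different seeds agree to L2 < 1e-5.

Inward scale factors fitted here are retained in the optimization (they
absorb inward contamination of the recording) but are *not* used for
tailoring; scale factors below 1e-10 are reported as absent (a dash).

**Contribution scores.** c_i = |I_final,i| / sum_j |I_final,j|, where
I_final,i = s_i x (unit component current at the last unmasked sample of
the +50 mV step). The denominator runs over the supplied component set;
scores are invariant under a common rescaling of s. With the fitted
factors of the two best-determined cells (s_Ks 139 / s_NaCa 3.32 and
s_Ks 129 / s_NaCa 2.08) the package computes c_Ks = 71.5% and 78.8%.

## Tailoring and drug block

A tailored cell model sets scale[I_Na] = 0.69, scale[I_CaL] = 0.80 (line
averages), and the cell's fitted s_Ks and s_NaCa (absent = 0, i.e. the
current was not discernible); all other currents keep unit scale, and no
kinetics change. 22 tailored models are bundled as a fixture table.

Drug block multiplies each targeted current's scale factor by
f(x) = 1 / (1 + (x/IC50)^h) with h = 1. The bundled drug table covers
dofetilide, quinidine, sotalol and verapamil (per-current IC50s in uM and
the tested concentrations) plus paracetamol as a no-effect negative
control; paracetamol's tested concentrations are nominal ([1, 10, 100]
uM) since it has no IC50 entries. Per-compound pacing cycle lengths
(s): dofetilide 1.375, quinidine 1.176, sotalol 0.933, verapamil 0.905,
paracetamol and all other experiments 1.0 — the mean spontaneous rates of
the coupled monolayers the predictions are compared against.

Paced simulations use the transcribed model's published stimulus
(~5.6 A/F for 5 ms) with 100 conditioning beats by default and ion
concentrations evolving freely. Dose-response measures the final recorded
beats: the selected APD is the longer of the last two beats; a
consecutive-beat relative APD90 difference above 5% flags *strong
alternans* (exclusion), and a beat that never crosses 90% repolarization
before the next stimulus flags *repolarization failure* (exclusion).
Population summaries are medians with 25th/75th percentiles (linear
interpolation) over the non-excluded tailored cells; the untailored
original model is simulated alongside but never enters the percentiles.
Under these settings the tailored population reproduces the study's
qualitative findings: median baseline APD90 at 1 Hz below the untailored
model's (~417 ms), dofetilide prolonging the tailored median while the
untailored model degenerates into 2:1 alternans and repolarization
failure at the higher concentrations, and verapamil shortening the
tailored median at the highest dose.

## AP normalization and APD

The same normalization serves optical-style and simulated traces. The
upstroke is the maximum first derivative of a Savitzky-Golay-smoothed
copy (5 ms window, cubic); the AP start is the last pre-upstroke sample
with derivative below 10% of maximum; the baseline (normalized 0) is the
mean of the 20 ms window ending there; the amplitude (normalized 1) is
the 95th percentile of the in-AP samples minus baseline. APD90/APD50 run
from the maximum-upstroke time to the first *sustained* downward crossing
of 0.1/0.5 normalized units (sustained = the 2 ms trailing mean also sits
below the level), linearly interpolated. On noisy recordings (detrended
baseline noise above 0.5% of amplitude — estimated from pre-AP samples,
or from the diastolic first-difference residual when the trace starts at
the stimulus) the crossings are read from the smoothed signal, as
semi-automatic optical pipelines do; a naive single-sample crossing is
biased early by noise first-passage at 10 kHz sampling.

A property of the 95th-percentile convention worth knowing: for a
plateau-less triangular waveform the in-AP samples are uniformly
distributed, the 95th percentile sits below the raw peak (q95 ~ 0.95),
and the exact APD closed form is APD_f = (1 - q95(1-f)) x decay — the
naive f x decay form holds only for waveforms with a plateau. The tests
assert both forms on the appropriate waveforms.

## Synthetic data

The generator produces every input the pipeline consumes, with known
ground truth and a mandatory seed (pure functions of spec + seed):

* **Outward recordings**: sum of scaled unit component traces + ohmic
  leak (V/R_leak, default 1 GOhm) + a capacitance transient after each
  potential change (amplitude dV/R_access, R_access 10 MOhm, tau 1 ms —
  decays to < 1e-4 within the 10 ms mask) + i.i.d. Gaussian noise,
  default SD 2% of the clean trace's robust (95th-percentile) amplitude.
* **Cell populations**: log-uniform scale factors within the observed
  per-cell min-max of the fixture table (s_Ks 9.18-467, s_NaCa
  0.38-21.1), reflecting the orders-of-magnitude inter-cell spread.
* **Pseudo-optical APs**: gain x V(t) + offset + linear drift + Gaussian
  noise at 10 kHz. "Realistic" test settings are 2% photon noise and
  1%-of-signal-per-second bleaching drift (dye bleaching is a few percent
  per minute; 1%/s is deliberately conservative).

What the generators do *not* emulate: kinetic differences between cell
lines (the central caveat of conductance-only tailoring), series-
resistance/imperfect-clamp artifacts beyond ohmic leak, stochastic
channel gating, motion artifacts, and electrotonic coupling. Passing
recovery tests therefore demonstrate identifiability of the scale factors
*given correct kinetics*, not robustness to kinetic model discrepancy —
on real recordings from a different line the fit residuals are expected
to be large and some currents to be fitted as absent.

## Numerical choices

* Integration: LSODA (stiff-switching) via `scipy.integrate.solve_ivp`
  with the study's tolerances abs 1e-6 / rel 1e-4 as defaults; the RHS is
  numba-compiled (pure-Python fallback is the same code). Paced beats are
  split at the stimulus edge so the solver never steps across the
  discontinuity, and recorded beats are returned on a uniform 1 ms grid
  (mixed adaptive/uniform grids bias percentile-based normalization).
* Holding steady states are found by relaxation with tightened tolerances
  (1e-9/1e-8) and verified by the derivative norm.
* Concentration floor 1e-6 mM inside reversal potentials.
* The I_CaL driving term uses its analytic V -> 0 limit below |V| < 0.1 uV.
* Percentiles: linear interpolation between order statistics throughout.
* Problem sizes in the test suite are scaled to the package's CI budget:
  recovery batches use 10 synthetic cells, dose-response checks use the
  full 22-cell population at two or three concentrations per compound,
  and paced runs use the 100-beat conditioning default (2:1 alternans
  under strong I_Kr block only emerges after ~60+ conditioning beats, so
  shorter conditioning would understate proarrhythmic behavior).

## Known limitations

* Conductance-only tailoring: no kinetic refitting, no Ba2+ IV-shift
  modeling, no IC50 uncertainty propagation, no tissue-level coupling.
* The fitted inward scale factors from the outward protocol are
  discarded by design; inward/outward covariance is not identifiable from
  these single-cell experiments.
* The transcription is validated behaviorally, not bit-for-bit against
  the published CellML; all downstream numbers inherit this provenance.
* Printed APD values of the source study's figures are figure-read and
  are not asserted numerically; the dose-response checks are qualitative
  (direction and exclusion behavior), as are the baseline-population
  comparisons.
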