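# Methods

`pknmm` simulates single-channel EEG during propofol anesthesia by chaining a
population pharmacokinetic model of the drug into a stochastic mean-field model
of a cortical macrocolumn, and then quantifies the simulated signal with the
standard depth-of-hypnosis metric suite. This note records the model, its
assumptions, the parameter choices that matter, and the design decisions taken
where the published description of this model family leaves the implementer
genuine freedom.

## Pharmacokinetics

Propofol disposition follows the Schnider three-compartment model in
concentration form,

    dC1/dt = −(k10 + k12 + k13)·C1 + k21·(V2/V1)·C2 + k31·(V3/V1)·C3 + u(t)/V1
    dC2/dt = k12·(V1/V2)·C1 − k21·C2
    dC3/dt = k13·(V1/V3)·C1 − k31·C3
    dCeff/dt = ke0·(C1 − Ceff)

with volumes (L) and clearances (L/min) given by the Schnider demographic
covariate formulas (age, weight, height, and sex through James lean body
mass), and rate constants k10 = Cl1/V1, k12 = Cl2/V1, k13 = Cl3/V1,
k21 = Cl2/V2, k31 = Cl3/V3. Concentrations are reported in µg/mL. The
effect-site equilibration constant `ke0` is not part of the volume/clearance
table; the default 0.456 min⁻¹ is the published Schnider effect-site value and
is config-exposed, since reported propofol ke0 estimates span roughly
0.2–1.2 min⁻¹ and the choice shifts the lag between plasma and effect site.
This is an assumption, not a fitted value.

Integration is classical fixed-step RK4 at 0.1 s. The system is linear and
non-stiff; a fixed step makes runs bit-reproducible, and infusion breakpoints
are snapped onto the grid so each step sees one exact piecewise-constant rate
and the scheme keeps its full order (verified against the one-compartment and
effect-site closed forms to <1e−6 relative error). Initial conditions are
drug-free (all compartments zero); the library accepts other initial states,
the CLI does not. Profiles whose covariate formulas produce a non-positive
volume or clearance (e.g. V2 at ages above ~101 y) are rejected rather than
clamped.

The cortical drive is the rescaled effect-site concentration

    rCeff(t) = 0.49 · Ceff(t) / max(Ceff) + 1  ∈  [1, 1.49],

where the maximum is taken over the full session trajectory (callers must
pass complete sessions, not prefixes). The ceiling 1.49 places peak drug
effect just below the model's critical anesthetic factor (see below). For
cross-subject overlays the time axis can be renormalized by each subject's
syringe-drop time, which aligns loss of consciousness at normalized time 1.

## Cortical macrocolumn

The cortex is a single spatially homogeneous macrocolumn of excitatory (85%)
and inhibitory (15%) populations in the Steyn-Ross/Liley mean-field lineage.
Its state is the pair of population-mean soma potentials (he, hi). Synaptic
input channels have the alpha-kernel impulse response γt·e^(1−γt) (unit peak
at t = 1/γ); firing rates are sigmoidal in the soma potential; synaptic
efficacy is weighted by reversal-potential factors
ψjk(h) = (hj_rev − h)/|hj_rev − hk_rest|. Subcortical input is a mean spike
rate plus white-noise fluctuation. Anesthetic action is the literal rate
substitution γi → γi/λ: the IPSP keeps its peak amplitude, lasts λ times
longer, and therefore transfers λ times the charge; the alternative
charge-conserving variant (amplitude rescaled down by λ) is *not* used.

Parameter defaults (all config-exposed) are transcribed from the published
mean-field parameter tables of this lineage: resting potentials −70 mV,
reversal potentials +45/−90 mV, γe = 300 s⁻¹, γi = 65 s⁻¹, EPSP/IPSP peaks
0.18/0.37 mV, local connectivities 3034/3034/536/536, long-range 4000/2000,
sigmoid Smax = 100 s⁻¹, θ = −60 mV, slopes 0.28/0.14 mV⁻¹, subcortical means
p_ee = 1100 s⁻¹, p_ei = 1600 s⁻¹, p_ie = p_ii = 0. Population response times
are Liley's τe = 94 ms, τi = 42 ms. With this set the active (top) equilibrium
branch of the noise-free system terminates in a saddle-node at λc ≈ 1.502 —
the first-order phase-transition picture of anesthetic loss of consciousness,
with the drive ceiling 1.49 approaching the fold from below.

### Model reduction

Two reductions are applied, and they matter:

1. **Spatial homogeneity.** Spatial derivative terms are dropped; the
   long-range flux obeys its homogeneous limit. The package models one EEG
   channel; no 2-D cortical sheet.

2. **Adiabatic slaving of the synaptic feedback.** The synaptic and
   cortico-cortical rates (γe = 300 s⁻¹, vΛ ≈ 2800 s⁻¹) are fast against the
   population response times, so the deterministic synaptic feedback is
   replaced by its quasi-steady value, leaving a planar drift in (he, hi).
   This choice is load-bearing: integrating the *full* second-order channel
   system with these constants destabilizes the active branch long before the
   fold (a Hopf bifurcation near λ ≈ 1.2 followed by ejection to the
   quiescent branch), which contradicts the intended behavior of small
   stationary fluctuations about a tracked steady state across the whole
   session. The adiabatic drift keeps the top branch stable up to λc, so the
   approach to the transition is expressed as growing, slowing fluctuations
   (the biphasic surge) rather than a premature oscillatory instability.

   The *stochastic* part of the subcortical input is deliberately not slaved:
   each of the four input channels carries its white noise through its own
   second-order PSP kernel, `(d/dt + γ)² ñ = e·G·γ·σ·ξ(t)`. White noise has
   power at all frequencies, so adiabatic elimination is not valid for it; and
   filtering the inhibitory noise with the stretched kernel γi/λ is exactly
   the mechanism by which the drug reddens the input spectrum. The integrated
   state is therefore 10-dimensional: (he, hi) plus four (channel, derivative)
   pairs.

### Noise amplitudes

Excitatory channel noise uses the shot-noise convention σ = √p̄
(σ_ee ≈ 33 s⁻¹, σ_ei = 40 s⁻¹). The inhibitory subcortical channels have zero
mean rate, so their fluctuation amplitude is a free constant; the default is
σ_ie = σ_ii = 2 s⁻¹ — a small stochastic inhibitory component (≈6% of the
excitatory amplitude) included so that the anesthetic-stretched IPSP kernel
shapes the input noise as well as the mean drive. A global `noise_scale`
multiplies all four. In the far-from-fold linear regime the simulated EEG
amplitude is proportional to the noise amplitudes while its *shape* (spectra,
permutation entropy) is invariant, so these constants mostly matter near the
transition. All were fixed from the qualitative behavior of the model
(broadband awake signal, progressive slowing with deepening effect, no
spontaneous basin escape during a session) before any cohort-level statistics
were computed, and are not fitted per subject.

### Integration, tracking, EEG extraction

Euler–Maruyama at a fixed 1e−4 s step (config), noise entering only the four
subcortical channels, each fed by an independent substream spawned
deterministically from one integer seed (bit-reproducible runs; channels
independent). λ(t) is held piecewise constant at the 1-s PK grid — PK
timescales are minutes, cortical timescales milliseconds. The steady-state
track he⁰(t) is computed by Newton continuation along λ(t) at 1-s knots
starting on the λ(0) top branch (on fold disappearance the track jumps once to
the surviving branch; with the default drive ceiling this never triggers) and
is interpolated linearly onto the output grid, so the subtracted reference is
smooth. Soma potentials leaving (−90, −10) mV abort the run with an error
rather than clipping, which would corrupt spectra.

The simulated EEG is sEEG(t) = he(t) − he⁰(t) in model millivolts (no display
magnification), recorded at 1 kHz and polyphase-resampled (anti-aliased) to
100 Hz, the analysis rate used throughout. Steady-state computation scans the
physiological he range densely (default 2001 points), eliminates hi by an
inner bracketed solve, polishes each sign change with Brent's method, and
requires equilibrium residuals below 1e−9 mV; coexisting roots are labeled
bottom/middle/top by he⁰ order, a lone root by its firing regime relative to
the sigmoid threshold.

## Metric suite

* **Spectrogram** — short-time Fourier power (scipy), default 10-s Hann
  windows with 7.5-s overlap to match the metric windowing; the window family
  is an implementation choice, only the transform itself is prescribed.
* **Permutation entropy** — ordinal patterns of the (m, τ)-embedded series;
  Shannon entropy of the pattern distribution over the len − (m−1)τ embedded
  vectors, normalized by ln m! so PE ∈ [0, 1]. Defaults m = 6, τ = 1 on 10-s
  windows with 7.5-s overlap. Ties are ranked by stable sort (earlier sample
  wins), a deterministic rule the fast implementation shares with the
  brute-force oracle in the tests.
* **Bispectrum / SynchFastSlow** — B(f1, f2) = |⟨X(f1)X(f2)X*(f1+f2)⟩| on the
  triangular domain f2 ≥ f1 > 0, f1+f2 ≤ fs/2. The estimator averages complex
  triple products over 2-s Hann sub-epochs with 50% overlap before taking the
  magnitude (sub-epoch length and averaging are config-exposed; a single-epoch
  estimator has no variance reduction and cannot distinguish phase-coupled
  from independent triplets). SFS = log10 of the bispectral sum over the
  0.5–47 Hz triplet region divided by the sum over triplets with
  f1+f2 ∈ [40, 47] Hz; since the denominator region is a subset of the
  numerator region, SFS ≥ 0. The published symbol definitions for the two
  regions are internally inconsistent with their prose description; the prose
  (full band over 40–47 Hz band) is implemented, and the discrepancy is noted
  here rather than silently resolved. "Normalized SFS" is per-record min–max
  scaling to [0, 1], a plotting convention only.
* **Correlation** — standard Pearson coefficient (covariance over the product
  of standard deviations). The printed formula in the source description
  degenerates to a ratio of identical covariances; the standard form is the
  evident intent and is what is implemented.
* **State summaries** — metric windows are assigned by window-center time:
  conscious before object time, unconscious from syringe-drop to number time
  (to command time for subjects who recalled no number — the recovery marker
  is the only available endpoint), recovery after command time; windows in
  the gaps between states are excluded. Empty states yield flagged summaries,
  not errors.

## Experiment pipeline

A session reproduces the study protocol: infusion at 1500 mg/h (25 mg/min)
from t = 0 until the subject's syringe-drop time, zero afterwards; session
end is command time + 60 s (the recordings' true lengths beyond the events
are not stated; one minute of recovery-state data is a pipeline choice). The
nine-subject cohort demographics and event times ship as package data. Per-
subject seeds derive from the cohort seed as seed + subject index. Cohort
aggregation takes each subject's per-state median over metric windows, then
the cross-subject median/min/max per state.

`compare_records` resamples two records of the same session to 100 Hz,
computes windowed PE and SFS on both, aligns series by window-center time,
and reports Pearson correlations plus per-state summaries for both records.
How the original study aligned windows between real and simulated EEG is not
stated; center-time alignment is this package's rule, and users comparing
against their own recordings should be aware of it.

## Surrogate EEG

No clinical recordings are available or redistributable, so the comparison
pipeline is exercised against surrogate EEG: per-state sums of band-limited
unit-variance Gaussian noise (delta/theta/alpha/beta bands, brick-wall
spectral masks so each component's power lies entirely in its nominal band)
weighted by √(relative band power), mixed with smooth cosine envelopes across
the behavioral transitions. Default profiles follow propofol phenomenology —
broadband/beta-weighted awake, delta-dominant unconscious, beta return in
recovery. Surrogates are deterministic per seed, and their measured band
powers match the requested profile within 5% relative error. Deliberately
*not* modeled: autoregressive fits to clinical data (to avoid implying
fidelity to unavailable recordings) and the bimodal delta+alpha spectral
peaks of real propofol EEG.

## What the tests do and do not show

Passing the suite shows: the PK stage agrees with closed forms and conserves
mass; the drive rescaling attains exactly [1, 1.49]; equilibria agree with a
dense-grid bracketing oracle and the zero-noise cortex stays on its steady
state; simulated EEG slows and grows toward the transition and the
depth-of-anesthesia indices move in the clinically expected directions
(PE falls with induction and recovers, SFS rises and declines, state
ordering conscious > recovery > unconscious); and the comparison pipeline is
sane (unit correlation on identical input, null on shuffled input, positive
on state-matched surrogates). It does *not* show fidelity to any particular
clinical recording: surrogate EEG is filtered noise, and the cortical
parameters are literature transcriptions, not fits.

## Known limitations

* The supplementary equation set this model family is usually specified in
  was not available; parameters and the reduction above were reconstructed
  from the cited Steyn-Ross/Liley literature. The per-state permutation
  entropy levels of the simulated EEG are sensitive to that reconstruction
  (most visibly in the unconscious state, where the simulated median runs
  high relative to the reported clinical-model value).
* No burst suppression (a distinct deep-anesthesia regime with different
  physiology), no thalamocortical circuitry — hence no frontal alpha or
  delta spectral peaks — no 2-D cortical sheet, no target-controlled-infusion
  logic, no PBPK organ model, and no fitting to clinical EEG.
* Recovery-state data cover only the 60-s margin after command time.
* EDF input is supported through mne; EDF export requires mne's optional
  export backend and is otherwise unavailable (CSV is the canonical format).

## Problem sizes used

The default cohort run integrates nine sessions of 440–892 s at a 1e−4 s
Euler–Maruyama step (≈5–9 million steps per subject, a few tens of seconds
per subject on one core). Desk-scale property checks use 5–60 s constant-λ
runs. These sizes are the package defaults, chosen to resolve the stiffest
kernel rate with ample margin.
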