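# pknmm

Simulation of EEG during propofol anesthesia by coupling a population
pharmacokinetic model to a stochastic neural mass model of the cortex, with
the standard depth-of-hypnosis metric suite to quantify the result.

## Who this is for

Researchers in anesthesia monitoring and computational neuroscience who want
to generate EEG-like signals from an actual drug infusion regimen and a
subject's demographics — for testing depth-of-anesthesia indices, for teaching,
or for exploring how GABAergic drug effect reshapes cortical dynamics — without
access to clinical recordings.

## The model

1. **Pharmacokinetics.** The Schnider three-compartment propofol model with an
   effect compartment: volumes and clearances are demographic functions of
   age, weight, height and sex (via lean body mass); the effect site
   equilibrates with plasma at rate ke0 (default 0.456 min⁻¹). Given a
   piecewise-constant infusion u(t), the model yields the effect-site
   concentration Ceff(t) in µg/mL.

2. **Anesthetic drive.** Ceff is mapped onto the dimensionless
   anesthetic-effect factor λ = 0.49·Ceff/max(Ceff) + 1 ∈ [1, 1.49].

3. **Cortical macrocolumn.** A Steyn-Ross/Liley mean-field model of one
   cortical macrocolumn (85% excitatory, 15% inhibitory), state variables
   he, hi (population-mean soma potentials). Propofol potentiates GABA_A
   inhibition by stretching the inhibitory postsynaptic kernel γt·e^(1−γt):
   γi → γi/λ, leaving the IPSP peak unchanged and multiplying transferred
   charge by λ. The noise-free model is bistable; its active branch ends in a
   saddle-node at λ ≈ 1.50, so the drive ceiling 1.49 brings peak drug effect
   just below the loss-of-consciousness phase transition. Stochastic
   subcortical input drives fluctuations about the tracked steady state, and
   the simulated EEG is sEEG(t) = he(t) − he⁰(t), resampled to 100 Hz.

4. **Metrics.** Spectrogram (STFT), normalized permutation entropy
   (PE = H(ordinal patterns)/ln m!, defaults m = 6, τ = 1, 10-s windows,
   7.5-s overlap), bispectral SynchFastSlow
   (SFS = log₁₀ ΣB(0.5–47 Hz)/ΣB(f1+f2 ∈ 40–47 Hz)), Pearson correlation
   between metric series, and per-state summaries over the behavioral states
   (conscious / unconscious / recovery, delimited by the object, syringe-drop,
   number and command event times).

See `docs/methods.md` for equations, parameter values, the model reduction,
and known limitations.

## Worked example

Simulate one subject of the bundled nine-subject cohort and summarize the
permutation entropy per behavioral state:

```python
from pknmm import load_cohort, run_subject

profile, timeline = load_cohort()[4]          # subject #5: male, 37 y, 78 kg
result = run_subject(profile, timeline, seed=123)
print(f"peak Ceff {result.pk.Ceff.max():.2f} µg/mL, "
      f"sEEG {result.seeg.duration:.0f} s at {result.seeg.fs:.0f} Hz")
for state in ("conscious", "unconscious", "recovery"):
    s = result.pe_states[state]
    print(f"PE {state:12s} median {s.median:.3f}  range [{s.min:.3f}, {s.max:.3f}]")
```

prints

```
peak Ceff 4.93 µg/mL, sEEG 440 s at 100 Hz
PE conscious    median 0.892  range [0.883, 0.902]
PE unconscious  median 0.824  range [0.790, 0.871]
PE recovery     median 0.880  range [0.851, 0.901]
```

Entropy of the simulated EEG falls after loss of consciousness (syringe drop,
289 s — infusion stops there) and recovers after the response-to-command
marker, the expected clinical signature. The same chain is available from the
shell:

```
pknmm simulate --sex male --age 37 --weight 78 --height 177 \
      --timeline events.txt --seed 123 --out seeg.csv
pknmm metrics seeg.csv --timeline events.txt --out metrics.csv
pknmm cohort --seed 1 --outdir cohort_out/      # all nine subjects
```

where `events.txt` holds `key=value` lines (`object=120`, `syringe_drop=289`,
`number=360`, `command=380`).

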