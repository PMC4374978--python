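# echolag

Delayed-coordination analysis and biosonar movement-interaction modelling
for paired animal trajectories.

When two echolocating bats forage together over a water surface, one of
them often copies the heading — or even the flight path — that the other
had a few hundred milliseconds earlier.  `echolag` implements the complete
computational chain for detecting, classifying and explaining this delayed
coordination from 2-D trajectory pairs sampled at 20 ms:

* **Delay maps.**  The time-dependent delayed directional correlation
  (TDDC) `C_ij(t, τ)` is the windowed mean of the normalised scalar product
  of bat *i*'s velocity at *t* with bat *j*'s velocity at *t + τ*; the
  time-dependent delayed separation (TDDS) `R_ij(t, τ)` is the windowed
  mean distance between *i* at *t* and *j* at *t + τ*.
* **Delay extraction.**  A dynamic program finds the single time-ordered
  interaction path τ(t) through the (t, τ) lattice that maximises the
  cumulative correlation of super-threshold cells (`C ≥ v_c = 0.95`, i.e.
  headings within arccos 0.95 ≈ 18.2°), subject to Δτ/Δt ≥ −1 (a reactor
  cannot reorder the actor's actions) and a penalty `q = 0.02` per delay
  change.  Chase paths instead minimise the delayed separation over cells
  with `R ≤ d_c = 0.15 m`; chases are a sub-category of coordinated flight.
  Asymmetric delay uncertainties follow from propagating slope −1 lines
  through the threshold contours.
* **Behaviour classification and roles.**  Each sample becomes
  unclassified / coordinated / chase; the sign of the extracted delay
  assigns actor (leader) and reactor (follower).
* **Biosonar perception field.**  The echo amplitude returning from a
  conspecific at range ρ and off-axis angle ζ is
  `α(ρ, ζ) = SL + TS + (A + 2)[cos ζ − 1] + 2[20 log10(0.1/ρ) + ρc]`
  with source level SL = 110 dB, target strength TS = −10 dB, emission
  directionality asymmetry A, 2 dB hearing asymmetry and absorption
  c = −1.28 dB/m; detection requires α ≥ B (hearing threshold).
* **Agent-based simulator.**  Pairs of correlated random walkers with
  Rician speeds 𝓡(4.81, 2.18) m/s, von Mises desired headings (κ = 557
  independent, κ = 2473 interacting), a 4 g lateral-acceleration turn
  clamp, echolocation every 100 ms, reaction delay τ and a 5% per-step
  escape probability.
* **Calibration.**  Reactor-centred relative-position densities
  (1.5 m cells) of observed and simulated coordinated flight are compared
  by RMS over cells, grid-searching (A, B, τ).
* **Synthetic ground truth.**  A generator producing labelled coordinated,
  chase, role-swap, piecewise-lag, independent and deterministic geometric
  pairs, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from echolag import classify
from echolag.synthetic import SynthSpec, generate

pair, truth = generate(SynthSpec(scenario="coordinated", lag=0.3, seed=42,
                                 duration=6.0))
cp = classify(pair)
print(cp.summary())
tau = cp.tau
print("median extracted delay (s):",
      round(float(np.median(tau[np.isfinite(tau)])), 3))
print(cp.to_frame().iloc[100:105].to_string(index=False))
```

prints

```
{'pair_id': 'coordinated-42', 'n_samples': 290, 'fraction_unclassified': 0.0,
 'fraction_coordinated': 1.0, 'fraction_chase': 0.0,
 'fraction_interacting': 1.0, 'flagged_out_of_range': False}
median extracted delay (s): 0.3
   t       label actor reactor  tau  tau_lo  tau_hi
2.10 coordinated     a       b  0.3    0.12    1.02
2.12 coordinated     a       b  0.3    0.10    1.02
2.14 coordinated     a       b  0.3    0.10    1.02
2.16 coordinated     a       b  0.3    0.10    1.04
2.18 coordinated     a       b  0.3    0.10    1.06
```

The generator hid a 300 ms heading-copy lag; the classifier labels the
whole overlap as coordinated flight, recovers the delay exactly on the
20 ms lattice, identifies bat `a` as the actor, and brackets each delay
with its asymmetric uncertainty interval (wide above, because alignment at
longer delays cannot be excluded on straighter flight segments).

The same pipeline runs from the shell:

```sh
echolag synth --scenario chase --lag 0.2 --n-pairs 3 --out pairs.csv
echolag classify --input pairs.csv --outdir out/
echolag simulate --n-pairs 50 --tau 0.3 --out model.csv
echolag fit --observed out/relative_samples.csv --outdir fit/
```

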