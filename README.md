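# oscsync

Analysis toolkit for **familiarity-induced 4–8 Hz oscillations** in
multi-area visual-cortex recordings: laminar LFP metrics and spectral
parameterization, inter-areal phase synchronization, spike–field
coupling, and directed-information functional connectivity — together
with a seeded synthetic-session generator that provides known ground
truth for every stage.

## Who this is for

Systems neuroscientists analyzing simultaneous laminar recordings from
mouse primary visual cortex (V1) and higher visual areas (LM, AL)
during repeated visual stimulation: multi-trial LFP at 1 kHz across
depth-resolved channel columns, curated single units, and a 5 × 5
spatial-frequency × temporal-frequency (SF/TF) stimulus grid with 20
trials per stimulus. The same machinery runs end-to-end on synthetic
sessions, so every estimator ships with a parameter-recovery test.

## What it computes

- **Laminar LFP metrics** (`oscsync.lfp`). Superficial/middle/deep
  channel assignment per probe column from the trial-averaged evoked
  response; alternating oscillation troughs/peaks (|amplitude| > 25 µV,
  ≥ 50 ms apart) and trough-to-peak amplitudes; Welch spectra (700 ms
  Hann windows, 350 ms overlap); and a knee-free spectral
  parameterization
  `log10 P(f) = offset − χ·log10 f + Σₖ G(f; cₖ, hₖ, σₖ)`
  whose Gaussian peak heights above the aperiodic component are the
  "adjusted" band powers.
- **Phase synchronization** (`oscsync.phase`). Morlet-wavelet phases
  (0 = oscillation peak, ±π = trough); the phase-locking value across
  N trials, `PLV(f,t) = |(1/N) Σₙ exp(j Δφₙ(f,t))|`, summarized as the
  median over 4–8 Hz × 0–0.7 s post-onset; pooled phase-difference
  samples for circular comparisons; and the phase slope index
  `PSI = Im Σ_f C*(f) C(f+δf)` from complex coherency, whose sign
  indicates which area temporally leads.
- **Spike–field coupling** (`oscsync.spikes`). PSTH Z-scoring against
  per-trial baseline rates, SF/TF tuning-hotspot detection (bilinear
  upsampling + Gaussian smoothing), early/middle/late firing-group
  classification, spike phases from the Butterworth band-passed
  best-channel LFP, and the bias-free pairwise phase consistency
  `PPC = 2/(N(N−1)) Σ_{n<m} cos(φₘ − φₙ)`.
- **Directed information** (`oscsync.di`). 1 ms binarized spike trains
  with summed-history features (refractory `Y(t−1)+Y(t−2)`,
  self-history `Y(t−3)+…+Y(t−10)`, one `X(t−1)+…+X(t−10)` term per
  candidate unit), an imbalance filter, lasso-logistic models selected
  by 5-fold CV over a 20-point penalty grid, held-out
  `I = (1/T) Σ_t log₂[P_full/P_self-only]` normalized by the empirical
  entropy of the target, two-area Shapley attribution, and per-stimulus
  area-level medians with Monte-Carlo permutation tests and
  Benjamini–Hochberg FDR control.
- **Statistics** (`oscsync.stats`). Rayleigh test, two-sample Kuiper
  test for circular distributions, common-language effect size, BH-FDR,
  and a seeded permutation test on median differences.
- **Synthetic sessions** (`oscsync.synth`). Two-area laminar sessions
  with a damped 4–8 Hz oscillation over 1/f background, a fixed
  inter-areal phase lag plus von Mises per-trial jitter (closed-form
  PLV oracle I₁(κ)/I₀(κ)), von Mises phase-locked spikes (PPC oracle
  (I₁(κ)/I₀(κ))²), and binary trains sampled from the same logistic
  model the DI stage fits.

## Worked example

```python
import numpy as np
from oscsync import morlet_phase, plv, phase_difference_samples, unit_ppc
from oscsync.synth import (LfpGenParams, SpikeGenParams,
                           gen_lfp_session, gen_phase_locked_spikes)

# two-area session, one stimulus, 20 trials, pi/4 inter-areal lag,
# von Mises trial jitter kappa = 2
sess = gen_lfp_session(LfpGenParams(stimuli=(12,), inter_areal_lag=np.pi/4,
                                    trial_jitter_kappa=2.0, seed=11))
sess = gen_phase_locked_spikes(sess, SpikeGenParams(phase_kappa=1.0,
                                                    base_rate=0.0,
                                                    resp_rate=20.0, seed=42))

ca = int(sess.channels_of_area("V1")[0])
cb = int(sess.channels_of_area("LM")[0])
freqs = np.arange(4, 9, 1.0)
res = plv(morlet_phase(sess.lfp[:, ca, :], freqs),
          morlet_phase(sess.lfp[:, cb, :], freqs), onset=sess.onset)
print(f"band-median PLV: {res.band_median:.3f}")

d = phase_difference_samples(res, window=(0.25, 0.7))
print(f"circular-mean lag: {np.angle(np.mean(np.exp(1j*d))):.3f} rad")

r = unit_ppc(sess, sess.units.index[0])
print(f"unit PPC: {r.ppc:.3f} (Rayleigh p = {r.rayleigh_p:.2e})")
```

Output:

```
band-median PLV: 0.766
circular-mean lag: 0.821 rad
unit PPC: 0.227 (Rayleigh p = 2.10e-24)
```

The band-median PLV sits near the von Mises resultant length
I₁(2)/I₀(2) ≈ 0.70 for the injected trial jitter (plus the known
finite-trial upward offset at N = 20), the circular-mean phase
difference recovers the π/4 ≈ 0.785 rad lag up to the jitter sample's
own circular-mean error (~0.16 rad sd at κ = 2, N = 20), and the
unit's PPC is close to the κ = 1 phase-locking oracle
(I₁(1)/I₀(1))² ≈ 0.199.

## Command line

```bash
oscsync make-fixture --name plv_locked --seed 1 --out sess.h5
oscsync lfp   --session sess.h5 --out out/          # laminar + spectral CSV
oscsync sync  --session sess.h5 --band 4 8 --out out/
oscsync spikes --session sess.h5 --out out/
oscsync run --config config.yaml                    # full pipeline
```

All tables are CSV with `#`-prefixed metadata headers; `run` writes a
provenance manifest (config hash, seeds, package version) and reruns
with the same config are byte-identical.

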