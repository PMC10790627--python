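# Methods

This note documents the models, estimators, and numerical choices
behind `oscsync`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Recording model and conventions

A session holds trial-aligned LFP (trials × channels × samples,
microvolts, exactly 1000 samples/s), channel geometry (depth in µm
below the pia increasing downward, shank column index, cortical area
∈ {V1, LM, AL}), per-unit per-trial spike times in seconds, and trial
metadata for a 5 × 5 SF × TF stimulus grid
(SF ∈ {0.015, 0.03, 0.06, 0.12, 0.24} cpd,
TF ∈ {0.75, 1.5, 3, 6, 12} Hz). All trial-relative times are seconds
with stimulus onset fixed at 0.5 s; the default synthetic trial is
2.2 s (the container requires ≥ 2.0 s so the post-onset analysis
windows to 1.5 s exist). Phases follow the convention 0 = oscillation
peak, ±π = trough, advancing in time. Sessions persist as single HDF5
files with a versioned schema; spike tables export to plain CSV.

## Laminar LFP selection

Per probe column, the middle-layer channel maximizes the
trial-averaged LFP amplitude 50–150 ms post-onset; the middle band is
that channel's depth ±100 µm; superficial and deep channels maximize
amplitude 50–1000 ms post-onset strictly above/below the band.
"Amplitude" is max |trial-averaged LFP| in the window — the definition
was genuinely open (peak-to-peak and RMS were alternatives); max
absolute value was chosen for polarity robustness and is flagged here
as an interpretation. Exact ties go to the shallower channel.
Columns need ≥ 3 channels spanning > 200 µm.

## Oscillation extrema

Local extrema within 0–1 s post-onset qualify if |amplitude| > 25 µV.
Candidates are scanned in descending |amplitude| (ties: earlier time)
and greedily retained if ≥ 50 ms from every retained extremum — a
deterministic, order-independent rule. Alternation is then enforced by
repeatedly dropping the smaller of two same-sign neighbors.
Trough-to-peak amplitudes are adjacent-pair differences; the mean over
pairs centered within 0–0.7 s is reported separately. An empty set is
a valid result.

## Spectra and parameterization

Welch PSDs use 700 ms Hann windows with 350 ms overlap (frequency
resolution ≈ 1.43 Hz), applied to the trial-averaged LFP of the window
of interest. The spectral model over 1–40 Hz is knee-free:
log10 P(f) = offset − exponent·log10 f plus Gaussian peaks
(center, height in log10 units above the aperiodic component,
sd in Hz). Fitting: robust log-log aperiodic fit (OLS, then refit on
the points least elevated above the first fit), iterative largest-first
peak extraction from the flattened spectrum (max 6 peaks, min height
0.05 log10 units, bandwidth 2·sd limited to 1–12 Hz), bounded joint
Gaussian refinement, and an aperiodic refit on the peak-subtracted
spectrum. The "adjusted 4–8 Hz power" is the largest peak height with
center in band, 0 if none. The fit is scale-equivariant: scaling power
by c shifts only the offset by log10 c. Peak-fit settings are package
defaults, configurable; they were not tuned to any dataset.

## Phase synchronization

Phases come from complex Morlet convolution
(`mne.time_frequency.tfr_array_morlet`, 5 cycles for PLV); the wavelet
output is the analytic signal, so a separate Hilbert step is redundant
and "wavelet then Hilbert" is treated as equivalent. The first/last
3 wavelet standard deviations per frequency are masked invalid and
excluded from all summaries. PLV across N trials is the modulus of the
mean phase-difference phasor; the band summary is the median over
4–8 Hz × 0–0.7 s post-onset jointly over time and frequency (a
time-only median is also emitted, since either reading of "median
within the window" is defensible). PLV for N = 1 is identically 1 and
warns. The phase slope index uses 3.5-cycle wavelets, complex
coherency C(f) from trial- and time-averaged cross-spectra at 1 Hz
spacing, and PSI = Im Σ_f C*(f)C(f+δf); positive PSI means the first
signal leads; the estimator is exactly antisymmetric under argument
swap. Inter-areal pairs default to superficial-layer channels of the
two areas' columns.

## Unit responses and spike–field coupling

PSTHs are 1 ms histograms averaged over trials, smoothed with a 30 ms
Gaussian kernel. The Z score normalizes by the mean and standard
deviation of *per-trial baseline rates* (0–0.5 s). The denominator was
genuinely ambiguous (std across baseline time points of the smoothed
PSTH vs across trials); the across-time reading makes Z unit-scale by
construction regardless of data, so the across-trial reading — under
which a well-sampled null unit has |Z| ≪ 1 and a threefold rate step
reaches Z ≈ 2 — is implemented. Zero baseline variability flags the
unit invalid.

Firing groups rank time-averaged rates in 0.5–0.7, 0.7–0.9, 0.9–1.2 s
(ties → earlier window). A peak-Z variant is available behind the
`group_statistic="peak_z"` flag; the mean-rate rule is the default and
the two are not interchangeable.

Tuning hotspots: per-mouse 5 × 5 maps are max-normalized, averaged,
bilinearly upsampled to 50 × 50, smoothed with a σ = 5 px Gaussian,
and the argmax maps back to the nearest grid (SF, TF). A uniform map
falls back to the lowest indices with a warning.

Spike phases sample the analytic phase of the 4th-order zero-phase
Butterworth band-passed best-channel LFP at spike times, restricted to
0–0.7 s post-onset. PPC is the mean cosine of all pairwise phase
differences, computed by the O(N) closed form
(|Σe^{iφ}|² − N)/(N(N−1)); spikes are pooled across trials as the
formula's unrestricted pair sum implies. Units are "phase-selective"
when the Rayleigh test rejects uniformity at p < 0.05; PPC needs
N ≥ 2 (N ≥ 5 by default for a stable Rayleigh p).

## Statistics

Rayleigh (Z = N·R̄² with the standard small-sample correction, via
pingouin) requires N ≥ 5. The two-sample Kuiper statistic
V = max(F₁−F₂) + max(F₂−F₁) is rotation-invariant on the circle; its p
value uses the asymptotic series with the Stephens finite-sample
correction at effective size n₁n₂/(n₁+n₂) — the approximation choice
was open and is documented here. CLES is P(X>Y) + ½P(X=Y) = U/(n₁n₂).
BH-FDR delegates to statsmodels and is cross-checked against the
step-up definition. The permutation test on median differences
relabels pooled values preserving group sizes and uses the add-one
estimator p = (1+#{|null|≥|obs|})/(1+n_iter), so p > 0 always; all
resampling is seeded.

## Directed information

Spike trains are binarized into 1 ms bins within 0.5–1.5 s trial time.
Rows: the first 10 bins of each trial are dropped (incomplete history
is not zero-padded); a row is dropped iff the target and every
candidate are silent at t and throughout the preceding 100 ms. The
imbalance mask is evaluated once against the full candidate set per
target so all four candidate-set models (All, area-1-only,
area-2-only, None) score identical rows — required for comparable
likelihoods. Features: refractory Y(t−1)+Y(t−2), self-history
Y(t−3)+…+Y(t−10), and X(t−1)+…+X(t−10) per candidate, plus an
intercept.

Rows are split 50/50 within every trial (stratified by stimulus since
trials are single-stimulus); a single-row trial goes to train with a
warning. Each model is lasso-penalized logistic regression
(liblinear), penalty selected from 20 log-spaced values in
[10⁻², 10¹] by 5-fold CV on mean held-fold negative log likelihood,
then refit on all training rows. The penalty weights the *summed*
negative log likelihood (sklearn C = 1/λ); with a per-sample-averaged
likelihood the entire grid would zero every coupling for realistic
spike statistics, so the summed form — the one matching fixed
hyper-parameter values passed to sklearn's CV — is the implemented
objective.

Held-out DI is (1/T)Σ log₂[P_full/P_reduced] over test rows, with the
None (self-history-only) model as the reduced model for all four
evaluations, hence I_None ≡ 0 structurally. Values are normalized by
the empirical binary entropy of the target on the same test rows
(internal consistency of the ratio) and are *not* clipped at zero:
held-out DI is legitimately negative for overfit candidate sets, and
clipping would bias the permutation null. Shapley attribution averages
each area's marginal contribution over the two inclusion orders:
I₁^Shap = ½(I_All − I₂) + ½(I₁ − I_None), and the shares sum to
I_All − I_None to machine precision.

Models are fit once per target on the stratified train split and
Eq.-level DI is evaluated per SF/TF cell on that cell's test rows;
per-cell refitting would multiply cost 25× without changing the
inference. Candidates for a target are all simultaneously recorded
units except the target (both areas in the All model). Area-level
grids take the median attributed normalized DI per (ordered area pair,
stimulus, condition) over target units pooled across sessions;
differences are post − pre; per-cell significance comes from the
seeded permutation test relabeling unit weights with the original
condition proportions (independently per cell); BH-FDR runs across the
grid separately per ordered area pair. The default n_perm is 10⁴
(config override available for larger runs).

## Synthetic-data generator

The generator is the package's study-condition definition, not a
demo. Defaults: 20 trials per stimulus over the full 5 × 5 grid, two
areas × one 6-channel column to 850 µm, 6 Hz oscillation of 50 µV peak
amplitude starting at stimulus offset (0.7 s trial time) with a 1 s
amplitude decay constant, a −120 µV evoked transient 80 ms after onset
peaked at mid depths, 1/f background noise (exponent 1.0) at 2 µV rms,
an inter-areal lag of π/4 with von Mises per-trial jitter on area 2,
and laminar gain profiles placing the oscillation superficially and
the transient at input layers. Firing-rate defaults (2 Hz baseline +
8 Hz response) sit in the low range typical of extrastriate units; no
numerical population rates were available to match. The background
noise is deliberately small relative to the oscillation — the
high-SNR regime makes the analytic oracles (Bessel-ratio resultant
lengths) sharp; real recordings are far noisier, so passing recovery
tests demonstrate estimator correctness, not field-data robustness.

Spike generation modulates an inhomogeneous Poisson intensity by
exp(κ·cos(φ(t) − φ₀))/I₀(κ) of the *measured* band phase of the
unit's best-channel LFP (the same trace the analysis reads), with
φ₀ = π (troughs) by default; the phase sweeps uniformly during the
oscillation epoch, so spike phases are von Mises and
E[PPC] = (I₁(κ)/I₀(κ))². Binary-train generation samples the logistic
model sequentially with exactly the DI stage's feature construction
(shared summed-history definition), eliminating model mismatch in
recovery tests; history resets at trial boundaries.

What the generator does **not** emulate: traveling-wave spatial
structure, locomotion and state covariates, biophysical laminar
current sources, across-frequency interactions, non-Poisson spiking
(bursts), electrode drift, and realistic noise levels (above). The
inter-areal transmission is an instantaneous phase shift, not a
conduction delay, except that a phase lag at band frequencies is
indistinguishable from a delay to the estimators used here.

## Oracles used in tests

- PPC: O(N²) brute-force pairwise sum; uniform-phase unbiasedness;
  (I₁(κ)/I₀(κ))² under von Mises locking.
- PLV: the finite-N expectation of the resultant length of N = 20
  von Mises draws, computed by seeded Monte Carlo (the raw Bessel
  ratio is its N → ∞ limit; at N = 20 the estimator has a known
  positive offset, ≈ 0.2 at κ = 0, which the oracle includes).
  Recovery sessions omit the evoked transient, which is
  stimulus-locked and common to both areas and therefore adds
  zero-jitter phase-difference mass the pure-jitter oracle does not
  model; each session's estimate is also paired against its own
  realized jitter resultant.
- Spectral fit: forward-model inversion on noise-free synthetic
  spectra; white-noise Welch spectra for the zero-exponent null.
- PSI: sign recovery on a 20 ms-lagged narrowband pair; exact
  antisymmetry.
- DI: ground-truth GLM couplings (directionality and independence
  nulls); hand-enumerated kept-row mask and features on a 30-bin toy.
- Permutation/FDR: type-I calibration on exchangeable nulls; null
  5 × 5 grids for FDR false-positive control.

Problem sizes in the test suite and acceptance script (e.g. 50 PLV
replicates, ~110-trial DI runs giving ~50 k test rows, 30-replicate
null batteries, a 1-stimulus × 6-trial pipeline determinism check)
were chosen so the full battery runs in minutes on one CPU while
keeping Monte-Carlo standard errors well below the assertion
tolerances.

## Known limitations

- The middle-layer "largest amplitude" criterion, the PSTH Z
  denominator, and the time-vs-time×frequency PLV median are
  interpretations of under-specified definitions; each is documented
  above and, where reasonable, the alternative is available.
- The Kuiper p value is asymptotic; for samples near the N = 5
  minimum it is conservative.
- Directed information is measured per target unit by nested model
  comparison; it quantifies predictive influence under the 10 ms
  Markov order, not anatomical connectivity, and slower common inputs
  can still leak in.
- The permutation relabeling is per grid cell; a joint-across-cells
  null would preserve cross-stimulus correlations but is not what the
  per-cell heatmap tests describe.
- `connectivity_grid_from_weights` treats per-unit weights as
  exchangeable under the null; units recorded in both conditions
  violate exchangeability if strongly paired.
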