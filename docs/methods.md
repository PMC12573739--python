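# Methods

This note documents the models implemented in `pitchcode`, the choices
made where the procedure was genuinely open, and what the synthetic-data
generators do and do not emulate.

## FFR phase locking (`pitchcode.ffr`)

Epochs (230 ms: 20 ms baseline + 210 ms response) are band-passed with a
4th-order Butterworth (60–1500 Hz) applied forward–backward; a zero-phase
IIR is used because epoch timing must not be skewed by group delay and no
particular FIR design is canonical for this step. Trials with any sample
beyond ±35 µV (after filtering) are rejected; if all trials are rejected
the operation fails loudly with the count.

PLV uses DPSS tapers with time–bandwidth NW = 2 and 3 tapers — the minimal
standard multitaper — with per-epoch phase read from the tapered FFT bin
nearest each frequency on a 1 Hz grid (30–3000 Hz, capped below Nyquist).
The 1 Hz grid resolves the noise-floor bands (85–95, 105–116 Hz) exactly,
and the F0 bin is explicitly excluded from the floor. "Equal draws" from
the two stimulus polarities are implemented as one seeded subsample of
`n_draws` trials per polarity, pooled before the PLV; with all trials
used, the statistic is invariant to trial order.

Two caveats discovered while validating on synthetic data, both inherent
to the method rather than implementation artifacts:

* With 230 ms epochs a 100 Hz component falls exactly on a DFT bin, where
  the *antisymmetric* DPSS taper has a spectral null; with per-epoch
  noise, that taper's phase at exactly-on-bin frequencies is
  noise-dominated and the taper-averaged PLV saturates below 1. Real FFRs
  (jittered, never exactly on-bin) are unaffected; synthetic tests use
  either exactly identical epochs (PLV = 1 to machine precision) or
  slightly off-bin frequencies.
* The floor bands' inner edges lie within the multitaper mainlobe
  (±NW/T ≈ ±8.7 Hz) of the F0 bin, so a very strong locked component
  leaks some phase locking into the floor. This mirrors real data and is
  why the floor is a *reference*, not an independent null.

Group contrasts: Mann–Whitney U (rank-biserial r = 1 − 2U/(n₁n₂),
normal-approximation z reported alongside the exact/asymptotic p chosen by
scipy); within-group F0-vs-floor uses a paired t whose Cohen's d is the
mean difference over its SD — the sign convention (F0 minus floor) is
stated rather than assumed, since the direction of such contrasts is
ambiguous in the literature.

## Dynamic-F0 extraction (`pitchcode.f0`, `pitchcode.emd`)

Conditioning: resample to 8820 Hz (polyphase), low-pass at 1500 Hz with a
97-tap linear-phase FIR compensated for its constant delay, and zero all
spans whose 10 ms moving-RMS envelope falls below 10 % of the maximum. A
moving-RMS envelope (not a Hilbert magnitude) keeps silence detection
strictly local, so exact-zero pauses stay sub-threshold right up to their
edges; the modest filter order keeps sinc tails from smearing appreciable
energy into pauses.

Autocorrelation track: 50 ms rectangular frames, 1 ms hop, parabolic
interpolation of the autocorrelation peak in the 60–400 Hz lag band.
Frames are zeroed when mostly silent, when the peak is weak
(< 0.3·r(0)), when the estimate leaves 60–400 Hz, or when consecutive
frames jump by more than 10 Hz per ms (both frames of a violating pair are
zeroed — symmetric treatment of the jump endpoints). An octave guard
rejects frames whose half-lag is an equally strong period at a frequency
above the band, so out-of-range tones do not alias to subharmonics.

EMD: classical sifting with cubic-spline envelopes through mirrored
extrema (2 extrema reflected per edge), a Cauchy-type stop
(Σ(h₁−h₂)²/Σh₁² < 0.2, ratio-of-sums variant for robustness), at most 10
siftings per mode and 12 modes; non-converged modes are flagged. Each
contiguous non-silent span is decomposed *independently*: spline envelopes
must not bridge exact-zero silences, where they would oscillate freely and
corrupt neighbouring modes. Spans shorter than 60 ms are left as residual.

Instantaneous frequency is the unwrapped-phase derivative of the analytic
signal, boxcar-averaged over 25 ms. The boxcar estimates the mean phase
increment across the window, which is exactly the quantity the 20 %
selection rule needs; a median would be biased because harmonic residue
produces skewed within-cycle phase wobble.

Wavemode selection: per sample, among the IMFs whose instantaneous
frequency is within 20 % (relative) of the track, the one with the largest
instantaneous amplitude contributes. The "within 20 %" rule is evaluated
per time point (the only dimensionally consistent reading). Selection
masks are smoothed with a unit-sum 10 ms raised-cosine kernel, giving
cosine crossfades that form a partition of unity across mode transitions
and silence boundaries. After resampling to the EEG rate the silence mask
(dilated by 2 samples to absorb resampling tails) re-imposes exact zeros.

Verification oracle: recovered instantaneous frequency is compared with
the generator's true F0 using a 50 ms averaging window — the same
quasi-stationarity scale as the autocorrelation tracker.

## Forward TRFs (`pitchcode.trf`)

High-band preprocessing: Hamming-window FIR of order 50 (70–1500 Hz)
applied causally with the constant group delay removed, average-mastoid
referencing, epoching (−5…70 s around segment onsets) and polyphase
resampling to 1000 Hz.

The encoding model is linear in lagged stimulus copies over −25…50 ms (76
lags at 1000 Hz). Per-lag columns are centred and standardized (via
sufficient statistics; coefficients mapped back to stimulus units) and
ridge-regularized: (Z'Z/n + λI)w = Z'y. λ comes from a 9-point log grid
(1e−2…1e6) selected *per outer fold* by leave-one-out validation over that
fold's training trials. A single per-subject λ chosen against all trials
was tried first and rejected: it touches every later test trial and
inflated the null-data mean r by about +2.6 standard errors in simulation,
whereas per-fold selection leaves the null unbiased. The reported kernel
averages the per-fold solutions; `lam` is the fold median. Held-out
Pearson r per channel/trial is computed from sufficient statistics
(no time-domain prediction needed), clipped to [−1, 1].

Identifiability: with a narrowband stimulus (the F0 waveform occupies
roughly 70–180 Hz under the default generator), only kernel components
inside the excited band are estimable; the ground-truth kernel used in
recovery simulations is therefore a 120 Hz damped oscillation (decay
12 ms) whose spectrum lies in-band. Envelope analysis takes the Hilbert
magnitude of the kernel over lags; group comparisons restrict to 0–40 ms
and average TRFs across electrodes first.

## ARP classification (`pitchcode.arp`, `pitchcode.nn`)

Low-band preprocessing: polyphase resampling to 128 Hz, a minimum-phase
(causal) windowed-sinc FIR band-pass 1–15 Hz (homomorphic construction
from a 257-tap linear-phase prototype), average-mastoid referencing, and
neighbour-based channel repair: a channel whose amplitude (SD over time)
falls outside 3 robust SDs (median/MAD with a 5 % floor) of its
neighbours' amplitudes is replaced by the mean of its clean neighbours.
Robust neighbourhood statistics matter: with plain mean/SD one broken
channel masks itself and drags its neighbours over threshold. More than
25 % flagged channels aborts. The synthetic pipeline carries no
ocular/muscle artifacts, so no subspace-reconstruction or ICA stage
exists here.

ARPs average epochs (−0.5…0.5 s, 128 samples) over all tokens of one
accent class; one ARP per participant and class, four classes
(H\*, L\*, L+H\*, L\*+H).

Classifier: EEGNet-8,2-style compact CNN — temporal convolution (8 filters,
kernel 64 ≈ half the 128 Hz rate), batch norm, depthwise spatial
convolution across channels (2 per temporal filter), batch norm, ELU,
average-pool 4, dropout 0.5; separable temporal convolution (depthwise 16
+ pointwise), batch norm, ELU, average-pool 8, dropout 0.5; dense softmax.
2,340 trainable parameters at 61 × 128. Implemented directly in numpy with
explicit backpropagation (verified against finite differences); max-norm
constraints of the original architecture are omitted. Training: Adam,
cross-entropy, batch size 4, learning rate 1e−4 decaying ×0.7 every 100
epochs, up to 300 epochs, ~25 % of input channel rows zeroed per batch
(15 of 61), model selection at minimal validation loss. The *reduced
protocol* used by simulation studies shortens this to ≤ 50 epochs with
learning rate 1e−3 (fewer steps need larger steps) and patience-10 early
stopping.

Cross-validation: per repetition the balanced ARP set splits into k folds
(re-randomized if any training set lacks a class); each fold is predicted
once by a model that never saw it, with ⌈15 %⌉ of the remaining folds held
out for validation. The full protocol is 30 folds × 30 repetitions; the
simulation studies use 5 × 3. Entropy uses natural log (bounded by
ln 4 ≈ 1.386), the convention of the reference implementation ecosystem.

## Attribution (`pitchcode.relevance`)

DeepLIFT-Rescale with an all-zeros reference (the standard choice for this
architecture family; configurable). Multipliers pass through linear layers
(convolutions, pooling, eval-mode batch norm, dense) as their transpose
maps and through ELUs as chord slopes (f(x)−f(x₀))/(x−x₀) with a
derivative fallback when |x−x₀| < 1e−7. Because every layer is linear or
elementwise, summation-to-delta holds exactly (machine precision), which
the tests assert at 1e−3 relative tolerance.

Aggregation: |scores| → mean over repetitions → z-transform within each
accent matrix → mean over the four accents, one map per participant.
Group contrasts average relevance over 0–0.5 s and run per-electrode
independent t-tests with Bonferroni correction; a two-way mixed ANOVA
(group × electrode, classical split-plot sums of squares, no sphericity
correction) is provided for the window-mean topographies.

## Group statistics (`pitchcode.stats`)

Cluster-mass permutation tests form clusters from same-sign statistics
exceeding the two-sided p ≤ 0.05 t-quantile, merge adjacent members
(Delaunay triangulation of the planar montage with edges > 1.5× the median
removed; consecutive lags in time), score clusters by summed t, and
compare against the permutation null of the maximum absolute cluster mass
(sign flips for the one-sample electrode test, group-label exchange for
the two-sample lag test), with the (1 + count)/(n_perm + 1) estimator.
The largest |t| inside significant clusters is reported as t_max.

The two-sample gate runs Shapiro–Wilk on both samples: both p > 0.05 →
Welch's t with pooled-SD Cohen's d and a Welch-df CI on the mean
difference; otherwise (or for constant samples, where Shapiro is
undefined) Mann–Whitney U with rank-biserial r. Spearman correlations use
average ranks for ties; Bonferroni multiplies p by the family size m.

## Synthetic data (`pitchcode.synth`)

What is emulated: harmonic-complex syllables (first 8 harmonics, 1/n
rolloff — formant structure is irrelevant to F0 analyses); narrated speech
as voiced spans (0.8–2.5 s) alternating with pauses (0.1–0.5 s, the 500 ms
cap of edited audiobooks), an F0 trajectory built from Gaussian noise
smoothed over 150 ms around a 110 ± 20 Hz male-narrator baseline, clipped
to 60–400 Hz, with stylized 250 ms accent excursions (±30 Hz bumps and
rise/fall shapes) at annotated onsets whose class counts follow
largest-remainder apportionment of the annotated audiobook's token
frequencies (1610 : 318 : 1188 : 322); FFR epochs as a fixed-phase 100 Hz
component (identical across polarities, as for an envelope FFR) in 1/f
noise at an exact power-ratio SNR; continuous EEG as the true F0 waveform
convolved with a known per-channel kernel plus 1/f noise, with signal-free
mastoids (making average-mastoid referencing a no-op on signal); ARPs as
class templates active only 0–200 ms post onset (where accent responses
are most separable) scaled by a separation factor plus per-subject 1/f
noise. Narrator F0 statistics are parameters (`F0Model`), not constants,
since they are a property of the recording, not the method.

What is *not* emulated — and therefore what passing tests do not show
about real data: vocal-tract formants and unvoiced consonants, ocular and
muscular artifacts, volume conduction from realistic head geometry
(channels are independent up to the shared kernel), inter-subject latency
and topography variability, and attention effects. Recovery numbers on
synthetic data are upper bounds on real-data performance.

All generators are pure functions of (parameters, seed); 1/f noise is
spectrally shaped white noise normalized per series; realized noise is
rescaled so the empirical signal/noise power ratio matches the requested
SNR exactly.

## Problem sizes in tests and the acceptance script

F0 recovery runs on one 60 s story (~10 s of compute); PLV null
calibration uses 200 Monte-Carlo draws of 100 epochs; TRF recovery uses 15
× 2 s trials at 4 channels and the null 50 subjects × 8 × 1.5 s trials at
2 channels; classifier checks use 80 ARPs (20 subjects × 4 classes,
61 × 128) under the reduced 5-fold × 3-repetition protocol; cluster
calibration uses 1500 null datasets (Monte-Carlo SE ≈ 0.005 on a rate near
0.05) and 100 effect simulations at 1000 permutations each. These sizes
were chosen to keep the full suite a few minutes on one CPU while leaving
the Monte-Carlo error of each calibrated rate small against its acceptance
band.

## Known limitations

* EMD mode mixing: for strongly harmonic signals the first IMF mixes
  upper harmonics; the frequency-gated amplitude selection recovers the F0
  mode, but instantaneous-frequency estimates need the stated 25–50 ms
  averaging to be stable.
* The autocorrelation tracker assumes a single voice; overlapping talkers
  and creak/subharmonics are out of scope.
* The compact CNN trains on ARPs (per-participant class averages), not
  single trials, so reports concern average representations.
* Cluster-permutation p-values are calibrated under exchangeability; the
  electrode test's slight conservatism (~0.045 empirical FWER at α=0.05)
  stems from the discrete permutation estimator.
* The mixed ANOVA applies no sphericity correction and reports classical
  split-plot degrees of freedom.
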