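"""Synthetic stimuli, annotations and EEG with known ground truth.

Every downstream stage (FFR phase locking, dynamic-F0 extraction, TRF
estimation, ARP classification) is testable against these generators:

* harmonic-complex syllable surrogates with a fixed 100 Hz F0;
* narrated-speech surrogates: a smoothed random-walk F0 trajectory
  (clipped to 60-400 Hz) over alternating voiced spans and silences, with
  stylised pitch-accent excursions at annotated token onsets whose class
  frequencies follow the annotated audiobook's token counts;
* FFR epoch sets containing an F0-phase-locked component at a controlled
  SNR with alternating stimulus polarity;
* continuous EEG formed by convolving the true F0 waveform with a known
  per-channel kernel plus 1/f noise (mastoids carry noise only);
* per-participant ARPs built from class templates plus subject noise.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .arp import ACCENT_CLASSES, ACCENT_TOKEN_COUNTS, ARP, ARPDataset
from .montage import ring_montage

# --------------------------------------------------------------- helpers


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance per series."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    out = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` into integer counts proportional to ``proportions``."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("proportions must be nonnegative with positive sum")
    quota = total * p / p.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return counts


# --------------------------------------------------------------- syllables


@dataclass
class SyllableStimulusSpec:
    """Harmonic-complex surrogate of a constant-F0 syllable."""

    f0_hz: float = 100.0
    duration_ms: float = 170.0
    voicing_onset_ms: float = 10.0
    harmonics: tuple[tuple[int, float], ...] = tuple((n, 1.0 / n) for n in range(1, 9))
    sample_rate_hz: float = 20000.0

    def validate(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if not (self.duration_ms > self.voicing_onset_ms >= 0):
            raise ValueError("need duration_ms > voicing_onset_ms >= 0")
        top = max(n for n, _ in self.harmonics) * self.f0_hz
        if self.sample_rate_hz < 4 * top:
            raise ValueError(
                f"sample rate {self.sample_rate_hz} < 4x highest harmonic {top} Hz"
            )


def gen_syllable(spec: SyllableStimulusSpec) -> np.ndarray:
    """Peak-normalised harmonic complex, silent before the voicing onset."""
    spec.validate()
    fs = spec.sample_rate_hz
    n = int(round(spec.duration_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    onset = spec.voicing_onset_ms / 1000.0
    tau = t - onset
    wave = np.zeros(n)
    voiced = tau >= 0
    for k, amp in spec.harmonics:
        wave[voiced] += amp * np.sin(2 * np.pi * k * spec.f0_hz * tau[voiced])
    # 2 ms raised-cosine onset to avoid a click
    ramp_n = int(round(0.002 * fs))
    if ramp_n > 1:
        i0 = np.searchsorted(tau, 0)
        seg = slice(i0, min(i0 + ramp_n, n))
        k = np.arange(seg.stop - seg.start)
        wave[seg] *= 0.5 * (1 - np.cos(np.pi * k / ramp_n))
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


# --------------------------------------------------------------- story


@dataclass
class F0Model:
    """Parameters of the narrated-speech F0 surrogate (male narrator)."""

    mean_hz: float = 110.0
    sd_hz: float = 20.0
    smooth_s: float = 0.15
    f0_range: tuple[float, float] = (60.0, 400.0)
    voiced_span_s: tuple[float, float] = (0.8, 2.5)
    pause_s: tuple[float, float] = (0.1, 0.5)
    excursion_hz: float = 30.0
    token_len_s: float = 0.25
    n_harmonics: int = 8


@dataclass
class ContinuousStimulus:
    """Audio with ground-truth F0 trajectory, segments and accent tokens."""

    audio: np.ndarray
    sample_rate_hz: float
    f0_true: np.ndarray                    # Hz per audio sample, 0 = unvoiced
    segments: list[tuple[float, float]]
    annotations: list[tuple[float, str]]   # (onset_s, accent label)


# stylised unit F0 excursion shapes per accent class
_ACCENT_SHAPES = {
    "H*": lambda u: np.sin(np.pi * u),
    "L*": lambda u: -np.sin(np.pi * u),
    "L+H*": lambda u: -np.sin(2 * np.pi * u),   # dip then late peak
    "L*+H": lambda u: np.sin(2 * np.pi * u),    # early peak then dip
}


def gen_continuous_stimulus(
    duration_s: float,
    f0_model_params: F0Model | None = None,
    accent_freqs: tuple[int, int, int, int] = ACCENT_TOKEN_COUNTS,
    seed: int = 0,
    n_tokens: int | None = None,
    sample_rate_hz: float = 22050.0,
    segment_s: float = 60.0,
) -> ContinuousStimulus:
    """Narrated-speech surrogate with known F0 and accent annotations.

    Voiced spans alternate with silences; the F0 trajectory is a smoothed
    Gaussian random walk around the narrator mean with class-specific
    excursions at token onsets.  Token class counts follow
    largest-remainder apportionment of ``accent_freqs``.
    """
    model = f0_model_params or F0Model()
    freqs = np.asarray(accent_freqs, dtype=float)
    if len(freqs) != 4 or np.any(freqs < 0):
        raise ValueError("accent_freqs must be 4 nonnegative entries")
    rng = np.random.default_rng(seed)
    fs = sample_rate_hz
    n = int(round(duration_s * fs))
    # voiced/pause structure
    spans: list[tuple[float, float, bool]] = []
    t = float(rng.uniform(*model.pause_s)) * 0.5
    spans.append((0.0, t, False))
    voiced = True
    while t < duration_s:
        length = float(
            rng.uniform(*model.voiced_span_s) if voiced else rng.uniform(*model.pause_s)
        )
        spans.append((t, min(t + length, duration_s), voiced))
        t += length
        voiced = not voiced
    voiced_mask = np.zeros(n, dtype=bool)
    for a, b, v in spans:
        if v:
            voiced_mask[int(a * fs) : int(b * fs)] = True
    # token slots: spaced onsets inside voiced spans
    min_gap = max(0.3, model.token_len_s + 0.05)
    slots: list[float] = []
    for a, b, v in spans:
        if not v:
            continue
        s = a + 0.1
        while s + model.token_len_s + 0.05 <= b:
            slots.append(s)
            s += min_gap
    if n_tokens is None:
        n_tokens = int(0.6 * len(slots))
    if n_tokens > len(slots):
        raise ValueError(
            f"duration too short: {len(slots)} token slots < {n_tokens} requested"
        )
    counts = largest_remainder(freqs, n_tokens)
    labels = [c for cls, k in zip(ACCENT_CLASSES, counts) for c in [cls] * k]
    rng.shuffle(labels)
    chosen = np.sort(rng.choice(len(slots), n_tokens, replace=False))
    annotations = [(slots[i], lab) for i, lab in zip(chosen, labels)]
    # F0 trajectory: smoothed noise on a 100 Hz grid, then accent excursions
    grid_rate = 100.0
    n_grid = int(np.ceil(duration_s * grid_rate)) + 2
    walk = gaussian_filter1d(rng.standard_normal(n_grid), model.smooth_s * grid_rate)
    sd = walk.std()
    walk = walk / sd if sd > 0 else walk
    f0_grid = model.mean_hz + model.sd_hz * walk
    t_grid = np.arange(n_grid) / grid_rate
    for onset, lab in annotations:
        sel = (t_grid >= onset) & (t_grid < onset + model.token_len_s)
        u = (t_grid[sel] - onset) / model.token_len_s
        f0_grid[sel] += model.excursion_hz * _ACCENT_SHAPES[lab](u)
    f0_grid = np.clip(f0_grid, *model.f0_range)
    tt = np.arange(n) / fs
    f0 = np.interp(tt, t_grid, f0_grid)
    f0_true = np.where(voiced_mask, f0, 0.0)
    # harmonic synthesis following the instantaneous F0
    phase = 2 * np.pi * np.cumsum(f0_true) / fs
    audio = np.zeros(n)
    for k in range(1, model.n_harmonics + 1):
        audio += (1.0 / k) * np.sin(k * phase)
    audio *= _span_ramps(voiced_mask, fs, ramp_s=0.010)
    peak = np.max(np.abs(audio))
    if peak > 0:
        audio /= peak
    n_seg = max(1, int(np.ceil(duration_s / segment_s)))
    segments = [
        (i * segment_s, min((i + 1) * segment_s, duration_s)) for i in range(n_seg)
    ]
    return ContinuousStimulus(
        audio=audio,
        sample_rate_hz=fs,
        f0_true=f0_true,
        segments=segments,
        annotations=annotations,
    )


def _span_ramps(mask: np.ndarray, fs: float, ramp_s: float) -> np.ndarray:
    """Unit gain inside voiced spans with raised-cosine edges, 0 elsewhere."""
    gain = mask.astype(float)
    k = int(round(ramp_s * fs))
    if k < 2:
        return gain
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
    for e in edges:
        if mask[e + 1]:  # onset at e+1
            seg = slice(e + 1, min(e + 1 + k, len(gain)))
            gain[seg] *= ramp[: seg.stop - seg.start]
        else:  # offset after e
            seg = slice(max(0, e + 1 - k), e + 1)
            gain[seg] *= ramp[::-1][-(seg.stop - seg.start):]
    return gain


def true_f0_oscillation(
    stim: ContinuousStimulus, rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude oscillation at the true F0, resampled to ``rate_hz``.

    Returns ``(signal, f0)`` where silence is exactly zero — the idealised
    F0 waveform used as ground truth for TRF simulations.
    """
    n_out = int(round(len(stim.f0_true) / stim.sample_rate_hz * rate_hz))
    tt = np.arange(n_out) / rate_hz
    src_t = np.arange(len(stim.f0_true)) / stim.sample_rate_hz
    f0 = np.interp(tt, src_t, stim.f0_true)
    phase = 2 * np.pi * np.cumsum(f0) / rate_hz
    sig = np.sin(phase)
    sig[f0 <= 0] = 0.0
    return sig, f0


# --------------------------------------------------------------- FFR


@dataclass
class SimulatedFFRSet:
    """Single-trial FFR surrogates with alternating stimulus polarity."""

    epochs: np.ndarray       # (n_epochs, n_samples), microvolts
    polarity: np.ndarray     # +1 / -1 per epoch
    rate_hz: float
    snr: float
    f0_hz: float
    window_ms: tuple[float, float] = (-20.0, 210.0)


def gen_ffr_epochs(
    snr: float,
    n_epochs: int,
    eeg_rate_hz: float = 8000.0,
    seed: int = 0,
    f0_hz: float = 100.0,
    epoch_ms: float = 230.0,
    pre_ms: float = 20.0,
    stim_dur_ms: float = 170.0,
    voicing_onset_ms: float = 10.0,
    signal_uv: float = 0.1,
) -> SimulatedFFRSet:
    """Phase-locked F0 component plus 1/f noise at a controlled SNR.

    The envelope-rate component has identical phase in every epoch of both
    polarities.  ``snr`` is the power ratio of the phase-locked component
    to the noise over the whole epoch; 0 gives pure noise and ``np.inf`` a
    noiseless set.  ``n_epochs`` must be even (equal polarity counts).
    """
    if n_epochs % 2 != 0:
        raise ValueError("n_epochs must be even for balanced polarities")
    if not (snr >= 0):
        raise ValueError("snr must be >= 0")
    fs = eeg_rate_hz
    n = int(round(epoch_ms / 1000.0 * fs))
    t = np.arange(n) / fs
    t0 = (pre_ms + voicing_onset_ms) / 1000.0
    t1 = (pre_ms + stim_dur_ms) / 1000.0
    comp = np.where((t >= t0) & (t < t1), np.sin(2 * np.pi * f0_hz * (t - t0)), 0.0)
    comp = signal_uv * comp
    sig_power = np.mean(comp**2)
    rng = np.random.default_rng(seed)
    if np.isinf(snr):
        noise = np.zeros((n_epochs, n))
        amp = 1.0
    else:
        noise = pink_noise(rng, (n_epochs, n))
        noise_power = np.mean(noise**2)
        if snr > 0:
            noise *= np.sqrt(sig_power / (snr * noise_power))
            amp = 1.0
        else:
            noise *= np.sqrt(sig_power / noise_power)  # unit-signal-power noise
            amp = 0.0
    epochs = amp * comp[None, :] + noise
    polarity = np.tile([1, -1], n_epochs // 2)
    return SimulatedFFRSet(
        epochs=epochs, polarity=polarity, rate_hz=fs, snr=snr, f0_hz=f0_hz
    )


# --------------------------------------------------------------- EEG


@dataclass
class SimulatedContinuousEEG:
    """Channels x time EEG from a known forward kernel; mastoids last."""

    data: np.ndarray              # (n_scalp + 2, n_samples)
    rate_hz: float
    kernel_true: np.ndarray       # (n_scalp, n_lags)
    lags_ms: np.ndarray
    channel_names: list[str]
    trial_bounds: list[tuple[int, int]]


def make_trf_kernel(
    n_channels: int,
    rate_hz: float = 1000.0,
    lags_ms: tuple[float, float] = (-25.0, 50.0),
    seed: int = 0,
    osc_hz: float = 120.0,
    peak_ms: float = 8.0,
    decay_ms: float = 12.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Damped-oscillation forward kernel with smooth per-channel gains.

    Support lies in positive lags (a causal brainstem-like response) and
    the oscillation frequency sits inside the band the F0 waveform excites,
    so the kernel is identifiable from the narrowband stimulus.  Returns
    ``(kernel (n_channels, n_lags), lag axis in ms)``.
    """
    l0 = int(round(lags_ms[0] * rate_hz / 1000.0))
    l1 = int(round(lags_ms[1] * rate_hz / 1000.0))
    lags = np.arange(l0, l1 + 1) / rate_hz * 1000.0
    base = np.where(
        lags >= 0,
        np.exp(-np.abs(lags - peak_ms) / decay_ms) * np.sin(2 * np.pi * osc_hz * lags / 1000.0),
        0.0,
    )
    rng = np.random.default_rng(seed)
    gains = 0.5 + rng.random(n_channels)
    return gains[:, None] * base[None, :], lags


def gen_continuous_eeg(
    f0_waveform: np.ndarray,
    kernel_true: np.ndarray,
    snr: float,
    n_channels: int,
    seed: int = 0,
    rate_hz: float = 1000.0,
    lags_ms: tuple[float, float] = (-25.0, 50.0),
    n_trials: int = 15,
) -> SimulatedContinuousEEG:
    """EEG = per-channel convolution of the F0 waveform with a known kernel.

    Scalp channels receive signal plus 1/f noise at the requested power
    ratio; the two mastoid channels are noise only.  ``trial_bounds`` split
    the record into equal segments for cross-validated TRF fits.
    """
    s = np.asarray(f0_waveform, dtype=float)
    kernel_true = np.atleast_2d(np.asarray(kernel_true, dtype=float))
    if kernel_true.shape[0] != n_channels:
        raise ValueError("kernel_true must have one row per scalp channel")
    l0 = int(round(lags_ms[0] * rate_hz / 1000.0))
    L = kernel_true.shape[1]
    T = len(s)
    sig = np.empty((n_channels, T))
    for c in range(n_channels):
        conv = np.convolve(s, kernel_true[c], mode="full")
        idx = np.arange(T) - l0
        sig[c] = conv[idx]
    rng = np.random.default_rng(seed)
    noise = pink_noise(rng, (n_channels + 2, T))
    sig_power = np.mean(sig**2)
    if np.isinf(snr):
        noise *= 0.0
    else:
        noise_power = np.mean(noise[:n_channels] ** 2)
        target = sig_power / snr if snr > 0 else 1.0
        noise *= np.sqrt(target / noise_power)
        if snr == 0:
            sig *= 0.0
    data = np.vstack([sig + noise[:n_channels], noise[n_channels:]])
    montage = ring_montage(n_channels)
    trial_len = T // n_trials  # equal-length trials; remainder dropped
    bounds = [(i * trial_len, (i + 1) * trial_len) for i in range(n_trials)]
    lag_axis = np.arange(l0, l0 + L) / rate_hz * 1000.0
    return SimulatedContinuousEEG(
        data=data,
        rate_hz=rate_hz,
        kernel_true=kernel_true,
        lags_ms=lag_axis,
        channel_names=montage.all_names,
        trial_bounds=bounds,
    )


# --------------------------------------------------------------- ARPs


@dataclass
class SyntheticARPSpec:
    """Class-dependent spatiotemporal templates plus subject noise."""

    n_subjects_per_group: int = 20
    templates: np.ndarray | None = None   # (4, n_channels, n_samples)
    subject_noise_sd: float = 1.0
    separation: float = 1.0
    n_channels: int = 61
    n_samples: int = 128
    rate_hz: float = 128.0

    def validate(self) -> None:
        if self.templates is not None:
            t = np.asarray(self.templates)
            if t.shape != (4, self.n_channels, self.n_samples):
                raise ValueError(
                    "templates must be (4, n_channels, n_samples) matching this spec object"
                )


def make_accent_templates(
    n_channels: int = 61,
    n_samples: int = 128,
    seed: int = 0,
    rate_hz: float = 128.0,
    onset_sample: int | None = None,
    active_s: tuple[float, float] = (0.0, 0.2),
) -> np.ndarray:
    """Four class templates active only in ``active_s`` after token onset.

    Each template is a smooth random spatial pattern times a smooth random
    temporal course inside the active window (ARPs are most class-separable
    shortly after the accent onset), unit RMS over the active window.
    """
    rng = np.random.default_rng(seed)
    if onset_sample is None:
        onset_sample = n_samples // 2
    t = (np.arange(n_samples) - onset_sample) / rate_hz
    active = (t >= active_s[0]) & (t < active_s[1])
    templates = np.zeros((4, n_channels, n_samples))
    for c in range(4):
        spatial = gaussian_filter1d(rng.standard_normal(n_channels), 2.0)
        temporal = np.zeros(n_samples)
        temporal[active] = gaussian_filter1d(rng.standard_normal(active.sum()), 2.0)
        temporal[active] *= np.hanning(active.sum())
        pattern = np.outer(spatial, temporal)
        rms = np.sqrt(np.mean(pattern[:, active] ** 2))
        templates[c] = pattern / rms if rms > 0 else pattern
    return templates


def gen_arps(spec: SyntheticARPSpec, seed: int = 0, group: str = "") -> ARPDataset:
    """Balanced ARP dataset: class template (scaled by separation) + noise."""
    spec.validate()
    rng = np.random.default_rng(seed)
    if spec.templates is None:
        templates = make_accent_templates(
            spec.n_channels, spec.n_samples, seed=rng.integers(2**31), rate_hz=spec.rate_hz
        )
    else:
        templates = np.asarray(spec.templates, dtype=float)
    arps = []
    for s in range(spec.n_subjects_per_group):
        for c, label in enumerate(ACCENT_CLASSES):
            noise = spec.subject_noise_sd * pink_noise(
                rng, (spec.n_channels, spec.n_samples)
            )
            matrix = spec.separation * templates[c] + noise
            arps.append(
                ARP(matrix=matrix, accent=label, participant=f"s{s + 1}", n_tokens=1)
            )
    return ARPDataset(arps=arps, group=group)
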