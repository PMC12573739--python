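"""Dynamic-F0 waveform extraction from continuous speech.

Pipeline: condition the audio (resample to 8820 Hz, low-pass at 1500 Hz with
delay compensation, zero sub-threshold-envelope silences), track F0 by
short-window autocorrelation, decompose into intrinsic mode functions, and
per time point select — among the modes whose instantaneous frequency lies
within 20 % of the autocorrelation track — the one with the greatest
amplitude.  Mode transitions are cosine-crossfaded over a 10 ms window and
the result is resampled to the EEG rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.ndimage import binary_dilation

from .emd import IMFSet, sift

F0_MIN_HZ = 60.0
F0_MAX_HZ = 400.0


@dataclass
class ConditionedStimulus:
    waveform: np.ndarray
    rate_hz: float
    silence_mask: np.ndarray  # True where the envelope was sub-threshold


@dataclass
class AutocorrF0Track:
    """Frame-wise F0 estimates; 0 marks undefined/unvoiced frames."""

    times_s: np.ndarray
    f0_hz: np.ndarray
    hop_s: float


@dataclass
class F0Waveform:
    """Oscillatory wavemode following the speech F0; zero in silences."""

    signal: np.ndarray
    rate_hz: float
    provenance: np.ndarray  # selected IMF index per sample, -1 = none


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    if rate_in == rate_out:
        return x.copy()
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def condition_stimulus(
    audio: np.ndarray,
    rate_hz: float,
    target_rate: float = 8820.0,
    lp_hz: float = 1500.0,
    silence_frac: float = 0.10,
    numtaps: int = 97,
) -> ConditionedStimulus:
    """Resample, low-pass (linear-phase FIR, delay-compensated), zero silences.

    Silence is defined on the Hilbert envelope of the filtered signal: spans
    where the (smoothed) envelope falls below ``silence_frac`` of its
    maximum are set exactly to zero.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono")
    if len(audio) == 0 or np.ptp(audio) == 0:
        raise ValueError("audio is empty or constant")
    x = _resample(audio, rate_hz, target_rate)
    if lp_hz < target_rate / 2:
        taps = sps.firwin(numtaps, lp_hz, fs=target_rate)
        y = sps.lfilter(taps, 1.0, np.concatenate([x, np.zeros(numtaps // 2)]))
        x = y[numtaps // 2:]  # compensate the linear-phase group delay
    # moving-RMS envelope: strictly local, so exact-zero pauses stay
    # sub-threshold right up to their edges (a Hilbert envelope would
    # spread voiced energy several ms into the silences)
    win = max(1, int(round(0.010 * target_rate)))
    env = np.sqrt(sps.convolve(x**2, np.ones(win) / win, mode="same"))
    mask = env < silence_frac * env.max()
    x = x.copy()
    x[mask] = 0.0
    return ConditionedStimulus(waveform=x, rate_hz=target_rate, silence_mask=mask)


def autocorr_f0(
    cond: ConditionedStimulus,
    window_s: float = 0.050,
    hop_s: float = 0.001,
    f0_range: tuple[float, float] = (F0_MIN_HZ, F0_MAX_HZ),
    max_jump_hz_per_ms: float = 10.0,
    min_voiced_frac: float = 0.5,
) -> AutocorrF0Track:
    """Frame-wise autocorrelation F0 with range and jump-rate gating.

    Rectangular 50 ms frames advance in 1 ms hops; each frame's F0 is the
    parabolic-interpolated autocorrelation peak in the 60-400 Hz lag band.
    Frames out of range, mostly silent, or adjacent to a jump larger than
    10 Hz per ms are zeroed.
    """
    x = cond.waveform
    fs = cond.rate_hz
    win = int(round(window_s * fs))
    hop = max(1, int(round(hop_s * fs)))
    if len(x) < win:
        return AutocorrF0Track(np.array([]), np.array([]), hop / fs)
    n_frames = 1 + (len(x) - win) // hop
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[::hop][:n_frames]
    lag_min = max(2, int(np.floor(fs / f0_range[1])))
    lag_max = int(np.ceil(fs / f0_range[0]))
    nfft = int(2 ** np.ceil(np.log2(2 * win)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    acf = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, : lag_max + 2]
    f0 = np.zeros(n_frames)
    r0 = acf[:, 0]
    voiced_frac = np.mean(frames != 0, axis=1)
    band = acf[:, lag_min : lag_max + 1]
    peak_rel = np.argmax(band, axis=1)
    for i in range(n_frames):
        if r0[i] <= 0 or voiced_frac[i] < min_voiced_frac:
            continue
        lag = lag_min + peak_rel[i]
        if band[i, peak_rel[i]] <= 0.3 * r0[i]:
            continue  # weak periodicity
        # octave guard: if half the lag is an equally strong period whose
        # frequency lies above the search band, the true F0 is out of range
        half = lag // 2
        if half >= 2 and fs / half > f0_range[1] and acf[i, half] > 0.9 * acf[i, lag]:
            continue
        # parabolic interpolation around the integer-lag maximum
        if 1 <= lag < acf.shape[1] - 1:
            y0, y1, y2 = acf[i, lag - 1], acf[i, lag], acf[i, lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        est = fs / (lag + delta)
        if f0_range[0] <= est <= f0_range[1]:
            f0[i] = est
    # jump rule: zero both frames around any |dF| > threshold between
    # consecutive nonzero frames
    hop_ms = hop / fs * 1000.0
    thresh = max_jump_hz_per_ms * hop_ms
    nz = (f0[:-1] > 0) & (f0[1:] > 0)
    bad = nz & (np.abs(np.diff(f0)) > thresh)
    f0[np.where(bad)[0]] = 0.0
    f0[np.where(bad)[0] + 1] = 0.0
    times = (starts + win / 2) / fs
    return AutocorrF0Track(times_s=times, f0_hz=f0, hop_s=hop / fs)


def decompose_imfs(
    cond: ConditionedStimulus, min_span_s: float = 0.060, **kwargs
) -> IMFSet:
    """Empirical mode decomposition of the conditioned waveform.

    Each contiguous non-silent span is sifted independently — spline
    envelopes must not bridge the exact-zero silences — and the spans'
    modes are assembled into global mode arrays (rows beyond a span's mode
    count stay zero there).  Spans shorter than ``min_span_s`` are left as
    residual.
    """
    x = cond.waveform
    fs = cond.rate_hz
    n = len(x)
    active = ~cond.silence_mask & (x != 0)
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = list(edges[active[edges + 1]] + 1)
    stops = list(edges[~active[edges + 1]] + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        stops.append(n)
    max_modes = int(kwargs.get("max_modes", 12))
    imfs = np.zeros((max_modes, n))
    inst_freq = np.zeros((max_modes, n))
    inst_amp = np.zeros((max_modes, n))
    residual = np.zeros(n)
    non_converged: list[int] = []
    n_used = 0
    min_len = int(round(min_span_s * fs))
    for a, b in zip(starts, stops):
        if b - a < min_len:
            residual[a:b] = x[a:b]
            continue
        span = sift(x[a:b], fs, **kwargs)
        k = min(span.imfs.shape[0], max_modes)
        imfs[:k, a:b] = span.imfs[:k]
        inst_freq[:k, a:b] = span.inst_freq_hz[:k]
        inst_amp[:k, a:b] = span.inst_amp[:k]
        residual[a:b] = span.residual + span.imfs[k:].sum(axis=0)
        n_used = max(n_used, k)
        non_converged.extend(m for m in span.non_converged if m < k)
    n_used = max(n_used, 1)
    return IMFSet(
        imfs=imfs[:n_used],
        residual=residual,
        inst_freq_hz=inst_freq[:n_used],
        inst_amp=inst_amp[:n_used],
        rate_hz=fs,
        non_converged=sorted(set(non_converged)),
    )


def _track_to_samples(track: AutocorrF0Track, n: int, fs: float) -> np.ndarray:
    """Nearest-frame interpolation of the frame-wise track onto samples."""
    out = np.zeros(n)
    if len(track.times_s) == 0:
        return out
    idx = np.clip(
        np.round((np.arange(n) / fs - track.times_s[0]) / track.hop_s).astype(int),
        0,
        len(track.f0_hz) - 1,
    )
    return track.f0_hz[idx]


def select_wavemode(
    imfset: IMFSet,
    track: AutocorrF0Track,
    crossfade_ms: float = 10.0,
    rel_tol: float = 0.20,
    silence_mask: np.ndarray | None = None,
) -> F0Waveform:
    """Per-sample maximal-amplitude IMF within 20 % of the track F0.

    Transitions between contributing modes (including into/out of silence)
    are cosine-crossfaded over ``crossfade_ms``; samples whose candidate set
    is empty, whose track is zero, or that fall in conditioned silence are
    exactly zero.
    """
    fs = imfset.rate_hz
    n = imfset.imfs.shape[1]
    f_track = _track_to_samples(track, n, fs)
    valid = f_track > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(imfset.inst_freq_hz - f_track[None, :]) / f_track[None, :]
    candidate = (rel < rel_tol) & valid[None, :]
    amp = np.where(candidate, imfset.inst_amp, -np.inf)
    sel = np.argmax(amp, axis=0)
    sel[~candidate.any(axis=0)] = -1
    if silence_mask is not None:
        sel[silence_mask] = -1
    # cosine crossfade: smooth the one-hot selection masks with a unit-sum
    # raised-cosine kernel so weights form a partition of unity
    width = max(1, int(round(crossfade_ms / 1000.0 * fs)))
    if width > 1:
        kern = np.hanning(width + 2)[1:-1]
        kern /= kern.sum()
    else:
        kern = np.ones(1)
    out = np.zeros(n)
    for m in range(imfset.imfs.shape[0]):
        w = (sel == m).astype(float)
        if not w.any():
            continue
        if len(kern) > 1:
            w = sps.convolve(w, kern, mode="same")
        out += w * imfset.imfs[m]
    if silence_mask is not None:
        out[silence_mask] = 0.0
    out[~valid] = 0.0
    return F0Waveform(signal=out, rate_hz=fs, provenance=sel)


def extract_f0_waveform(
    audio: np.ndarray,
    rate_hz: float,
    eeg_rate_hz: float = 1000.0,
    **emd_kwargs,
) -> F0Waveform:
    """Full dynamic-F0 extraction, resampled to the EEG rate.

    Deterministic composition of conditioning, autocorrelation tracking,
    EMD, and wavemode selection.  Silent spans remain exactly zero after
    resampling.
    """
    audio = np.asarray(audio, dtype=float)
    if len(audio) and np.all(audio == 0):
        n_out = int(round(len(audio) * eeg_rate_hz / rate_hz))
        return F0Waveform(np.zeros(n_out), eeg_rate_hz, -np.ones(n_out, int))
    cond = condition_stimulus(audio, rate_hz)
    if np.all(cond.waveform == 0):
        n_out = int(round(len(cond.waveform) * eeg_rate_hz / cond.rate_hz))
        return F0Waveform(np.zeros(n_out), eeg_rate_hz, -np.ones(n_out, int))
    track = autocorr_f0(cond)
    imfset = decompose_imfs(cond, **emd_kwargs)
    wave = select_wavemode(imfset, track, silence_mask=cond.silence_mask)
    out = _resample(wave.signal, cond.rate_hz, eeg_rate_hz)
    n_out = len(out)
    # re-impose exact zeros over silent spans after polyphase resampling;
    # the mask is dilated by 2 output samples so resampling tails at span
    # edges cannot leak into the silences
    sil_idx = np.clip(
        np.round(np.arange(n_out) * cond.rate_hz / eeg_rate_hz).astype(int),
        0,
        len(cond.silence_mask) - 1,
    )
    sil = binary_dilation(cond.silence_mask[sil_idx], iterations=2)
    out[sil] = 0.0
    prov = wave.provenance[sil_idx]
    return F0Waveform(signal=out, rate_hz=eeg_rate_hz, provenance=prov)
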