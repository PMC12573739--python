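"""Empirical mode decomposition with Hilbert spectral estimates.

Classic EMD sifting: a signal is iteratively reduced to intrinsic mode
functions (IMFs), each satisfying (1) the number of extrema and of zero
crossings are equal or differ by one and (2) the local mean of the upper and
lower cubic-spline envelopes vanishes.  Envelope end effects are suppressed
by mirroring extrema at the boundaries.  Sifting of a mode stops on a
Cauchy-type criterion, SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_stop,
or after ``max_siftings`` iterations (the mode is then flagged as
non-converged).  Per-mode instantaneous frequency and amplitude come from
the analytic signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert
from scipy.ndimage import uniform_filter1d


@dataclass
class IMFSet:
    """Intrinsic mode functions of a signal plus Hilbert-spectral estimates.

    ``inst_freq_hz`` and ``inst_amp`` have one row per mode, aligned with
    the input samples.  ``residual`` completes the decomposition:
    ``imfs.sum(0) + residual`` reconstructs the input.
    """

    imfs: np.ndarray          # (n_modes, n_samples)
    residual: np.ndarray      # (n_samples,)
    inst_freq_hz: np.ndarray  # (n_modes, n_samples)
    inst_amp: np.ndarray      # (n_modes, n_samples)
    rate_hz: float
    non_converged: list[int] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima."""
    dx = np.diff(x)
    # collapse plateaus: use sign changes of the first difference
    sign = np.sign(dx)
    nonzero = sign != 0
    if not nonzero.any():
        return np.array([], int), np.array([], int)
    # forward-fill zero signs so plateau edges count once
    idx = np.where(nonzero, np.arange(len(sign)), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = sign[idx]
    change = np.diff(filled)
    maxima = np.where(change < 0)[0] + 1
    minima = np.where(change > 0)[0] + 1
    return maxima, minima


def count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def is_imf(x: np.ndarray, tol: int = 1) -> bool:
    """Check the extrema/zero-crossing counting property of an IMF."""
    maxima, minima = _local_extrema(x)
    n_ext = len(maxima) + len(minima)
    n_zc = count_zero_crossings(x)
    return abs(n_ext - n_zc) <= tol


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int, n_mirror: int = 2) -> np.ndarray:
    """Cubic-spline envelope through extrema with mirror boundary extension."""
    t = idx.astype(float)
    v = x[idx]
    if len(idx) < 2:
        return np.full(n, v[0] if len(idx) else 0.0)
    k = min(n_mirror, len(idx) - 1)
    left_t = 2 * t[0] - t[1:k + 1][::-1] if t[0] > 0 else -t[1:k + 1][::-1]
    left_v = v[1:k + 1][::-1]
    right_t = 2 * t[-1] - t[-k - 1:-1][::-1]
    right_v = v[-k - 1:-1][::-1]
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    spline = CubicSpline(tt[keep], vv[keep])
    return spline(np.arange(n))


def sift(
    signal: np.ndarray,
    rate_hz: float,
    max_modes: int = 12,
    max_siftings: int = 10,
    sd_stop: float = 0.2,
    freq_smooth_s: float = 0.025,
) -> IMFSet:
    """Decompose ``signal`` into IMFs and compute Hilbert estimates."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    n = len(x)
    residual = x.copy()
    modes: list[np.ndarray] = []
    non_converged: list[int] = []
    for _ in range(max_modes):
        maxima, minima = _local_extrema(residual)
        if len(maxima) + len(minima) < 4:
            break
        h = residual.copy()
        converged = False
        for _ in range(max_siftings):
            mx, mn = _local_extrema(h)
            if len(mx) < 2 or len(mn) < 2:
                converged = True
                break
            upper = _mirrored_envelope(h, mx, n)
            lower = _mirrored_envelope(h, mn, n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = np.sum(h * h)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_stop:
                converged = True
                break
        if not converged:
            non_converged.append(len(modes))
        modes.append(h)
        residual = residual - h
    if not modes:
        modes = [np.zeros(n)]
    imfs = np.vstack(modes)
    inst_freq, inst_amp = hilbert_spectrum(imfs, rate_hz, smooth_s=freq_smooth_s)
    return IMFSet(
        imfs=imfs,
        residual=residual,
        inst_freq_hz=inst_freq,
        inst_amp=inst_amp,
        rate_hz=rate_hz,
        non_converged=non_converged,
    )


def hilbert_spectrum(
    modes: np.ndarray, rate_hz: float, smooth_s: float = 0.025
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous frequency (Hz) and amplitude of each mode.

    Frequency is the centred phase derivative of the analytic signal,
    boxcar-averaged over ``smooth_s``.  The boxcar is the right smoother
    here: it estimates the mean phase increment over the window, which is
    robust to the within-cycle phase wobble that harmonic residue induces
    (a median would be biased by its skew).  Negative estimates are clipped
    to zero.
    """
    modes = np.atleast_2d(np.asarray(modes, dtype=float))
    analytic = hilbert(modes, axis=-1)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=-1)
    freq = np.gradient(phase, axis=-1) * rate_hz / (2 * np.pi)
    win = max(1, int(round(smooth_s * rate_hz)))
    if win > 1:
        freq = uniform_filter1d(freq, size=win, axis=-1, mode="nearest")
    return np.clip(freq, 0.0, None), amp
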