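"""Frequency-following response preprocessing and phase-locking spectra.

FFR epochs to a static-F0 syllable are band-limited (60-1500 Hz), trials
exceeding an absolute amplitude bound are rejected, and phase locking is
measured per frequency as the magnitude of the mean unit phase vector across
an equal number of draws from each stimulus polarity, using DPSS multitaper
phase estimates.  The noise floor is the mean PLV over flanking bands that
exclude the F0 bin (85-95 and 105-116 Hz for F0 = 100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from scipy.signal.windows import dpss

from .stats import TestResult


@dataclass
class FFREpochSet:
    """Band-limited, artifact-screened single-trial FFR epochs."""

    epochs: np.ndarray          # (n_trials, n_samples), microvolts
    polarity: np.ndarray        # (+1 / -1) per trial
    rate_hz: float
    window_ms: tuple[float, float] = (-20.0, 210.0)
    rejected_count: int = 0


@dataclass
class PLVSpectrum:
    """Per-frequency phase-locking values plus the noise-floor statistic."""

    freqs_hz: np.ndarray
    plv: np.ndarray
    plv_at_f0: float
    noise_floor: float
    f0_hz: float
    floor_bands: tuple[tuple[float, float], ...] = ((85.0, 95.0), (105.0, 116.0))


def preprocess_ffr(
    raw_epochs: np.ndarray,
    polarity: np.ndarray,
    rate_hz: float,
    band_hz: tuple[float, float] = (60.0, 1500.0),
    reject_uv: float = 35.0,
    window_ms: tuple[float, float] = (-20.0, 210.0),
) -> FFREpochSet:
    """Band-pass (zero-phase Butterworth) then reject epochs beyond ±reject_uv.

    Raises ``ValueError`` if every trial is rejected, reporting the count.
    """
    raw_epochs = np.asarray(raw_epochs, dtype=float)
    polarity = np.asarray(polarity)
    if raw_epochs.ndim != 2:
        raise ValueError("raw_epochs must be (n_trials, n_samples)")
    if len(polarity) != len(raw_epochs):
        raise ValueError("polarity labels must match trial count")
    hi = min(band_hz[1], 0.99 * rate_hz / 2)
    sos = sps.butter(4, [band_hz[0], hi], btype="bandpass", fs=rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, raw_epochs, axis=1)
    keep = np.max(np.abs(filtered), axis=1) <= reject_uv
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise ValueError(f"all {n_rejected} epochs exceeded ±{reject_uv} µV")
    return FFREpochSet(
        epochs=filtered[keep],
        polarity=polarity[keep],
        rate_hz=rate_hz,
        window_ms=window_ms,
        rejected_count=n_rejected,
    )


def _multitaper_phases(
    epochs: np.ndarray, rate_hz: float, freqs_hz: np.ndarray, nw: float, n_tapers: int
) -> np.ndarray:
    """Phases (n_tapers, n_trials, n_freqs) at the FFT bin nearest each frequency."""
    n = epochs.shape[1]
    tapers = dpss(n, nw, n_tapers)
    bins = np.round(freqs_hz * n / rate_hz).astype(int)
    bins = np.clip(bins, 0, n // 2)
    tapered = tapers[:, None, :] * epochs[None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)[..., bins]
    return np.angle(spec)


def compute_plv(
    epochset: FFREpochSet,
    freqs_hz: np.ndarray | None = None,
    n_draws: int | None = None,
    f0_hz: float = 100.0,
    floor_bands: tuple[tuple[float, float], ...] = ((85.0, 95.0), (105.0, 116.0)),
    nw: float = 2.0,
    n_tapers: int = 3,
    seed: int | None = 0,
) -> PLVSpectrum:
    """Multitaper PLV spectrum from equal draws of each polarity.

    ``n_draws`` trials per polarity (default: all of the smaller polarity)
    are pooled; at each frequency the PLV is the resultant length of the
    unit phase vectors across the pooled draws, averaged over tapers.
    """
    fs = epochset.rate_hz
    if freqs_hz is None:
        freqs_hz = np.arange(30.0, min(3000.0, fs / 2 - 1) + 1)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.max() >= fs / 2:
        raise ValueError("frequency grid exceeds Nyquist")
    pol = np.asarray(epochset.polarity)
    pos = np.where(pol > 0)[0]
    neg = np.where(pol < 0)[0]
    n_min = min(len(pos), len(neg))
    if n_draws is None:
        n_draws = n_min
    if n_draws > n_min or n_draws < 1:
        raise ValueError(f"n_draws must be in [1, {n_min}]")
    rng = np.random.default_rng(seed)
    take = np.concatenate([
        np.sort(rng.choice(pos, n_draws, replace=False)),
        np.sort(rng.choice(neg, n_draws, replace=False)),
    ])
    phases = _multitaper_phases(epochset.epochs[take], fs, freqs_hz, nw, n_tapers)
    resultant = np.abs(np.mean(np.exp(1j * phases), axis=1))  # (tapers, freqs)
    plv = resultant.mean(axis=0)
    plv_at_f0 = float(plv[np.argmin(np.abs(freqs_hz - f0_hz))])
    floor_mask = np.zeros(len(freqs_hz), dtype=bool)
    for lo, hi in floor_bands:
        floor_mask |= (freqs_hz >= lo) & (freqs_hz <= hi)
    # the F0 bin itself never enters the floor
    floor_mask &= np.abs(freqs_hz - f0_hz) > 1e-9
    noise_floor = float(plv[floor_mask].mean()) if floor_mask.any() else float("nan")
    return PLVSpectrum(
        freqs_hz=freqs_hz,
        plv=plv,
        plv_at_f0=plv_at_f0,
        noise_floor=noise_floor,
        f0_hz=f0_hz,
        floor_bands=floor_bands,
    )


def plv_group_contrast(plv_a: np.ndarray, plv_b: np.ndarray) -> TestResult:
    """Mann-Whitney U comparison of per-subject PLV at F0 between groups.

    Returns the U statistic, its normal-approximation z, the two-sided p
    (exact where SciPy chooses the exact null), and the rank-biserial
    effect size r = 1 - 2U/(n1*n2).
    """
    x = np.asarray(plv_a, dtype=float)
    y = np.asarray(plv_b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = spstats.mannwhitneyu(x, y, alternative="two-sided")
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    effect = 1 - 2 * res.statistic / (n1 * n2)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect=float(effect),
        method="mann-whitney-u",
        z=float(z),
    )


def plv_vs_floor(plv_at_f0: np.ndarray, noise_floor: np.ndarray) -> TestResult:
    """Within-group paired t of PLV at F0 against the noise floor.

    Cohen's d is the mean paired difference over its SD; both the signed d
    and the difference direction are meaningful (a positive d means F0 above
    floor under the F0-minus-floor convention used here).
    """
    x = np.asarray(plv_at_f0, dtype=float)
    y = np.asarray(noise_floor, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    diff = x - y
    res = spstats.ttest_rel(x, y)
    sd = diff.std(ddof=1)
    d = diff.mean() / sd if sd > 0 else np.inf * np.sign(diff.mean())
    se = sd / np.sqrt(len(diff))
    tcrit = spstats.t.ppf(0.975, len(diff) - 1)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect=float(d),
        method="paired-t",
        ci=(float(diff.mean() - tcrit * se), float(diff.mean() + tcrit * se)),
    )
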