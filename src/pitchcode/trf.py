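"""Forward temporal response functions from the F0 waveform to high-band EEG.

The encoding model is linear in lagged copies of the stimulus:
``eeg_c(t) = sum_l w_c(l) * f0w(t - l) + b_c`` over lags spanning -25 to
50 ms.  Kernels are estimated by ridge regression on standardized lagged
columns under leave-one-trial-out cross-validation; held-out Pearson r
between predicted and observed EEG is the neural-coding score.  The ridge
strength is chosen per subject by nested validation inside each training
set.  Hilbert envelopes of the kernels support amplitude-based group
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

DEFAULT_LAGS_MS = (-25.0, 50.0)
DEFAULT_LAMBDA_GRID = np.logspace(-2, 6, 9)


@dataclass
class HighBandEEG:
    """Filtered, mastoid-referenced, epoched EEG at the processing rate."""

    trials: np.ndarray  # (n_trials, n_channels, n_samples)
    rate_hz: float
    channel_names: list[str] | None = None


@dataclass
class TRFKernel:
    """Per-channel lag-domain weights of the forward model."""

    weights: np.ndarray   # (n_channels, n_lags)
    lags_ms: np.ndarray
    envelope: np.ndarray  # Hilbert magnitude per channel over lags
    lam: float


@dataclass
class CodingScore:
    """Held-out prediction accuracy of the forward model."""

    r_per_channel_trial: np.ndarray  # (n_trials, n_channels)
    r_mean: float


def preprocess_highband(
    data: np.ndarray,
    rate_hz: float,
    onsets_s: np.ndarray,
    mastoid_idx: tuple[int, int] = (-2, -1),
    band_hz: tuple[float, float] = (70.0, 1500.0),
    numtaps: int = 51,
    epoch_s: tuple[float, float] = (-5.0, 70.0),
    target_rate: float = 1000.0,
    channel_names: list[str] | None = None,
) -> HighBandEEG:
    """Band-pass (Hamming FIR, order ``numtaps``-1), mastoid-reference, epoch.

    The linear-phase FIR is applied causally and the constant group delay
    removed, then scalp channels are referenced to the mastoid average,
    epoched around segment onsets, and resampled to ``target_rate``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_channels, n_samples)")
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    if len(onsets_s) == 0:
        raise ValueError("no segment onsets supplied")
    n_ch = data.shape[0]
    mast = [i % n_ch for i in mastoid_idx]
    if len(set(mast)) != 2:
        raise ValueError("two distinct mastoid channels are required")
    hi = min(band_hz[1], 0.99 * rate_hz / 2)
    taps = sps.firwin(numtaps, [band_hz[0], hi], fs=rate_hz, pass_zero=False, window="hamming")
    delay = (numtaps - 1) // 2
    padded = np.concatenate([data, np.zeros((n_ch, delay))], axis=1)
    filt = sps.lfilter(taps, 1.0, padded, axis=1)[:, delay:]
    reference = filt[mast].mean(axis=0)
    scalp = np.array([i for i in range(n_ch) if i not in mast])
    ref_data = filt[scalp] - reference
    win = (int(round(epoch_s[0] * rate_hz)), int(round(epoch_s[1] * rate_hz)))
    trials = []
    for onset in onsets_s:
        start = int(round(onset * rate_hz)) + win[0]
        stop = int(round(onset * rate_hz)) + win[1]
        if start < 0 or stop > ref_data.shape[1]:
            raise ValueError(f"epoch around onset {onset:.3f}s exceeds the recording")
        trials.append(ref_data[:, start:stop])
    arr = np.stack(trials)
    if target_rate != rate_hz:
        from fractions import Fraction

        frac = Fraction(target_rate / rate_hz).limit_denominator(10000)
        arr = sps.resample_poly(arr, frac.numerator, frac.denominator, axis=2)
    names = None
    if channel_names is not None:
        names = [channel_names[i] for i in scalp]
    return HighBandEEG(trials=arr, rate_hz=target_rate, channel_names=names)


def lag_span_samples(lags_ms: tuple[float, float], rate_hz: float) -> np.ndarray:
    l0 = int(round(lags_ms[0] * rate_hz / 1000.0))
    l1 = int(round(lags_ms[1] * rate_hz / 1000.0))
    return np.arange(l0, l1 + 1)


def _lagged_design(stim: np.ndarray, lag_samples: np.ndarray) -> np.ndarray:
    """(T, L) design: column j holds the stimulus delayed by lag_samples[j]."""
    T = len(stim)
    X = np.zeros((T, len(lag_samples)))
    for j, lag in enumerate(lag_samples):
        if lag >= 0:
            X[lag:, j] = stim[: T - lag] if lag > 0 else stim
        else:
            X[:lag, j] = stim[-lag:]
    return X


class _TrialStats:
    """Sufficient statistics of one trial for ridge fits and r scoring."""

    def __init__(self, stim: np.ndarray, eeg: np.ndarray, lag_samples: np.ndarray):
        X = _lagged_design(stim, lag_samples)
        Y = eeg.T  # (T, C)
        self.n = X.shape[0]
        self.A = X.T @ X
        self.b = X.T @ Y
        self.sx = X.sum(axis=0)
        self.sy = Y.sum(axis=0)
        self.syy = (Y**2).sum(axis=0)


def _totals(stats: list[_TrialStats]):
    n = sum(s.n for s in stats)
    A = sum(s.A for s in stats)
    b = sum(s.b for s in stats)
    sx = sum(s.sx for s in stats)
    sy = sum(s.sy for s in stats)
    return n, A, b, sx, sy


def _minus(totals, excluded: list[_TrialStats]):
    n, A, b, sx, sy = totals
    for s in excluded:
        n = n - s.n
        A = A - s.A
        b = b - s.b
        sx = sx - s.sx
        sy = sy - s.sy
    return n, A, b, sx, sy


def _ridge_fit(totals, lam: float):
    """Ridge on centred+standardized columns; returns (w, intercept).

    ``w`` is mapped back to the original stimulus units;
    the normal equations use (Z'Z/n + lam*I) on the z-scored design.
    """
    n, A, b, sx, sy = totals
    mu = sx / n
    ybar = sy / n
    Ac = A - n * np.outer(mu, mu)
    bc = b - np.outer(mu, n * ybar)
    var = np.clip(np.diag(Ac) / n, 1e-30, None)
    sd = np.sqrt(var)
    Z = Ac / np.outer(sd, sd) / n
    rhs = bc / sd[:, None] / n
    L = Z.shape[0]
    w_std = np.linalg.solve(Z + lam * np.eye(L), rhs)
    w = w_std / sd[:, None]
    intercept = ybar - w.T @ mu
    return w, intercept


def _heldout_r(w: np.ndarray, trial: _TrialStats) -> np.ndarray:
    """Pearson r per channel on a held-out trial, from sufficient stats."""
    n = trial.n
    mu_pred = (w.T @ trial.sx) / n
    var_pred = np.einsum("lc,lm,mc->c", w, trial.A, w) / n - mu_pred**2
    mu_y = trial.sy / n
    var_y = trial.syy / n - mu_y**2
    cov = np.einsum("lc,lc->c", w, trial.b) / n - mu_pred * mu_y
    denom = np.sqrt(np.clip(var_pred * var_y, 0, None))
    r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def fit_trf(
    f0w_trials: np.ndarray,
    eeg: HighBandEEG,
    lags_ms: tuple[float, float] = DEFAULT_LAGS_MS,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    k: int | None = None,
) -> tuple[TRFKernel, CodingScore]:
    """Cross-validated forward TRF and neural-coding score.

    ``f0w_trials`` is (n_trials, n_samples) at the EEG rate.  With
    ``k = n_trials`` (default) each fold holds out one trial, trains the
    ridge on the rest, and predicts the held-out trial.  The ridge strength
    is selected per fold by nested leave-one-out over that fold's training
    trials only (maximizing mean validation r), so held-out scores stay
    unbiased under the null; the reported kernel is the average of per-fold
    training solutions and ``lam`` the median selected strength.
    """
    f0w_trials = np.asarray(f0w_trials, dtype=float)
    trials_eeg = eeg.trials
    n_trials = trials_eeg.shape[0]
    if f0w_trials.shape[0] != n_trials or f0w_trials.shape[1] != trials_eeg.shape[2]:
        raise ValueError("stimulus trials must align with EEG trials")
    if k is None:
        k = n_trials
    if k != n_trials:
        raise ValueError("leave-one-trial-out requires k == n_trials")
    if n_trials < 3:
        raise ValueError("need at least 3 trials")
    lag_samples = lag_span_samples(lags_ms, eeg.rate_hz)
    stats = [
        _TrialStats(f0w_trials[i], trials_eeg[i], lag_samples) for i in range(n_trials)
    ]
    totals = _totals(stats)
    # nested lambda selection per outer fold: leave-one-out over that
    # fold's training trials only; fits for an unordered exclusion pair
    # are shared across outer folds
    pair_w: dict[tuple[float, frozenset], np.ndarray] = {}
    inner_r = np.zeros((len(lambda_grid), n_trials, n_trials))  # [lam, outer, inner]
    for li, lam in enumerate(lambda_grid):
        for outer in range(n_trials):
            for inner in range(n_trials):
                if inner == outer:
                    continue
                key = (lam, frozenset((outer, inner)))
                if key not in pair_w:
                    sub = _minus(totals, [stats[outer], stats[inner]])
                    pair_w[key], _ = _ridge_fit(sub, lam)
                inner_r[li, outer, inner] = _heldout_r(pair_w[key], stats[inner]).mean()
    r = np.zeros((n_trials, trials_eeg.shape[1]))
    kernels = []
    fold_lams = []
    for fold in range(n_trials):
        scores = [
            np.mean([inner_r[li, fold, j] for j in range(n_trials) if j != fold])
            for li in range(len(lambda_grid))
        ]
        lam_f = float(lambda_grid[int(np.argmax(scores))])
        fold_lams.append(lam_f)
        train = _minus(totals, [stats[fold]])
        w, _ = _ridge_fit(train, lam_f)
        r[fold] = _heldout_r(w, stats[fold])
        kernels.append(w.T)  # (C, L)
    lam = float(np.median(fold_lams))
    weights = np.mean(kernels, axis=0)
    env = np.abs(sps.hilbert(weights, axis=1))
    kernel = TRFKernel(
        weights=weights,
        lags_ms=lag_samples / eeg.rate_hz * 1000.0,
        envelope=env,
        lam=lam,
    )
    score = CodingScore(r_per_channel_trial=r, r_mean=float(r.mean()))
    return kernel, score


def trf_envelope(kernel: TRFKernel, window_ms: tuple[float, float] | None = None) -> np.ndarray:
    """Hilbert magnitude of the kernel over lags, optionally windowed.

    The envelope discards carrier phase so group contrasts act on amplitude
    only; comparisons downstream typically restrict to 0-40 ms.
    """
    env = np.abs(sps.hilbert(kernel.weights, axis=1))
    if window_ms is not None:
        sel = (kernel.lags_ms >= window_ms[0]) & (kernel.lags_ms <= window_ms[1])
        env = env[:, sel]
    return env
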