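"""Accent-related potentials: extraction and compact-CNN classification.

An ARP is the average of low-band EEG epochs time-locked to every token of
one pitch-accent class (H*, L*, L+H*, L*+H), one per participant and class.
ARPs are classified with the compact CNN under repeated k-fold
cross-validation; each unique ARP is predicted once per repetition by a
model that never saw it, yielding a per-ARP proportion correct and a mean
Shannon entropy (nats) of the output probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .nn import (
    CompactCNNConfig,
    TrainConfig,
    train_compact_cnn,
)

ACCENT_CLASSES = ("H*", "L*", "L+H*", "L*+H")
#: token counts of the four classes in the annotated audiobook
ACCENT_TOKEN_COUNTS = (1610, 318, 1188, 322)


@dataclass
class LowBandEEG:
    """1-15 Hz, 128 Hz, mastoid-referenced EEG with channel-repair log."""

    data: np.ndarray  # (n_scalp, n_samples)
    rate_hz: float
    channel_names: list[str] | None = None
    interpolated: list[int] = field(default_factory=list)


@dataclass
class ARP:
    matrix: np.ndarray  # (n_channels, n_timepoints), window -0.5..0.5 s
    accent: str
    participant: str
    n_tokens: int


@dataclass
class ARPDataset:
    arps: list[ARP]
    group: str = ""

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([a.matrix for a in self.arps])
        y = np.array([ACCENT_CLASSES.index(a.accent) for a in self.arps])
        return X, y

    def is_balanced(self) -> bool:
        _, y = self.to_arrays()
        counts = np.bincount(y, minlength=len(ACCENT_CLASSES))
        return bool(np.all(counts == counts[0]))

    def __len__(self) -> int:
        return len(self.arps)


@dataclass
class ClassificationReport:
    """Per-ARP accuracy and uncertainty over CV repetitions."""

    per_arp_accuracy: np.ndarray      # (n_arps,) proportion correct
    per_arp_entropy: np.ndarray       # (n_arps,) mean entropy, nats
    per_arp_probs: np.ndarray         # (n_reps, n_arps, n_classes)
    labels: np.ndarray                # (n_arps,) true class indices
    participants: list[str]
    accents: list[str]
    n_repetitions: int

    @property
    def mean_accuracy(self) -> float:
        return float(self.per_arp_accuracy.mean())

    @property
    def median_entropy(self) -> float:
        return float(np.median(self.per_arp_entropy))


def minimum_phase_bandpass(
    band_hz: tuple[float, float], rate_hz: float, numtaps: int = 257
) -> np.ndarray:
    """Minimum-phase (causal) windowed-sinc FIR band-pass taps."""
    if numtaps % 2 == 0:
        numtaps += 1
    linear = sps.firwin(numtaps, list(band_hz), fs=rate_hz, pass_zero=False)
    return sps.minimum_phase(linear, method="homomorphic")


def preprocess_lowband(
    data: np.ndarray,
    rate_hz: float,
    mastoid_idx: tuple[int, int] = (-2, -1),
    neighbor_adjacency: np.ndarray | None = None,
    band_hz: tuple[float, float] = (1.0, 15.0),
    target_rate: float = 128.0,
    outlier_sd: float = 3.0,
    max_flagged_frac: float = 0.25,
    channel_names: list[str] | None = None,
) -> LowBandEEG:
    """Downsample to 128 Hz, causal band-pass 1-15 Hz, reference, repair.

    Channels whose amplitude (SD over time) falls outside ``outlier_sd``
    standard deviations of their neighbours' amplitudes are replaced by the
    mean of those neighbours; more than ``max_flagged_frac`` flagged
    channels aborts with an error.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_channels, n_samples)")
    n_ch = data.shape[0]
    mast = [i % n_ch for i in mastoid_idx]
    if len(set(mast)) != 2:
        raise ValueError("two distinct mastoid channels are required")
    if target_rate != rate_hz:
        from fractions import Fraction

        frac = Fraction(target_rate / rate_hz).limit_denominator(10000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    taps = minimum_phase_bandpass(band_hz, target_rate)
    filt = sps.lfilter(taps, 1.0, data, axis=1)
    reference = filt[mast].mean(axis=0)
    scalp = np.array([i for i in range(n_ch) if i not in mast])
    out = filt[scalp] - reference
    interpolated: list[int] = []
    if neighbor_adjacency is not None:
        adj = np.asarray(neighbor_adjacency, dtype=bool)
        if adj.shape != (len(scalp), len(scalp)):
            raise ValueError("adjacency must be n_scalp x n_scalp")
        amp = out.std(axis=1)
        for c in range(len(scalp)):
            nb = np.where(adj[c])[0]
            if len(nb) < 2:
                continue
            # robust neighbourhood statistics so one bad channel cannot
            # mask itself or drag its neighbours over the threshold
            mu = np.median(amp[nb])
            sd = 1.4826 * np.median(np.abs(amp[nb] - mu))
            sd = max(sd, 0.05 * mu)
            if sd > 0 and abs(amp[c] - mu) > outlier_sd * sd:
                interpolated.append(c)
        if len(interpolated) > max_flagged_frac * len(scalp):
            raise ValueError(
                f"{len(interpolated)} of {len(scalp)} channels flagged as outliers"
            )
        clean = np.setdiff1d(np.arange(len(scalp)), interpolated)
        repaired = out.copy()
        for c in interpolated:
            nb = np.intersect1d(np.where(adj[c])[0], clean)
            if len(nb) == 0:
                nb = clean
            repaired[c] = out[nb].mean(axis=0)
        out = repaired
    names = [channel_names[i] for i in scalp] if channel_names is not None else None
    return LowBandEEG(
        data=out, rate_hz=target_rate, channel_names=names, interpolated=interpolated
    )


def extract_arps(
    eeg: LowBandEEG,
    annotations: list[tuple[float, str]],
    participant: str = "s0",
    window_s: tuple[float, float] = (-0.5, 0.5),
) -> list[ARP]:
    """Average token-locked epochs per accent class into one ARP each.

    Epochs span ``window_s`` around each token onset (128 samples at
    128 Hz); tokens whose epoch exceeds the recording are skipped.  A class
    without any usable token fails for this participant.
    """
    fs = eeg.rate_hz
    pre = int(round(-window_s[0] * fs))
    post = int(round(window_s[1] * fs))
    n_t = eeg.data.shape[1]
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {c: 0 for c in ACCENT_CLASSES}
    for onset_s, label in annotations:
        if label not in ACCENT_CLASSES:
            raise ValueError(f"unknown accent label {label!r}")
        center = int(round(onset_s * fs))
        if center - pre < 0 or center + post > n_t:
            continue
        epoch = eeg.data[:, center - pre : center + post]
        sums[label] = sums.get(label, 0) + epoch
        counts[label] += 1
    arps = []
    for label in ACCENT_CLASSES:
        if counts[label] == 0:
            raise ValueError(f"participant {participant}: no tokens for {label!r}")
        arps.append(
            ARP(
                matrix=sums[label] / counts[label],
                accent=label,
                participant=participant,
                n_tokens=counts[label],
            )
        )
    return arps


def shannon_entropy(probs: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """H = -sum p ln p (nats) of probability vectors, with 0*ln0 = 0."""
    p = np.asarray(probs, dtype=float)
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=axis) - 1.0) > 1e-6):
        raise ValueError("probs must be a probability simplex")
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=axis)
    return float(h) if np.isscalar(h) or h.ndim == 0 else h


def _make_folds(
    rng: np.random.Generator, y: np.ndarray, n_folds: int, max_tries: int = 100
) -> list[np.ndarray]:
    """Random fold split; re-randomized if any training set misses a class."""
    n = len(y)
    n_classes = len(np.unique(y))
    for _ in range(max_tries):
        perm = rng.permutation(n)
        folds = [f for f in np.array_split(perm, n_folds) if len(f)]
        ok = all(
            len(np.unique(y[np.concatenate([g for j, g in enumerate(folds) if j != i])]))
            == n_classes
            for i in range(len(folds))
        )
        if ok:
            return folds
    raise RuntimeError("could not build folds with all classes in every training set")


def run_repeated_cv(
    dataset: ARPDataset,
    folds: int = 30,
    repetitions: int = 30,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    arch: CompactCNNConfig | None = None,
    val_fold_frac: float = 0.15,
) -> ClassificationReport:
    """Repeated leave-one-fold-out classification of the ARP dataset.

    Per repetition the dataset is split into ``folds`` folds; each fold is
    held out once while 15 % of the remaining folds (at least one) form the
    validation set for model selection at minimal validation loss, and the
    rest trains a fresh network.  Probabilities for every ARP are collected
    per repetition.
    """
    if not dataset.is_balanced():
        raise ValueError("ARP dataset must be class-balanced")
    X, y = dataset.to_arrays()
    n = len(y)
    if folds > n:
        raise ValueError("more folds than ARPs")
    n_classes = len(ACCENT_CLASSES)
    cfg = train_config or TrainConfig()
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(repetitions)
    probs = np.zeros((repetitions, n, n_classes))
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        fold_list = _make_folds(rng, y, folds)
        for i, test_ids in enumerate(fold_list):
            train_folds = [f for j, f in enumerate(fold_list) if j != i]
            n_val = max(1, int(np.ceil(val_fold_frac * len(train_folds))))
            val_pick = rng.choice(len(train_folds), n_val, replace=False)
            val_ids = np.concatenate([train_folds[j] for j in val_pick])
            fit_ids = np.concatenate(
                [f for j, f in enumerate(train_folds) if j not in val_pick]
            )
            model, _ = train_compact_cnn(
                X[fit_ids],
                y[fit_ids],
                X[val_ids],
                y[val_ids],
                n_classes=n_classes,
                config=cfg,
                arch=arch,
                seed=rng.integers(2**31),
            )
            probs[rep, test_ids] = model.predict_proba(X[test_ids])
    predicted = probs.argmax(axis=2)
    accuracy = (predicted == y[None, :]).mean(axis=0)
    entropy = np.stack([shannon_entropy(probs[r], axis=-1) for r in range(repetitions)])
    return ClassificationReport(
        per_arp_accuracy=accuracy,
        per_arp_entropy=entropy.mean(axis=0),
        per_arp_probs=probs,
        labels=y,
        participants=[a.participant for a in dataset.arps],
        accents=[a.accent for a in dataset.arps],
        n_repetitions=repetitions,
    )
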