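"""Attribution of classifier decisions to channels x timepoints.

DeepLIFT with the Rescale rule propagates multipliers from the target
logit back to the input, relative to a reference input (all zeros by
default).  Linear layers pass multipliers through their transpose map;
elementwise nonlinearities use the chord slope
``(f(x) - f(x_ref)) / (x - x_ref)`` (falling back to the derivative when
the input difference vanishes).  Contributions are
``multiplier * (x - x_ref)`` and satisfy summation-to-delta: they add up
to the change in the target logit from the reference.

Per-participant relevance: absolute contribution matrices are averaged
over CV repetitions, z-transformed within each matrix, then averaged over
the four accent classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .nn import ELU, CompactCNN


@dataclass
class RelevanceMatrix:
    """Channels x timepoints relevance, z-scored within the matrix."""

    scores: np.ndarray
    participant: str = ""
    window_s: tuple[float, float] = (-0.5, 0.5)


def attribute(
    model: CompactCNN,
    arp: np.ndarray,
    target_class: int,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """DeepLIFT-Rescale contributions of each input sample to a target logit.

    Returns a signed (channels x timepoints) matrix; positive scores are
    evidence toward ``target_class`` relative to the reference input.
    """
    x = np.asarray(arp, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != (model.n_channels, model.n_samples):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match model "
            f"({model.n_channels}, {model.n_samples})"
        )
    ref = np.zeros_like(x) if reference is None else np.asarray(reference, float)
    if ref.ndim == 2:
        ref = ref[None]
    # capture layer inputs for both passes (eval mode)
    acts_x, acts_r = [x], [ref]
    hx, hr = x, ref
    for layer in model.layers:
        hr = layer.forward(hr, training=False)
        acts_r.append(hr)
    for layer in model.layers:
        hx = layer.forward(hx, training=False)
        acts_x.append(hx)
    mult = np.zeros_like(hx)
    mult[:, target_class] = 1.0
    for i in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[i]
        if isinstance(layer, ELU):
            xin, rin = acts_x[i], acts_r[i]
            dx = xin - rin
            dy = layer.f(xin) - layer.f(rin)
            deriv = np.where(xin > 0, 1.0, layer.f(xin) + layer.alpha)
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = np.where(np.abs(dx) > 1e-7, dy / np.where(dx == 0, 1.0, dx), deriv)
            mult = mult * slope
        else:
            mult = layer.backprop_input_eval(mult)
    return (mult * (x - ref))[0]


def completeness_gap(
    model: CompactCNN,
    arp: np.ndarray,
    target_class: int,
    reference: np.ndarray | None = None,
) -> tuple[float, float]:
    """(contribution sum, logit delta) for the summation-to-delta check."""
    x = np.asarray(arp, dtype=float)
    ref = np.zeros_like(x) if reference is None else np.asarray(reference, float)
    contrib = attribute(model, x, target_class, reference=ref)
    lx = model.logits(x[None], training=False)[0, target_class]
    lr = model.logits(ref[None], training=False)[0, target_class]
    return float(contrib.sum()), float(lx - lr)


def aggregate_relevance(
    matrices: np.ndarray, participant: str = ""
) -> RelevanceMatrix:
    """Aggregate raw contribution matrices into one relevance map.

    ``matrices`` is (n_repetitions, n_accents, channels, timepoints).
    Pipeline: absolute value -> mean over repetitions -> z-transform within
    each accent matrix -> mean over accents.
    """
    m = np.asarray(matrices, dtype=float)
    if m.ndim != 4:
        raise ValueError("matrices must be (reps, accents, channels, timepoints)")
    mean_rep = np.abs(m).mean(axis=0)  # (accents, C, T)
    zs = np.empty_like(mean_rep)
    for a in range(mean_rep.shape[0]):
        mat = mean_rep[a]
        sd = mat.std()
        zs[a] = (mat - mat.mean()) / sd if sd > 0 else 0.0
    return RelevanceMatrix(scores=zs.mean(axis=0), participant=participant)


def group_relevance_contrast(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times_s: np.ndarray,
    window_s: tuple[float, float] = (0.0, 0.5),
    alpha: float = 0.05,
    electrode_names: list[str] | None = None,
) -> pd.DataFrame:
    """Electrode-wise group contrast of window-mean relevance, Bonferroni-corrected.

    ``group_a``/``group_b`` are (n_subjects, channels, timepoints) stacks of
    per-participant relevance matrices.  Within ``window_s`` relevance is
    averaged over time, then compared per electrode with an independent-
    samples t-test; p-values are multiplied by the electrode count.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 participants")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group matrices must share (channels, timepoints)")
    times_s = np.asarray(times_s, float)
    sel = (times_s >= window_s[0]) & (times_s <= window_s[1])
    wa = a[:, :, sel].mean(axis=2)  # (nA, C)
    wb = b[:, :, sel].mean(axis=2)
    n_el = wa.shape[1]
    t, p = spstats.ttest_ind(wa, wb, axis=0)
    p_bonf = np.minimum(1.0, p * n_el)
    names = electrode_names or [f"E{i + 1}" for i in range(n_el)]
    return pd.DataFrame(
        {
            "electrode": names,
            "t": t,
            "p_raw": p,
            "p_bonferroni": p_bonf,
            "significant": p_bonf < alpha,
        }
    )


def mixed_anova_relevance(
    group_a: np.ndarray, group_b: np.ndarray
) -> pd.DataFrame:
    """Two-way mixed ANOVA on subject x electrode relevance means.

    Between-subjects factor: age group (2 levels); within-subjects factor:
    electrode.  Classical split-plot sums of squares, no sphericity
    correction.  Inputs are (n_subjects, n_electrodes) window means.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    k = a.shape[1]
    if b.shape[1] != k:
        raise ValueError("electrode counts differ between groups")
    y = np.vstack([a, b])
    groups = np.array([0] * len(a) + [1] * len(b))
    N = len(y)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_between_subj = k * np.sum((subj_means - grand) ** 2)
    ss_group = sum(
        k * (groups == g).sum() * (y[groups == g].mean() - grand) ** 2 for g in (0, 1)
    )
    ss_subj_within = ss_between_subj - ss_group
    el_means = y.mean(axis=0)
    ss_electrode = N * np.sum((el_means - grand) ** 2)
    ss_inter = 0.0
    for g in (0, 1):
        yg = y[groups == g]
        cell = yg.mean(axis=0)
        ss_inter += len(yg) * np.sum((cell - yg.mean() - el_means + grand) ** 2)
    ss_total_within = np.sum((y - subj_means[:, None]) ** 2)
    ss_err = ss_total_within - ss_electrode - ss_inter
    df_group, df_subj = 1, N - 2
    df_el = k - 1
    df_int = k - 1
    df_err = (N - 2) * (k - 1)
    rows = []
    for name, ss, df, err_ss, err_df in (
        ("group", ss_group, df_group, ss_subj_within, df_subj),
        ("electrode", ss_electrode, df_el, ss_err, df_err),
        ("group:electrode", ss_inter, df_int, ss_err, df_err),
    ):
        ms = ss / df
        ms_err = err_ss / err_df
        F = ms / ms_err if ms_err > 0 else np.inf
        p = float(spstats.f.sf(F, df, err_df))
        rows.append({"effect": name, "F": F, "df1": df, "df2": err_df, "p": p})
    return pd.DataFrame(rows)
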