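"""DeepLIFT attribution: completeness, aggregation, group contrasts."""

import numpy as np
import pytest

from pitchcode.montage import delaunay_adjacency, ring_montage
from pitchcode.nn import (
    CompactCNN,
    CompactCNNConfig,
    Dense,
    Flatten,
    TrainConfig,
    train_compact_cnn,
)
from pitchcode.relevance import (
    aggregate_relevance,
    attribute,
    completeness_gap,
    group_relevance_contrast,
    mixed_anova_relevance,
)
from pitchcode.synth import SyntheticARPSpec, gen_arps, make_accent_templates

TINY_ARCH = CompactCNNConfig(temporal_kernel=16, separable_kernel=8, pool1=2, pool2=4)


class _LinearModel:
    """Bias-free linear classifier exposing the layer protocol."""

    def __init__(self, n_channels, n_samples, n_classes, rng):
        self.n_channels = n_channels
        self.n_samples = n_samples
        dense = Dense(n_channels * n_samples, n_classes, rng)
        dense.params["b"][...] = 0.0
        self.layers = [Flatten(), dense]

    def logits(self, x, training=False):
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        return h


class TestAttribute:
    def test_zero_weight_output_head_gives_zero_contributions(self):
        model = CompactCNN(8, 32, 4, config=TINY_ARCH, seed=0)
        dense = model.layers[-1]
        dense.params["W"][:, 2] = 0.0
        dense.params["b"][2] = 0.0
        x = np.random.default_rng(0).standard_normal((8, 32))
        contrib = attribute(model, x, target_class=2)
        assert np.allclose(contrib, 0.0)

    def test_linear_model_reduces_to_input_times_weight(self):
        rng = np.random.default_rng(1)
        model = _LinearModel(4, 8, 3, rng)
        x = rng.standard_normal((4, 8))
        contrib = attribute(model, x, target_class=1)
        W = model.layers[1].params["W"][:, 1].reshape(4, 8)
        assert np.allclose(contrib, x * W)

    def test_completeness_on_random_inputs(self):
        model = CompactCNN(12, 64, 4, seed=2, config=TINY_ARCH)
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.standard_normal((12, 64))
            total, delta = completeness_gap(model, x, int(rng.integers(4)))
            assert abs(total - delta) <= 1e-3 * max(abs(delta), 1e-6)

    def test_shape_mismatch_rejected(self):
        model = CompactCNN(8, 32, 4, config=TINY_ARCH, seed=0)
        with pytest.raises(ValueError):
            attribute(model, np.zeros((4, 32)), target_class=0)


class TestAggregate:
    def test_identical_matrices_aggregate_to_single_z_transform(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((4, 6, 10))
        stack = np.repeat(base[None], 3, axis=0)  # 3 reps, identical
        out = aggregate_relevance(stack)
        one = np.abs(base)
        zs = np.stack([(m - m.mean()) / m.std() for m in one])
        assert np.allclose(out.scores, zs.mean(axis=0))

    def test_z_transform_mean_zero_sd_one(self):
        rng = np.random.default_rng(1)
        stack = rng.standard_normal((5, 4, 6, 10))
        out = aggregate_relevance(stack)
        # each accent matrix was z-scored before averaging
        mean_rep = np.abs(stack).mean(axis=0)
        for a in range(4):
            z = (mean_rep[a] - mean_rep[a].mean()) / mean_rep[a].std()
            assert abs(z.mean()) < 1e-9
            assert z.std() == pytest.approx(1.0)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        stack = rng.standard_normal((3, 4, 6, 10))
        a = aggregate_relevance(stack)
        b = aggregate_relevance(-stack)
        assert np.allclose(a.scores, b.scores)

    def test_repetition_and_accent_order_invariance(self):
        rng = np.random.default_rng(3)
        stack = rng.standard_normal((4, 4, 6, 10))
        a = aggregate_relevance(stack)
        b = aggregate_relevance(stack[::-1, ::-1])
        assert np.allclose(a.scores, b.scores)


class TestGroupContrast:
    def test_identical_groups_no_significant_electrodes(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((10, 8, 20))
        times = np.linspace(-0.5, 0.5, 20)
        df = group_relevance_contrast(base, base.copy(), times)
        assert not df["significant"].any()

    def test_boosted_electrodes_detected(self):
        rng = np.random.default_rng(1)
        times = np.linspace(-0.5, 0.5, 64)
        window = (times >= 0) & (times <= 0.5)
        # window-mean of iid noise has SD 1/sqrt(n_win); shift 5 electrodes
        # of group A by 1.5 of that SD
        delta = 1.5 / np.sqrt(window.sum())
        hits = np.zeros(5)
        n_sims = 50
        for s in range(n_sims):
            a = rng.standard_normal((20, 16, 64))
            b = rng.standard_normal((20, 16, 64))
            a[:, :5, :][:, :, window] += delta
            df = group_relevance_contrast(a, b, times)
            hits += df["significant"].to_numpy()[:5]
        # theoretical marginal power ~0.92 per electrode at this n/effect;
        # assert a stable lower envelope over 50 simulations
        assert hits.mean() / n_sims >= 0.85
        assert np.all(hits / n_sims >= 0.78)

    def test_tiny_groups_rejected(self):
        times = np.linspace(-0.5, 0.5, 10)
        with pytest.raises(ValueError):
            group_relevance_contrast(
                np.zeros((1, 4, 10)), np.zeros((5, 4, 10)), times
            )


class TestTemporalProfile:
    def test_relevance_concentrates_where_templates_differ(self):
        """Templates differ only 0-200 ms post onset; attribution should
        assign higher relevance there than at 300-500 ms (sign test)."""
        n_ch, n_t = 16, 128
        templates = make_accent_templates(n_ch, n_t, seed=4)
        spec = SyntheticARPSpec(
            n_subjects_per_group=12, templates=templates, separation=3.0,
            subject_noise_sd=1.0, n_channels=n_ch, n_samples=n_t,
        )
        ds = gen_arps(spec, seed=6)
        X, y = ds.to_arrays()
        model, _ = train_compact_cnn(
            X, y, X, y, config=TrainConfig(max_epochs=25, lr=1e-3), seed=0
        )
        times = (np.arange(n_t) - n_t // 2) / 128.0
        early = (times >= 0.0) & (times < 0.2)
        late = (times >= 0.3) & (times < 0.5)
        n_subj = 12
        wins = 0
        for s in range(n_subj):
            mats = np.stack(
                [np.abs(attribute(model, X[4 * s + c], y[4 * s + c])) for c in range(4)]
            )
            rel = aggregate_relevance(mats[None]).scores
            if rel[:, early].mean() > rel[:, late].mean():
                wins += 1
        from scipy.stats import binomtest

        assert binomtest(wins, n_subj, 0.5, alternative="greater").pvalue < 0.05


def test_mixed_anova_detects_interaction():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((15, 8))
    b = rng.standard_normal((15, 8))
    b[:, :4] += 1.5  # group-by-electrode interaction
    res = mixed_anova_relevance(a, b)
    inter = res[res["effect"] == "group:electrode"].iloc[0]
    assert inter["p"] < 0.001
    null = mixed_anova_relevance(a, a + 0.0)
    assert null[null["effect"] == "group:electrode"].iloc[0]["p"] > 0.9
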