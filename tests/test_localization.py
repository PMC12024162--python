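"""Top-down importance propagation: oracle equivalence, conservation, scoring."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from lemmap import nn
from lemmap.extremum import aggregate, detect_extrema
from lemmap.localization import (CapabilityError, ImportanceMap,
                                 binarize_and_score, dice, localize,
                                 propagate_importance, recall, select_extrema)


def tiny_net(rng, c_mid=2, ksize=3, size=3, pad=0, positive=False):
    """Conv(1->c_mid, no padding by default) + ReLU + 1x1 score head."""
    conv = nn.Conv2D(1, c_mid, ksize, pad=pad, rng=rng, pad_mode="zeros")
    proj = nn.ScoreProjection(c_mid, rng=rng)
    if positive:
        conv.W[...] = np.abs(conv.W)
        proj.V[...] = np.abs(proj.V)
    return nn.Network([conv, nn.ReLU()], proj)


def oracle_importance(net, x, extremum):
    """Exhaustive path-enumeration oracle for a Conv+ReLU+head net.

    Builds the dense unit graph with scipy correlations (independent of the
    package's conv code) and sums, over all pixel->hidden->extremum paths,
    the product of per-layer importance fractions.
    """
    conv, _ = net.features
    proj = net.proj
    r, c, kind = extremum
    img = x[0, 0]
    # hidden activations, via scipy
    pre = np.stack([correlate2d(img, conv.W[o, 0], mode="valid") + conv.b[o]
                    for o in range(conv.W.shape[0])])
    hidden = np.maximum(pre, 0.0)
    # layer-2 fractions: channels at (r, c) -> extremum
    v = np.maximum(proj.V, 0.0) if kind == "max" else np.maximum(-proj.V, 0.0)
    num2 = v * hidden[:, r, c]
    z2 = num2.sum()
    if z2 <= 0:
        return np.zeros_like(img)
    frac2 = num2 / z2
    # layer-1 fractions: pixel (i, j) -> hidden unit (o, r, c)
    out = np.zeros_like(img)
    k = conv.W.shape[-1]
    for o in range(conv.W.shape[0]):
        num1 = np.maximum(conv.W[o, 0], 0.0) * img[r:r + k, c:c + k]
        z1 = num1.sum()
        if z1 <= 0:
            continue
        out[r:r + k, c:c + k] += frac2[o] * num1 / z1
    return out


class TestSelectExtrema:
    def test_malignant_branch_returns_positive_maxima(self):
        S = np.zeros((3, 3))
        S[1, 1] = 2.0
        E = detect_extrema(S)
        agg = aggregate(S, E)
        sel = select_extrema(S, E, agg, threshold=0.5)
        assert agg.y_lem > 0.5
        assert sel == [(1, 1, "max")]

    def test_benign_branch_returns_only_minima(self):
        S = np.zeros((3, 3))
        S[1, 1] = -2.0
        E = detect_extrema(S)
        agg = aggregate(S, E)
        assert agg.y_lem < 0.5
        sel = select_extrema(S, E, agg, threshold=0.5)
        assert sel == [(1, 1, "min")]

    def test_constant_zero_map_benign_branch_is_empty(self):
        S = np.zeros((4, 4))
        E = detect_extrema(S)
        agg = aggregate(S, E)
        assert agg.y_lem == pytest.approx(0.5)
        assert select_extrema(S, E, agg, threshold=0.5) == []


class TestPropagation:
    def test_single_unit_single_pixel(self, rng):
        """One pixel, one positive-weight unit: all importance lands there."""
        conv = nn.Conv2D(1, 1, 1, pad=0, rng=rng)
        conv.W[...] = 0.7
        proj = nn.ScoreProjection(1, rng=rng)
        proj.V[...] = 1.0
        net = nn.Network([conv, nn.ReLU()], proj)
        net.forward(np.full((1, 1, 1, 1), 0.4))
        imap = propagate_importance(net, (0, 0, "max"))
        assert imap.values.shape == (1, 1)
        assert imap.values[0, 0] == pytest.approx(1.0)

    def test_matches_path_enumeration_oracle(self, rng):
        for trial in range(30):
            net = tiny_net(rng, c_mid=3, size=4)
            x = rng.uniform(0.05, 1.0, (1, 1, 4, 4))
            _, S = net.forward(x)
            kind = "max" if trial % 2 == 0 else "min"
            r, c = rng.integers(0, 2), rng.integers(0, 2)
            imap = propagate_importance(net, (int(r), int(c), kind))
            expected = oracle_importance(net, x, (int(r), int(c), kind))
            assert np.allclose(imap.values, expected, atol=1e-10)

    def test_unit_mass_conservation_with_positive_weights(self, rng):
        """All weights and inputs positive: every normaliser is positive and
        each extremum delivers exactly unit mass to the pixels."""
        from lemmap import LemConfig, build_tiny_backbone
        cfg = LemConfig(seed=3, channels=(4, 6), image_size=32)
        net = build_tiny_backbone(cfg, np.random.default_rng(3))
        for layer in net.features:
            if isinstance(layer, nn.Conv2D):
                layer.W[...] = np.abs(layer.W)
        net.proj.V[...] = np.abs(net.proj.V) + 0.01
        x = np.random.default_rng(4).uniform(0.1, 1.0, (1, 1, 32, 32))
        net.forward(x)
        imap = propagate_importance(net, (3, 3, "max"))
        assert np.all(imap.values >= 0)
        assert imap.values.sum() == pytest.approx(1.0, abs=1e-5)

    def test_nonnegativity_everywhere(self, rng):
        net = tiny_net(rng, c_mid=4, size=5)
        x = rng.uniform(0, 1, (1, 1, 5, 5))
        net.forward(x)
        imap = propagate_importance(net, (1, 1, "max"))
        assert np.all(imap.values >= 0)

    def test_max_min_branch_symmetry_under_negated_projection(self, rng):
        """Negating V turns the score map into its mirror image; the min
        branch on the negated head yields the same map as the max branch."""
        net = tiny_net(rng, c_mid=3, size=4)
        x = rng.uniform(0.05, 1.0, (1, 1, 4, 4))
        net.forward(x)
        a = propagate_importance(net, (1, 1, "max")).values
        net.proj.V *= -1.0
        net.forward(x)
        b = propagate_importance(net, (1, 1, "min")).values
        assert np.allclose(a, b, atol=1e-12)

    def test_unsupported_layer_raises_capability_error(self, rng):
        class Strange(nn.Layer):
            def forward(self, x):
                self.x = x
                return x

        proj = nn.ScoreProjection(1, rng=rng)
        net = nn.Network([Strange()], proj)
        net.forward(np.ones((1, 1, 4, 4)))
        with pytest.raises(CapabilityError, match="Strange"):
            propagate_importance(net, (0, 0, "max"))

    def test_avgpool_propagation_conserves_mass(self, rng):
        conv = nn.Conv2D(1, 2, 3, rng=rng)
        conv.W[...] = np.abs(conv.W)
        proj = nn.ScoreProjection(2, rng=rng)
        proj.V[...] = np.abs(proj.V) + 0.1
        net = nn.Network([conv, nn.ReLU(), nn.AvgPool2D(2)], proj)
        x = rng.uniform(0.1, 1.0, (1, 1, 8, 8))
        net.forward(x)
        imap = propagate_importance(net, (2, 2, "max"))
        assert imap.values.sum() == pytest.approx(1.0, abs=1e-5)


class TestLocalize:
    def test_additivity_over_selected_extrema(self, rng):
        net = tiny_net(rng, c_mid=3, size=6, positive=True)
        x = rng.uniform(0.05, 1.0, (1, 1, 6, 6))
        imap, agg = localize(net, x[0, 0], threshold=0.5)
        if imap.source_extrema:
            net.forward(x)
            total = sum(propagate_importance(net, e).values
                        for e in imap.source_extrema)
            assert np.allclose(imap.values, total, atol=1e-10)

    def test_untrained_net_still_yields_valid_distribution(self, rng):
        from lemmap import LemConfig, build_tiny_backbone
        cfg = LemConfig(seed=9, channels=(4, 4), image_size=32)
        net = build_tiny_backbone(cfg, rng)
        imap, _ = localize(net, rng.uniform(0, 1, (32, 32)), cfg)
        assert np.all(imap.values >= 0)
        if imap.source_extrema:
            assert imap.values.sum() <= len(imap.source_extrema) + 1e-6

    def test_empty_selection_returns_zero_map_with_status(self):
        from lemmap import LemConfig, build_tiny_backbone
        cfg = LemConfig(seed=9, channels=(4, 4), image_size=32)
        net = build_tiny_backbone(cfg, np.random.default_rng(0))
        # zero image -> constant activations -> benign branch, no negatives
        imap, _ = localize(net, np.zeros((32, 32)), cfg)
        if imap.status == "empty-selection":
            assert imap.values.sum() == 0.0


class TestBinarizeAndScore:
    def test_identical_masks_score_one(self):
        truth = np.zeros((8, 8), dtype=bool)
        truth[2:4, 2:4] = True
        imap = ImportanceMap(values=truth.astype(float))
        res = binarize_and_score(imap, truth)
        assert res.dsc == 1.0 and res.recall == 1.0

    def test_disjoint_masks_score_zero(self):
        truth = np.zeros((8, 8), dtype=bool)
        truth[:2, :2] = True
        values = np.zeros((8, 8))
        values[6:, 6:] = 1.0
        res = binarize_and_score(ImportanceMap(values=values), truth)
        assert res.dsc == 0.0 and res.recall == 0.0

    def test_half_overlap_dice_formula(self):
        pred = np.zeros(200, dtype=bool)
        truth = np.zeros(200, dtype=bool)
        pred[:100] = True
        truth[50:150] = True
        assert dice(pred, truth) == pytest.approx(0.5)
        assert recall(pred, truth) == pytest.approx(0.5)

    def test_all_zero_map_gives_empty_mask(self):
        truth = np.ones((4, 4), dtype=bool)
        res = binarize_and_score(ImportanceMap(values=np.zeros((4, 4))), truth)
        assert not res.binary_mask.any()
        assert res.dsc == 0.0
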