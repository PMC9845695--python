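"""Architecture contracts: encoder/decoder shapes, channel attention,
point selection and the refinement override."""

import numpy as np
import pytest

from cropseg import autodiff as ad
from cropseg import losses, nn
from cropseg.autodiff import Tensor
from cropseg.model import (CP_PIXEL_FRACTION, ECA, MLP, CropSegNet, DoubleConv,
                           NetConfig, effective_k, point_difficulty,
                           sample_point_features, select_topk)


class TestPReLU:
    @pytest.mark.parametrize("x,slope,expected", [
        (3.0, 0.25, 3.0),        # positive branch passes through
        (-2.0, 0.25, -0.5),      # negative branch scaled by the slope
        (-5.0, 0.0, 0.0),        # zero slope reduces to ReLU
    ])
    def test_scalar_values(self, x, slope, expected):
        out = ad.prelu(Tensor(np.full((1, 1), x)), Tensor(np.array([slope])))
        assert out.data[0, 0] == pytest.approx(expected)

    def test_slope_is_learnable_per_channel(self):
        layer = nn.PReLU(3, init=0.25)
        assert layer.slope.data.shape == (3,)
        assert layer.slope.requires_grad
        np.testing.assert_allclose(layer.slope.data, 0.25)


class TestDoubleConv:
    def test_shape_contract(self):
        rng = np.random.default_rng(0)
        block = DoubleConv(4, 64, "prelu", 0.25, rng)
        out = block(Tensor(rng.normal(size=(1, 4, 64, 64)).astype(np.float32)))
        assert out.shape == (1, 64, 64, 64)

    def test_zero_weights_give_zero_output_in_eval(self):
        rng = np.random.default_rng(0)
        block = DoubleConv(2, 8, "relu", 0.25, rng)
        for p in block.parameters():
            p.data[...] = 0.0
        block.eval()  # identity BN statistics
        out = block(Tensor(np.ones((1, 2, 8, 8), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_parameter_count_4_to_64(self):
        rng = np.random.default_rng(0)
        block = DoubleConv(4, 64, "relu", 0.25, rng)
        expected = (4 * 9 * 64 + 64) + 2 * 64 + (64 * 9 * 64 + 64) + 2 * 64
        assert sum(p.data.size for p in block.parameters()) == expected


class TestEncoder:
    def test_halving_doubling_rule_small_width(self):
        net = CropSegNet(NetConfig.scaled(8), seed=0)
        x = np.zeros((1, 4, 64, 64), dtype=np.float32)
        levels, attended = net.encode(Tensor(x))
        assert [l.shape for l in levels] == [
            (1, 8, 64, 64), (1, 16, 32, 32), (1, 32, 16, 16),
            (1, 64, 8, 8), (1, 128, 4, 4)]
        for lev, att in zip(levels[:4], attended):
            assert att.shape == lev.shape  # attention keeps channel count

    def test_indivisible_input_raises(self):
        net = CropSegNet(NetConfig.scaled(8), seed=0)
        with pytest.raises(ValueError, match="divisible by 16"):
            net.encode(Tensor(np.zeros((1, 4, 60, 64), dtype=np.float32)))

    def test_shape_conservation_rectangular(self):
        net = CropSegNet(NetConfig.scaled(8, cp_enabled=False), seed=0)
        pred = net.forward(np.zeros((1, 4, 32, 48), dtype=np.float32))
        assert pred.master_logits.shape == (1, 4, 32, 48)


class TestECA:
    def test_zero_input_gives_zero_output(self):
        eca = ECA(3)
        out = eca(Tensor(np.zeros((1, 4, 5, 5), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_hand_convolution_example(self):
        # channel means (1,2,3,4), kernel (0.25,0.5,0.25), zero-padded centred
        # correlation -> (0.5*1+0.25*2, 1*0.25+2*0.5+3*0.25, 2*0.25+3*0.5+4*0.25,
        # 3*0.25+4*0.5) = (1.0, 2.0, 3.0, 2.75); weights = sigmoid of that
        eca = ECA(3)
        eca.weight.data = np.array([0.25, 0.5, 0.25], dtype=np.float32)
        x = np.zeros((1, 4, 2, 2), dtype=np.float32)
        for c in range(4):
            x[0, c] = c + 1.0
        out = eca(Tensor(x)).data
        expected_w = 1.0 / (1.0 + np.exp(-np.array([1.0, 2.0, 3.0, 2.75])))
        for c in range(4):
            np.testing.assert_allclose(out[0, c], (c + 1.0) * expected_w[c],
                                       rtol=1e-6)

    def test_contraction_per_channel(self, rng):
        eca = ECA(3, rng=rng)
        x = rng.normal(size=(2, 8, 6, 6)).astype(np.float32)
        out = eca(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)


class TestPointDifficulty:
    def test_one_hot_is_easiest(self):
        scores = np.zeros((4, 1, 1))
        scores[0] = 1.0
        assert point_difficulty(scores)[0, 0] == pytest.approx(1.0)

    def test_uniform_is_hardest(self):
        scores = np.full((4, 1, 1), 0.25)
        assert point_difficulty(scores)[0, 0] == pytest.approx(0.0)

    def test_matches_full_sort_oracle(self, rng):
        raw = rng.uniform(size=(4, 8, 8))
        scores = raw / raw.sum(axis=0)
        margins = point_difficulty(scores)
        for r in range(8):
            for c in range(8):
                srt = np.sort(scores[:, r, c])
                assert margins[r, c] == pytest.approx(srt[-1] - srt[-2])

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="2 classes"):
            point_difficulty(np.ones((1, 4, 4)))


class TestSelectTopk:
    def test_saturation_selects_all_valid(self, rng):
        margins = rng.uniform(size=(4, 4))
        valid = rng.uniform(size=(4, 4)) > 0.5
        idx = select_topk(margins, valid, k=100)
        assert set(idx.tolist()) == set(np.flatnonzero(valid.ravel()).tolist())

    def test_patch_fraction_at_default_k(self):
        idx = select_topk(np.random.default_rng(0).uniform(size=(256, 256)),
                          None, k=8096)
        assert len(idx) == 8096
        assert 100 * len(idx) / 256**2 == pytest.approx(12.35, abs=0.01)

    def test_matches_bruteforce_sort(self, rng):
        margins = rng.uniform(size=(16, 16))
        valid = rng.uniform(size=(16, 16)) > 0.3
        idx = select_topk(margins, valid, k=40)
        flat = margins.ravel().copy()
        flat[~valid.ravel()] = np.inf
        expected = np.argsort(flat, kind="stable")[:min(40, valid.sum())]
        np.testing.assert_array_equal(np.sort(idx), np.sort(expected))

    def test_ties_break_by_ascending_flat_index(self):
        margins = np.zeros((3, 3))
        idx = select_topk(margins, None, k=4)
        np.testing.assert_array_equal(idx, [0, 1, 2, 3])

    def test_masked_pixels_never_selected(self, rng):
        margins = np.zeros((8, 8))  # everything maximally hard
        valid = np.zeros((8, 8), dtype=bool)
        valid[0, :3] = True
        idx = select_topk(margins, valid, k=64)
        assert set(idx.tolist()) == {0, 1, 2}

    def test_no_valid_pixels_raises(self):
        with pytest.raises(ValueError, match="no valid"):
            select_topk(np.zeros((2, 2)), np.zeros((2, 2), dtype=bool), 1)

    def test_effective_k_keeps_pixel_fraction(self):
        cfg = NetConfig()
        assert effective_k(cfg, 256, 256) == 8096
        assert effective_k(cfg, 64, 64) == round(CP_PIXEL_FRACTION * 64 * 64)


class TestSamplePointFeatures:
    def test_constant_map_samples_constant(self):
        fmap = np.full((1, 5, 4, 4), 3.25)
        out = sample_point_features(Tensor(fmap), np.array([[0, 7, 63]]), (8, 8))
        np.testing.assert_allclose(out.data, 3.25, rtol=1e-6)

    def test_corner_value_under_pixel_centre_convention(self):
        fmap = np.array([[[[1.0, 2.0], [3.0, 4.0]]]])
        out = sample_point_features(Tensor(fmap), np.array([[0, 15]]), (4, 4))
        assert out.data[0, 0, 0] == pytest.approx(1.0)
        assert out.data[0, 1, 0] == pytest.approx(4.0)

    def test_channel_dimension_contract(self, rng):
        fmap = rng.normal(size=(2, 128, 4, 4))
        out = sample_point_features(Tensor(fmap), np.array([[0, 1], [2, 3]]), (8, 8))
        assert out.shape == (2, 2, 128)

    def test_out_of_range_index_raises(self):
        with pytest.raises(IndexError):
            sample_point_features(Tensor(np.zeros((1, 2, 2, 2))),
                                  np.array([[99]]), (4, 4))


class TestCPHead:
    def test_zero_weights_bias_broadcasts(self):
        rng = np.random.default_rng(0)
        head = MLP(10, (8,), 4, "relu", 0.25, rng)
        for p in head.parameters():
            p.data[...] = 0.0
        head.out.bias.data[...] = [1.0, 2.0, 3.0, 4.0]
        out = head(Tensor(np.random.default_rng(1).normal(size=(6, 10))))
        np.testing.assert_allclose(out.data, np.tile([1, 2, 3, 4], (6, 1)))

    def test_pointwise_permutation_equivariance(self, rng):
        head = MLP(12, (16, 16), 4, "prelu", 0.25, np.random.default_rng(3))
        x = rng.normal(size=(9, 12))
        perm = rng.permutation(9)
        out = head(Tensor(x)).data
        out_perm = head(Tensor(x[perm])).data
        np.testing.assert_allclose(out_perm, out[perm], rtol=1e-5)

    def test_parameter_count_default_geometry(self):
        head = MLP(132, (256, 256), 4, "relu", 0.25, np.random.default_rng(0))
        expected = (132 * 256 + 256) + (256 * 256 + 256) + (256 * 4 + 4)
        assert sum(p.data.size for p in head.parameters()) == expected


@pytest.fixture(scope="module")
def small_net_input():
    rng = np.random.default_rng(5)
    return rng.normal(size=(2, 4, 32, 32)).astype(np.float32)


class TestForward:
    def test_baseline_reduction_without_cp(self, small_net_input):
        net = CropSegNet(NetConfig.scaled(8, cp_enabled=False), seed=1)
        net.eval()
        pred = net.forward(small_net_input)
        assert pred.selection is None and pred.cp_logits is None
        np.testing.assert_array_equal(pred.label_map,
                                      pred.master_probs.argmax(axis=1))

    def test_override_touches_only_selected_indices(self, small_net_input):
        net = CropSegNet(NetConfig.scaled(8, cp_enabled=True), seed=1)
        net.eval()
        pred = net.forward(small_net_input)
        master = pred.master_probs.argmax(axis=1)
        diff = (pred.label_map != master).reshape(2, -1)
        for i in range(2):
            changed = set(np.flatnonzero(diff[i]).tolist())
            assert changed <= set(pred.selection.indices[i].tolist())

    def test_eval_forward_is_deterministic(self, small_net_input):
        net = CropSegNet(NetConfig.scaled(8), seed=2)
        net.eval()
        a = net.forward(small_net_input)
        b = net.forward(small_net_input)
        np.testing.assert_array_equal(a.label_map, b.label_map)
        np.testing.assert_array_equal(a.master_logits, b.master_logits)

    def test_selection_margins_sorted_and_unique(self, small_net_input):
        net = CropSegNet(NetConfig.scaled(8), seed=3)
        net.eval()
        sel = net.forward(small_net_input).selection
        for i in range(2):
            assert len(set(sel.indices[i].tolist())) == sel.indices.shape[1]
            assert np.all(np.diff(sel.margins[i]) >= -1e-7)
            assert np.all(sel.margins[i] >= 0)


def test_baseline_parameter_census_matches_plain_unet():
    """ReLU, no attention, no point branch: the census is exactly a bilinear
    U-Net with doubling encoder and (8w,4w,2w,w) decoder double-convs."""
    w = 8
    net = CropSegNet(NetConfig.scaled(w, activation="relu", eca_levels=0,
                                      cp_enabled=False), seed=0)

    def dc(cin, cout):
        return (cin * 9 * cout + cout) + 2 * cout + (cout * 9 * cout + cout) + 2 * cout

    ch = [w, 2 * w, 4 * w, 8 * w, 16 * w]
    expected = dc(4, ch[0])
    for i in range(4):
        expected += dc(ch[i], ch[i + 1])          # encoder downs
    for i in range(4):
        expected += dc(ch[4 - i] + ch[3 - i], ch[3 - i])   # decoder ups
    expected += ch[0] * 4 + 4                      # 1x1 classifier
    assert net.parameter_count() == expected


def test_gradient_flow_reaches_every_parameter():
    """One optimization step leaves no trainable tensor without gradient."""
    net = CropSegNet(NetConfig.scaled(8), seed=4)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 4, 32, 32)).astype(np.float32)
    y = rng.integers(0, 4, size=(2, 32, 32)).astype(np.uint8)
    pred = net.forward(x, valid=np.ones_like(y, dtype=bool))
    pl = np.take_along_axis(y.reshape(2, -1), pred.selection.indices, axis=1)
    loss = losses.total_loss(pred.probs_t, y, pred.cp_logits_t, pl,
                             losses.LossConfig(ce_weight=1.0, dice_weight=1.0))
    loss.backward()
    missing = [name for name, p in net.named_parameters()
               if p.grad is None or not np.any(p.grad != 0)]
    assert missing == []
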