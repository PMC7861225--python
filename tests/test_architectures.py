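import numpy as np
import pytest

from bravenet.architectures import (
    ArchitectureConfig,
    build_network,
    count_trainable_parameters,
    downsample_context,
    load_network,
    save_network,
)
from bravenet.autodiff import Tensor


def closed_form_count(variant, levels=4, base=32):
    """Independent layer-by-layer parameter sum:
    27*c_in*c_out + c_out per 3x3x3 conv, c_in*c_out + c_out per 1x1x1
    conv, 2*c per batch-norm."""
    conv = lambda ci, co, k=27: k * ci * co + co
    bn = lambda c: 2 * c

    def encoder():
        total = bn(1)  # initial input BN
        ci = 1
        for lvl in range(levels - 1):
            w = base * 2 ** lvl
            total += conv(ci, w) + bn(w) + conv(w, w) + bn(w)
            ci = w
        w = base * 2 ** (levels - 1)
        total += conv(ci, w) + bn(w) + conv(w, w) + bn(w)
        return total

    bottom = base * 2 ** (levels - 1)
    has_context = variant in ("context", "bravenet")
    has_ds = variant in ("ds", "bravenet")
    paths = 2 if has_context else 1
    total = paths * encoder()
    total += conv(bottom * paths, bottom, 1) + conv(bottom, bottom, 1)
    up_in = bottom
    for lvl in range(levels - 2, -1, -1):
        w = base * 2 ** lvl
        ci = up_in + paths * w
        total += conv(ci, w) + bn(w) + conv(w, w) + bn(w)
        up_in = w
        if has_ds and lvl > 0:
            total += conv(w, 1, 1)
    total += conv(base, 1, 1)
    return total


class TestParameterCounts:
    @pytest.mark.parametrize("variant", ["unet", "ds", "context", "bravenet"])
    def test_count_matches_closed_form(self, variant):
        net = build_network(ArchitectureConfig(variant=variant), seed=0)
        assert count_trainable_parameters(net) == closed_form_count(variant)

    def test_rounds_to_printed_millions(self):
        unet = build_network(ArchitectureConfig(variant="unet"), seed=0)
        brave = build_network(ArchitectureConfig(variant="bravenet"), seed=0)
        assert round(count_trainable_parameters(unet) / 1e6) == 6
        assert round(count_trainable_parameters(brave) / 1e6) == 10

    def test_variant_ordering_and_head_increment(self):
        counts = {
            v: count_trainable_parameters(
                build_network(ArchitectureConfig(variant=v), seed=0)
            )
            for v in ("unet", "ds", "context", "bravenet")
        }
        assert (counts["unet"] < counts["ds"] < counts["context"]
                < counts["bravenet"])
        # ds adds exactly the two intermediate 1x1x1 heads
        head_params = (128 * 1 + 1) + (64 * 1 + 1)
        assert counts["ds"] - counts["unet"] == head_params
        assert counts["bravenet"] - counts["context"] == head_params

    def test_quadratic_width_scaling(self):
        big = count_trainable_parameters(
            build_network(ArchitectureConfig(variant="bravenet"), seed=0)
        )
        small = count_trainable_parameters(
            build_network(
                ArchitectureConfig(variant="bravenet", base_width=8), seed=0
            )
        )
        assert 13 < big / small < 17


class TestForward:
    @pytest.mark.parametrize("variant", ["unet", "ds", "context", "bravenet"])
    def test_heads_have_label_shape_and_unit_range(self, variant):
        cfg = ArchitectureConfig(variant=variant, base_width=4)
        net = build_network(cfg, seed=0)
        p = Tensor(np.zeros((1, 1, 64, 64, 8), dtype=np.float32))
        c = (Tensor(np.zeros((1, 1, 128, 128, 16), dtype=np.float32))
             if cfg.has_context else None)
        heads = net.forward(p, c, train=False)
        expected_heads = 3 if cfg.has_deep_supervision else 1
        assert len(heads) == expected_heads
        for h in heads:
            assert h.shape == (1, 1, 64, 64, 8)
            assert (h.data > 0).all() and (h.data < 1).all()

    def test_seeded_twins_are_parameter_identical(self):
        cfg = ArchitectureConfig(variant="context", base_width=4)
        a = build_network(cfg, seed=42)
        b = build_network(cfg, seed=42)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_context_encoder_parameter_disjoint(self, rng):
        cfg = ArchitectureConfig(variant="bravenet", base_width=2,
                                 primary_patch=(16, 16, 8))
        net = build_network(cfg, seed=0)
        p_names = {k for k in net.params if k.startswith("p_")}
        c_names = {k for k in net.params if k.startswith("c_")}
        assert p_names and c_names and not (p_names & c_names)
        # perturbing a primary-encoder weight leaves context weights alone
        before = {k: net.params[k].data.copy() for k in c_names}
        net.params["p_enc0_conv1_w"].data += 1.0
        for k in c_names:
            np.testing.assert_array_equal(net.params[k].data, before[k])

    def test_missing_context_patch_rejected(self):
        cfg = ArchitectureConfig(variant="context", base_width=2,
                                 primary_patch=(16, 16, 8))
        net = build_network(cfg, seed=0)
        with pytest.raises(ValueError, match="context"):
            net.forward(Tensor(np.zeros((1, 1, 16, 16, 8))), None)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureConfig(variant="unet", primary_patch=(60, 64, 8))
        with pytest.raises(ValueError, match="divisible"):
            ArchitectureConfig(variant="unet", primary_patch=(64, 64, 4))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = ArchitectureConfig(variant="bravenet", base_width=2,
                                 primary_patch=(16, 16, 8))
        net = build_network(cfg, seed=5)
        p = rng.random((2, 16, 16, 8)).astype(np.float32)
        c = rng.random((2, 32, 32, 16)).astype(np.float32)
        out = net.predict_patches(p, c)
        path = tmp_path / "ckpt.npz"
        save_network(net, path)
        back = load_network(path)
        np.testing.assert_array_equal(back.predict_patches(p, c), out)


class TestDownsampleContext:
    def test_constant_patch_preserved(self):
        patch = np.full((8, 8, 4), 3.5)
        np.testing.assert_array_equal(downsample_context(patch),
                                      np.full((4, 4, 2), 3.5))

    def test_single_block_mean(self):
        patch = np.zeros((4, 4, 4))
        patch[1, 1, 1] = 8.0  # one entry of the (0,0,0) block
        assert downsample_context(patch)[0, 0, 0] == 1.0

    def test_matches_brute_force_block_mean(self, rng):
        patch = rng.normal(size=(8, 6, 4))
        out = downsample_context(patch)
        for i in range(4):
            for j in range(3):
                for k in range(2):
                    block = patch[2*i:2*i+2, 2*j:2*j+2, 2*k:2*k+2]
                    assert np.isclose(out[i, j, k], block.mean())

    def test_ramp_doubles_spacing(self):
        x = np.arange(8, dtype=float)[:, None, None] * np.ones((8, 4, 4))
        out = downsample_context(x)
        np.testing.assert_allclose(out[:, 0, 0], [0.5, 2.5, 4.5, 6.5])

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            downsample_context(np.zeros((5, 4, 4)))
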