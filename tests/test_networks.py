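"""Architecture contracts, backprop correctness, patch extraction and the
training loop."""

import numpy as np
import pytest

from sinomar.nn import (
    Adam,
    NetConfig,
    PatchSet,
    TrainConfig,
    build_modified_resunet,
    build_modified_unet,
    desk_preset,
    extract_patches,
    load_model,
    paper_preset,
    save_model,
    train_model,
)
from sinomar.nn.layers import Conv2d


def _builders():
    return [
        ("modified_unet", build_modified_unet, 32),
        ("modified_resunet", build_modified_resunet, 24),
    ]


class TestArchitectures:
    @pytest.mark.parametrize("kind,builder,patch", _builders())
    def test_shape_preserving(self, kind, builder, patch):
        cfg = NetConfig(kind=kind, depth=2, base_channels=4, patch_size=patch)
        model = builder(cfg, seed=0)
        for size in (patch, 2 * patch):
            x = np.random.default_rng(0).normal(size=(2, 1, size, size)).astype(np.float32)
            assert model.forward(x).shape == x.shape

    @pytest.mark.parametrize("kind,builder,patch", _builders())
    def test_zero_weights_act_as_identity(self, kind, builder, patch):
        cfg = NetConfig(kind=kind, depth=2, base_channels=4, patch_size=patch)
        model = builder(cfg, seed=0)
        for p in model.params():
            p.value[...] = 0.0
        x = np.random.default_rng(1).normal(size=(3, 1, patch, patch)).astype(np.float32)
        assert np.array_equal(model.forward(x), x)

    def test_strided_conv_halves_spatial_size(self):
        conv = Conv2d(1, 8, kernel_size=2, stride=2, pad=0)
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        assert conv.forward(x).shape == (1, 8, 32, 32)

    @pytest.mark.parametrize("kind,builder,patch", _builders())
    def test_forward_deterministic(self, kind, builder, patch):
        cfg = NetConfig(kind=kind, depth=2, base_channels=4, patch_size=patch)
        model = builder(cfg, seed=5)
        x = np.random.default_rng(2).normal(size=(1, 1, patch, patch)).astype(np.float32)
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_patch_size_depth_divisibility_enforced(self):
        with pytest.raises(ValueError):
            NetConfig(kind="modified_unet", depth=3, patch_size=36)

    def test_parameter_count_scales_with_width(self):
        """Doubling base_channels roughly quadruples convolution parameters."""
        small = build_modified_resunet(
            NetConfig(kind="modified_resunet", depth=2, base_channels=8, patch_size=24)
        )
        big = build_modified_resunet(
            NetConfig(kind="modified_resunet", depth=2, base_channels=16, patch_size=24)
        )
        ratio = big.n_parameters / small.n_parameters
        assert 3.2 < ratio < 4.2

    @pytest.mark.parametrize("kind,builder,patch", _builders())
    def test_backprop_matches_numerical_gradient(self, kind, builder, patch):
        """Analytic parameter gradients agree with central differences on a
        tiny float64 network (the independent oracle for the backward pass)."""
        cfg = NetConfig(kind=kind, depth=1, base_channels=2, patch_size=4)
        model = builder(cfg, seed=3, dtype=np.float64)
        rng = np.random.default_rng(4)
        x = rng.normal(size=(1, 1, 4, 4))
        tgt = rng.normal(size=(1, 1, 4, 4))

        def loss():
            d = model.forward(x) - tgt
            return 0.5 * np.sum(d * d)

        model.zero_grad()
        model.backward(model.forward(x) - tgt)
        for p in model.params():
            flat = p.value.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert np.isclose(num, p.grad.reshape(-1)[idx], rtol=1e-5, atol=1e-8)


class TestExtractPatches:
    def _pairs(self, rng, n=2, size=40):
        return [(rng.random((size, size)), rng.random((size, size))) for _ in range(n)]

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(0)
        pairs = self._pairs(rng)
        a = extract_patches(pairs, 16, 20, sampling_weights="uniform", seed=12)
        b = extract_patches(pairs, 16, 20, sampling_weights="uniform", seed=12)
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.targets, b.targets)

    def test_concentrated_weights_hit_one_region(self):
        """When input and target differ only in one corner, artifact-energy
        sampling draws every patch overlapping that corner."""
        inp = np.zeros((64, 64))
        tgt = np.zeros((64, 64))
        tgt[:8, :8] = 5.0
        ps = extract_patches([(inp, tgt)], 16, 30, sampling_weights="artifact", seed=1)
        assert np.all(np.abs(ps.targets).sum(axis=(1, 2, 3)) > 0)

    def test_artifact_weighting_emphasizes_error_regions(self):
        rng = np.random.default_rng(7)
        inp = rng.random((80, 80))
        tgt = inp.copy()
        tgt[20:50, 20:50] += rng.random((30, 30)) * 2  # artifact hotspot
        art = extract_patches([(inp, tgt)], 16, 200, sampling_weights="artifact", seed=3)
        uni = extract_patches([(inp, tgt)], 16, 200, sampling_weights="uniform", seed=3)
        err = lambda ps: np.mean(np.abs(ps.inputs - ps.targets))
        assert err(art) >= err(uni)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            extract_patches([(np.zeros((20, 20)), np.zeros((20, 20)))], 8, 0)


class TestTraining:
    def test_reference_presets(self):
        u = paper_preset("modified_unet")
        assert (u.n_train_patches, u.n_val_patches, u.epochs, u.learning_rate) == (
            180_000, 18_000, 100, 1e-5)
        r = paper_preset("modified_resunet")
        assert (r.n_train_patches, r.n_val_patches, r.epochs, r.learning_rate) == (
            458_640, 80_000, 1300, 1e-3)
        assert u.optimizer == "adam" and u.loss == "rmse"

    def _toy_patchset(self, rng, n=120, p=8, identity=False):
        tgt = rng.random((n, 1, p, p))
        inp = tgt.copy() if identity else tgt + rng.normal(0, 0.3, tgt.shape)
        return PatchSet(inp, tgt)

    def test_loss_decreases_on_learnable_task(self):
        rng = np.random.default_rng(0)
        ps = self._toy_patchset(rng, identity=True)
        cfg = NetConfig(kind="modified_unet", depth=1, base_channels=4, patch_size=8)
        model = build_modified_unet(cfg, seed=0)
        # perturb away from the identity so there is something to learn
        prng = np.random.default_rng(1)
        for p in model.params():
            p.value[...] = prng.normal(0, 0.1, p.value.shape)
        state = train_model(model, ps, TrainConfig(100, 20, epochs=8, seed=0))
        assert len(state.train_loss) == 8 == len(state.val_loss)
        assert state.train_loss[-1] < state.train_loss[0]
        assert state.best_val_loss <= state.initial_val_loss

    def test_training_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        ps = self._toy_patchset(rng)
        cfg = NetConfig(kind="modified_unet", depth=1, base_channels=2, patch_size=8)
        weights = []
        for _ in range(2):
            model = build_modified_unet(cfg, seed=2)
            train_model(model, ps, TrainConfig(100, 20, epochs=3, seed=9))
            weights.append([p.value.copy() for p in model.params()])
        for a, b in zip(*weights):
            assert np.array_equal(a, b)

    def test_model_round_trips_through_file(self, tmp_path):
        cfg = NetConfig(kind="modified_resunet", depth=2, base_channels=4, patch_size=24)
        model = build_modified_resunet(cfg, seed=6)
        model.set_normalization(-1.0, 3.0)
        path = tmp_path / "weights.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = np.random.default_rng(3).normal(size=(1, 1, 24, 24)).astype(np.float32)
        assert np.array_equal(loaded.forward(x), model.forward(x))
        assert loaded.norm_lo == -1.0 and loaded.norm_hi == 3.0


class TestAdam:
    def test_converges_on_quadratic(self):
        from sinomar.nn.layers import Param

        p = Param(np.array([5.0, -3.0]), dtype=np.float64)
        opt = Adam([p], lr=0.1)
        for _ in range(500):
            p.zero_grad()
            p.grad += 2 * p.value
            opt.step()
        assert np.abs(p.value).max() < 1e-3
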