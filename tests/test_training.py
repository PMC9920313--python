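
import numpy as np
import pandas as pd
import pytest

from freqcycle.losses import LossWeights
from freqcycle.networks import DiscriminatorSpec, GeneratorSpec
from freqcycle.nn import Tensor
from freqcycle.synthetic import DegradationSpec, PhantomSpec, degrade_to_cbct, make_phantom_ct
from freqcycle.training import (
    ImagePool,
    TrainConfig,
    _VolumeCache,
    blend_weight_map,
    init_state,
    load_checkpoint,
    lr_schedule,
    sample_scan_pair,
    sample_unpaired_patch_pair,
    sliding_window_apply,
    train,
    train_step,
    translate,
    translate_volume,
)
from freqcycle.volume import Volume3D, clip_and_scale

TINY_CFG = dict(
    patch_size=(4, 16, 16),
    generator=GeneratorSpec(base_filters=2),
    discriminator=DiscriminatorSpec(base_filters=4),
    total_iterations=6,
    checkpoint_every=3,
    image_pool_size=4,
)


@pytest.fixture(scope="module")
def tiny_pools():
    ct, _ = make_phantom_ct(PhantomSpec(shape=(8, 32, 32), spacing=(3.0, 3.0, 3.0), seed=0,
                                        tumor_radius=1.5))
    cbct = degrade_to_cbct(ct, DegradationSpec(seed=1))
    return [cbct], [ct]


class TestLrSchedule:
    def test_flat_first_half(self):
        assert lr_schedule(10_000, 30_000, 0.0004) == 0.0004
        assert lr_schedule(15_000, 30_000, 0.0004) == 0.0004

    def test_linear_decay_midpoint(self):
        assert lr_schedule(22_500, 30_000, 0.0004) == pytest.approx(0.0002)

    def test_zero_at_the_end(self):
        assert lr_schedule(30_000, 30_000, 0.0004) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            lr_schedule(30_001, 30_000, 0.0004)


class TestSampling:
    def test_singleton_pools_always_selected(self, rng):
        cb, ct = sample_scan_pair(["only_cbct"], ["only_ct"], rng)
        assert (cb, ct) == ("only_cbct", "only_ct")

    def test_two_scan_pool_is_uniform(self):
        rng = np.random.default_rng(2024)
        counts = {0: 0, 1: 0}
        for _ in range(10_000):
            cb, _ = sample_scan_pair([0, 1], ["ct"], rng)
            counts[cb] += 1
        # binomial(10000, 1/2): 4 sigma = 200
        assert abs(counts[0] - 5000) <= 200

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            sample_scan_pair([], ["ct"], rng)

    def test_exact_size_scan_yields_full_scan(self, rng):
        ct, _ = make_phantom_ct(PhantomSpec(shape=(8, 32, 32), spacing=(3.0, 3.0, 3.0), seed=3))
        cbct = degrade_to_cbct(ct, DegradationSpec(seed=4))
        cb_patch, ct_patch = sample_unpaired_patch_pair(
            [cbct], [ct], (8, 32, 32), rng)
        assert cb_patch.shape == (8, 32, 32)
        assert ct_patch.shape == (8, 32, 32)
        # single valid position: the whole (masked, normalized) scan
        expected = clip_and_scale(ct, -1000.0, 2000.0, "to_normalized")
        body = ct.data > -300.0
        np.testing.assert_allclose(ct_patch.data[body], expected.data[body], atol=1e-9)

    def test_smaller_scans_are_air_padded(self, rng):
        ct, _ = make_phantom_ct(PhantomSpec(shape=(8, 32, 32), spacing=(3.0, 3.0, 3.0), seed=5))
        cbct = degrade_to_cbct(ct, DegradationSpec(seed=6))
        cb_patch, ct_patch = sample_unpaired_patch_pair([cbct], [ct], (16, 48, 48), rng)
        assert cb_patch.shape == (16, 48, 48)
        assert cb_patch.data[0, 0, 0] == -1.0  # air maps to -1 under the window

    def test_patches_are_normalized(self, tiny_pools, rng):
        cb_patch, ct_patch = sample_unpaired_patch_pair(
            tiny_pools[0], tiny_pools[1], (4, 16, 16), rng)
        for p in (cb_patch, ct_patch):
            assert p.scale_tag == "normalized"
            assert p.data.min() >= -1.0 and p.data.max() <= 1.0


class TestImagePool:
    def test_size_zero_is_passthrough(self, rng):
        pool = ImagePool(0, rng)
        img = np.ones((2, 2))
        assert pool.query(img) is img

    def test_returns_current_or_historical(self):
        pool = ImagePool(2, np.random.default_rng(0))
        a, b = np.zeros((1, 1)), np.ones((1, 1))
        pool.query(a)
        pool.query(b)
        seen = {float(pool.query(np.full((1, 1), float(i)))[0, 0]) for i in range(2, 30)}
        assert len(seen) > 1  # mixes history with fresh fakes


class TestTrainStep:
    def test_smoke_finite_and_all_networks_update(self, tiny_pools, rng):
        cfg = TrainConfig(**TINY_CFG, seed=1)
        state = init_state(cfg)
        before = {tag: net.state_dict() for tag, net in
                  (("G", state.G), ("F", state.F), ("D_A", state.D_A), ("D_B", state.D_B))}
        batch = sample_unpaired_patch_pair(*tiny_pools, cfg.patch_size, state.rng)
        bd = train_step(batch, state)
        assert all(np.isfinite(v) for v in bd.as_dict().values())
        w = cfg.weights
        assert bd.total == pytest.approx(
            bd.adv_G + bd.adv_F + w.lambda_A * bd.cycle_A + w.lambda_B * bd.cycle_B
            + w.lambda_fA * bd.freq_A + w.lambda_fB * bd.freq_B, abs=1e-9)
        for tag, net in (("G", state.G), ("F", state.F), ("D_A", state.D_A), ("D_B", state.D_B)):
            after = net.state_dict()
            changed = any(not np.array_equal(before[tag][k], after[k]) for k in after)
            assert changed, f"no parameter of {tag} changed"

    def test_deterministic_given_seed(self, tiny_pools):
        results = []
        for _ in range(2):
            cfg = TrainConfig(**TINY_CFG, seed=9)
            state = init_state(cfg)
            batch = sample_unpaired_patch_pair(*tiny_pools, cfg.patch_size, state.rng)
            bd = train_step(batch, state)
            results.append(bd.as_dict())
        assert results[0] == results[1]

    def test_baseline_and_frequency_share_nonfreq_terms_at_step_zero(self, tiny_pools):
        """With identical initialization, a zero-frequency-weight run and a
        frequency run must agree on all non-frequency terms of the first step."""
        bds = {}
        for name, w in (("freq", LossWeights()),
                        ("baseline", LossWeights(lambda_fA=0.0, lambda_fB=0.0))):
            cfg = TrainConfig(**TINY_CFG, seed=9, weights=w)
            state = init_state(cfg)
            batch = sample_unpaired_patch_pair(*tiny_pools, cfg.patch_size, state.rng)
            bds[name] = train_step(batch, state).as_dict()
        for key in ("adv_G", "adv_F", "cycle_A", "cycle_B"):
            assert bds["freq"][key] == bds["baseline"][key]
        assert bds["baseline"]["freq_A"] == 0.0
        assert bds["freq"]["freq_A"] > 0.0


class TestTrainLoop:
    def test_short_run_writes_log_and_checkpoint(self, tiny_pools, tmp_path):
        cfg = TrainConfig(**TINY_CFG, seed=2)
        state = train(cfg, tiny_pools[0], tiny_pools[1], tmp_path / "run")
        assert state.iteration == cfg.total_iterations
        assert (tmp_path / "run" / "checkpoint.npz").exists()
        log = pd.read_csv(tmp_path / "run" / "loss_log.csv")
        assert len(log) == cfg.total_iterations
        assert list(log.columns) == ["iteration", "lr", "adv_G", "adv_F",
                                     "cycle_A", "cycle_B", "freq_A", "freq_B", "total"]
        assert np.isfinite(log.total).all()

    def test_resume_continues_bit_identically(self, tiny_pools, tmp_path):
        cfg = TrainConfig(**TINY_CFG, seed=2)
        full = train(cfg, tiny_pools[0], tiny_pools[1], tmp_path / "full")

        # interrupt at iteration 3, then resume under the same schedule horizon
        train(cfg, tiny_pools[0], tiny_pools[1], tmp_path / "half", stop_after=3)
        ckpt = tmp_path / "half" / "checkpoint.npz"
        assert load_checkpoint(ckpt).iteration == 3
        resumed = train(cfg, tiny_pools[0], tiny_pools[1], tmp_path / "resumed",
                        resume_from=ckpt)
        assert resumed.iteration == full.iteration
        for k, v in full.G.state_dict().items():
            np.testing.assert_array_equal(v, resumed.G.state_dict()[k])

    def test_checkpoint_round_trip(self, tiny_pools, tmp_path):
        from freqcycle.training import save_checkpoint
        cfg = TrainConfig(**TINY_CFG, seed=4)
        state = init_state(cfg)
        batch = sample_unpaired_patch_pair(*tiny_pools, cfg.patch_size, state.rng)
        train_step(batch, state)
        save_checkpoint(tmp_path / "ck.npz", state)
        back = load_checkpoint(tmp_path / "ck.npz")
        assert back.iteration == state.iteration
        assert back.config == state.config
        for k, v in state.G.state_dict().items():
            np.testing.assert_array_equal(v, back.G.state_dict()[k])
        assert back.opt_G.t == state.opt_G.t


class TestTrainConfig:
    def test_defaults_follow_published_recipe(self):
        cfg = TrainConfig()
        d = cfg.to_dict()
        assert d["lr_discriminator"] == 0.0002
        assert d["lr_generator"] == 0.0004
        assert d["batch_size"] == 1
        assert d["optimizer_betas"] == [0.5, 0.999]
        assert d["lambda_A"] == 5 and d["lambda_B"] == 5
        assert d["lambda_fA"] == 5 and d["lambda_fB"] == 5
        assert d["patch_size"] == [16, 320, 320]
        assert d["total_iterations"] == 30_000
        assert d["normalization"] == "instance normalization".split()[0]

    def test_dict_round_trip(self):
        cfg = TrainConfig(**TINY_CFG, seed=7)
        assert TrainConfig.from_dict(cfg.to_dict()) == cfg

    def test_invalid_patch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TrainConfig(patch_size=(10, 320, 320))


class TestTranslate:
    def test_blend_weights_partition_of_unity(self):
        wsum, positions = blend_weight_map((10, 20, 20), (4, 8, 8))
        assert (wsum >= 1.0).all()
        # the normalised weight of every covering tile sums to exactly 1
        norm_total = np.zeros((10, 20, 20))
        for (s0, s1, s2) in positions:
            norm_total[s0:s0 + 4, s1:s1 + 8, s2:s2 + 8] += 1.0 / wsum[s0:s0 + 4,
                                                                      s1:s1 + 8, s2:s2 + 8]
        np.testing.assert_allclose(norm_total, 1.0, atol=1e-12)

    def test_identity_stub_round_trips(self, rng):
        data = rng.uniform(-900, 1900, size=(10, 40, 40))
        vol = Volume3D(data, spacing=(1.0, 1.0, 2.0), origin=(3.0, 4.0, 5.0))
        out = translate_volume(vol, network=lambda t: t, patch_size=(4, 16, 16))
        np.testing.assert_allclose(out.data, data, atol=1e-5)
        assert out.spacing == vol.spacing
        assert out.origin == vol.origin
        assert out.scale_tag == "hu"

    def test_sliding_window_constant_function(self, rng):
        data = rng.normal(size=(8, 12, 12))
        out = sliding_window_apply(data, lambda p: np.zeros_like(p), (4, 6, 6))
        np.testing.assert_array_equal(out, 0.0)

    def test_translate_from_checkpoint(self, tiny_pools, tmp_path):
        cfg = TrainConfig(**{**TINY_CFG, "total_iterations": 2, "checkpoint_every": 2}, seed=3)
        train(cfg, tiny_pools[0], tiny_pools[1], tmp_path / "run")
        cbct = tiny_pools[0][0]
        out = translate(cbct, tmp_path / "run" / "checkpoint.npz", "cbct_to_ct",
                        patch_size=(4, 16, 16))
        assert out.shape == cbct.shape
        assert out.scale_tag == "hu"
        assert out.data.min() >= -1000.0 - 1e-6 and out.data.max() <= 2000.0 + 1e-6
        with pytest.raises(ValueError, match="direction"):
            translate(cbct, tmp_path / "run" / "checkpoint.npz", "sideways")
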