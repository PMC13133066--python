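"""Backbone and training loop: determinism, parameter round-trips, gradient
correctness of the primitives, order consumption and the learning invariant."""

import numpy as np
import pytest

from fairseg import nn as fnn
from fairseg.curriculum import order_shuffled
from fairseg.losses import LossSchedule
from fairseg.model import (
    Adam,
    LossSpec,
    MiniUNet,
    ModelDescriptor,
    OptimizerConfig,
    build_model,
    evaluate,
    train_epoch,
)


class TestBuild:
    def test_same_seed_same_parameters(self, tiny_descriptor):
        a = build_model(tiny_descriptor, seed=4)
        b = build_model(tiny_descriptor, seed=4)
        assert np.array_equal(a.flatten(), b.flatten())

    def test_different_seed_different_parameters(self, tiny_descriptor):
        a = build_model(tiny_descriptor, seed=4)
        b = build_model(tiny_descriptor, seed=5)
        assert not np.array_equal(a.flatten(), b.flatten())

    def test_flatten_restore_round_trip(self, tiny_descriptor):
        m = build_model(tiny_descriptor, seed=1)
        vec = m.flatten()
        m.restore(vec * 2.0)
        assert np.allclose(m.flatten(), vec * 2.0)
        with pytest.raises(ValueError):
            m.restore(vec[:-1])

    def test_output_shape(self):
        m = build_model(ModelDescriptor(depth=3, base_channels=8, n_classes=7), seed=0)
        logits = m.forward(m.prepare(np.zeros((2, 96, 96), dtype=np.float32)))
        assert logits.shape == (2, 7, 96, 96)

    def test_descriptor_serialization_round_trip(self):
        d = ModelDescriptor(depth=2, base_channels=4, n_classes=5)
        assert ModelDescriptor.from_json(d.to_json()) == d

    def test_checkpoint_round_trip(self, tmp_path, tiny_descriptor):
        m = build_model(tiny_descriptor, seed=2)
        m.step_counter = 17
        m.save(tmp_path / "ckpt.npz")
        loaded = MiniUNet.load(tmp_path / "ckpt.npz")
        assert loaded.descriptor == m.descriptor
        assert np.array_equal(loaded.flatten(), m.flatten())
        assert loaded.step_counter == 17

    def test_invalid_descriptor_rejected(self):
        with pytest.raises(ValueError):
            ModelDescriptor(n_classes=1)

    def test_indivisible_input_rejected(self, tiny_descriptor):
        m = build_model(tiny_descriptor, seed=0)
        with pytest.raises(ValueError):
            m.forward(m.prepare(np.zeros((1, 31, 31), dtype=np.float32)))


class TestOptimizerConfig:
    def test_explored_ranges_enforced(self):
        with pytest.raises(ValueError):
            OptimizerConfig(lr=0.02)
        with pytest.raises(ValueError):
            OptimizerConfig(lr=5e-5)
        with pytest.raises(ValueError):
            OptimizerConfig(weight_decay=0.01)
        OptimizerConfig(lr=0.0)  # frozen optimizer is allowed
        OptimizerConfig(lr=1e-4, weight_decay=1e-8)
        OptimizerConfig(lr=1e-2, weight_decay=1e-3)


class TestGradients:
    def test_conv_pool_upsample_backward_exact_in_float64(self):
        """Finite differences on a float64 composite net agree with the
        hand-written adjoints to machine precision."""
        rng = np.random.default_rng(1)
        c1, c2, c3 = (
            fnn.Conv2d(2, 3, 3, rng),
            fnn.Conv2d(3, 4, 3, rng),
            fnn.Conv2d(4, 2, 1, rng),
        )
        for c in (c1, c2, c3):
            c.W = c.W.astype(np.float64)
            c.b = c.b.astype(np.float64)
        x = rng.normal(size=(2, 2, 8, 8))
        t = rng.normal(size=(2, 2, 8, 8))

        def forward():
            h, k1 = c1.forward(x)
            r, m1 = fnn.relu(h)
            p, ps = fnn.avgpool2(r)
            h2, k2 = c2.forward(p)
            u, us = fnn.upsample2(h2)
            y, k3 = c3.forward(u)
            return y, (k1, m1, ps, k2, us, k3)

        y, (k1, m1, ps, k2, us, k3) = forward()
        dx3, dW3, db3 = c3.backward(t, k3)
        du = fnn.upsample2_back(dx3, us)
        dx2, dW2, db2 = c2.backward(du, k2)
        dp = fnn.avgpool2_back(dx2, ps)
        dr = fnn.relu_back(dp, m1)
        _, dW1, db1 = c1.backward(dr, k1)

        def loss():
            return float((forward()[0] * t).sum())

        for conv, dW, db in ((c1, dW1, db1), (c2, dW2, db2), (c3, dW3, db3)):
            for attr, g in (("W", dW), ("b", db)):
                arr = getattr(conv, attr)
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                eps = 1e-6
                arr[idx] += eps
                up = loss()
                arr[idx] -= 2 * eps
                down = loss()
                arr[idx] += eps
                assert (up - down) / (2 * eps) == pytest.approx(g[idx], rel=1e-6)

    def test_full_model_directional_derivative(self, tiny_descriptor):
        """Backprop through the full U-Net matches a numeric directional
        derivative (float32 forward, so tolerance is loose)."""
        m = build_model(tiny_descriptor, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((2, tiny_descriptor.in_channels, 16, 16)).astype(np.float32)
        masks = rng.integers(0, tiny_descriptor.n_classes, (2, 16, 16))

        def loss_of(vec):
            m.restore(vec)
            probs = fnn.softmax_channels(m.forward(x).astype(np.float64))
            losses, _ = fnn.cross_entropy_per_sample(probs, masks)
            return losses.mean()

        v0 = m.flatten()
        logits, cache = m.forward(x, need_cache=True)
        probs = fnn.softmax_channels(logits.astype(np.float64))
        _, dce = fnn.cross_entropy_per_sample(probs, masks)
        grads = m.backward(dce / 2, cache)
        flat_g = np.concatenate([grads[k].ravel() for k, _ in m.param_items()])
        d = rng.normal(size=v0.size)
        d /= np.linalg.norm(d)
        eps = 1e-3
        numeric = (loss_of(v0 + eps * d) - loss_of(v0 - eps * d)) / (2 * eps)
        assert numeric == pytest.approx(float(flat_g @ d), rel=0.05, abs=1e-4)


class TestTrainEpoch:
    def _dataset(self, tiny_dataset):
        return {r.sample_id: r for r in tiny_dataset}

    def test_zero_lr_freezes_parameters_but_scores(self, tiny_dataset, tiny_descriptor):
        ds = self._dataset(tiny_dataset)
        m = build_model(tiny_descriptor, seed=0)
        before = m.flatten()
        opt = Adam(m, OptimizerConfig(lr=0.0))
        m, perf, _ = train_epoch(m, ds, sorted(ds), LossSpec("ce"), opt)
        assert np.array_equal(m.flatten(), before)
        assert set(perf.per_sample) == set(ds)

    def test_training_is_deterministic(self, tiny_dataset, tiny_descriptor, tiny_optimizer):
        ds = self._dataset(tiny_dataset)
        finals = []
        for _ in range(2):
            m = build_model(tiny_descriptor, seed=0)
            opt = Adam(m, tiny_optimizer)
            m, _, _ = train_epoch(m, ds, sorted(ds), LossSpec("ce"), opt)
            finals.append(m.flatten())
        assert np.array_equal(finals[0], finals[1])

    def test_order_consumed_verbatim(self, tiny_dataset, tiny_descriptor, tiny_optimizer):
        visits = []

        class SpyDict(dict):
            def __getitem__(self, key):
                visits.append(key)
                return super().__getitem__(key)

        ds = SpyDict(self._dataset(tiny_dataset))
        order = order_shuffled(sorted(ds), 13)
        m = build_model(tiny_descriptor, seed=0)
        opt = Adam(m, tiny_optimizer)
        train_epoch(m, ds, order, LossSpec("ce"), opt)
        # samples are first touched exactly in curriculum order
        first_touch = list(dict.fromkeys(visits))
        assert first_touch[: len(order)] == order

    def test_empty_order_rejected(self, tiny_dataset, tiny_descriptor):
        m = build_model(tiny_descriptor, seed=0)
        with pytest.raises(ValueError):
            train_epoch(m, self._dataset(tiny_dataset), [], LossSpec("ce"))

    def test_progressive_at_zero_weight_equals_ce(
        self, tiny_dataset, tiny_descriptor
    ):
        """One whole-dataset batch at the schedule midpoint (w=0) produces
        bit-identical updates to plain cross-entropy, in both modes."""
        ds = self._dataset(tiny_dataset)
        order = sorted(ds)
        cfg = OptimizerConfig(lr=1e-3, batch_size=len(order))
        finals = {}
        for mode in ("ce", "reweight", "additive"):
            m = build_model(tiny_descriptor, seed=0)
            m.step_counter = 1  # midpoint of a 2-step schedule -> w = 0
            opt = Adam(m, cfg)
            spec = (
                LossSpec("ce")
                if mode == "ce"
                else LossSpec(
                    "tpl",
                    schedule=LossSchedule(alpha=1.0, total_steps=2, variant="tpl", mode=mode),
                    ref_mean_iou=0.5,
                )
            )
            m, _, loss = train_epoch(m, ds, order, spec, opt)
            finals[mode] = (m.flatten(), loss)
        assert np.array_equal(finals["ce"][0], finals["reweight"][0])
        assert np.array_equal(finals["ce"][0], finals["additive"][0])
        assert finals["ce"][1] == pytest.approx(finals["reweight"][1])


class TestEvaluate:
    def test_pure_and_complete(self, tiny_dataset, tiny_descriptor):
        m = build_model(tiny_descriptor, seed=1)
        a = evaluate(m, tiny_dataset)
        b = evaluate(m, tiny_dataset)
        assert a == b
        assert set(a) == {r.sample_id for r in tiny_dataset}
        assert all(0.0 <= v <= 1.0 for v in a.values())

    def test_epoch_performance_mean_is_mean_of_entries(
        self, tiny_dataset, tiny_descriptor, tiny_optimizer
    ):
        ds = {r.sample_id: r for r in tiny_dataset}
        m = build_model(tiny_descriptor, seed=0)
        opt = Adam(m, tiny_optimizer)
        _, perf, _ = train_epoch(m, ds, sorted(ds), LossSpec("ce"), opt)
        assert perf.mean == pytest.approx(np.mean(list(perf.per_sample.values())))

    def test_empty_rejected(self, tiny_descriptor):
        with pytest.raises(ValueError):
            evaluate(build_model(tiny_descriptor, seed=0), [])


def test_mini_unet_learns_the_synthetic_benchmark():
    """Non-degenerate learning: on the packaged benchmark conditions (200
    samples, 96x96, 15 epochs) the mini U-Net exceeds mean train IoU 0.5."""
    import fairseg as fs

    samples = fs.make_benchmark_dataset(n_samples=200, seed=11)
    train = [r for r in samples if r.split == "train"]
    ds = {r.sample_id: r for r in train}
    m = build_model(ModelDescriptor(), seed=11)
    opt = Adam(m, OptimizerConfig(lr=3e-3))
    perf = None
    for epoch in range(1, 16):
        order = order_shuffled(sorted(ds), 1000 + epoch)
        m, perf, _ = train_epoch(m, ds, order, LossSpec("ce"), opt, epoch=epoch)
    assert perf.mean > 0.5
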