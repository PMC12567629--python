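"""Metrics, corruption, interpolation curves and clustering diagnostics."""
import numpy as np
import pytest

from irkd.distillation import DistillConfig, TrainConfig, train
from irkd.evaluation import (
    CORRUPTION_LEVELS,
    CorruptionSpec,
    alpha_sweep,
    corrupt,
    evaluate,
    parametric_curve,
    v_score,
)
from irkd.models import WRNConfig, build_wrn, load_state_dict
from irkd.synthetic import LabeledWindowSet


class _StubNet:
    """Minimal forward-only predictor for metric tests."""

    def __init__(self, predict_fn, n_classes):
        self.predict_fn = predict_fn
        self.cfg = type("C", (), {"n_classes": n_classes})

    def forward(self, x, train=False):
        return self.predict_fn(np.asarray(x))


def _onehot(labels, k):
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


class TestEvaluate:
    def test_perfect_predictor(self, rng):
        labels = rng.integers(0, 3, 30)
        windows = labels[:, None, None] * np.ones((30, 1, 4))
        net = _StubNet(lambda x: _onehot(x[:, 0, 0].astype(int), 3), 3)
        rep = evaluate(net, windows, labels)
        assert rep.accuracy == 100.0
        assert rep.macro_f1 == 1.0
        assert np.all(rep.confusion == np.diag(np.bincount(labels, minlength=3)))
        assert np.allclose(rep.per_class_recall, 1.0)

    def test_constant_predictor_on_balanced_binary(self):
        labels = np.array([0] * 10 + [1] * 10)
        net = _StubNet(lambda x: _onehot(np.zeros(len(x), dtype=int), 2), 2)
        rep = evaluate(net, np.zeros((20, 1, 4)), labels)
        assert rep.accuracy == 50.0
        assert rep.macro_f1 == pytest.approx(1 / 3)

    def test_confusion_rows_sum_to_class_counts(self, rng):
        labels = rng.integers(0, 4, 50)
        net = _StubNet(lambda x: rng.standard_normal((len(x), 4)), 4)
        rep = evaluate(net, np.zeros((50, 1, 4)), labels)
        assert np.array_equal(rep.confusion.sum(axis=1), np.bincount(labels, minlength=4))

    def test_order_invariance(self, rng):
        labels = rng.integers(0, 3, 40)
        windows = rng.standard_normal((40, 2, 8)).astype(np.float32)
        net = _StubNet(lambda x: x[:, 0, :3], 3)
        a = evaluate(net, windows, labels)
        perm = rng.permutation(40)
        b = evaluate(net, windows[perm], labels[perm])
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_empty_test_set_rejected(self):
        net = _StubNet(lambda x: x, 2)
        with pytest.raises(ValueError):
            evaluate(net, np.zeros((0, 1, 4)), np.zeros(0, dtype=int))


class TestCorrupt:
    def test_level_presets(self):
        assert CORRUPTION_LEVELS["level1"] == CorruptionSpec(0.15, 0.06, "level1")
        assert CORRUPTION_LEVELS["level2"] == CorruptionSpec(0.22, 0.09, "level2")
        assert CORRUPTION_LEVELS["level3"] == CorruptionSpec(0.30, 0.12, "level3")

    @pytest.mark.parametrize("level,zeros", [("level1", 75), ("level2", 110), ("level3", 150)])
    def test_zeroed_step_counts_on_t500(self, level, zeros):
        windows = np.ones((10, 3, 500), dtype=np.float32)
        spec = CorruptionSpec(CORRUPTION_LEVELS[level].missing_fraction, 0.0)
        out = corrupt(windows, spec, seed=0)
        for w in out:
            idx = np.where(w[0] == 0.0)[0]
            assert len(idx) == zeros
            assert np.array_equal(idx, np.arange(idx[0], idx[0] + zeros))  # contiguous
            assert np.array_equal(w[0] == 0, w[1] == 0)  # all channels share the gap

    def test_identity_when_disabled(self, rng):
        w = rng.standard_normal((5, 2, 100)).astype(np.float32)
        assert np.array_equal(corrupt(w, CorruptionSpec(0.0, 0.0), 3), w)

    def test_noise_sd_recovered_outside_gap(self, rng):
        """Sample SD of corrupted-minus-clean in the intact region matches
        the configured noise SD within 5% over 100 windows."""
        s = 0.09
        w = rng.standard_normal((100, 1, 500)).astype(np.float32)
        out = corrupt(w, CorruptionSpec(0.0, s), seed=1)
        est = (out - w).std()
        assert abs(est - s) / s < 0.05

    def test_determinism(self, rng):
        w = rng.standard_normal((4, 2, 200)).astype(np.float32)
        spec = CORRUPTION_LEVELS["level2"]
        assert np.array_equal(corrupt(w, spec, 11), corrupt(w, spec, 11))


def _trained_pair(rng):
    t = np.arange(32) / 8.0
    xs, ys = [], []
    for c, f in enumerate((0.5, 2.0)):
        for _ in range(12):
            xs.append(
                np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))[None, :]
                + 0.05 * rng.standard_normal((1, 32))
            )
            ys.append(c)
    ds = LabeledWindowSet(
        np.stack(xs).astype(np.float32), np.array(ys),
        np.zeros(len(ys), dtype=np.int64), {"n_classes": 2},
    )
    cfg = WRNConfig(16, 1, "1d", 1, 2, 32)
    tcfg = TrainConfig(epochs=3, batch_size=8)
    a = train(cfg, DistillConfig(seed=1), tcfg, ds)
    b = train(cfg, DistillConfig(seed=2), tcfg, ds)
    return cfg, ds, a, b


class TestParametricCurve:
    def test_endpoints_match_direct_evaluation_without_reestimation(self, rng):
        cfg, ds, a, b = _trained_pair(rng)
        rows = parametric_curve(
            a, b, cfg, ds, ds, etas=(0.0, 1.0), reestimate_bn=False
        )
        net_a = load_state_dict(build_wrn(cfg, 0), a.final_state)
        net_b = load_state_dict(build_wrn(cfg, 0), b.final_state)
        assert rows[0]["test_acc"] == evaluate(net_a, ds.windows, ds.labels).accuracy
        assert rows[1]["test_acc"] == evaluate(net_b, ds.windows, ds.labels).accuracy

    def test_identical_checkpoints_give_flat_curve(self, rng):
        cfg, ds, a, _ = _trained_pair(rng)
        rows = parametric_curve(a, a, cfg, ds, ds, etas=(0.0, 0.5, 1.0))
        accs = {r["test_acc"] for r in rows}
        assert len(accs) == 1

    def test_default_grid_has_13_points(self, rng):
        cfg, ds, a, b = _trained_pair(rng)
        rows = parametric_curve(a, b, cfg, ds, ds, reestimate_bn=False)
        assert [r["eta"] for r in rows] == list(np.arange(-1.0, 2.01, 0.25))
        assert len(rows) == 13


class TestVScore:
    def test_separated_blobs_recover_labels(self, rng):
        centers = np.array([[0, 0], [40, 0], [0, 40]])
        labels = np.repeat(np.arange(3), 40)
        feats = centers[labels] + rng.standard_normal((120, 2))
        assert v_score(feats, labels, k=3, seed=0) == pytest.approx(1.0)

    def test_unstructured_features_score_near_zero(self, rng):
        feats = rng.standard_normal((400, 8))
        labels = rng.integers(0, 4, 400)
        assert v_score(feats, labels, k=4, seed=0) < 0.05

    def test_label_permutation_invariance(self, rng):
        centers = np.array([[0, 0], [40, 0], [0, 40]])
        labels = np.repeat(np.arange(3), 30)
        feats = centers[labels] + rng.standard_normal((90, 2))
        permuted = np.array([2, 0, 1])[labels]
        assert v_score(feats, labels, 3, 0) == v_score(feats, permuted, 3, 0)

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            v_score(rng.standard_normal((10, 2)), np.zeros(10), k=1)


class TestAlphaSweep:
    def test_grid_rows_and_single_seed_mean(self):
        grid = (0.1, 0.3, 0.5, 0.7, 0.9)
        rows = alpha_sweep(grid, lambda a, s: 100 * a + s, seeds=(0,))
        assert len(rows) == 5
        assert [r["alpha"] for r in rows] == list(grid)
        assert rows[2]["mean_acc"] == 50.0 and rows[2]["sd"] == 0.0

    def test_rows_independent_of_grid_order(self):
        f = lambda a, s: 10 * a + s
        fwd = alpha_sweep((0.1, 0.9), f, seeds=(0, 1))
        rev = alpha_sweep((0.9, 0.1), f, seeds=(0, 1))
        assert fwd[0] == rev[1] and fwd[1] == rev[0]

    def test_out_of_range_alpha_rejected(self):
        with pytest.raises(ValueError):
            alpha_sweep((1.5,), lambda a, s: 0.0)
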