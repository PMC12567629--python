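"""Evaluation: metrics, corruption robustness, weight-space interpolation
curves and clustering diagnostics.

Corruption model: one contiguous segment of ``round(p * T)`` time steps is
zeroed across all channels at a seeded uniform-random start, then i.i.d.
Gaussian noise of standard deviation ``s`` is added everywhere.  The three
presets (Level 1..3) tighten both screws together; corruptions apply to
test data only, and a fixed corruption seed guarantees every method sees
the identical corrupted test set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix, f1_score, v_measure_score

from .models import (
    WRNConfig,
    build_wrn,
    flatten_params,
    interpolate_params,
    load_params,
    load_state_dict,
)
from .distillation import predict_logits
from .synthetic import LabeledWindowSet

__all__ = [
    "CorruptionSpec",
    "CORRUPTION_LEVELS",
    "EvalReport",
    "evaluate",
    "corrupt",
    "parametric_curve",
    "v_score",
    "alpha_sweep",
]


@dataclass(frozen=True)
class CorruptionSpec:
    """(missing fraction p, noise standard deviation s) with a level tag."""

    missing_fraction: float
    noise_sd: float
    level_name: str = "custom"

    def __post_init__(self):
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


CORRUPTION_LEVELS = {
    "level1": CorruptionSpec(0.15, 0.06, "level1"),
    "level2": CorruptionSpec(0.22, 0.09, "level2"),
    "level3": CorruptionSpec(0.30, 0.12, "level3"),
}


@dataclass
class EvalReport:
    accuracy: float  # percent
    macro_f1: float
    confusion: np.ndarray  # [K x K], rows = true class
    per_class_recall: np.ndarray

    def __repr__(self):
        return (
            f"EvalReport(accuracy={self.accuracy:.2f}%, "
            f"macro_f1={self.macro_f1:.4f}, K={len(self.confusion)})"
        )


def evaluate(net, windows: np.ndarray, labels: np.ndarray, batch_size: int = 256) -> EvalReport:
    """Argmax-of-logits evaluation: accuracy (%), macro-averaged F1,
    confusion matrix and per-class recall."""
    labels = np.asarray(labels)
    if len(windows) == 0:
        raise ValueError("empty test set")
    preds = predict_logits(net, windows, batch_size).argmax(axis=1)
    k = net.cfg.n_classes
    conf = confusion_matrix(labels, preds, labels=np.arange(k))
    acc = 100.0 * np.trace(conf) / conf.sum()
    macro = f1_score(labels, preds, labels=np.arange(k), average="macro", zero_division=0)
    row = conf.sum(axis=1)
    recall = np.divide(np.diag(conf), row, out=np.zeros(k, dtype=float), where=row > 0)
    return EvalReport(float(acc), float(macro), conf, recall)


def corrupt(windows: np.ndarray, spec: CorruptionSpec, seed: int) -> np.ndarray:
    """Apply missing-segment + Gaussian-noise corruption to a batch of
    [N x channels x T] windows; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    out = np.array(windows, dtype=np.float32, copy=True)
    n, _, T = out.shape
    seg = int(round(spec.missing_fraction * T))
    if seg > 0:
        starts = rng.integers(0, T - seg + 1, size=n)
        for i, s0 in enumerate(starts):
            out[i, :, s0 : s0 + seg] = 0.0
    if spec.noise_sd > 0:
        out += rng.normal(0.0, spec.noise_sd, size=out.shape).astype(np.float32)
    return out


def parametric_curve(
    result_a,
    result_b,
    cfg: WRNConfig,
    train_set: LabeledWindowSet,
    test_set: LabeledWindowSet,
    etas=None,
    reestimate_bn: bool = True,
    batch_size: int = 256,
):
    """Accuracy along the line (1 - eta) x_a + eta x_b through weight space.

    ``result_a`` / ``result_b`` are state dicts (or TrainResult-like objects
    with ``final_state``) of two same-architecture checkpoints.  For each
    eta the interpolated weights are loaded and, by default, the
    normalization layers' running statistics are re-estimated with one pass
    over the training inputs (interpolating running statistics linearly is
    meaningless); ``reestimate_bn=False`` restores the endpoint statistics
    from checkpoint a (used for endpoint-exactness checks).

    Returns a list of dicts with keys eta / train_acc / test_acc.
    """
    state_a = getattr(result_a, "final_state", result_a)
    state_b = getattr(result_b, "final_state", result_b)
    if etas is None:
        etas = np.arange(-1.0, 2.0 + 1e-9, 0.25)
    net_a = load_state_dict(build_wrn(cfg, seed=0), state_a)
    net_b = load_state_dict(build_wrn(cfg, seed=0), state_b)
    x_a = flatten_params(net_a)
    x_b = flatten_params(net_b)
    net = load_state_dict(build_wrn(cfg, seed=0), state_a)  # buffers from a
    rows = []
    for eta in np.asarray(etas, dtype=float):
        load_params(net, interpolate_params(x_a, x_b, eta))
        if reestimate_bn:
            batches = [
                train_set.windows[i : i + batch_size]
                for i in range(0, len(train_set), batch_size)
            ]
            net.reestimate_bn(batches)
        elif eta == 1.0:
            load_state_dict(net, state_b)
        elif eta == 0.0:
            load_state_dict(net, state_a)
        tr = evaluate(net, train_set.windows, train_set.labels, batch_size)
        te = evaluate(net, test_set.windows, test_set.labels, batch_size)
        rows.append(
            {"eta": float(eta), "train_acc": tr.accuracy, "test_acc": te.accuracy}
        )
    return rows


def v_score(features: np.ndarray, labels: np.ndarray, k: int, seed: int = 0) -> float:
    """V-measure (harmonic mean of homogeneity and completeness) between
    the true labels and a k-means clustering of the 2-D t-SNE embedding of
    penultimate-layer features."""
    if k < 2:
        raise ValueError("k must be >= 2")
    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    perplexity = min(30.0, max(5.0, (n - 1) / 4))
    emb = TSNE(
        n_components=2, random_state=seed, perplexity=min(perplexity, n - 1), init="pca"
    ).fit_transform(features)
    clusters = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
    return float(v_measure_score(labels, clusters))


def alpha_sweep(
    alphas,
    run_fn,
    seeds=(0,),
):
    """Sensitivity of the multi-teacher objective to the teacher-balance
    weight: runs ``run_fn(alpha, seed) -> accuracy`` per grid point per
    seed and returns rows of (alpha, mean_acc, sd)."""
    rows = []
    for a in alphas:
        if not 0.0 <= a <= 1.0:
            raise ValueError("alpha values must lie in [0, 1]")
        accs = [float(run_fn(a, s)) for s in seeds]
        rows.append(
            {
                "alpha": float(a),
                "mean_acc": float(np.mean(accs)),
                "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            }
        )
    return rows
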