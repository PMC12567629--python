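"""Knowledge-distillation objectives, schedules and training loops.

The student objective combines hard-label cross-entropy with
temperature-softened KL terms from one or two frozen teachers:

    L = (1 - lambda) * L_CE + lambda * L_KD                 (one teacher)
    L = (1 - lambda) * L_CE
        + lambda * [(1 - alpha) * L_KD^T1 + alpha * L_KD^T2] (two teachers)

with ``L_KD = tau^2 KL(softmax(l_T / tau) || softmax(l_S / tau))`` (teacher
as the reference distribution) and mean reduction over the batch.  Teachers
are pre-trained and never updated; their logits are precomputed in
evaluation mode once per dataset.  ``alpha = 0.5`` is the equal-weight
(AVER) configuration.

Annealing initialization: before distillation, an identically-shaped
model is trained from scratch on the raw series with cross-entropy only,
and its weights initialize the student in place of random ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .models import (
    WRNConfig,
    WideResNet,
    build_wrn,
    load_checkpoint,
    load_state_dict,
    state_dict,
)
from .synthetic import LabeledWindowSet

__all__ = [
    "DistillConfig",
    "TrainConfig",
    "TrainResult",
    "softmax",
    "ce_loss",
    "kd_loss",
    "vanilla_kd_objective",
    "multi_teacher_objective",
    "objective_grad",
    "lr_at_epoch",
    "anneal_initialize",
    "train",
    "predict_logits",
]

SCRATCH = "scratch"
KD_SINGLE = "kd_single"
KD_MULTI = "kd_multi"


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (SGD + momentum).

    The learning rate starts at ``lr0``, is multiplied by ``decay_factor``
    once at ``decay_epoch``, and additionally by ``late_factor`` at every
    positive multiple of ``late_every`` (default: a third of the total
    epoch budget)."""

    epochs: int = 200
    batch_size: int = 64
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr0: float = 0.05
    decay_epoch: int = 10
    decay_factor: float = 0.2
    late_factor: float = 0.1
    late_every: int | None = None  # None -> epochs // 3

    def __post_init__(self):
        if min(self.epochs, self.batch_size) < 1 or self.lr0 <= 0:
            raise ValueError("epochs, batch_size and lr0 must be positive")


@dataclass
class DistillConfig:
    """Everything (besides data) that determines a student training run."""

    strategy: str = SCRATCH
    lam: float = 0.7
    tau: float = 4.0
    alpha: float = 0.5
    teacher1: object = None  # WideResNet | checkpoint path | None
    teacher2: object = None
    anneal: bool = False
    anneal_checkpoint: object = None  # state dict | checkpoint path
    seed: int = 0

    def validate(self):
        if self.strategy not in (SCRATCH, KD_SINGLE, KD_MULTI):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        n_teachers = (self.teacher1 is not None) + (self.teacher2 is not None)
        if self.strategy == KD_MULTI and n_teachers != 2:
            raise ValueError("kd_multi requires both teachers")
        if self.strategy == KD_SINGLE and n_teachers != 1:
            raise ValueError("kd_single requires exactly one teacher")
        if self.anneal and self.anneal_checkpoint is None:
            raise ValueError("anneal=True requires anneal_checkpoint")


@dataclass
class TrainResult:
    final_state: dict
    best_state: dict
    best_epoch: int
    history: list  # per-epoch dicts
    config: WRNConfig


# -- losses ----------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def ce_loss(student_logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    logits = np.asarray(student_logits, dtype=float)
    labels = np.asarray(labels)
    B, K = logits.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= K:
        raise ValueError(f"labels must lie in [0, {K})")
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(B), labels].mean())


def kd_loss(teacher_logits: np.ndarray, student_logits: np.ndarray, tau: float) -> float:
    """tau^2-scaled KL(teacher || student) of temperature-softened outputs,
    mean over the batch; zero iff the softened distributions coincide."""
    lt = np.asarray(teacher_logits, dtype=float)
    ls = np.asarray(student_logits, dtype=float)
    if lt.shape != ls.shape:
        raise ValueError(f"shape mismatch {lt.shape} vs {ls.shape}")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    pt = softmax(lt / tau)
    zs = ls / tau
    zs = zs - zs.max(axis=1, keepdims=True)
    log_ps = zs - np.log(np.exp(zs).sum(axis=1, keepdims=True))
    zt = lt / tau
    zt = zt - zt.max(axis=1, keepdims=True)
    log_pt = zt - np.log(np.exp(zt).sum(axis=1, keepdims=True))
    kl = (pt * (log_pt - log_ps)).sum(axis=1)
    return float(tau * tau * kl.mean())


def vanilla_kd_objective(
    student_logits, labels, teacher_logits, lam: float, tau: float
) -> float:
    """(1 - lambda) CE + lambda KD."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    return (1.0 - lam) * ce_loss(student_logits, labels) + lam * kd_loss(
        teacher_logits, student_logits, tau
    )


def multi_teacher_objective(
    student_logits, labels, teacher1_logits, teacher2_logits,
    lam: float, alpha: float, tau: float,
) -> float:
    """(1 - lambda) CE + lambda [(1 - alpha) KD_T1 + alpha KD_T2]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    kd1 = kd_loss(teacher1_logits, student_logits, tau)
    kd2 = kd_loss(teacher2_logits, student_logits, tau)
    return (1.0 - lam) * ce_loss(student_logits, labels) + lam * (
        (1.0 - alpha) * kd1 + alpha * kd2
    )


def objective_grad(
    student_logits, labels, lam, tau, alpha=0.0,
    teacher1_logits=None, teacher2_logits=None,
):
    """Analytic gradient of the (possibly multi-teacher) objective with
    respect to the student logits, mean reduction.  Returns (loss_parts,
    grad) where loss_parts = (ce, kd1, kd2)."""
    logits = np.asarray(student_logits, dtype=float)
    B, K = logits.shape
    ps = softmax(logits)
    onehot = np.zeros_like(ps)
    onehot[np.arange(B), labels] = 1.0
    grad = (1.0 - lam) * (ps - onehot) / B
    ce = ce_loss(logits, labels)
    kd1 = kd2 = 0.0
    ps_tau = softmax(logits / tau)
    if teacher1_logits is not None and lam > 0:
        pt1 = softmax(np.asarray(teacher1_logits, dtype=float) / tau)
        w1 = lam if teacher2_logits is None else lam * (1.0 - alpha)
        grad += w1 * tau * (ps_tau - pt1) / B
        kd1 = kd_loss(teacher1_logits, logits, tau)
    if teacher2_logits is not None and lam > 0:
        pt2 = softmax(np.asarray(teacher2_logits, dtype=float) / tau)
        grad += lam * alpha * tau * (ps_tau - pt2) / B
        kd2 = kd_loss(teacher2_logits, logits, tau)
    return (ce, kd1, kd2), grad.astype(np.float32)


# -- schedule --------------------------------------------------------------

def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant learning rate: ``lr0`` until ``decay_epoch``,
    one ``decay_factor`` there, plus one ``late_factor`` at every positive
    multiple of ``late_every`` reached."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch must be in [0, {cfg.epochs})")
    lr = cfg.lr0
    if epoch >= cfg.decay_epoch:
        lr *= cfg.decay_factor
    every = cfg.late_every if cfg.late_every is not None else cfg.epochs // 3
    if every and every > 0:
        lr *= cfg.late_factor ** (epoch // every)
    return lr


# -- training --------------------------------------------------------------

def _resolve_teacher(ref) -> WideResNet | None:
    if ref is None or isinstance(ref, WideResNet):
        return ref
    return load_checkpoint(ref)


def predict_logits(net: WideResNet, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode logits over a dataset, batched."""
    out = []
    for i in range(0, len(windows), batch_size):
        out.append(net.forward(windows[i : i + batch_size], train=False))
    return np.concatenate(out) if out else np.zeros((0, net.cfg.n_classes))


def _accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((logits.argmax(axis=1) == labels).mean() * 100.0)


def anneal_initialize(
    student_cfg: WRNConfig,
    dataset: LabeledWindowSet,
    train_cfg: TrainConfig,
    seed: int,
    eval_set: LabeledWindowSet | None = None,
) -> TrainResult:
    """Scratch (cross-entropy only) pretraining of the student architecture
    on raw series; the resulting weights initialize subsequent KD runs."""
    if student_cfg.dimensionality != "1d":
        raise ValueError("annealing pretrains the 1-D student architecture")
    cfg = DistillConfig(strategy=SCRATCH, seed=seed)
    return train(student_cfg, cfg, train_cfg, dataset, eval_set)


def train(
    student_cfg: WRNConfig,
    distill_cfg: DistillConfig,
    train_cfg: TrainConfig,
    train_set: LabeledWindowSet,
    eval_set: LabeledWindowSet | None = None,
    train_images: np.ndarray | None = None,
) -> TrainResult:
    """Train a student per the configured strategy.

    ``train_images`` supplies the 2-D teacher's modality (image
    representations of the same windows, index-aligned with
    ``train_set``); required iff ``teacher2`` is set.  Teachers are used
    in evaluation mode only and their parameters are never touched.
    """
    distill_cfg.validate()
    teacher1 = _resolve_teacher(distill_cfg.teacher1)
    teacher2 = _resolve_teacher(distill_cfg.teacher2)
    use_teachers = distill_cfg.strategy in (KD_SINGLE, KD_MULTI)
    if use_teachers and teacher2 is not None and train_images is None:
        raise ValueError("teacher2 requires train_images (its input modality)")
    if use_teachers and teacher2 is not None:
        if len(train_images) != len(train_set):
            raise ValueError("train_images must align index-wise with train_set")

    net = build_wrn(student_cfg, seed=distill_cfg.seed)
    if distill_cfg.anneal:
        ck = distill_cfg.anneal_checkpoint
        if isinstance(ck, TrainResult):
            if ck.config != student_cfg:
                raise ValueError("anneal checkpoint config mismatch")
            load_state_dict(net, ck.final_state)
        elif isinstance(ck, dict):
            load_state_dict(net, ck)
        else:
            load_state_dict(net, state_dict(load_checkpoint(ck, student_cfg)))

    # frozen-teacher soft targets, computed once in evaluation mode
    t1_logits = t2_logits = None
    if use_teachers:
        if teacher1 is not None:
            t1_logits = predict_logits(teacher1, train_set.windows)
        if teacher2 is not None:
            t2_logits = predict_logits(teacher2, train_images)
        if distill_cfg.strategy == KD_SINGLE and t1_logits is None:
            t1_logits, t2_logits = t2_logits, None  # single teacher in slot 1

    opt = nn.SGD(
        net.parameters(),
        momentum=train_cfg.momentum,
        weight_decay=train_cfg.weight_decay,
    )
    rng = np.random.default_rng(distill_cfg.seed + 1)
    n = len(train_set)
    history = []
    best_acc, best_epoch, best_state = -1.0, -1, None
    lam = distill_cfg.lam if use_teachers else 0.0
    for epoch in range(train_cfg.epochs):
        lr = lr_at_epoch(epoch, train_cfg)
        order = rng.permutation(n)
        sums = {"loss_ce": 0.0, "loss_kd_t1": 0.0, "loss_kd_t2": 0.0}
        correct = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            xb = train_set.windows[idx]
            yb = train_set.labels[idx]
            opt.zero_grad()
            logits = net.forward(xb, train=True)
            (ce, kd1, kd2), grad = objective_grad(
                logits, yb, lam, distill_cfg.tau, distill_cfg.alpha,
                None if t1_logits is None else t1_logits[idx],
                None if t2_logits is None else t2_logits[idx],
            )
            net.backward(grad)
            opt.step(lr)
            b = len(idx)
            sums["loss_ce"] += ce * b
            sums["loss_kd_t1"] += kd1 * b
            sums["loss_kd_t2"] += kd2 * b
            correct += int((logits.argmax(axis=1) == yb).sum())
        record = {
            "epoch": epoch,
            "lr": lr,
            "train_acc": 100.0 * correct / n,
            **{k: v / n for k, v in sums.items()},
        }
        if eval_set is not None and len(eval_set):
            acc = _accuracy(predict_logits(net, eval_set.windows), eval_set.labels)
            record["eval_acc"] = acc
            if acc > best_acc:
                best_acc, best_epoch = acc, epoch
                best_state = state_dict(net)
        history.append(record)
    final_state = state_dict(net)
    if best_state is None:
        best_state, best_epoch = final_state, train_cfg.epochs - 1
    return TrainResult(final_state, best_state, best_epoch, history, student_cfg)
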