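"""Experiment orchestration: the synthetic distillation benchmark and
architecture reports.

``make_benchmark`` fixes the study conditions for the desk-scale
experiment: 5 activity classes with distinct fundamental frequencies and
harmonic profiles, 3 channels, 500-sample windows, 20 subjects (16 train /
4 held out), 200 training and 50 test windows per class, noise SD 0.3.
``run_distillation_benchmark`` executes the full protocol on it: train a
1-D time-series teacher and a 2-D teacher on GASF images, pretrain scratch
students (which double as annealing initializers), distill multi-teacher
students, and collect accuracy, weight-interpolation and corruption
diagnostics.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distillation import (
    KD_MULTI,
    SCRATCH,
    DistillConfig,
    TrainConfig,
    TrainResult,
    anneal_initialize,
    train,
)
from .evaluation import (
    CORRUPTION_LEVELS,
    corrupt,
    evaluate,
    parametric_curve,
)
from .models import (
    WRNConfig,
    build_wrn,
    compression_ratio,
    count_params,
    flops_report,
    load_state_dict,
)
from .representations import windows_to_images
from .synthetic import ClassParams, LabeledWindowSet, SyntheticSpec, generate_activity_dataset

__all__ = [
    "benchmark_class_params",
    "make_benchmark",
    "run_distillation_benchmark",
    "table1_report",
    "run_experiment",
]


def benchmark_class_params(noise_sd: float = 0.3) -> tuple:
    """Five activity-like classes: distinct cadences (Hz) and harmonic
    shapes, equal unit amplitude."""
    return (
        ClassParams(0.8, 1.0, (1.0, 0.3), noise_sd),
        ClassParams(1.3, 1.0, (1.0,), noise_sd),
        ClassParams(2.0, 1.0, (0.8, 0.5), noise_sd),
        ClassParams(2.9, 1.0, (1.0, 0.2, 0.2), noise_sd),
        ClassParams(4.0, 1.0, (0.6, 0.8), noise_sd),
    )


def make_benchmark(
    seed: int = 0,
    *,
    train_per_class: int = 200,
    test_per_class: int = 50,
    n_train_subjects: int = 16,
    n_test_subjects: int = 4,
    window_length: int = 500,
    channels: int = 3,
    noise_sd: float = 0.3,
    subject_jitter: float = 0.1,
) -> tuple[LabeledWindowSet, LabeledWindowSet]:
    """Subject-disjoint train/test sets under the benchmark conditions.

    Held-out subjects are fresh draws (new people, new jitter factors),
    which is what a subject-wise split of real data would give."""
    params = benchmark_class_params(noise_sd)
    train_spec = SyntheticSpec(
        class_params=params,
        n_subjects=n_train_subjects,
        windows_per_class=train_per_class,
        channels=channels,
        window_length=window_length,
        sample_rate=33.0,
        subject_jitter=subject_jitter,
        seed=seed * 2 + 1,
    )
    test_spec = SyntheticSpec(
        class_params=params,
        n_subjects=n_test_subjects,
        windows_per_class=test_per_class,
        channels=channels,
        window_length=window_length,
        sample_rate=33.0,
        subject_jitter=subject_jitter,
        seed=seed * 2 + 2,
    )
    train_ds = generate_activity_dataset(train_spec)
    test_ds = generate_activity_dataset(test_spec)
    test_ds.subject_ids = test_ds.subject_ids + n_train_subjects
    return train_ds, test_ds


@dataclass
class BenchmarkResult:
    teacher1: TrainResult
    teacher2: TrainResult
    scratch: list  # TrainResult per seed
    distilled: list  # TrainResult per seed
    scratch_acc: list
    distilled_acc: list
    curves: dict = field(default_factory=dict)
    corruption: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        def row(method, accs):
            return {
                "method": method,
                "mean_acc": float(np.mean(accs)),
                "sd": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "n_seeds": len(accs),
            }

        return pd.DataFrame(
            [row("scratch", self.scratch_acc), row("KDm(TS+GAF)+Ann", self.distilled_acc)]
        )


def run_distillation_benchmark(
    seed: int = 1,
    *,
    epochs: int = 30,
    seeds: tuple = (0, 1, 2),
    lam: float = 0.7,
    tau: float = 4.0,
    alpha: float = 0.3,
    gaf_resolution: int = 32,
    eta_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    with_curves: bool = True,
    with_corruption: bool = True,
    train_cfg: TrainConfig | None = None,
    benchmark_kwargs: dict | None = None,
) -> BenchmarkResult:
    """Full desk-scale protocol: teachers -> anneal -> multi-teacher KD.

    Returns per-seed scratch and distilled accuracies plus the
    weight-interpolation curves (Ann student vs its own initializer, and
    two independent scratch students) and corruption-level accuracies.
    """
    bk = benchmark_kwargs or {}
    train_ds, test_ds = make_benchmark(seed, **bk)
    k = int(train_ds.meta["n_classes"])
    length = train_ds.windows.shape[2]
    channels = train_ds.windows.shape[1]
    tcfg = train_cfg or TrainConfig(epochs=epochs)

    cfg_1d = WRNConfig(16, 1, "1d", channels, k, length)
    cfg_2d = WRNConfig(16, 1, "2d", channels, k, (gaf_resolution, gaf_resolution))

    train_imgs = windows_to_images(
        train_ds.windows, "gaf", variant="gasf", resolution=gaf_resolution
    )

    base = (seed % 20011) * 100000
    teacher1 = train(
        cfg_1d, DistillConfig(strategy=SCRATCH, seed=base + 11), tcfg, train_ds, test_ds
    )
    teacher2_set = LabeledWindowSet(
        train_imgs, train_ds.labels, train_ds.subject_ids, dict(train_ds.meta)
    )
    test_imgs = windows_to_images(
        test_ds.windows, "gaf", variant="gasf", resolution=gaf_resolution
    )
    teacher2_eval = LabeledWindowSet(
        test_imgs, test_ds.labels, test_ds.subject_ids, dict(test_ds.meta)
    )
    teacher2 = train(
        cfg_2d,
        DistillConfig(strategy=SCRATCH, seed=base + 22),
        tcfg,
        teacher2_set,
        teacher2_eval,
    )
    t1_net = load_state_dict(build_wrn(cfg_1d, 0), teacher1.final_state)
    t2_net = load_state_dict(build_wrn(cfg_2d, 0), teacher2.final_state)

    scratch_results, distilled_results = [], []
    scratch_acc, distilled_acc = [], []
    for s in seeds:
        run_seed = base + 1000 + int(s)
        scratch = anneal_initialize(cfg_1d, train_ds, tcfg, run_seed, eval_set=test_ds)
        scratch_results.append(scratch)
        scratch_acc.append(
            evaluate(
                load_state_dict(build_wrn(cfg_1d, 0), scratch.final_state),
                test_ds.windows,
                test_ds.labels,
            ).accuracy
        )
        dcfg = DistillConfig(
            strategy=KD_MULTI,
            lam=lam,
            tau=tau,
            alpha=alpha,
            teacher1=t1_net,
            teacher2=t2_net,
            anneal=True,
            anneal_checkpoint=scratch,
            seed=run_seed,
        )
        distilled = train(cfg_1d, dcfg, tcfg, train_ds, test_ds, train_images=train_imgs)
        distilled_results.append(distilled)
        distilled_acc.append(
            evaluate(
                load_state_dict(build_wrn(cfg_1d, 0), distilled.final_state),
                test_ds.windows,
                test_ds.labels,
            ).accuracy
        )

    result = BenchmarkResult(
        teacher1,
        teacher2,
        scratch_results,
        distilled_results,
        scratch_acc,
        distilled_acc,
    )

    if with_curves:
        # connected path: the Ann student against the very weights that
        # initialized it; disconnected baseline: two independent scratch runs
        result.curves["ann_vs_init"] = parametric_curve(
            distilled_results[0], scratch_results[0], cfg_1d, train_ds, test_ds,
            etas=eta_grid,
        )
        result.curves["scratch_vs_scratch"] = parametric_curve(
            scratch_results[0], scratch_results[1], cfg_1d, train_ds, test_ds,
            etas=eta_grid,
        )

    if with_corruption:
        corr_seed = base + 777
        for name in ("clean", "level1", "level2", "level3"):
            accs = []
            for res in distilled_results:
                net = load_state_dict(build_wrn(cfg_1d, 0), res.final_state)
                w = (
                    test_ds.windows
                    if name == "clean"
                    else corrupt(test_ds.windows, CORRUPTION_LEVELS[name], corr_seed)
                )
                accs.append(evaluate(net, w, test_ds.labels).accuracy)
            result.corruption[name] = accs
    return result


# -- architecture report ---------------------------------------------------

_TABLE1_PAIRS = ((16, 1), (16, 3), (28, 1), (28, 3))


def table1_report(in_channels: int = 3, n_classes: int = 14,
                  input_length: int = 500, image_size: int = 64) -> pd.DataFrame:
    """Teacher/student architecture report: exact parameter counts (M),
    multiply-accumulate counts and the student/teachers compression ratio
    for a 1-D WRN16-1 student against same-depth/width 1-D + 2-D teacher
    pairs."""
    student_cfg = WRNConfig(16, 1, "1d", in_channels, n_classes, input_length)
    s_count = count_params(build_wrn(student_cfg))
    rows = []
    for depth, width in _TABLE1_PAIRS:
        c1 = WRNConfig(depth, width, "1d", in_channels, n_classes, input_length)
        c2 = WRNConfig(depth, width, "2d", in_channels, n_classes, (image_size, image_size))
        n1 = count_params(build_wrn(c1))
        n2 = count_params(build_wrn(c2))
        rows.append(
            {
                "teacher": f"WRN{depth}-{width}",
                "t1_params_M": round(n1 / 1e6, 2),
                "t2_params_M": round(n2 / 1e6, 2),
                "student_params_M": round(s_count / 1e6, 2),
                "t1_mmacs": round(flops_report(c1) / 1e6, 2),
                "t2_mmacs": round(flops_report(c2) / 1e6, 2),
                "compression_pct": compression_ratio(s_count, n1, n2),
            }
        )
    return pd.DataFrame(rows)


# -- declarative experiment runner ----------------------------------------

def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def run_experiment(config: dict, output_dir) -> Path:
    """Run the full benchmark protocol from a declarative config and write
    a results directory (summary.csv, history CSVs, manifest.json).

    Recognized keys (all optional): ``seed``, ``epochs``, ``seeds``,
    ``lam``, ``tau``, ``alpha``, ``gaf_resolution``, ``benchmark``
    (kwargs for :func:`make_benchmark`), ``with_curves``,
    ``with_corruption``.  Rerunning with an unchanged config reuses the
    cached result (idempotent).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = _config_hash(config)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == h and (out / "summary.csv").exists():
            return out
    kwargs = dict(
        seed=int(config.get("seed", 1)),
        epochs=int(config.get("epochs", 30)),
        seeds=tuple(config.get("seeds", (0, 1, 2))),
        lam=float(config.get("lam", 0.7)),
        tau=float(config.get("tau", 4.0)),
        alpha=float(config.get("alpha", 0.3)),
        gaf_resolution=int(config.get("gaf_resolution", 32)),
        with_curves=bool(config.get("with_curves", True)),
        with_corruption=bool(config.get("with_corruption", True)),
        benchmark_kwargs=config.get("benchmark", None),
    )
    result = run_distillation_benchmark(**kwargs)
    result.summary().to_csv(out / "summary.csv", index=False)
    for tag, res in (
        ("teacher1", result.teacher1),
        ("teacher2", result.teacher2),
        *((f"scratch_s{i}", r) for i, r in enumerate(result.scratch)),
        *((f"distilled_s{i}", r) for i, r in enumerate(result.distilled)),
    ):
        pd.DataFrame(res.history).to_csv(out / f"history_{tag}.csv", index=False)
    for name, rows in result.curves.items():
        pd.DataFrame(rows).to_csv(out / f"curve_{name}.csv", index=False)
    if result.corruption:
        pd.DataFrame(result.corruption).to_csv(out / "corruption.csv", index=False)
    manifest_path.write_text(
        json.dumps({"config_hash": h, "config": config}, indent=1)
    )
    return out
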