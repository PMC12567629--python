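"""Synthetic class-structured quasi-periodic sensor signals.

Real wrist-worn accelerometer corpora for activity recognition are either
private or external downloads, so this module generates windows that keep
the properties the downstream pipeline actually exploits: class-specific
fundamental frequencies and harmonic profiles (activities differ in cadence
and movement shape), per-subject multiplicative variation in frequency and
amplitude (physiology), per-channel phase offsets (sensor orientation), and
additive Gaussian noise.  It also implements the windowing conventions used
for such corpora: fixed-length segmentation with configurable overlap,
sample-rate reduction, and leave-one-subject-out (LOSO) splits.

Each window is ``sum_k w_k * A * sin(2 pi k f_subj t + phase_ch) + eps``
with ``f_subj = base_freq * (1 + jitter)`` drawn once per subject and
``eps ~ N(0, noise_sd^2)`` i.i.d. per sample.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClassParams",
    "SyntheticSpec",
    "LabeledWindowSet",
    "generate_activity_dataset",
    "segment_series",
    "downsample_rate",
    "make_loso_splits",
    "save_window_set",
    "load_window_set",
    "load_pamap2_subject",
]


@dataclass(frozen=True)
class ClassParams:
    """Signal recipe for one activity class."""

    base_freq_hz: float
    amplitude: float = 1.0
    harmonic_weights: tuple = (1.0,)
    noise_sd: float = 0.0

    def validate(self, name: str):
        if self.base_freq_hz <= 0:
            raise ValueError(f"{name}.base_freq_hz must be > 0")
        if self.amplitude <= 0:
            raise ValueError(f"{name}.amplitude must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"{name}.noise_sd must be >= 0")
        if len(self.harmonic_weights) == 0:
            raise ValueError(f"{name}.harmonic_weights must be non-empty")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic dataset draw.

    ``windows_per_class`` may be an int (balanced) or a sequence of ints
    (one entry per class) to express class imbalance.
    """

    class_params: tuple  # of ClassParams
    n_subjects: int = 9
    windows_per_class: object = 100
    channels: int = 3
    window_length: int = 500
    sample_rate: float = 100.0
    subject_jitter: float = 0.1
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_params)

    def counts(self) -> np.ndarray:
        if np.isscalar(self.windows_per_class):
            return np.full(self.n_classes, int(self.windows_per_class))
        counts = np.asarray(self.windows_per_class, dtype=int)
        if counts.shape != (self.n_classes,):
            raise ValueError(
                "windows_per_class must be scalar or one entry per class"
            )
        return counts

    def validate(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2 (need class_params for each)")
        if self.window_length < 8:
            raise ValueError("window_length must be >= 8")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be >= 0")
        if (self.counts() < 0).any():
            raise ValueError("windows_per_class entries must be >= 0")
        for i, cp in enumerate(self.class_params):
            cp.validate(f"class_params[{i}]")


@dataclass
class LabeledWindowSet:
    """The universal dataset currency: windows [N x channels x length] with
    integer labels and subject ids."""

    windows: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        # [N x channels x length] for series; image sets reuse the
        # container with [N x channels x H x W]
        if self.windows.ndim not in (3, 4):
            raise ValueError("windows must be [N x channels x length] (or x H x W)")
        n = self.windows.shape[0]
        if self.labels.shape != (n,) or self.subject_ids.shape != (n,):
            raise ValueError("labels/subject_ids must match window count")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_classes(self) -> int:
        return int(self.meta.get("n_classes", self.labels.max() + 1 if len(self) else 0))

    def subset(self, idx) -> "LabeledWindowSet":
        return LabeledWindowSet(
            self.windows[idx], self.labels[idx], self.subject_ids[idx], dict(self.meta)
        )


def generate_activity_dataset(spec: SyntheticSpec) -> LabeledWindowSet:
    """Draw a dataset per ``spec``; deterministic for a fixed seed.

    Subject jitter factors (frequency and amplitude) are drawn once per
    subject; windows of each class are assigned to subjects round-robin so
    every class appears for every subject whenever counts permit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    freq_jit = 1.0 + spec.subject_jitter * rng.uniform(-1, 1, size=spec.n_subjects)
    amp_jit = 1.0 + spec.subject_jitter * rng.uniform(-1, 1, size=spec.n_subjects)
    t = np.arange(spec.window_length) / spec.sample_rate
    counts = spec.counts()

    windows, labels, subjects = [], [], []
    for ci, cp in enumerate(spec.class_params):
        for wi in range(counts[ci]):
            sid = wi % spec.n_subjects
            f = cp.base_freq_hz * freq_jit[sid]
            amp = cp.amplitude * amp_jit[sid]
            phases = rng.uniform(0, 2 * np.pi, size=spec.channels)
            sig = np.zeros((spec.channels, spec.window_length))
            for k, w in enumerate(cp.harmonic_weights, start=1):
                sig += w * amp * np.sin(
                    2 * np.pi * k * f * t[None, :] + phases[:, None]
                )
            if cp.noise_sd > 0:
                sig += rng.normal(0, cp.noise_sd, size=sig.shape)
            windows.append(sig.astype(np.float32))
            labels.append(ci)
            subjects.append(sid)

    meta = {
        "n_classes": spec.n_classes,
        "sample_rate": spec.sample_rate,
        "seed": spec.seed,
        "generator": "synthetic-harmonic",
    }
    return LabeledWindowSet(
        np.stack(windows) if windows else np.zeros((0, spec.channels, spec.window_length)),
        np.array(labels, dtype=np.int64),
        np.array(subjects, dtype=np.int64),
        meta,
    )


def segment_series(series: np.ndarray, window: int, overlap: int) -> np.ndarray:
    """Cut [channels x T] into [n x channels x window] sliding windows.

    Window starts fall on multiples of ``stride = window - overlap``; any
    trailing remainder shorter than a full window is dropped.  A window
    longer than the series yields an empty result with a warning.
    """
    series = np.atleast_2d(np.asarray(series))
    if overlap < 0 or overlap >= window:
        raise ValueError("require 0 <= overlap < window")
    T = series.shape[1]
    if window > T:
        warnings.warn(
            f"window {window} longer than series length {T}: no windows",
            stacklevel=2,
        )
        return np.zeros((0, series.shape[0], window), dtype=series.dtype)
    stride = window - overlap
    n = (T - window) // stride + 1
    return np.stack([series[:, i * stride : i * stride + window] for i in range(n)])


def downsample_rate(
    series: np.ndarray, from_hz: float, to_hz: float, method: str = "interp"
) -> np.ndarray:
    """Reduce the sample rate of [channels x T] (or [T]) by linear
    interpolation on a uniform grid spanning the original index range
    (endpoints preserved); ``method='decimate'`` takes every
    ``floor(from/to)``-th sample instead."""
    if from_hz <= 0 or to_hz <= 0:
        raise ValueError("rates must be positive")
    if to_hz >= from_hz:
        raise ValueError("to_hz must be below from_hz")
    x = np.atleast_2d(np.asarray(series, dtype=float))
    T = x.shape[1]
    if method == "decimate":
        step = int(from_hz // to_hz)
        out = x[:, ::step]
    elif method == "interp":
        n_new = int(np.floor(T * to_hz / from_hz))
        grid = np.linspace(0, T - 1, n_new)
        out = np.stack([np.interp(grid, np.arange(T), row) for row in x])
    else:
        raise ValueError(f"unknown method {method!r}")
    return out[0] if np.asarray(series).ndim == 1 else out


def make_loso_splits(ds: LabeledWindowSet) -> list[tuple[LabeledWindowSet, LabeledWindowSet]]:
    """Leave-one-subject-out folds: one (train, test) pair per subject,
    ordered by subject id; each fold's test set is exactly that subject's
    windows."""
    subjects = np.unique(ds.subject_ids)
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least 2 distinct subjects")
    folds = []
    for s in subjects:
        test_mask = ds.subject_ids == s
        folds.append((ds.subset(~test_mask), ds.subset(test_mask)))
    return folds


# -- persistence -----------------------------------------------------------

def save_window_set(path, ds: LabeledWindowSet):
    """Directory layout: windows.npy (binary array), labels.tsv
    (label + subject table), meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "windows.npy", ds.windows)
    pd.DataFrame({"label": ds.labels, "subject_id": ds.subject_ids}).to_csv(
        path / "labels.tsv", sep="\t", index=False
    )
    (path / "meta.json").write_text(json.dumps(ds.meta, indent=1))


def load_window_set(path) -> LabeledWindowSet:
    path = Path(path)
    windows = np.load(path / "windows.npy")
    table = pd.read_csv(path / "labels.tsv", sep="\t")
    meta = json.loads((path / "meta.json").read_text())
    return LabeledWindowSet(
        windows, table["label"].to_numpy(), table["subject_id"].to_numpy(), meta
    )


def load_pamap2_subject(
    path,
    channels: list[int],
    *,
    from_hz: float = 100.0,
    to_hz: float = 33.0,
    window: int = 100,
    overlap: int = 78,
    activity_column: int = 1,
) -> LabeledWindowSet:
    """Optional ingestion hook for PAMAP2-style space-delimited subject
    files (never exercised by the test suite; requires the external
    download).  ``channels`` selects sensor columns, since there is no
    single canonical axis subset."""
    raw = pd.read_csv(path, sep=r"\s+", header=None).to_numpy()
    labels_col = raw[:, activity_column].astype(int)
    data = raw[:, channels].T  # [channels x T]
    windows, labels = [], []
    for activity in np.unique(labels_col):
        if activity == 0:  # transient/no-activity marker
            continue
        seg = data[:, labels_col == activity]
        seg = np.nan_to_num(seg)
        seg = downsample_rate(seg, from_hz, to_hz)
        if seg.shape[1] < window:
            continue
        w = segment_series(seg, window, overlap)
        windows.append(w)
        labels.extend([activity] * len(w))
    if not windows:
        raise ValueError(f"no usable activity segments in {path}")
    allw = np.concatenate(windows)
    return LabeledWindowSet(
        allw,
        np.asarray(labels),
        np.zeros(len(allw), dtype=np.int64),
        {"source": str(path)},
    )
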