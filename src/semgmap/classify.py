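"""Evaluation harness: chronological hold-out, ablation runs, metrics.

The protocol mirrors standard myoelectric-recognition practice: grayscale
feature windows are ordered in time per (subject, gesture) stream, the first
fraction trains the classifier and the last fraction tests it, with an
overlap-safety option that drops test windows sharing raw samples with any
training window. Classifier back ends are pluggable; the default is a
regularized multinomial logistic regression on flattened pixels, and any
image classifier implementing ``fit``/``predict`` can be substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.neural_network import MLPClassifier

from .errors import SemgError
from .imaging import GrayscaleMap, imagize, window_length
from .multimap import MappingConfig, multiple_mapping
from .preprocess import Recording, bandpass_filter

logger = logging.getLogger(__name__)


@dataclass
class EvaluationResult:
    """Metrics of one train/test evaluation."""

    per_subject_accuracy: dict[str, float]
    average_accuracy: float
    rate_distribution: float
    confusion: np.ndarray
    classes: list
    variant: str | None = None
    split: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def overall_accuracy(self) -> float:
        """Trace / total of the confusion matrix."""
        return float(np.trace(self.confusion) / self.confusion.sum())


class ClassifierBackend(Protocol):
    """Adapter contract for external image classifiers.

    ``fit`` receives a list of ``T × L`` uint8 pixel arrays with their labels;
    ``predict`` returns one label per image. Any model honoring this contract
    (e.g. a CNN trained in an external framework) can replace the built-in
    back ends.
    """

    def fit(self, images: Sequence[np.ndarray], labels: Sequence) -> "ClassifierBackend": ...
    def predict(self, images: Sequence[np.ndarray]) -> np.ndarray: ...


def _flatten(images: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([np.asarray(im, dtype=float).ravel() / 255.0 for im in images])


class _SklearnBackend:
    """Flattened-pixel back end over a scikit-learn estimator."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._single_class = None

    def fit(self, images, labels):
        labels = np.asarray(labels)
        uniq = np.unique(labels)
        if uniq.size == 1:
            # degenerate training set: constant prediction
            self._single_class = uniq[0]
            return self
        self.estimator.fit(_flatten(images), labels)
        return self

    def predict(self, images):
        if self._single_class is not None:
            return np.full(len(images), self._single_class)
        return self.estimator.predict(_flatten(images))


def make_backend(name: str = "linear", seed: int = 0) -> ClassifierBackend:
    """Instantiate a built-in back end: ``linear`` (logistic regression on
    flattened pixels, the default) or ``mlp`` (one-hidden-layer perceptron)."""
    if name == "linear":
        return _SklearnBackend(
            LogisticRegression(max_iter=2000, C=1.0, random_state=seed)
        )
    if name == "mlp":
        return _SklearnBackend(
            MLPClassifier(hidden_layer_sizes=(64,), max_iter=500,
                          random_state=seed)
        )
    raise ValueError(f"unknown backend {name!r}; use 'linear', 'mlp', or pass "
                     "an object with fit/predict")


def chronological_split(
    maps: Sequence[GrayscaleMap],
    train_frac: float = 0.8,
    overlap_safe: bool = True,
    window_samples: int | None = None,
) -> tuple[list[GrayscaleMap], list[GrayscaleMap]]:
    """Time-ordered hold-out split per (subject, gesture) stream.

    Within each stream — ordered by (recording, start_index) — the first
    ``train_frac`` of windows train and the rest test; no window appears in
    both sets. With ``overlap_safe`` (default on) test windows whose sample
    span intersects a training window's span in the same recording are
    dropped, so overlapping strides cannot leak raw samples across the split.
    ``window_samples`` (the span length L) defaults to each map's pixel width.
    Streams with fewer than 2 windows are excluded with a warning.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    streams: dict[tuple, list[GrayscaleMap]] = {}
    for gm in maps:
        streams.setdefault((gm.subject, gm.label), []).append(gm)

    train: list[GrayscaleMap] = []
    test: list[GrayscaleMap] = []
    for key, stream in streams.items():
        if len(stream) < 2:
            logger.warning("stream %s has < 2 windows; excluded from split", key)
            continue
        stream = sorted(stream, key=lambda g: (str(g.recording), g.start_index))
        cut = int(np.floor(train_frac * len(stream)))
        cut = min(max(cut, 1), len(stream) - 1)
        tr, te = stream[:cut], stream[cut:]
        if overlap_safe:
            last_train_start: dict = {}
            for g in tr:
                last_train_start[g.recording] = max(
                    last_train_start.get(g.recording, -1), g.start_index
                )
            kept = []
            for g in te:
                L = window_samples if window_samples is not None else g.width
                boundary = last_train_start.get(g.recording)
                if boundary is not None and g.start_index < boundary + L:
                    continue  # shares raw samples with a training window
                kept.append(g)
            te = kept
        train.extend(tr)
        test.extend(te)
    return train, test


def evaluate_predictions(
    test: Sequence[GrayscaleMap],
    predictions: np.ndarray,
    classes: Iterable | None = None,
    variant: str | None = None,
    split: str = "",
) -> EvaluationResult:
    """Pure metric computation from (test windows, predicted labels)."""
    y_true = np.array([g.label for g in test])
    y_pred = np.asarray(predictions)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = list(classes)
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    subjects = np.array([g.subject for g in test])
    per_subject = {
        str(s): float((y_pred[subjects == s] == y_true[subjects == s]).mean())
        for s in np.unique(subjects)
    }
    accs = list(per_subject.values())
    return EvaluationResult(
        per_subject_accuracy=per_subject,
        average_accuracy=float(np.mean(accs)),
        rate_distribution=float(max(accs) - min(accs)),
        confusion=conf,
        classes=classes,
        variant=variant,
        split=split,
    )


def train_eval(
    train: Sequence[GrayscaleMap],
    test: Sequence[GrayscaleMap],
    backend: str | ClassifierBackend = "linear",
    seed: int = 0,
    variant: str | None = None,
) -> EvaluationResult:
    """Fit a back end on training windows and evaluate on test windows."""
    if len(train) == 0:
        raise SemgError("empty training set")
    if len(test) == 0:
        raise SemgError("empty test set")
    shapes = {g.pixels.shape for g in list(train) + list(test)}
    if len(shapes) != 1:
        raise SemgError(f"inconsistent image shapes across dataset: {shapes}")
    if isinstance(backend, str):
        backend = make_backend(backend, seed=seed)
    backend.fit([g.pixels for g in train], [g.label for g in train])
    preds = backend.predict([g.pixels for g in test])
    classes = sorted({g.label for g in list(train) + list(test)})
    return evaluate_predictions(
        test, preds, classes=classes, variant=variant,
        split=f"chronological {len(train)}/{len(test)}",
    )


def run_pipeline(
    recordings: Sequence[Recording],
    cfg: MappingConfig | None = None,
    k_ms: float = 200.0,
    h_ms: float = 50.0,
    filter_signal: bool = True,
    grayscale_scope: str = "per-window",
) -> list[GrayscaleMap]:
    """Map recordings with the configured variant and imagize every one."""
    if cfg is None:
        cfg = MappingConfig()
    maps: list[GrayscaleMap] = []
    for rec in recordings:
        if filter_signal:
            rec = bandpass_filter(rec)
        fm = multiple_mapping(rec, cfg)
        maps.extend(imagize(fm, k_ms=k_ms, h_ms=h_ms, scope=grayscale_scope))
    return maps


def shuffle_labels(
    maps: Sequence[GrayscaleMap], seed: int = 0
) -> list[GrayscaleMap]:
    """Permute window labels (one label per window, kept across the split).

    A leakage control: with labels shuffled at the window level any honest
    split scores at chance, while a split that lets the same window reach
    both sides lets the classifier memorize its shuffled label.
    """
    rng = np.random.default_rng(seed)
    labels = [g.label for g in maps]
    perm = rng.permutation(len(labels))
    out = []
    for g, j in zip(maps, perm):
        out.append(GrayscaleMap(g.pixels, label=labels[j], subject=g.subject,
                                recording=g.recording, start_index=g.start_index,
                                meta=dict(g.meta)))
    return out


def ablation_run(
    recordings: Sequence[Recording],
    cfgs: dict[str, MappingConfig] | None = None,
    backend: str = "linear",
    seed: int = 0,
    k_ms: float = 200.0,
    h_ms: float = 50.0,
    train_frac: float = 0.8,
) -> tuple[dict[str, EvaluationResult], pd.DataFrame]:
    """Evaluate ablation variants T1–T4 with an identical protocol.

    Every variant uses the same windowing, the same chronological split rule
    and the same back-end seed; only the feature mapping differs. Returns the
    per-variant results and a tidy summary table.
    """
    if cfgs is None:
        cfgs = {v: MappingConfig(variant=v) for v in ("T1", "T2", "T3", "T4")}
    results: dict[str, EvaluationResult] = {}
    rows = []
    for variant, cfg in cfgs.items():
        maps = run_pipeline(recordings, cfg, k_ms=k_ms, h_ms=h_ms)
        train, test = chronological_split(maps, train_frac=train_frac)
        res = train_eval(train, test, backend=backend, seed=seed, variant=variant)
        results[variant] = res
        rows.append({
            "variant": variant,
            "overall_accuracy": res.overall_accuracy,
            "average_accuracy": res.average_accuracy,
            "rate_distribution": res.rate_distribution,
            "n_train": len(train), "n_test": len(test),
        })
    return results, pd.DataFrame(rows)
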