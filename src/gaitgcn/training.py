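"""Training loop, leave-one-subject-out protocol and evaluation metrics.

The evaluation protocol is leave-one-subject-out (LOSO) cross-validation:
one fold per subject, testing on every sample of the held-out subject and
training on all remaining subjects, so reported accuracy measures
generalization to unseen people rather than unseen trials.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import BRANCH_NAMES, assemble_branches
from .graph import SkeletonGraph, kinect_v2_graph
from .io import SkeletonSequence, resample_sequence
from .model import MIBNetwork, ModelConfig, build_mib_network
from . import nn

__all__ = [
    "Sample",
    "FoldSplit",
    "EvalReport",
    "TrainConfig",
    "prepare_dataset",
    "loso_splits",
    "train",
    "evaluate",
    "cross_validate",
]

log = logging.getLogger(__name__)


@dataclass
class Sample:
    """One preprocessed trial: branch feature streams plus metadata."""

    features: dict[str, np.ndarray]  # branch name → 6×T×V
    label: int
    subject_id: str
    sample_id: str


@dataclass(frozen=True)
class FoldSplit:
    """One LOSO fold: all samples of ``held_out_subject`` form the test set."""

    held_out_subject: str
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class EvalReport:
    """Classification accuracy with its confusion matrix.

    ``confusion[i, j]`` counts samples of true class i predicted as j;
    ``accuracy`` is the pooled sample accuracy trace/sum.  For
    cross-validated runs ``per_fold`` holds each fold's accuracy and
    ``fold_mean`` their unweighted mean.
    """

    accuracy: float
    confusion: np.ndarray
    per_fold: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        total = self.confusion.sum()
        if total:
            expected = np.trace(self.confusion) / total
            if abs(expected - self.accuracy) > 1e-9:
                raise ValueError(
                    "accuracy inconsistent with confusion matrix"
                )

    @property
    def fold_mean(self) -> float:
        return float(np.mean(self.per_fold)) if self.per_fold else self.accuracy

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "accuracy": self.accuracy,
                "fold_mean": self.fold_mean,
                "per_fold": self.per_fold,
                "confusion": self.confusion.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def confusion_to_csv(self, path: str | Path,
                         class_names: list[str] | None = None) -> None:
        n = self.confusion.shape[0]
        names = class_names or [f"class{i}" for i in range(n)]
        pd.DataFrame(self.confusion, index=names, columns=names).to_csv(path)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults are sized for single-CPU training on the synthetic
    benchmark; Adam with a constant learning rate converges in a few
    epochs there.  ``deterministic`` seeds batch shuffling so repeated
    runs produce identical weights.
    """

    epochs: int = 12
    batch_size: int = 32
    lr: float = 2e-3
    optimizer: str = "adam"       # "adam" | "sgd"
    momentum: float = 0.9
    weight_decay: float = 0.0
    lr_step: int | None = None    # epoch interval for 10× step decay (sgd)
    crop_t: int | None = 32       # random temporal crop length at train time
    seed: int = 0
    deterministic: bool = True
    verbose: bool = False


def prepare_dataset(
    sequences: list[SkeletonSequence],
    graph: SkeletonGraph | None = None,
    t_target: int | None = 64,
) -> list[Sample]:
    """Resample sequences to a common length and compute branch features."""
    graph = graph if graph is not None else kinect_v2_graph()
    samples = []
    for seq in sequences:
        if t_target is not None and seq.num_frames != t_target:
            seq = resample_sequence(seq, t_target)
        feats = assemble_branches(seq, graph)
        samples.append(
            Sample(
                features=feats.as_dict(),
                label=int(seq.class_label),
                subject_id=seq.subject_id,
                sample_id=seq.sample_id,
            )
        )
    return samples


def loso_splits(dataset: list[Sample]) -> list[FoldSplit]:
    """One fold per subject; the fold's test set is that subject's samples."""
    subjects = sorted({s.subject_id for s in dataset})
    if len(subjects) < 2:
        raise ValueError(
            "leave-one-subject-out needs at least 2 subjects, got "
            f"{len(subjects)}"
        )
    folds = []
    for subject in subjects:
        test = tuple(s.sample_id for s in dataset if s.subject_id == subject)
        train_ = tuple(
            s.sample_id for s in dataset if s.subject_id != subject
        )
        folds.append(FoldSplit(subject, train_, test))
    return folds


def _stack_branches(
    samples: list[Sample], branches: tuple[str, ...]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    X = {
        name: np.stack([s.features[name] for s in samples]).astype(
            np.float32
        )
        for name in branches
    }
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y


def train(
    model: MIBNetwork,
    dataset: list[Sample],
    branch_selection: tuple[str, ...] | None = None,
    train_config: TrainConfig | None = None,
) -> dict:
    """Minimize cross-entropy on ``dataset``; returns the training history.

    ``branch_selection`` must match the branches the model was built
    with — disabled branches are absent from the architecture, not
    zero-filled.
    """
    cfg = train_config or TrainConfig()
    if branch_selection is not None and len(branch_selection) == 0:
        raise ValueError("branch_selection must be a nonempty subset of "
                         f"{BRANCH_NAMES}")
    branches = tuple(
        branch_selection if branch_selection is not None
        else model.branch_names
    )
    if set(branches) != set(model.branch_names):
        raise ValueError(
            f"model was built for branches {model.branch_names}, "
            f"requested {branches}"
        )
    X, y = _stack_branches(dataset, model.branch_names)
    N = y.size

    params = model.parameters()
    if cfg.optimizer == "adam":
        opt: nn.Adam | nn.SGD = nn.Adam(
            params, lr=cfg.lr, weight_decay=cfg.weight_decay
        )
    elif cfg.optimizer == "sgd":
        opt = nn.SGD(params, lr=cfg.lr, momentum=cfg.momentum,
                     weight_decay=cfg.weight_decay)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    rng = np.random.default_rng(cfg.seed if cfg.deterministic else None)
    history: dict = {"loss": [], "accuracy": []}
    model.set_training(True)
    for epoch in range(cfg.epochs):
        if cfg.lr_step and cfg.optimizer == "sgd" and epoch > 0 \
                and epoch % cfg.lr_step == 0:
            opt.lr *= 0.1
        perm = rng.permutation(N)
        losses, correct = [], 0
        T_full = next(iter(X.values())).shape[2]
        for start in range(0, N, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            if cfg.crop_t is not None and cfg.crop_t < T_full:
                # random temporal crop (shared within the batch): a cheap
                # augmentation that also shortens each update
                t0 = int(rng.integers(0, T_full - cfg.crop_t + 1))
                batch = {
                    name: X[name][idx, :, t0 : t0 + cfg.crop_t]
                    for name in model.branch_names
                }
            else:
                batch = {name: X[name][idx] for name in model.branch_names}
            logits = model.forward(batch)
            loss, glogits = nn.cross_entropy(logits, y[idx])
            model.zero_grad()
            model.backward(glogits)
            opt.step()
            losses.append(loss * idx.size)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        history["loss"].append(float(np.sum(losses) / N))
        history["accuracy"].append(correct / N)
        if cfg.verbose:
            log.info("epoch %d: loss %.4f acc %.3f", epoch + 1,
                     history["loss"][-1], history["accuracy"][-1])
    model.set_training(False)
    return history


def predict(model: MIBNetwork, samples: list[Sample],
            batch_size: int = 64) -> np.ndarray:
    """Argmax-of-logits class predictions (ties break to the lowest index)."""
    X, _ = _stack_branches(samples, model.branch_names)
    model.set_training(False)
    preds = []
    N = len(samples)
    for start in range(0, N, batch_size):
        batch = {
            name: X[name][start : start + batch_size]
            for name in model.branch_names
        }
        logits = model.forward(batch)
        preds.append(logits.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: MIBNetwork, test_samples: list[Sample]) -> EvalReport:
    """Confusion matrix and pooled accuracy on held-out samples."""
    n_classes = model.config.num_classes
    labels = np.array([s.label for s in test_samples])
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("test labels outside the training label set")
    preds = predict(model, test_samples)
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(confusion, (labels, preds), 1)
    acc = float(np.trace(confusion) / confusion.sum())
    return EvalReport(accuracy=acc, confusion=confusion)


def cross_validate(
    dataset: list[Sample],
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    keep_models: bool = False,
) -> tuple[EvalReport, list[tuple[MIBNetwork, list[Sample]]]]:
    """Run the full LOSO protocol.

    Trains one fresh model per fold and pools the per-fold confusion
    matrices.  With ``keep_models`` the trained fold models are returned
    together with their held-out samples (used for CAM analysis, which
    must only look at out-of-subject predictions).
    """
    cfg = train_config or TrainConfig()
    folds = loso_splits(dataset)
    by_id = {s.sample_id: s for s in dataset}
    n_classes = model_config.num_classes
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    per_fold: list[float] = []
    kept: list[tuple[MIBNetwork, list[Sample]]] = []
    for fi, fold in enumerate(folds):
        train_set = [by_id[i] for i in fold.train_ids]
        test_set = [by_id[i] for i in fold.test_ids]
        fold_model_cfg = model_config
        model = build_mib_network(fold_model_cfg)
        train(model, train_set, model.branch_names, cfg)
        report = evaluate(model, test_set)
        confusion += report.confusion
        per_fold.append(report.accuracy)
        log.info("fold %d (%s): accuracy %.3f", fi,
                 fold.held_out_subject, report.accuracy)
        if keep_models:
            kept.append((model, test_set))
    acc = float(np.trace(confusion) / confusion.sum())
    return EvalReport(accuracy=acc, confusion=confusion,
                      per_fold=per_fold), kept
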