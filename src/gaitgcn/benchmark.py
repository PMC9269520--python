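"""The synthetic gait-classification benchmark.

One canonical experiment used by the test suite, the CLI ``ablate``
verb and the acceptance script: simulate a balanced multi-subject
cohort (default 8 subjects × 6 classes × 10 trials, 64 frames,
severity 0.7, 5 mm sensor noise), run leave-one-subject-out
cross-validation with a compact model configuration sized for a single
CPU, and compare branch combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .features import BRANCH_NAMES
from .model import ModelConfig
from .simulate import GaitParams, simulate_dataset
from .training import (EvalReport, Sample, TrainConfig, cross_validate,
                       prepare_dataset)

__all__ = [
    "BenchmarkSettings",
    "branch_combinations",
    "make_dataset",
    "model_config_for",
    "run_combination",
    "run_ablation",
]


@dataclass(frozen=True)
class BenchmarkSettings:
    """Study conditions of the synthetic benchmark.

    The cohort (8 subjects × 6 classes × 10 trials, 64 frames, severity
    0.7, 5 mm noise) defines the data; the model and optimizer fields
    are sized for single-CPU training.  ``folds_per_seed`` LOSO folds
    are trained per seed (chosen deterministically from the seed), so a
    multi-seed run estimates the LOSO mean from a fold subsample rather
    than training all subjects × seeds × branch combinations.
    """

    n_subjects: int = 8
    trials_per_class: int = 10
    severity: float = 0.7
    noise_sd: float = 0.005
    t_target: int = 64
    branch_width: int = 8
    main_width: int = 16
    epochs: int = 10
    batch_size: int = 16
    lr: float = 5e-3
    folds_per_seed: int = 2


def branch_combinations() -> list[tuple[str, ...]]:
    """The seven nonempty branch subsets: 3 singles, 3 pairs, 1 triple."""
    combos: list[tuple[str, ...]] = []
    for k in (1, 2, 3):
        combos.extend(combinations(BRANCH_NAMES, k))
    return combos


def make_dataset(
    seed: int, settings: BenchmarkSettings | None = None
) -> list[Sample]:
    """Simulate and preprocess the benchmark cohort."""
    st = settings or BenchmarkSettings()
    shared = GaitParams(severity=st.severity, noise_sd=st.noise_sd,
                        n_frames=st.t_target)
    sequences = simulate_dataset(
        st.n_subjects, st.trials_per_class, shared=shared, seed=seed
    )
    return prepare_dataset(sequences, t_target=st.t_target)


def model_config_for(
    branches: tuple[str, ...], seed: int,
    settings: BenchmarkSettings | None = None,
) -> ModelConfig:
    st = settings or BenchmarkSettings()
    return ModelConfig(
        branch_width=st.branch_width,
        main_width=st.main_width,
        branches=tuple(branches),
        seed=seed,
    )


def train_config_for(
    seed: int, settings: BenchmarkSettings | None = None
) -> TrainConfig:
    st = settings or BenchmarkSettings()
    return TrainConfig(epochs=st.epochs, batch_size=st.batch_size,
                       lr=st.lr, seed=seed)


def run_combination(
    dataset: list[Sample],
    branches: tuple[str, ...],
    seed: int,
    settings: BenchmarkSettings | None = None,
    keep_models: bool = False,
):
    """Full LOSO cross-validation of one branch combination at one seed."""
    st = settings or BenchmarkSettings()
    mc = model_config_for(branches, seed, st)
    return cross_validate(dataset, mc, train_config_for(seed, st),
                          keep_models=keep_models)


def folds_for_seed(
    n_subjects: int, seed: int, n_folds: int
) -> list[int]:
    """Deterministic choice of which LOSO folds a seed trains."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(101,)))
    return sorted(rng.choice(n_subjects, size=n_folds,
                             replace=False).tolist())


def run_subsampled(
    dataset: list[Sample],
    branches: tuple[str, ...],
    seed: int,
    settings: BenchmarkSettings | None = None,
    keep_models: bool = False,
) -> tuple[EvalReport, list]:
    """LOSO estimate from ``folds_per_seed`` folds of one seed.

    Trains a fresh model per selected fold and pools their confusions.
    The returned models (with their held-out test samples) are reused
    for activation-map analysis.
    """
    from .model import build_mib_network
    from .training import evaluate, loso_splits, train

    st = settings or BenchmarkSettings()
    folds = loso_splits(dataset)
    chosen = folds_for_seed(len(folds), seed, st.folds_per_seed)
    by_id = {s.sample_id: s for s in dataset}
    mc = model_config_for(branches, seed, st)
    tc = train_config_for(seed, st)
    confusion = None
    per_fold, kept = [], []
    for fi in chosen:
        fold = folds[fi]
        train_set = [by_id[i] for i in fold.train_ids]
        test_set = [by_id[i] for i in fold.test_ids]
        model = build_mib_network(mc)
        train(model, train_set, model.branch_names, tc)
        report = evaluate(model, test_set)
        confusion = (report.confusion if confusion is None
                     else confusion + report.confusion)
        per_fold.append(report.accuracy)
        if keep_models:
            kept.append((model, test_set))
    acc = float(np.trace(confusion) / confusion.sum())
    return EvalReport(accuracy=acc, confusion=confusion,
                      per_fold=per_fold), kept


def run_ablation(
    seeds: list[int],
    settings: BenchmarkSettings | None = None,
    combos: list[tuple[str, ...]] | None = None,
    subsample: bool = True,
    keep_models_for: tuple[str, ...] | None = None,
) -> tuple[dict[tuple[str, ...], list[EvalReport]], list]:
    """Benchmark accuracy of branch combinations across seeds.

    The dataset is regenerated per seed (fresh subjects, fresh noise),
    so seed-to-seed spread reflects both cohort and training variation.
    With ``subsample`` each seed trains only its ``folds_per_seed``
    LOSO folds.  Models of the ``keep_models_for`` combination are
    retained (with their held-out samples) for downstream analysis.
    """
    st = settings or BenchmarkSettings()
    combos = combos if combos is not None else branch_combinations()
    results: dict[tuple[str, ...], list[EvalReport]] = {
        c: [] for c in combos
    }
    kept_models: list = []
    for seed in seeds:
        dataset = make_dataset(seed, st)
        for combo in combos:
            keep = keep_models_for is not None and combo == keep_models_for
            if subsample:
                report, kept = run_subsampled(
                    dataset, combo, seed, st, keep_models=keep)
            else:
                report, kept = run_combination(
                    dataset, combo, seed, st, keep_models=keep)
            results[combo].append(report)
            if keep:
                kept_models.extend(kept)
    return results, kept_models


def mean_accuracy(reports: list[EvalReport]) -> float:
    return float(np.mean([r.accuracy for r in reports]))
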