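"""Pairwise two-class evaluation of the four voting variants.

For a C-class dataset every unordered class pair becomes one two-class
task (C(C-1)/2 tasks; 45 for ten digit classes).  Per task the four
variants differ only in their smoothness-term set:

- ``independent``: empty set (plain per-point majority voting);
- ``neighbor_dependent``: a constant symmetric lambda on consecutive pairs
  (t, t+1) only;
- ``fully_dependent``: infinite terms on a connected pair graph, forcing a
  uniform labeling — identical to the conventional summed-distance
  nearest-prototype classifier;
- ``optimally_dependent``: the trained set of :mod:`seqvote.training`.

With multiple prototypes per class, a classifier bank exists for every
cross-class prototype pair and the bank used for a test sample is chosen by
Mahalanobis pre-selection on each class side.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SequencePattern
from .energy import INF, SmoothnessTermSet
from .inference import classify_pair
from .local_model import (
    ClassPrototype,
    LocalClassifierBank,
    adaptive_kmeans_prototypes,
    fit_class_prototype,
    preselect_prototype,
)
from .training import TrainingConfig, train_smoothness, training_accuracy

__all__ = [
    "VARIANTS",
    "EvaluationConfig",
    "PairwiseTaskResult",
    "EvaluationReport",
    "neighbor_dependent_termset",
    "full_termset",
    "choose_neighbor_lambda",
    "run_pairwise_evaluation",
    "export_smoothness_matrix",
    "read_smoothness_matrix",
]

VARIANTS = ("independent", "neighbor_dependent", "fully_dependent", "optimally_dependent")

NEIGHBOR_LAMBDA_GRID = (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)


def neighbor_dependent_termset(n_points: int, lam: float) -> SmoothnessTermSet:
    """Symmetric lambda on every consecutive pair (t, t+1), zero elsewhere."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out = SmoothnessTermSet()
    for t in range(n_points - 1):
        out.add(t, t + 1, lam)
    return out


def full_termset(n_points: int, lam: float = INF) -> SmoothnessTermSet:
    """Terms on every pair; with the default infinite lambda this is the
    fully-dependent variant (a chain of infinite terms would be equivalent,
    but the complete graph matches the zero-threshold initialization)."""
    out = SmoothnessTermSet()
    for t, tp in itertools.combinations(range(n_points), 2):
        out.add(t, tp, lam)
    return out


def choose_neighbor_lambda(unaries: Sequence[np.ndarray], truths: Sequence[int],
                           n_points: int,
                           grid: Sequence[float] = NEIGHBOR_LAMBDA_GRID) -> float:
    """Pick the neighbor-chain lambda maximizing training accuracy over a
    small logarithmic grid (ties go to the smallest lambda)."""
    best_lam, best_acc = None, -1.0
    for lam in sorted(grid):
        acc = training_accuracy(unaries, truths, neighbor_dependent_termset(n_points, lam))
        if acc > best_acc:
            best_lam, best_acc = lam, acc
    return float(best_lam)


@dataclass(frozen=True)
class EvaluationConfig:
    """Configuration of the pairwise evaluation driver.

    ``multiple_prototypes`` enables adaptive k-means (with
    ``cost_threshold``); otherwise one prototype per class.  ``variants``
    selects which smoothness regimes to evaluate.  ``neighbor_lambda`` may
    be fixed; if ``None`` it is chosen per task on the training samples.
    """

    variants: tuple[str, ...] = VARIANTS
    metric: str = "mahalanobis"
    squared: bool = False
    multiple_prototypes: bool = False
    cost_threshold: float = math.inf
    neighbor_lambda: float | None = None
    neighbor_lambda_grid: tuple[float, ...] = NEIGHBOR_LAMBDA_GRID
    training: TrainingConfig = field(default_factory=TrainingConfig)
    eps: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants {sorted(unknown)}")


@dataclass
class PairwiseTaskResult:
    """Accuracies of the evaluated variants on one class pair, measured on
    identical test samples."""

    class_pair: tuple[str, str]
    accuracies: dict[str, float]
    n_train: int
    n_test: int
    neighbor_lambda: float | None = None
    trained_pairs: list[tuple[int, int]] | None = None
    decisions: dict[str, list[int]] | None = None


@dataclass
class EvaluationReport:
    tasks: list[PairwiseTaskResult]

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def macro_average(self) -> dict[str, float]:
        """Unweighted mean accuracy over tasks, per variant."""
        out: dict[str, float] = {}
        for v in self.tasks[0].accuracies:
            out[v] = float(np.mean([t.accuracies[v] for t in self.tasks]))
        return out

    def weighted_average(self) -> dict[str, float]:
        """Test-sample-weighted mean accuracy over tasks, per variant."""
        out: dict[str, float] = {}
        total = sum(t.n_test for t in self.tasks)
        for v in self.tasks[0].accuracies:
            out[v] = float(sum(t.accuracies[v] * t.n_test for t in self.tasks) / total)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tasks:
            for v, acc in t.accuracies.items():
                rows.append({"class_a": t.class_pair[0], "class_b": t.class_pair[1],
                             "variant": v, "accuracy": acc,
                             "n_train": t.n_train, "n_test": t.n_test})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def aggregate_json(self, path: str | Path) -> None:
        payload = {
            "n_tasks": self.n_tasks,
            "macro_average": self.macro_average(),
            "weighted_average": self.weighted_average(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _group_by_class(samples: Sequence[SequencePattern]) -> dict[str, list[SequencePattern]]:
    out: dict[str, list[SequencePattern]] = {}
    for s in samples:
        if s.class_id is None:
            raise ValueError(f"sample {s.sample_id!r} has no class label")
        out.setdefault(s.class_id, []).append(s)
    return out


def run_pairwise_evaluation(train: Sequence[SequencePattern],
                            test: Sequence[SequencePattern],
                            config: EvaluationConfig | None = None,
                            ) -> EvaluationReport:
    """Evaluate every unordered class pair with the configured variants.

    Prototypes are fitted per class (adaptive k-means when
    ``multiple_prototypes``); per task a bank exists for every cross-class
    prototype pair, the smoothness set of each variant is built/trained per
    bank on the training samples routed to it by pre-selection, and every
    test sample is classified after pre-selecting the closest prototype on
    each class side.
    """
    config = config or EvaluationConfig()
    train_by_class = _group_by_class(train)
    test_by_class = _group_by_class(test)
    classes = sorted(train_by_class)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if not train_by_class[c]:
            raise ValueError(f"class {c!r} has no training samples")

    if config.multiple_prototypes:
        prototypes = adaptive_kmeans_prototypes(
            train_by_class, config.cost_threshold, seed=config.seed, eps=config.eps
        )
    else:
        prototypes = {c: [fit_class_prototype(train_by_class[c], class_id=c, eps=config.eps)]
                      for c in classes}

    tasks = []
    for ca, cb in itertools.combinations(classes, 2):
        tasks.append(_run_task(ca, cb, prototypes, train_by_class, test_by_class, config))
    return EvaluationReport(tasks)


def _route(samples: Sequence[SequencePattern], protos: Sequence[ClassPrototype],
           config: EvaluationConfig) -> list[int]:
    """Index of the pre-selected prototype for each sample."""
    by_cluster = {p.cluster_id: i for i, p in enumerate(protos)}
    return [by_cluster[preselect_prototype(s, protos, config.metric, config.squared).cluster_id]
            for s in samples]


def _run_task(ca: str, cb: str, prototypes: dict[str, list[ClassPrototype]],
              train_by_class: dict[str, list[SequencePattern]],
              test_by_class: dict[str, list[SequencePattern]],
              config: EvaluationConfig) -> PairwiseTaskResult:
    protos_a, protos_b = prototypes[ca], prototypes[cb]
    train_a, train_b = train_by_class[ca], train_by_class[cb]
    T = protos_a[0].n_points

    route_a = _route(train_a, protos_a, config)
    route_b = _route(train_b, protos_b, config)

    # one bank (and its variant term sets) per cross-class prototype pair
    banks: dict[tuple[int, int], LocalClassifierBank] = {}
    termsets: dict[tuple[int, int], dict[str, SmoothnessTermSet]] = {}
    chosen_lambda: float | None = None
    trained_pairs: list[tuple[int, int]] = []
    for i, pa in enumerate(protos_a):
        for j, pb in enumerate(protos_b):
            bank = LocalClassifierBank(pa, pb, metric=config.metric, squared=config.squared)
            banks[(i, j)] = bank
            pats = [s for s, r in zip(train_a, route_a) if r == i] + \
                   [s for s, r in zip(train_b, route_b) if r == j]
            sides = [0] * sum(1 for r in route_a if r == i) + \
                    [1] * sum(1 for r in route_b if r == j)
            sets: dict[str, SmoothnessTermSet] = {}
            if "independent" in config.variants:
                sets["independent"] = SmoothnessTermSet()
            if "fully_dependent" in config.variants:
                sets["fully_dependent"] = full_termset(T)
            need_unaries = ("neighbor_dependent" in config.variants
                            and config.neighbor_lambda is None)
            if need_unaries or "optimally_dependent" in config.variants:
                if not pats:
                    # no training sample routed here; fall back to untrained sets
                    if "neighbor_dependent" in config.variants:
                        sets["neighbor_dependent"] = neighbor_dependent_termset(
                            T, config.neighbor_lambda or 0.0)
                    if "optimally_dependent" in config.variants:
                        sets["optimally_dependent"] = SmoothnessTermSet()
                    termsets[(i, j)] = sets
                    continue
            if "neighbor_dependent" in config.variants:
                if config.neighbor_lambda is not None:
                    lam = config.neighbor_lambda
                else:
                    unaries = [bank.unary_costs(p.points) for p in pats]
                    lam = choose_neighbor_lambda(unaries, sides, T,
                                                 config.neighbor_lambda_grid)
                chosen_lambda = lam
                sets["neighbor_dependent"] = neighbor_dependent_termset(T, lam)
            if "optimally_dependent" in config.variants:
                trained = train_smoothness(bank, pats, sides, config.training)
                sets["optimally_dependent"] = trained.termset
                trained_pairs.extend(trained.termset.pairs)
            termsets[(i, j)] = sets

    test_samples = [(s, 0) for s in test_by_class.get(ca, [])] + \
                   [(s, 1) for s in test_by_class.get(cb, [])]
    hits = {v: 0 for v in config.variants}
    decisions: dict[str, list[int]] = {v: [] for v in config.variants}
    for sample, truth in test_samples:
        pa = preselect_prototype(sample, protos_a, config.metric, config.squared)
        pb = preselect_prototype(sample, protos_b, config.metric, config.squared)
        key = ({p.cluster_id: i for i, p in enumerate(protos_a)}[pa.cluster_id],
               {p.cluster_id: j for j, p in enumerate(protos_b)}[pb.cluster_id])
        bank = banks[key]
        for v in config.variants:
            res = classify_pair(sample, bank, termsets[key][v])
            decisions[v].append(res.decided_class)
            hits[v] += res.decided_class == truth
    n_test = len(test_samples)
    acc = {v: (hits[v] / n_test if n_test else math.nan) for v in config.variants}
    return PairwiseTaskResult(
        class_pair=(ca, cb),
        accuracies=acc,
        n_train=len(train_a) + len(train_b),
        n_test=n_test,
        neighbor_lambda=chosen_lambda,
        trained_pairs=sorted(set(trained_pairs)) or None,
        decisions=decisions,
    )


# ---------------------------------------------------------------------------
# Smoothness-matrix export (the pair-matrix visualizations as TSV)
# ---------------------------------------------------------------------------

def export_smoothness_matrix(termset: SmoothnessTermSet, n_points: int,
                             path: str | Path, binary: bool = False) -> None:
    """Write the T x T symmetric pair matrix as TSV (zero diagonal).

    Entries are the symmetric lambda values (``inf`` for infinite terms), or
    0/1 with ``binary=True``.  Round-trips through
    :func:`read_smoothness_matrix`.
    """
    termset.validate_for(n_points)
    M = np.zeros((n_points, n_points))
    for term in termset:
        val = 1.0 if binary else term.penalty_01
        M[term.t, term.t_prime] = val
        M[term.t_prime, term.t] = 1.0 if binary else term.penalty_10
    with open(path, "w") as fh:
        for row in M:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_smoothness_matrix(path: str | Path) -> SmoothnessTermSet:
    """Read a TSV pair matrix back into a term set (nonzero entries only)."""
    M = np.loadtxt(path, delimiter="\t", ndmin=2)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is not square: {M.shape}")
    out = SmoothnessTermSet()
    for t in range(M.shape[0]):
        for tp in range(t + 1, M.shape[0]):
            if M[t, tp] != 0.0 or M[tp, t] != 0.0:
                out.add(t, tp, float(M[t, tp]), float(M[tp, t]))
    return out
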