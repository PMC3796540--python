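"""Training the smoothness-term set.

The trained regularizer uses only *infinite* terms: a pair either forces
its two points to share a label or leaves them free.  Training has two
stages:

1. *Threshold initialization.*  Measure each local classifier's training
   accuracy; for a threshold theta, link every pair of points whose
   accuracies both exceed theta (strictly) with an infinite term.
   theta = 100% gives the empty set (independent voting); theta = 0% (with
   all accuracies positive) links every pair (fully-dependent voting).  The
   theta maximizing whole-pattern training accuracy is kept (ties go to the
   smallest theta, i.e. the denser set).

2. *Greedy error-correcting refinement.*  Scan the remaining zero-term
   pairs in a deterministic order; tentatively upgrade each to an infinite
   term and keep the change only if training accuracy strictly improves.
   Sweeps repeat until a full sweep accepts nothing (or ``max_sweeps``).
   Accuracy over n samples takes at most n+1 values and each acceptance
   strictly increases it, so the loop terminates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data import SequencePattern
from .energy import INF, EnergyModel, SmoothnessTermSet
from .inference import majority_vote, min_cut_assignment
from .local_model import LocalClassifierBank, local_accuracies

__all__ = [
    "TrainingConfig",
    "TrainingTrace",
    "TrainedSmoothness",
    "training_accuracy",
    "init_smoothness_by_threshold",
    "select_threshold",
    "refine_smoothness",
    "train_smoothness",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.0, 1.0, 101), 2))


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the smoothness-training loop.

    ``threshold_grid`` are candidate accuracy thresholds in [0, 1] (default
    0%, 1%, ..., 100%).  ``pair_scan_order`` orders the refinement scan:
    ``"distance"`` (default) visits pairs by ascending (|t - t'|, t),
    ``"lexicographic"`` by (t, t').  ``restart_on_change`` restarts the scan
    from the first pair after every acceptance instead of finishing the
    sweep.  ``max_sweeps`` caps the number of full sweeps.
    """

    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLDS
    pair_scan_order: str = "distance"
    max_sweeps: int = 50
    restart_on_change: bool = False

    def __post_init__(self) -> None:
        if not self.threshold_grid:
            raise ValueError("threshold_grid must be non-empty")
        if any(not 0.0 <= th <= 1.0 for th in self.threshold_grid):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.pair_scan_order not in ("distance", "lexicographic"):
            raise ValueError(f"unknown pair_scan_order {self.pair_scan_order!r}")


@dataclass
class TrainingTrace:
    """Audit log of the training loop: the chosen threshold, every tentative
    pair decision, and the training accuracy after each accepted change
    (non-decreasing by construction)."""

    threshold: float
    initial_accuracy: float
    decisions: list[tuple[tuple[int, int], bool]] = field(default_factory=list)
    accuracies: list[float] = field(default_factory=list)

    @property
    def final_accuracy(self) -> float:
        return self.accuracies[-1] if self.accuracies else self.initial_accuracy


@dataclass(frozen=True)
class TrainedSmoothness:
    """A trained term set with its provenance."""

    termset: SmoothnessTermSet
    trace: TrainingTrace
    local_accuracies: np.ndarray


def training_accuracy(unaries: Sequence[np.ndarray], truths: Sequence[int],
                      termset: SmoothnessTermSet) -> float:
    """Whole-pattern accuracy of dependent voting over precomputed unary
    tables (one (T, 2) table per sample, with its true side in ``truths``)."""
    if len(unaries) == 0:
        raise ValueError("need at least one sample")
    hits = 0
    for unary, truth in zip(unaries, truths):
        labels, _ = min_cut_assignment(EnergyModel(unary, termset))
        hits += majority_vote(labels, unary) == truth
    return hits / len(unaries)


def init_smoothness_by_threshold(accuracies: Sequence[float] | np.ndarray,
                                 theta: float) -> SmoothnessTermSet:
    """Link every pair whose two local accuracies strictly exceed ``theta``
    with an infinite smoothness term."""
    acc = np.asarray(accuracies, dtype=float)
    keep = np.flatnonzero(acc > theta)
    out = SmoothnessTermSet()
    for i, t in enumerate(keep):
        for tp in keep[i + 1:]:
            out.add(int(t), int(tp), INF)
    return out


def select_threshold(accuracies: Sequence[float] | np.ndarray,
                     unaries: Sequence[np.ndarray], truths: Sequence[int],
                     thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                     ) -> tuple[float, SmoothnessTermSet, float]:
    """Choose the threshold whose initialized set maximizes training
    accuracy; ties go to the smallest threshold.  Returns
    (theta, initialized set, its training accuracy).

    Thresholds yielding identical point sets are evaluated once.
    """
    if len(thresholds) == 0:
        raise ValueError("need at least one candidate threshold")
    acc = np.asarray(accuracies, dtype=float)
    best: tuple[float, SmoothnessTermSet, float] | None = None
    cache: dict[frozenset[int], float] = {}
    sets: dict[frozenset[int], SmoothnessTermSet] = {}
    for theta in sorted(thresholds):
        key = frozenset(np.flatnonzero(acc > theta).tolist())
        if key not in cache:
            termset = init_smoothness_by_threshold(acc, theta)
            sets[key] = termset
            cache[key] = training_accuracy(unaries, truths, termset)
        score = cache[key]
        if best is None or score > best[2]:
            best = (float(theta), sets[key], score)
    return best


def _scan_pairs(T: int, existing: SmoothnessTermSet, order: str) -> list[tuple[int, int]]:
    pairs = [(t, tp) for t in range(T) for tp in range(t + 1, T)
             if (t, tp) not in existing]
    if order == "distance":
        pairs.sort(key=lambda p: (p[1] - p[0], p[0]))
    else:
        pairs.sort()
    return pairs


def refine_smoothness(initial: SmoothnessTermSet, unaries: Sequence[np.ndarray],
                      truths: Sequence[int], config: TrainingConfig | None = None,
                      n_points: int | None = None,
                      trace: TrainingTrace | None = None,
                      ) -> tuple[SmoothnessTermSet, TrainingTrace]:
    """Greedy error-correcting refinement of a term set.

    Zero-term pairs are scanned in the configured order; each is tentatively
    upgraded to an infinite term and the change is accepted iff training
    accuracy strictly improves.  Stops when a full sweep accepts nothing.
    """
    config = config or TrainingConfig()
    T = n_points if n_points is not None else int(unaries[0].shape[0])
    current = SmoothnessTermSet(iter(initial))
    acc = training_accuracy(unaries, truths, current)
    if trace is None:
        trace = TrainingTrace(threshold=math.nan, initial_accuracy=acc)
    for _ in range(config.max_sweeps):
        changed = False
        scanning = True
        while scanning:
            scanning = False
            for pair in _scan_pairs(T, current, config.pair_scan_order):
                candidate = current.with_term(*pair, INF)
                cand_acc = training_accuracy(unaries, truths, candidate)
                accepted = cand_acc > acc
                trace.decisions.append((pair, accepted))
                if accepted:
                    current, acc = candidate, cand_acc
                    trace.accuracies.append(acc)
                    changed = True
                    if config.restart_on_change:
                        scanning = True
                        break
        if not changed:
            break
    return current, trace


def train_smoothness(bank: LocalClassifierBank,
                     patterns: Sequence[SequencePattern], sides: Sequence[int],
                     config: TrainingConfig | None = None) -> TrainedSmoothness:
    """Full training pipeline for one prototype pair.

    Measures per-point local accuracies, picks the best initialization
    threshold, then refines greedily.  ``sides`` are the true binary sides
    of the training patterns relative to the bank.
    """
    config = config or TrainingConfig()
    accs = local_accuracies(bank, patterns, sides)
    unaries = [bank.unary_costs(p.points) for p in patterns]
    truths = [int(s) for s in sides]
    theta, init, init_acc = select_threshold(
        accs, unaries, truths, config.threshold_grid
    )
    trace = TrainingTrace(threshold=theta, initial_accuracy=init_acc)
    termset, trace = refine_smoothness(
        init, unaries, truths, config, n_points=bank.n_points, trace=trace
    )
    return TrainedSmoothness(termset, trace, accs)
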