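"""Per-point local classifiers and class prototypes.

A class prototype is a sequence of per-point Gaussians (mean, covariance)
fitted from training patterns of one cluster.  At each point t a two-class
local classifier compares the cost of the input feature vector against the
two prototypes; the cost is the (non-squared) Euclidean or Mahalanobis
distance by default, with a squared-distance switch.  Multiple prototypes
per class come from adaptive k-means: k is incremented for the class with
the largest quantization error until every class is below a cost threshold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .data import SequencePattern

__all__ = [
    "PointGaussian",
    "ClassPrototype",
    "LocalClassifierBank",
    "euclidean_cost",
    "mahalanobis_cost",
    "fit_class_prototype",
    "local_label",
    "local_accuracy",
    "local_accuracies",
    "adaptive_kmeans_prototypes",
    "preselect_prototype",
    "summed_cost",
    "bank_to_dict",
    "bank_from_dict",
    "save_prototypes",
    "load_prototypes",
]


@dataclass(frozen=True)
class PointGaussian:
    """A d-dimensional Gaussian (mean, covariance); covariance must be
    symmetric positive-definite after regularization."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        d = mean.shape[0]
        if mean.ndim != 1 or cov.shape != (d, d):
            raise ValueError(f"mean/covariance shapes inconsistent: {mean.shape}, {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance not positive-definite after regularization") from exc
        object.__setattr__(self, "_chol", chol)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def euclidean_cost(x: np.ndarray, p: np.ndarray) -> float:
    """Euclidean distance ||x - p||."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {p.shape}")
    return float(np.linalg.norm(x - p))


def mahalanobis_cost(x: np.ndarray, gaussian: PointGaussian) -> float:
    """Mahalanobis distance sqrt((x - m)^T S^-1 (x - m))."""
    x = np.asarray(x, dtype=float)
    if x.shape != gaussian.mean.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {gaussian.mean.shape}")
    z = np.linalg.solve(gaussian._chol, x - gaussian.mean)
    return float(np.linalg.norm(z))


@dataclass(frozen=True)
class ClassPrototype:
    """Per-point Gaussian sequence for one cluster of one class.

    ``means`` has shape (T, d), ``covariances`` shape (T, d, d); every
    covariance is regularized positive-definite at construction.
    """

    class_id: str
    cluster_id: int
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        covs = np.asarray(self.covariances, dtype=float)
        if means.ndim != 2 or covs.shape != (*means.shape, means.shape[1]):
            raise ValueError(f"inconsistent shapes: means {means.shape}, covs {covs.shape}")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)
        # Cholesky factors once; reused for every Mahalanobis evaluation.
        try:
            chols = np.linalg.cholesky(covs)
        except np.linalg.LinAlgError as exc:
            raise ValueError("non-PD covariance in prototype") from exc
        object.__setattr__(self, "_chols", chols)

    @property
    def n_points(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def point_gaussian(self, t: int) -> PointGaussian:
        return PointGaussian(self.means[t], self.covariances[t])

    def mahalanobis_profile(self, points: np.ndarray) -> np.ndarray:
        """Per-point Mahalanobis distances of a (T, d) pattern, shape (T,)."""
        diff = np.asarray(points, dtype=float) - self.means
        # solve L z = diff for each t
        z = np.linalg.solve(self._chols, diff[..., None])[..., 0]
        return np.linalg.norm(z, axis=1)

    def euclidean_profile(self, points: np.ndarray) -> np.ndarray:
        diff = np.asarray(points, dtype=float) - self.means
        return np.linalg.norm(diff, axis=1)


def fit_class_prototype(samples: Sequence[SequencePattern], class_id: str | None = None,
                        cluster_id: int = 0, eps: float | None = None) -> ClassPrototype:
    """Fit per-point Gaussians from same-length patterns of one cluster.

    Per point t the mean is the sample mean of x_t and the covariance is the
    sample covariance plus ``eps * I`` shrinkage.  ``eps`` defaults to
    ``1e-6`` times the mean diagonal of the pooled covariance (floored at
    1e-12 for degenerate all-identical clusters), which keeps covariances
    invertible when clusters are small or points barely vary.
    """
    if not samples:
        raise ValueError("cannot fit a prototype from an empty cluster")
    X = np.stack([s.points for s in samples])  # (n, T, d)
    n, T, d = X.shape
    if class_id is None:
        class_id = samples[0].class_id or "?"
    means = X.mean(axis=0)
    diff = X - means
    if n > 1:
        covs = np.einsum("nti,ntj->tij", diff, diff) / (n - 1)
    else:
        covs = np.zeros((T, d, d))
    if eps is None:
        mean_diag = float(np.trace(covs.sum(axis=0))) / (T * d)
        eps = max(1e-6 * mean_diag, 1e-12)
    covs = covs + eps * np.eye(d)
    return ClassPrototype(str(class_id), cluster_id, means, covs)


@dataclass(frozen=True)
class LocalClassifierBank:
    """A two-class local classifier at every point.

    ``prototype_0`` plays binary label 0 and ``prototype_1`` label 1; the
    per-point cost g_t(x_t, w) is the distance of x_t to prototype w's
    Gaussian at t under ``metric`` ("mahalanobis" or "euclidean"), squared
    if ``squared`` is set.
    """

    prototype_0: ClassPrototype
    prototype_1: ClassPrototype
    metric: str = "mahalanobis"
    squared: bool = False

    def __post_init__(self) -> None:
        p0, p1 = self.prototype_0, self.prototype_1
        if (p0.n_points, p0.dim) != (p1.n_points, p1.dim):
            raise ValueError("prototypes disagree on (T, d)")
        if self.metric not in ("mahalanobis", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n_points(self) -> int:
        return self.prototype_0.n_points

    @property
    def dim(self) -> int:
        return self.prototype_0.dim

    def unary_costs(self, points: np.ndarray) -> np.ndarray:
        """The (T, 2) table of local-classifier costs for one pattern."""
        points = np.asarray(points, dtype=float)
        if points.shape != (self.n_points, self.dim):
            raise ValueError(
                f"pattern shape {points.shape} does not match bank "
                f"({self.n_points}, {self.dim})"
            )
        if self.metric == "mahalanobis":
            c0 = self.prototype_0.mahalanobis_profile(points)
            c1 = self.prototype_1.mahalanobis_profile(points)
        else:
            c0 = self.prototype_0.euclidean_profile(points)
            c1 = self.prototype_1.euclidean_profile(points)
        table = np.column_stack([c0, c1])
        return table**2 if self.squared else table


def local_label(bank: LocalClassifierBank, t: int,
                x_t: np.ndarray) -> tuple[int, tuple[float, float]]:
    """Label of the local classifier at point ``t`` (ties go to 0)."""
    if not 0 <= t < bank.n_points:
        raise IndexError(f"point index {t} outside 0..{bank.n_points - 1}")
    x_t = np.asarray(x_t, dtype=float)
    if bank.metric == "mahalanobis":
        c0 = mahalanobis_cost(x_t, bank.prototype_0.point_gaussian(t))
        c1 = mahalanobis_cost(x_t, bank.prototype_1.point_gaussian(t))
    else:
        c0 = euclidean_cost(x_t, bank.prototype_0.means[t])
        c1 = euclidean_cost(x_t, bank.prototype_1.means[t])
    if bank.squared:
        c0, c1 = c0 * c0, c1 * c1
    return (0 if c0 <= c1 else 1), (c0, c1)


def local_accuracies(bank: LocalClassifierBank, patterns: Sequence[SequencePattern],
                     sides: Sequence[int]) -> np.ndarray:
    """Per-point fractions of samples whose local label matches their side.

    ``sides[i]`` is the true binary side (0/1) of pattern i relative to the
    bank's prototype pair.  Invariant to sample order.
    """
    if len(patterns) == 0:
        raise ValueError("need at least one labeled sample")
    if len(patterns) != len(sides):
        raise ValueError("patterns and sides length mismatch")
    sides_arr = np.asarray(sides, dtype=int)
    hits = np.zeros(bank.n_points)
    for pat, side in zip(patterns, sides_arr):
        costs = bank.unary_costs(pat.points)
        labels = (costs[:, 1] < costs[:, 0]).astype(int)  # tie -> 0
        hits += labels == side
    return hits / len(patterns)


def local_accuracy(bank: LocalClassifierBank, t: int,
                   patterns: Sequence[SequencePattern], sides: Sequence[int]) -> float:
    """Recognition accuracy of the single local classifier at point ``t``."""
    return float(local_accuracies(bank, patterns, sides)[t])


def _class_cost(X: np.ndarray, k: int, seed: int) -> tuple[float, np.ndarray]:
    """k-means quantization error (mean squared distance to centroid)."""
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    return float(km.inertia_) / X.shape[0], assign


def adaptive_kmeans_prototypes(
    samples_by_class: dict[str, Sequence[SequencePattern]],
    cost_threshold: float,
    seed: int = 0,
    eps: float | None = None,
) -> dict[str, list[ClassPrototype]]:
    """Select multiple prototypes per class by adaptive k-means.

    Every class starts at k=1; while some class's quantization error (mean
    squared distance of concatenated T*d vectors to their centroid) is at or
    above ``cost_threshold``, k is incremented for the worst class and
    k-means re-run for it.  A class whose k reaches its sample count stops
    growing (with a warning).  Each resulting cluster is fitted into a
    :class:`ClassPrototype`.  Deterministic given ``seed``.
    """
    if not samples_by_class:
        raise ValueError("no classes given")
    flat = {c: np.stack([s.points.ravel() for s in ss])
            for c, ss in samples_by_class.items()}
    for c, X in flat.items():
        if X.shape[0] < 1:
            raise ValueError(f"class {c!r} has no samples")
    ks = {c: 1 for c in flat}
    costs: dict[str, float] = {}
    assigns: dict[str, np.ndarray] = {}
    capped: set[str] = set()
    for c, X in flat.items():
        costs[c], assigns[c] = _class_cost(X, 1, seed)
    while True:
        eligible = {c: v for c, v in costs.items() if c not in capped}
        if not eligible:
            break
        worst = max(sorted(eligible), key=lambda c: eligible[c])
        if costs[worst] < cost_threshold:
            break
        if ks[worst] + 1 > flat[worst].shape[0]:
            warnings.warn(
                f"class {worst!r}: k would exceed sample count; not incrementing",
                stacklevel=2,
            )
            capped.add(worst)
            continue
        ks[worst] += 1
        costs[worst], assigns[worst] = _class_cost(flat[worst], ks[worst], seed)
    out: dict[str, list[ClassPrototype]] = {}
    for c, ss in samples_by_class.items():
        out[c] = []
        for j in range(ks[c]):
            members = [s for s, a in zip(ss, assigns[c]) if a == j]
            out[c].append(fit_class_prototype(members, class_id=c, cluster_id=j, eps=eps))
    return out


def summed_cost(pattern: SequencePattern, prototype: ClassPrototype,
                metric: str = "mahalanobis", squared: bool = False) -> float:
    """Fully-dependent distance: the per-point costs summed over t."""
    if metric == "mahalanobis":
        prof = prototype.mahalanobis_profile(pattern.points)
    elif metric == "euclidean":
        prof = prototype.euclidean_profile(pattern.points)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    if squared:
        prof = prof**2
    return float(prof.sum())


def preselect_prototype(pattern: SequencePattern,
                        prototypes: Sequence[ClassPrototype],
                        metric: str = "mahalanobis",
                        squared: bool = False) -> ClassPrototype:
    """Pick the prototype with the smallest summed Mahalanobis distance.

    This is the pre-selection step used before two-class inference when a
    class has multiple prototypes; ties go to the lowest cluster_id.
    """
    if not prototypes:
        raise ValueError("need at least one prototype")
    best = None
    best_key = None
    for p in prototypes:
        key = (summed_cost(pattern, p, metric, squared), p.cluster_id)
        if best_key is None or key < best_key:
            best, best_key = p, key
    return best


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _proto_to_dict(p: ClassPrototype) -> dict:
    return {
        "class_id": p.class_id,
        "cluster_id": p.cluster_id,
        "means": p.means.tolist(),
        "covariances": p.covariances.tolist(),
    }


def _proto_from_dict(d: dict) -> ClassPrototype:
    return ClassPrototype(d["class_id"], int(d["cluster_id"]),
                          np.asarray(d["means"]), np.asarray(d["covariances"]))


def bank_to_dict(bank: LocalClassifierBank) -> dict:
    return {
        "metric": bank.metric,
        "squared": bank.squared,
        "prototype_0": _proto_to_dict(bank.prototype_0),
        "prototype_1": _proto_to_dict(bank.prototype_1),
    }


def bank_from_dict(d: dict) -> LocalClassifierBank:
    return LocalClassifierBank(
        _proto_from_dict(d["prototype_0"]),
        _proto_from_dict(d["prototype_1"]),
        metric=d.get("metric", "mahalanobis"),
        squared=bool(d.get("squared", False)),
    )


def save_prototypes(prototypes: dict[str, list[ClassPrototype]], path: str | Path) -> None:
    payload = {c: [_proto_to_dict(p) for p in ps] for c, ps in prototypes.items()}
    Path(path).write_text(json.dumps(payload))


def load_prototypes(path: str | Path) -> dict[str, list[ClassPrototype]]:
    payload = json.loads(Path(path).read_text())
    return {c: [_proto_from_dict(d) for d in ds] for c, ds in payload.items()}
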