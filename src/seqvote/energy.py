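"""The label-assignment energy: unary recognition costs plus pairwise
smoothness terms.

For a pattern of T points the binary label vector w = (w_0..w_{T-1}) is
scored by

    E(w) = sum_t g_t(x_t, w_t) + sum_{(t,t') in N} B_{t,t'}(w_t, w_{t'})

where g is the local-classifier cost table and each smoothness term B
penalizes differing labels on its pair: B(w, w') = 0 when w = w',
``penalty_01`` for (0, 1), ``penalty_10`` for (1, 0) (symmetric Potts,
penalty_01 == penalty_10 == lambda, in all shipped workflows).  Penalties
may be ``math.inf``, the "infinite smoothness term" that forbids the pair
from ever disagreeing.  With the empty pair set N the criterion decouples
into independent per-point decisions.

Every such term is submodular (B(0,0) + B(1,1) <= B(0,1) + B(1,0)), which
is what lets the global minimum be found by an s-t min-cut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "SmoothnessTerm",
    "SmoothnessTermSet",
    "EnergyModel",
    "smoothness_value",
    "total_energy",
    "check_submodularity",
    "infinite_sentinel",
]

INF = math.inf


@dataclass(frozen=True)
class SmoothnessTerm:
    """Pairwise penalty between points ``t`` and ``t_prime`` (t < t').

    ``penalty_01``/``penalty_10`` apply to label pairs (0,1)/(1,0); the
    equal-label penalties are fixed at 0 for terms built by this package
    (``penalty_00``/``penalty_11`` exist only so hypothetical non-Potts
    terms can be probed with :func:`check_submodularity`).
    """

    t: int
    t_prime: int
    penalty_01: float
    penalty_10: float
    penalty_00: float = 0.0
    penalty_11: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.t < self.t_prime:
            raise ValueError(f"need 0 <= t < t_prime, got ({self.t}, {self.t_prime})")
        if self.penalty_01 < 0 or self.penalty_10 < 0:
            raise ValueError("differing-label penalties must be >= 0")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.t, self.t_prime)

    @property
    def is_symmetric(self) -> bool:
        return self.penalty_01 == self.penalty_10

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.penalty_01) and math.isinf(self.penalty_10)


def smoothness_value(term: SmoothnessTerm, w: int, w_prime: int) -> float:
    """B(w, w') for binary labels."""
    if w not in (0, 1) or w_prime not in (0, 1):
        raise ValueError("labels must be binary")
    table = ((term.penalty_00, term.penalty_01), (term.penalty_10, term.penalty_11))
    return table[w][w_prime]


def check_submodularity(term: SmoothnessTerm) -> bool:
    """True iff B(0,0) + B(1,1) <= B(0,1) + B(1,0)."""
    return term.penalty_00 + term.penalty_11 <= term.penalty_01 + term.penalty_10


class SmoothnessTermSet:
    """The pair set N: a map from unordered point pairs to smoothness terms.

    At most one term per pair, no self-pairs; terms constructed through
    :meth:`add` have zero equal-label penalty and are therefore submodular
    by construction.
    """

    def __init__(self, terms: Iterable[SmoothnessTerm] = ()) -> None:
        self._terms: dict[tuple[int, int], SmoothnessTerm] = {}
        for term in terms:
            if term.pair in self._terms:
                raise ValueError(f"duplicate term for pair {term.pair}")
            self._terms[term.pair] = term

    # -- construction ------------------------------------------------------
    def add(self, t: int, t_prime: int, lam: float,
            lam_10: float | None = None) -> None:
        """Add a term with penalty ``lam`` for (0,1) and ``lam_10`` (default
        ``lam``, i.e. symmetric Potts) for (1,0); the pair may be given in
        either order."""
        if t == t_prime:
            raise ValueError("self-pairs are not allowed")
        a, b = (t, t_prime) if t < t_prime else (t_prime, t)
        p01 = lam if t < t_prime else (lam if lam_10 is None else lam_10)
        p10 = (lam if lam_10 is None else lam_10) if t < t_prime else lam
        if (a, b) in self._terms:
            raise ValueError(f"duplicate term for pair {(a, b)}")
        self._terms[(a, b)] = SmoothnessTerm(a, b, p01, p10)

    def with_term(self, t: int, t_prime: int, lam: float) -> "SmoothnessTermSet":
        """A copy with one extra symmetric term (the training loop's
        tentative change)."""
        out = SmoothnessTermSet(self._terms.values())
        out.add(t, t_prime, lam)
        return out

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], lam: float) -> "SmoothnessTermSet":
        out = cls()
        for t, tp in pairs:
            out.add(t, tp, lam)
        return out

    # -- mapping interface -------------------------------------------------
    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[SmoothnessTerm]:
        return iter(self._terms.values())

    def __contains__(self, pair: tuple[int, int]) -> bool:
        a, b = pair
        return (min(a, b), max(a, b)) in self._terms

    def get(self, t: int, t_prime: int) -> SmoothnessTerm | None:
        return self._terms.get((min(t, t_prime), max(t, t_prime)))

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self._terms)

    def max_index(self) -> int:
        return max((tp for _, tp in self._terms), default=-1)

    def validate_for(self, n_points: int) -> None:
        if self.max_index() >= n_points:
            raise ValueError(
                f"term set references point {self.max_index()} but T={n_points}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SmoothnessTermSet):
            return NotImplemented
        return self._terms == other._terms

    def __repr__(self) -> str:
        return f"SmoothnessTermSet({len(self._terms)} terms)"

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as ``t<TAB>t_prime<TAB>lambda`` rows, ``inf`` for the
        infinite term; asymmetric terms get a fourth column."""
        lines = ["t\tt_prime\tlambda\tlambda_10"]
        for (a, b), term in sorted(self._terms.items()):
            lines.append(f"{a}\t{b}\t{float(term.penalty_01)!r}\t{float(term.penalty_10)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SmoothnessTermSet":
        out = cls()
        lines = Path(path).read_text().splitlines()
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            t, tp = int(fields[0]), int(fields[1])
            p01 = float(fields[2])
            p10 = float(fields[3]) if len(fields) > 3 else p01
            out.add(t, tp, p01, p10)
        return out


@dataclass(frozen=True)
class EnergyModel:
    """Unary cost table (T, 2) plus a smoothness term set over its points."""

    unary: np.ndarray
    smoothness: SmoothnessTermSet = field(default_factory=SmoothnessTermSet)

    def __post_init__(self) -> None:
        unary = np.asarray(self.unary, dtype=float)
        if unary.ndim != 2 or unary.shape[1] != 2 or unary.shape[0] < 1:
            raise ValueError(f"unary table must be (T>=1, 2), got {unary.shape}")
        if not np.all(np.isfinite(unary)):
            raise ValueError("unary costs must be finite")
        object.__setattr__(self, "unary", unary)
        self.smoothness.validate_for(unary.shape[0])

    @property
    def n_points(self) -> int:
        return self.unary.shape[0]


def total_energy(model: EnergyModel, labels: Sequence[int] | np.ndarray) -> float:
    """E(w): unary costs of the assignment plus all smoothness penalties.

    Reduces to the independent (per-point) criterion when the pair set is
    empty; returns ``inf`` if the assignment separates an infinite term.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (model.n_points,):
        raise ValueError(
            f"assignment length {labels.shape} does not match T={model.n_points}"
        )
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary")
    e = float(model.unary[np.arange(model.n_points), labels].sum())
    for term in model.smoothness:
        e += smoothness_value(term, int(labels[term.t]), int(labels[term.t_prime]))
    return e


def infinite_sentinel(model: EnergyModel) -> float:
    """A finite surrogate for the infinite smoothness term.

    Strictly exceeds ``sum_t max_w g_t(w) + 1``, so no globally optimal
    assignment can ever pay it: cutting a sentinel-weighted pair costs more
    than the worst possible all-unary assignment.
    """
    return float(model.unary.max(axis=1).sum()) + 2.0
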