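"""Trajectory IO, preprocessing, and synthetic benchmark generation.

Trajectories are ordered sequences of d-dimensional points (pen-tip
positions, cell/particle track coordinates, ...). Before classification they
are brought to a canonical form: linear size normalization into the unit
hypercube followed by resampling to a fixed number of points ``T`` at
uniform arc-length spacing. All point indices in this package are 0-based.

Two on-disk dialects are supported:

``long_csv``
    Comma-separated with header ``sample_id,class,point_index,x0,x1,...``;
    ``point_index`` is 1-based ascending within each sample.

``uci_pendigits_orig``
    Best-effort reader for the "original/unprocessed" pen-based handwritten
    digit trajectory files (``.SEGMENT`` blocks with one ``x y`` pair per
    line). Pen-up/pen-down markers are ignored and strokes concatenated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawTrajectory",
    "SequencePattern",
    "SyntheticSpec",
    "read_trajectories",
    "write_trajectories",
    "normalize_size",
    "resample_arclength",
    "preprocess",
    "generate_synthetic_pair_dataset",
    "confusable_benchmark_spec",
]


@dataclass(frozen=True)
class RawTrajectory:
    """A variable-length trajectory before preprocessing.

    Parameters
    ----------
    sample_id : str
        Opaque identifier, preserved through preprocessing.
    class_id : str or None
        Class label; ``None`` for unlabeled inputs.
    points : ndarray of shape (L, d)
        Ordered coordinates, ``L >= 1``, all finite.
    """

    sample_id: str
    class_id: str | None
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: points must be a (L>=1, d>=1) "
                f"array, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def length(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


@dataclass(frozen=True)
class SequencePattern:
    """A fixed-length sequence of feature vectors, one per point t = 0..T-1."""

    sample_id: str
    class_id: str | None
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: points must be (T>=1, d), "
                f"got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_LONG_CSV_FIXED = ("sample_id", "class", "point_index")


def read_trajectories(path: str | Path, dialect: str = "long_csv") -> list[RawTrajectory]:
    """Read trajectories from ``path`` in the given dialect.

    Returns one :class:`RawTrajectory` per sample with point order as in the
    file and class labels preserved verbatim.
    """
    path = Path(path)
    if dialect == "long_csv":
        return _read_long_csv(path)
    if dialect == "uci_pendigits_orig":
        return _read_uci_pendigits_orig(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long_csv(path: Path) -> list[RawTrajectory]:
    if path.stat().st_size == 0:
        return []
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "class": str})
    except pd.errors.EmptyDataError:
        return []
    except (pd.errors.ParserError, ValueError) as exc:
        # pandas reports the offending line in its message
        raise ValueError(f"{path}: unparseable long_csv: {exc}") from exc
    missing = [c for c in _LONG_CSV_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    coord_cols = [c for c in df.columns if c not in _LONG_CSV_FIXED]
    if not coord_cols:
        raise ValueError(f"{path}: no coordinate columns after {_LONG_CSV_FIXED}")
    for col in ("point_index", *coord_cols):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: unparseable value in column {col!r} at line {bad[0] + 2}"
            )
    out: list[RawTrajectory] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("point_index", kind="stable")
        cls = grp["class"].iloc[0]
        pts = grp[coord_cols].to_numpy(dtype=float)
        out.append(RawTrajectory(str(sid), None if pd.isna(cls) else str(cls), pts))
    return out


_NUM_PAIR = re.compile(r"^\s*[-+0-9.eE]+(\s+[-+0-9.eE]+)+\s*$")


def _read_uci_pendigits_orig(path: Path) -> list[RawTrajectory]:
    out: list[RawTrajectory] = []
    label: str | None = None
    sid: str | None = None
    pts: list[list[float]] = []

    def flush() -> None:
        nonlocal pts
        if sid is not None and pts:
            out.append(RawTrajectory(sid, label, np.asarray(pts, dtype=float)))
        pts = []

    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith(".COMMENT") or s.startswith(".VERSION"):
            continue
        if s.startswith(".SEGMENT"):
            flush()
            quoted = re.findall(r'"([^"]*)"', s)
            label = quoted[-1] if quoted else None
            toks = s.split()
            sid = f"seg{toks[2]}" if len(toks) > 2 else f"line{lineno}"
            continue
        if s.startswith("."):  # .PEN_UP / .PEN_DOWN / .DT etc.
            continue
        if _NUM_PAIR.match(s):
            try:
                pts.append([float(v) for v in s.split()])
            except ValueError as exc:
                raise ValueError(f"{path}: unparseable line {lineno}: {s!r}") from exc
            if len(pts) > 1 and len(pts[-1]) != len(pts[-2]):
                raise ValueError(
                    f"{path}: inconsistent dimension in sample {sid!r} at line {lineno}"
                )
            continue
        raise ValueError(f"{path}: unparseable line {lineno}: {s!r}")
    flush()
    return out


def write_trajectories(trajectories: Sequence[RawTrajectory | SequencePattern],
                       path: str | Path) -> None:
    """Write trajectories as long_csv (round-trips with ``read_trajectories``)."""
    rows = []
    for traj in trajectories:
        for i, p in enumerate(traj.points, start=1):
            rows.append((traj.sample_id, traj.class_id, i, *p))
    d = trajectories[0].points.shape[1] if trajectories else 1
    cols = [*_LONG_CSV_FIXED, *(f"x{k}" for k in range(d))]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_size(traj: RawTrajectory, aspect_preserving: bool = True) -> RawTrajectory:
    """Linearly map a trajectory into the unit hypercube.

    With ``aspect_preserving=True`` (default) a single scale factor is used
    for all dimensions so the longest bounding-box side spans [0, 1] and the
    box is centered in the hypercube.  With ``aspect_preserving=False`` each
    dimension is stretched to [0, 1] independently.  Degenerate inputs
    (single point, or zero extent in every/that dimension) map to the
    hypercube center, keeping the operation total.
    """
    pts = traj.points
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    extent = hi - lo
    if aspect_preserving:
        emax = extent.max()
        if emax <= 0.0:
            out = np.full_like(pts, 0.5)
        else:
            scale = 1.0 / emax
            offset = (1.0 - extent * scale) / 2.0
            out = (pts - lo) * scale + offset
    else:
        out = np.empty_like(pts)
        for k in range(pts.shape[1]):
            if extent[k] <= 0.0:
                out[:, k] = 0.5
            else:
                out[:, k] = (pts[:, k] - lo[k]) / extent[k]
    return replace(traj, points=out)


def resample_arclength(traj: RawTrajectory, n_points: int = 49) -> SequencePattern:
    """Resample a polyline to exactly ``n_points`` at uniform arc-length spacing.

    Points are linearly interpolated along the polyline; the first and last
    output points equal the first and last input points exactly.  A
    zero-length polyline (single point or all points coincident) yields
    ``n_points`` copies of the first point.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    pts = traj.points
    if n_points == 1:
        if pts.shape[0] != 1:
            raise ValueError("n_points=1 is only allowed for single-point input")
        return SequencePattern(traj.sample_id, traj.class_id, pts.copy())
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) if pts.shape[0] > 1 else np.zeros(0)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        out = np.repeat(pts[:1], n_points, axis=0)
        return SequencePattern(traj.sample_id, traj.class_id, out)
    targets = np.linspace(0.0, total, n_points)
    out = np.column_stack(
        [np.interp(targets, cum, pts[:, k]) for k in range(pts.shape[1])]
    )
    out[0] = pts[0]
    out[-1] = pts[-1]
    return SequencePattern(traj.sample_id, traj.class_id, out)


def preprocess(traj: RawTrajectory, n_points: int = 49,
               aspect_preserving: bool = True) -> SequencePattern:
    """Size-normalize then arc-length resample (the standard pipeline)."""
    return resample_arclength(normalize_size(traj, aspect_preserving), n_points)


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a two-class synthetic trajectory benchmark.

    Each sample is its class template plus independent per-point Gaussian
    noise.  Inside ``confusable_segment`` (a 0-based half-open index range)
    the class-1 template is forced identical to the class-0 template, so the
    segment carries no class information.  At each index in
    ``outlier_points`` an additional large isotropic Gaussian deviation of
    scale ``outlier_scale`` is added with probability ``outlier_prob``,
    emulating gross local deviations (tracking glitches, stroke hesitation).

    ``noise_scale`` may be a scalar or a length-``n_points`` array of
    per-point standard deviations.  ``n_train``/``n_test`` are per class.
    """

    n_points: int = 49
    dim: int = 2
    template_0: np.ndarray | None = None
    template_1: np.ndarray | None = None
    noise_scale: float | np.ndarray = 0.05
    confusable_segment: tuple[int, int] | None = None
    outlier_points: tuple[int, ...] = ()
    outlier_prob: float = 0.0
    outlier_scale: float = 0.0
    n_train: int = 100
    n_test: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        T, d = self.n_points, self.dim
        if T < 1 or d < 1:
            raise ValueError("n_points and dim must be >= 1")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")
        noise = np.broadcast_to(np.asarray(self.noise_scale, dtype=float), (T,)).copy()
        if np.any(noise < 0):
            raise ValueError("noise scales must be >= 0")
        object.__setattr__(self, "noise_scale", noise)
        if self.confusable_segment is not None:
            a, b = self.confusable_segment
            if not (0 <= a < b <= T):
                raise ValueError(f"confusable_segment {a, b} outside 0..{T}")
        if any(not 0 <= t < T for t in self.outlier_points):
            raise ValueError("outlier_points outside 0..T-1")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must be in [0, 1]")
        if self.outlier_scale < 0:
            raise ValueError("outlier_scale must be >= 0")
        for name in ("template_0", "template_1"):
            tpl = getattr(self, name)
            if tpl is not None:
                tpl = np.asarray(tpl, dtype=float)
                if tpl.shape != (T, d):
                    raise ValueError(f"{name} must have shape {(T, d)}")
                object.__setattr__(self, name, tpl)

    def resolved_templates(self) -> tuple[np.ndarray, np.ndarray]:
        """Templates with defaults filled in and the confusable segment applied."""
        T, d = self.n_points, self.dim
        t0 = self.template_0 if self.template_0 is not None else _default_template(T, d, 0)
        t1 = self.template_1 if self.template_1 is not None else _default_template(T, d, 1)
        t1 = t1.copy()
        if self.confusable_segment is not None:
            a, b = self.confusable_segment
            t1[a:b] = t0[a:b]
        return t0, t1


def _default_template(T: int, d: int, cls: int) -> np.ndarray:
    """Two smooth digit-like curves in the unit box (an arc vs. an S-bend)."""
    s = np.linspace(0.0, 1.0, T)
    tpl = np.zeros((T, d))
    if cls == 0:
        tpl[:, 0] = 0.5 + 0.4 * np.cos(2 * np.pi * s)
        if d > 1:
            tpl[:, 1] = 0.5 + 0.4 * np.sin(2 * np.pi * s)
    else:
        tpl[:, 0] = 0.5 + 0.35 * np.cos(np.pi * s)
        if d > 1:
            tpl[:, 1] = 0.1 + 0.8 * s
    for k in range(2, d):
        tpl[:, k] = 0.5
    return tpl


def generate_synthetic_pair_dataset(
    spec: SyntheticSpec,
) -> tuple[list[SequencePattern], list[SequencePattern]]:
    """Generate a reproducible two-class train/test set from ``spec``.

    Class ids are ``"0"`` and ``"1"``.  Identical seeds yield bitwise
    identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.resolved_templates()
    noise = spec.noise_scale[:, None]

    def draw(template: np.ndarray, cls: str, n: int, split: str) -> list[SequencePattern]:
        out = []
        for i in range(n):
            pts = template + noise * rng.standard_normal(template.shape)
            for t in spec.outlier_points:
                if rng.random() < spec.outlier_prob:
                    pts[t] += spec.outlier_scale * rng.standard_normal(spec.dim)
            out.append(SequencePattern(f"{split}-{cls}-{i}", cls, pts))
        return out

    train = draw(t0, "0", spec.n_train, "train") + draw(t1, "1", spec.n_train, "train")
    test = draw(t0, "0", spec.n_test, "test") + draw(t1, "1", spec.n_test, "test")
    return train, test


CONFUSABLE_SEGMENT = (5, 10)
"""0-based half-open index range of the benchmark's confusable segment."""

OUTLIER_POINTS = (0, 1, 2)
"""Benchmark points receiving occasional gross deviations."""


def confusable_benchmark_spec(seed: int = 1) -> SyntheticSpec:
    """The canonical confusable-segment benchmark.

    Two classes share an identical middle segment (points 5..9 of 15, the
    confusable segment: its per-point votes are coin flips) and are
    moderately separated at the ten remaining points; the three beginning
    points additionally suffer occasional gross deviations (probability
    0.35, scale ten times the noise).  Evaluated with squared-Euclidean
    local costs (``EvaluationConfig(metric="euclidean", squared=True)``)
    this exhibits the trade-off the method targets: independent per-point
    voting is diluted by the coin-flip middle and the noisy per-point
    decisions, the summed-distance nearest-prototype rule (fully-dependent
    voting) is flipped outright by the gross deviations — a single
    deviating point contributes an unbounded term to the accumulated
    squared distance — while voting treats the same deviation as one bad
    ballot, and trained smoothness terms linking the clean informative
    points recover the decision.  Sizes are deliberately small (T=15,
    60 train / 50 test per class) so the full four-variant comparison runs
    in seconds; the default seed is part of the benchmark definition.
    """
    T, d = 15, 2
    s = np.linspace(0.0, 1.0, T)
    base = np.column_stack([s, 0.5 + 0.1 * np.sin(2 * np.pi * s)])
    t0 = base.copy()
    t1 = base.copy()
    informative = np.array([0, 1, 2, 3, 4, 10, 11, 12, 13, 14])
    t0[informative, 1] += 0.08
    t1[informative, 1] -= 0.08
    return SyntheticSpec(
        n_points=T,
        dim=d,
        template_0=t0,
        template_1=t1,
        noise_scale=0.07,
        confusable_segment=CONFUSABLE_SEGMENT,
        outlier_points=OUTLIER_POINTS,
        outlier_prob=0.35,
        outlier_scale=0.7,
        n_train=60,
        n_test=50,
        seed=seed,
    )
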