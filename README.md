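# seqvote — voting-based sequential pattern recognition

`seqvote` classifies variable-length sequential patterns — pen-tip
trajectories, cell/particle tracks, or any sequence of d-dimensional
feature vectors — by an ensemble of **per-point local classifiers whose
votes are regularized by pairwise smoothness terms and combined through a
globally optimal label assignment**.

## The method

A pattern is preprocessed to a fixed length (size normalization into the
unit hypercube, arc-length resampling to `T` points, default 49). For a
two-class problem a local classifier is prepared at every point `t`: the
cost `g_t(x_t, ω)` of labeling point `t` with class `ω ∈ {0, 1}` is the
Euclidean or Mahalanobis distance of `x_t` to class `ω`'s per-point
Gaussian prototype. The binary label vector `ω = (ω_1 … ω_T)` is chosen to
minimize

```
E(ω) = Σ_t g_t(x_t, ω_t)  +  Σ_{(t,t') ∈ N} B_{t,t'}(ω_t, ω_t')
```

where each smoothness term `B` is a Potts penalty: zero for equal labels
and `λ_{t,t'} ≥ 0` (possibly `∞`) for differing ones. Pairs in `N` may be
**distant** — the problem is then non-Markovian and out of reach for
dynamic programming, but every such term is submodular
(`B(0,0) + B(1,1) ≤ B(0,1) + B(1,0)`), so the exact global minimum is
found by an s-t min-cut in polynomial time. The optimized labels are
aggregated by **majority vote** into the final class.

Two limits recover classical rules: `λ ≡ 0` is independent per-point
voting; `λ ≡ ∞` on a connected pair graph forces a uniform labeling and is
identical to the conventional summed-distance nearest-prototype
classifier. In between, the smoothness terms are **trained**: points whose
local classifiers exceed an accuracy threshold are linked with infinite
terms (the threshold chosen to maximize training accuracy), then remaining
zero pairs are greedily upgraded whenever that strictly improves training
accuracy. Multiple prototypes per class come from adaptive k-means, with
Mahalanobis pre-selection of the closest prototype at test time.

## Worked example

`examples/confusable_benchmark.py` generates the canonical synthetic
benchmark — two trajectory classes sharing an identical (confusable)
middle segment, with occasional gross deviations at three beginning
points — and compares the four smoothness regimes:

```
test accuracy per variant:
           independent:  98.00 %
    neighbor_dependent:  97.00 %
       fully_dependent:  86.00 %
   optimally_dependent: 100.00 %

trained smoothness pairs: 21, of which 21 lie entirely outside the confusable segment
```

The summed-distance rule (`fully_dependent`) is flipped by the gross local
deviations — a single deviating point contributes an unbounded term to an
accumulated squared distance — while voting treats the same deviation as
one bad ballot. Independent voting is diluted by the coin-flip middle
votes. The trained terms link only the reliable informative points, and
`examples/train_and_inspect.py` prints the trained pair matrix showing
exactly that structure (a blank block over the confusable segment).
`examples/boundary_smoothing.py` shows the boundary-geometry view: the
fraction of a T=2 input grid receiving mixed labels falls monotonically
from 0.50 at `λ = 0` to 0 at `λ = ∞`. `examples/graphcut_vs_enumeration.py`
verifies the optimizer against exhaustive enumeration (agreement to
`4e-15`).

A thin CLI mirrors the library: `seqvote generate | preprocess | train |
classify | evaluate | export-matrix` (see `seqvote --help`). Trajectory
files use a long CSV format (`sample_id,class,point_index,x0,x1,…`); a
best-effort reader for the classic "original/unprocessed" pen-digit
trajectory dialect is included. All point indices in the API and in
serialized files are 0-based.

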