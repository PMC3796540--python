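# Methods

## Model

A sequential pattern is a sequence `x = (x_1 … x_T)` of d-dimensional
feature vectors; `T` is fixed by preprocessing. Two-class recognition is
posed as a binary label-assignment problem: every point gets a label
`ω_t ∈ {0, 1}` by minimizing

    E(ω) = Σ_t g_t(x_t, ω_t) + Σ_{(t,t') ∈ N} B_{t,t'}(ω_t, ω_t'),

and the pattern's class is the majority label of the minimizer. The unary
cost `g_t` comes from per-point class prototypes; each pairwise term `B`
is zero for equal labels and carries non-negative constants (one per
direction, collapsing to a single symmetric `λ` in every shipped
workflow; `λ = ∞` forbids disagreement outright). The pair set `N` is
unrestricted — in particular it may contain distant pairs, making the
objective higher-order Markovian. All such terms satisfy submodularity
`B(0,0) + B(1,1) ≤ B(0,1) + B(1,0)`, which is the exactness condition for
the min-cut solver below.

Assumptions worth stating: class-conditional features at a point are
modeled as a single Gaussian per prototype (multi-modality is handled by
multiple prototypes, not by mixture densities at a point); patterns are
assumed comparable point-by-point after linear size normalization and
arc-length resampling — no nonlinear time warping is performed.

## Solver

The energy is minimized exactly by an s-t min-cut. One graph node per
point; terminal capacities carry the unary costs (source side = label 0),
and a term with penalties `(λ_01, λ_10)` adds directed inter-node edges
`t → t'` with capacity `λ_01` and `t' → t` with `λ_10`. Before the flow
runs, pairs joined by an infinite term are contracted into super-nodes
(unary costs summed): an infinite term can never be cut at an optimum —
`infinite_sentinel` returns a finite surrogate strictly exceeding the
worst all-unary assignment plus one, proving the bound — so contraction
is exact and keeps every solver capacity finite. When no finite
inter-component term survives (the fully-dependent and trained-sentinel
workflows), the contracted problem decouples and is solved by
per-component argmin with no flow call at all.

Max-flow itself is networkx's Boykov–Kolmogorov implementation. The
source-side partition is *not* taken from `networkx.minimum_cut`: with
floating-point capacities, saturated edges can retain ±1e-16 residuals
that corrupt the reachability partition even though the flow value is
correct. The source side is instead recomputed by BFS over the residual
network using an explicit tolerance of `1e-12 × max capacity`. Solver
correctness is defined by oracle equivalence: on random submodular
instances (T ≤ 12, long-range pairs) the cut energy equals the exhaustive
`brute_force_min` enumeration to 1e-9 (tests and the acceptance script
re-verify this on 200 fresh instances per run).

Tie handling: ties in local labels, prototype pre-selection and the final
vote at even T (vote counts equal → smaller total unary cost → class 0)
are resolved deterministically toward the lower id; degenerate minimizers
of the energy may differ in labels but never in energy, and tests compare
energies.

## Preprocessing

`normalize_size` maps a trajectory into the unit hypercube with a single
scale factor (longest bounding-box side spans [0, 1], box centered);
aspect-preserving is the default because per-axis stretching distorts the
shape cues the local classifiers use, but a per-axis switch exists.
Degenerate (zero-extent) inputs map to the hypercube center, keeping the
operation total. `resample_arclength` interpolates linearly at uniform
arc-length spacing — invariant to the original sampling rate, the
standard choice for pen trajectories — preserving the endpoints bitwise.
`T` defaults to 49; an odd count avoids majority-vote ties.

## Local models

Prototypes are per-point Gaussians: mean = sample mean, covariance =
sample covariance + `ε·I` with `ε` defaulting to 1e-6 times the mean
diagonal (floored at 1e-12) — minimal shrinkage against degenerate
covariances from small clusters. The unary cost is the **non-squared**
distance by default (Euclidean, or Mahalanobis via per-point Cholesky
factors); a `squared` switch is provided since the choice is a genuine
modeling option — squaring does not change any individual local decision
but changes how costs accumulate across points (see the benchmark note
below). Multiple prototypes per class come from adaptive k-means on
concatenated `T·d` vectors: all classes start at k = 1, the class with
the largest quantization error (mean squared distance to centroid) gets
its k incremented and re-clustered until every class is under a
user-supplied cost threshold (k-means++ with a fixed seed; k is capped at
the class sample count with a warning). At test time the closest
prototype per class is pre-selected by the summed per-point Mahalanobis
distance, ties to the lowest cluster id.

## Training the smoothness terms

Trained terms are only ever infinite — a pair either must agree or is
free; no finite-λ tuning is attempted. Stage one links every pair of
points whose local-classifier training accuracies both strictly exceed a
threshold θ; θ is chosen from a 1 % grid over [0, 1] to maximize
whole-pattern training accuracy (θ = 100 % reduces to independent voting,
θ = 0 % to fully-dependent; ties go to the smallest θ, i.e. the denser
set — thresholds inducing identical point sets are evaluated once).
Stage two scans the remaining zero pairs in ascending `(|t − t'|, t)`
order — near pairs first, a deterministic documented choice; the order is
configurable — tentatively upgrading each to an infinite term and keeping
the change only on strict improvement of training accuracy. A full sweep
with no acceptance terminates the loop (restart-on-change is available
but off by default); since accuracy over n samples takes at most n + 1
values and each acceptance strictly increases it, termination is
guaranteed and bounded. Training accuracy is measured on the training
samples themselves, matching the algorithm's definition; a held-out
variant can be built by the caller by passing a different sample set.

## Evaluation driver

For a C-class dataset every unordered class pair is one two-class task
(C(C−1)/2). Four variants share the identical unary models and test
samples and differ only in `N`: independent (empty), neighbor-dependent
(constant λ on consecutive pairs; λ is a required configuration — it is
chosen per task by maximizing training accuracy over a small logarithmic
grid when unset), fully-dependent (infinite terms on all pairs), and
optimally-dependent (trained as above). With multiple prototypes a bank
exists per cross-class prototype pair; training samples are routed to
banks by pre-selection on their own class side. Reports carry both a
macro (per-task) and a test-sample-weighted average, since either
convention is defensible. The pair structure exports as a symmetric T×T
TSV matrix (zero diagonal, `inf` literal for infinite terms) that
round-trips losslessly.

## Synthetic data generator

`SyntheticSpec` draws each sample as its class template plus independent
per-point Gaussian noise (a per-point scale vector, shared by both
classes). Inside the `confusable_segment` the class-1 template is forced
identical to class-0, so those points carry no class information; at
`outlier_points` an additional large isotropic deviation of scale
`outlier_scale` is added with probability `outlier_prob`, independently
per point — emulating gross local deviations such as tracking glitches.
Generation is bit-reproducible given the seed. What the generator does
*not* emulate: temporal correlation of noise along the trajectory,
nonlinear time warping, within-class multimodality, and class-dependent
noise levels. Passing tests therefore demonstrate the method's behavior
under its own modeling assumptions, not robustness to those real-data
effects.

### The confusable-segment benchmark

`confusable_benchmark_spec` fixes the study conditions used by the tests
and the acceptance script: T = 15, d = 2, identical templates on points
5–9 (the confusable segment), a vertical separation of 0.16 at the ten
remaining points with noise σ = 0.07, gross deviations (probability 0.35,
scale 0.7 — ten times the noise) at the three beginning points, 60
training and 50 test samples per class, and a fixed seed that is part of
the benchmark definition. It is evaluated with **squared-Euclidean**
local costs: with squared distances one gross deviation contributes an
unbounded term to the accumulated (fully-dependent) distance, which is
precisely the failure mode the voting ensemble neutralizes — the same
deviation is a single wrong ballot. (Non-squared or Mahalanobis costs
bound or re-normalize the deviation's influence and largely hide the
phenomenon; the per-point *votes* are identical either way, as squaring
is monotone.) The geometry is chosen so that the clean informative points
form a voting majority on their own once linked: the trained block then
decides nearly every sample correctly, training accuracy saturates, and
greedy refinement has nothing to accept — so the trained structure is the
threshold initialization, which by construction links only points outside
the confusable segment. Expected behavior at the canonical seed:
independent ≈ 98 %, neighbor-dependent ≈ 97 %, fully-dependent ≈ 86 %,
optimally-dependent ≈ 100 %, all trained pairs outside the segment. The
deliberately small sizes keep the full four-variant comparison (including
threshold search and a complete refinement sweep) at about two seconds.

## Numerical and scale choices

- Oracle checks use 200 random instances with T ∈ [2, 12] (enumeration is
  2^T) and energy tolerance 1e-9; `brute_force_min` refuses T > 20 and
  breaks ties lexicographically.
- The T = 2 boundary probe (`mixed_label_fraction`) evaluates the four
  candidate assignments in closed form over a 201×201 input grid — for
  two points this *is* the exact global minimum — and cross-checks a
  random subsample of grid cells against the min-cut solver on every
  call. Mixed-label ties against a uniform assignment count as uniform,
  so the fraction is exactly 0 at the infinite term.
- k-means uses `n_init=10` and a caller-supplied seed; clustering cost is
  the mean squared distance to the assigned centroid.

## Known limitations

Two classes per energy (multi-class runs as pairwise tasks); no time
warping inside the energy; only distance-based local classifiers ship
(the bank interface accepts any per-point cost table); non-submodular
terms are rejected, not approximated; the greedy trainer explores single
pair flips only and can stop in a local optimum of training accuracy.
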