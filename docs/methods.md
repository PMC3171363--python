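# Methods

## Model and procedure

All three clustering routines minimize the within-class variance
SSE = Σᵢ Σ_{x∈Cᵢ} ‖x − cᵢ‖², differing only in how centers move:

- **Batch (Lloyd).** Alternate full nearest-center reassignment and exact
  centroid recomputation. Each half-step lowers SSE, so the recorded MSE
  trace is non-increasing and membership stability is an exact convergence
  certificate.
- **Online (MacQueen).** Records are presented one at a time; the winning
  center, having won n points so far (its initializing record counts as the
  first win), moves by (x − c)/(n+1) and therefore always equals the running
  mean of the points it has won. Win counts persist across epochs.
- **Adaptive online (the package's main method).** The winning center moves
  by η(t)(x − c) with a single rate per epoch, decayed after each epoch by
  η ← η·exp(−1/√(k + t)) where k is the number of clusters and t the epoch
  counter starting at 1. The schedule gives a large clustering rate early
  and a small steady-state step late. η is deliberately updated once per
  epoch, not per record: the schedule is time-indexed, and per-record decay
  would make the effective rate depend on N.

All methods initialize centers as k distinct records drawn uniformly
without replacement (seeded). Ties in nearest-center competitions always go
to the lowest center index. Labels returned to the caller are the
nearest-center assignment under the final centers.

### Stopping rules

Every method stops at `max_iter` (default 20 epochs) or when the maximum
per-center displacement over an epoch falls below `epsilon` (default 1e-4,
coordinate units), or when the relative change in MSE falls below 1e-8.
The batch method additionally stops when membership repeats exactly. The
online methods do **not** stop on membership stability: their centers keep
a residual jitter of order √(η/2)·(within-cluster spread) while η is still
large, so a stable partition does not imply converged centers; stopping
there would freeze the centers mid-schedule and waste the decaying-rate
design. Letting the schedule run (or the displacement test fire) leaves the
final centers within O(√η_final) of the running means — in practice a few
hundredths of the cluster spread after 20 epochs.

### Dead centers

A center that owns no records at an epoch's end is a *dead center*. By
default it is left in place and reported (`dead_centers` in results and
reports) rather than hidden. With `reseed_dead=True` (CLI
`--reseed-dead`) each dead center is relocated to the record farthest from
its nearest center, a cheap coverage-restoring heuristic.

## The k-d tree and lossless filtering

The tree recursively splits each cell's longest side at its midpoint
(ties to the lowest dimension index); points exactly on the split go left.
Cell boxes are the tight bounds of the points they contain, so a midpoint
split of a non-degenerate side always separates the points into two
nonempty groups; the slide-to-median fallback only fires on floating-point
degeneracies, and a cell whose points all coincide becomes a leaf even
above `leaf_size` (default 10). Each node stores its subtree's point count
and coordinate sum.

Assignment uses candidate filtering: starting at the root with all centers,
a candidate is pruned for a cell when the cell's winning candidate (the one
nearest the cell midpoint) is strictly closer for every point of the cell's
box — evaluated in closed form at the box corner extremal in the direction
between the two centers. When one candidate survives, the whole subtree is
assigned in bulk from the stored count/sum. Pruning is tolerance-guarded
(a relative 1e-12 error bound on the corner margin): near-ties and
coincident centers are *not* pruned but resolved at the leaf scan, which
uses the same distance arithmetic as a brute-force pass, so filtered
assignments equal brute-force assignments bitwise, including tie-breaks.

The sequential adaptive pass cannot use bulk filtering directly because
centers move within the epoch. Instead, a best-two filtering pass at epoch
start records each point's nearest and second-nearest center distances
(d1, d2); during the pass the per-center drift since epoch start is
tracked, and by the triangle inequality only centers whose drift exceeds
d2 − d1 − drift(winner) can have overtaken the point's epoch-start winner.
Only those "suspect" centers are evaluated (with a small absolute slack,
1e-9 of the data span, guarding rounding); most points need zero distance
evaluations. The instrumented point-to-center distance-evaluation count
(`n_dist_evals` on results) is the hardware-independent measure of the
speed advantage; wall-clock time is reported in benchmarks but never
asserted.

## Validity statistics

- **SSE** as above; **MSE(dB) = 10·log₁₀(SSE/N)**. The decibel transform of
  a squared-error (power-like) quantity uses the 10·log₁₀ convention; an
  exact zero SSE has no finite dB value and raises a dedicated error.
- **Davies-Bouldin index** with the classical q = 1 dispersion (mean plain
  Euclidean member-to-center distance): DBI = (1/k)Σᵢ maxⱼ≠ᵢ (eᵢ+eⱼ)/Dᵢⱼ.
  Dead clusters are excluded with a warning and k reduced; coincident
  centers of two live clusters are an error (zero Dᵢⱼ). The report carries
  all intermediates (dispersions, center distances, pairwise ratios).

## Post-processing

Per cluster, each member's Euclidean distance to its center is summarized
by Tukey quartiles (linear interpolation between order statistics, the
`statistics.quantiles(method="inclusive")` convention) and records beyond
Q3 + 1.5·IQR are flagged. Only the upper fence is used: distances are
non-negative and right-skewed, and the targets are extreme-distance
records. Clusters with fewer than four members get fences but no flags;
empty clusters are listed as dead.

The benchmark harness runs each method on seeded subsamples of
10%, 20%, …, 100% of the data (drawn without replacement; the same
subsample is shared by the three methods at each fraction so the comparison
is paired) and records n, wall seconds and final MSE(dB) per
(method, fraction) — 30 records for the default grid.

## Synthetic data generator

The generator emulates georeferenced point datasets with known structure:
equal-size planar Gaussian clusters whose centers are drawn uniformly in a
box. Defaults are 10 clusters × 3,600 points in 2-D — the full-scale
synthetic configuration the package's headline check uses — with unit
within-cluster spread and a (0, 100)² center box.

- *Separable mode* (default) enforces pairwise center separation of at
  least 6 within-cluster standard deviations by rejection sampling (error
  if infeasible in the box), so ground truth is recoverable and the
  generator doubles as a test oracle.
- *Hard mode* drops the constraint, letting clusters run together at the
  edges.
- *Density gradient* scales each cluster's spread linearly with its
  center's distance from the origin (sd × (0.5 + r/r_max)), reproducing the
  structure where clusters near the origin are concentrated and far ones
  diffuse. Separation in this mode is taken relative to the largest spread.
- *Binary indicator columns* append per-cluster Bernoulli 0/1 features
  (success probabilities drawn once per cluster from U(0.1, 0.9)), mimicking
  exposure flags attached to case locations.

What the generator does **not** emulate: real street-network/census-block
geometry, spatial autocorrelation beyond cluster membership, non-Gaussian
cluster shapes, and measurement error. Tests passing on this generator
demonstrate algorithmic correctness and recoverability under the stated
conditions, not performance on any particular real dataset.

## Test and verification design

- Every accelerated path is checked against an independent naive
  implementation kept in the test suite: linear-scan nearest neighbor,
  brute-force assignment, a standalone sequential adaptive run (bitwise
  comparison), a loop-based Davies-Bouldin reference (plus scikit-learn's
  implementation for the centroid-centered special case), and
  `statistics.quantiles` for box-plot fences.
- The parameter-recovery check uses 3 separable blobs × 300 points and, for
  each method, the lowest-SSE run of 20 seeded restarts — the standard
  multi-restart k-means estimator; a single random-init run of any k-means
  variant has substantial probability of a doubled/missed blob, which is a
  property of the initialization, not of the update rules under test.
  Recovered centers are compared to the blobs' *sample* means: the batch
  method reproduces those exactly, so the 3·sd/√n per-coordinate tolerance
  then measures the online methods' residual step-size noise rather than
  the generator's own sampling noise.
- Problem sizes in the suite (hundreds to 10,000 points) keep the full run
  around a quarter of a minute; the acceptance script runs the full-scale
  36,000-point configuration in seconds.

## Known limitations

- The filtering fast path falls back to near-full scans in early epochs,
  while centers travel far from their initial positions; the asymptotic
  advantage appears once centers localize.
- k is user input; no model selection is provided.
- No feature scaling by default (an optional z-score flag exists in the
  CLI); mixed coordinate/indicator columns are clustered in raw units,
  matching the upstream practice this package follows.
- GeoJSON export writes coordinates as given; reprojection/CRS handling is
  out of scope.
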