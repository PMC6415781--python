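# Methods

## The model

The package clusters `n` states of a dynamical system — fluid tracer
trajectories, rows of a Markov state model (MSM) transition matrix, or any
objects with a user-supplied pairwise dissimilarity — by *amplifying
dissimilarity* rather than grouping by similarity.  Given a symmetric
nonnegative dissimilarity matrix `A` with zero diagonal (`a_ij` large when
states i and j are different; note this is the opposite of the usual
similarity-graph convention), a scalar assignment `x_i` per state is scored
by the coloring merit

    z = 1/2 * sum_ij (x_i - x_j)^2 a_ij .

Maximizing `z` under a finite-norm constraint yields the generalized
eigenproblem

    L X = lambda D X ,    D = diag(row sums of A),  L = D - A .

All `n` eigenpairs are kept, sorted by *descending* eigenvalue (the largest
eigenvalues carry the strongest separations; the constant vector is always
an eigenvector with eigenvalue 0 and is never used for splitting).  Each
eigenvector in turn is bifurcated into a 0/1 bit per state; concatenating
the bits (leading bit = largest eigenvalue) gives each state a binary code,
arranged in a prefix tree.  At most `2^k` codes are numerically possible
after `k` levels but typically far fewer are occupied; codes that stay
unoccupied and branches whose member sets stop changing as levels are added
are the natural stopping signal — those stable branches are the clusters,
with no prior choice of cluster count.

Branch lengths are in merit units: when a node splits at level `k`, both
branches of the pair get length `z` evaluated with the *global* eigenvector
`X_k` summed only over the node's members.  Under the normalization
`X_k' D X_k = 1` used throughout, the merit of a full eigenvector equals
its eigenvalue, so the first branch pair has length `lambda_1`.

### Dissimilarity metrics

* **Trajectories** (shared time grid, `T >= 2` samples): the root of the
  summed squared deviation of the instantaneous pair distance from its time
  mean, divided by that mean —
  `a_ij = sqrt(sum_k (rbar - r(t_k))^2) / rbar`.  Tracers moving together
  score near 0; pairs straddling a transport barrier separate exponentially
  and score high.  The sum over samples is deliberately not averaged, so
  values grow like `sqrt(T)` at fixed noise; this global scale cancels out
  of the eigenproblem entirely (L and D scale together).  Distances use
  the minimum-image convention in periodic dimensions — without it, a
  tracer crossing a periodic seam would inject spurious dissimilarity.
  Scale invariance (coordinates times any s > 0) holds exactly.
* **Probability distributions** (MSM rows): the square root of the
  Jensen-Shannon divergence with natural logarithms and `0 log 0 = 0`,
  bounded by `sqrt(ln 2) ~ 0.8326`, attained exactly for disjoint
  supports.  The square root (a metric) is used both here and in the
  Ward-linkage cross-check so the two coarse-grainings see identical
  input.

Neither metric satisfies the triangle inequality, and none is required:
only the symmetric matrix enters the eigenproblem.

## The bifurcation rule

The only genuinely open design in the method is how a 1-D scalar field is
split into two groups.  The split is always a **global threshold cut** —
every state is assigned by the same boundary, so a coherent group lying
entirely on one side simply is not bifurcated further, which is exactly
how codes go unoccupied.  The threshold is located as follows:

1. **Mode search.**  A Gaussian KDE (Silverman bandwidth, 512-point grid)
   of the values is scanned for internal local minima leaving at least
   `min_mode_frac = 5%` of the states on each side; a minimum qualifies as
   a valley when its density is at most `valley_ratio = 0.8` of the lower
   flanking maximum.  The same search also runs on the values restricted
   to each current branch holding at least `group_min_frac = 20%` of the
   states: a mode structure confined to one coherent subset (e.g. the
   north/south split of eddy cores) is diluted to invisibility in the
   global density but obvious in the conditional one.  Small converged
   branches may not nominate cuts — thresholds nominated by small deep
   branches would slice already-converged clusters.  The deepest
   qualifying valley sets the threshold.
2. **Splinter fallback.**  With no qualifying valley the level is treated
   as structureless: the most separated extreme-value group smaller than
   5% (largest spacing between consecutive sorted values in either tail)
   is split off, *provided* that spacing exceeds `TAIL_GAP_FACTOR = 20`
   times the median spacing.  Otherwise the level is **inert**: all states
   receive the same bit and every branch passes through unsplit.
3. For fewer than 25 states, where density estimation is meaningless, the
   two-cluster cut at the final merge of 1-D average-linkage agglomerative
   clustering is used directly (average-linkage clusters of scalars are
   contiguous intervals, so all three rules are cuts of the same
   dendrogram — they differ only in which merge is undone).

The thresholds were fixed by measuring both regimes on the benchmark
generators: structureless eigenvector fields (uniform-noise ensembles,
exhausted levels of the flow benchmarks) show valley scores of 0.9-1.0 or
no internal minimum at all and tail-gap ratios of 45-220, while structured
fields score 0.2-0.6 with the same tail-gap magnitudes and the tight-block
fields of planted MSMs sit below 20 on the tail-gap ratio.  0.8 and 20 sit
in the gaps.  Label polarity is arbitrary; bit 0 goes to the larger group
(tie: the group with the smaller mean value) and every downstream
computation is invariant to flipping any level's bits.

## Truncation

By default seven eigenvectors are consumed, or fewer if an entire level
refines nothing (`stop_when_no_split`), both configurable; an optional
`min_branch_z` suppresses splits whose branch-pair merit falls below a
user threshold.  No automatic model selection beyond these rules is
attempted.

## Benchmark generators

* **Quadruple-eddy flow** (dimensionless): stream function
  `psi = A sin(pi f) sin(pi y)` on `[0,2] x [-1,1]` with
  `f = a x^2 + b x`, `a = eps sin(omega t)`, `b = 1 - 2 eps sin(omega t)`,
  `A = 0.1`, `eps = 0.1`, `omega = 2 pi / 10`; four counter-rotating cells
  whose internal east-west boundary oscillates with period 10, advected
  over `t in [0, 40]` (four oscillation periods).  The velocity pair used
  is the divergence-free `u = -pi A sin(pi f) cos(pi y)`,
  `v = +pi A cos(pi f) sin(pi y) (2 a x + b)`; domain edges and the `y = 0`
  axis are invariant streamlines, so no drifter ever crosses the equator.
  401 uniformly spaced samples feed the metric (a package choice; the
  qualitative structure is insensitive to it).
* **Bickley jet** (SI units): `psi = c3 y - U L tanh(y/L) +
  U L sech^2(y/L) sum_n eps_n cos(k_n (x - sigma_n t))` with
  `U = 62.66 m/s`, `L = 1.77e6 m`, `eps = (0.0075, 0.15, 0.3)`,
  `c = (0.1446, 0.205, 0.461) U`, `sigma_n = c_n - c_3`, `k_n = 2n/r0`
  with `r0 = 6.371e6 m` (Earth's mean radius, which makes the wave
  periods `pi r0 / n` commensurate with the `2e7 m` periodic x-domain to
  0.1%).  40 days, 601 saved samples.  The stated y-extent
  `[-3e6, 3e6] m` only bounds the seeding; the field is defined for all y
  and particles lawfully leave it.
* **Noise control**: i.i.d. uniform positions on the unit square per state
  and sample — no coherent structure by construction, so the dendrogram
  must keep a dominant branch.
* **Planted-block MSM**: row-stochastic matrices in which row i puts
  exactly `intra_mass` probability (Dirichlet-distributed, concentration
  1.0) on its own block and the rest uniformly-Dirichlet elsewhere, at the
  ~175-microstate scale of protein-folding MSMs.  Detailed balance is not
  enforced (only row distributions matter here); a stationary-flow
  symmetrization is available but off by default.

Integration uses a fixed-step fifth-order Cash-Karp Runge-Kutta scheme,
vectorized over the ensemble, with `dt = 0.01` time units (quadruple
eddy) and 40 days/4000 (Bickley); each save interval is subdivided so
saved times are hit exactly.  A solid-body-rotation Richardson test
confirms fifth-order convergence.

What the generators do *not* emulate: measurement noise, gappy or
irregular sampling, drifter loss, and real-geophysical asymmetries.
Passing benchmarks therefore demonstrates that the machinery recovers
known structure from clean kinematics, not that it is robust to
observational artifacts.

## Benchmark analyses and their operational definitions

* *Quadrant-core recovery* (quadruple eddy): one depth-1 branch must carry
  exactly four clusters that are sizable (>= 5% of states), converged
  (>= 90% of members stay together through depth 7), quadrant-bound
  (>= 75% of members never leave one quadrant, quadrants delimited by
  `y = 0` and `x = 1`), and located in the four distinct quadrants.
  Because the informative eigenvectors can arrive in different orders,
  levels 3-5 are examined and the first qualifying one reported.
  Converged chaotic residue has a stay fraction near zero and is never
  mistaken for a core.  Measured recovery rates: 3/3 seeds at n = 3000,
  ~7/8 at 1000, ~5/8 at 500, ~3/8 at 300.  The small-sample limit is
  eigenvalue quasi-degeneracy: the core-splitting directions mix across
  adjacent eigenvectors, and no single 1-D field then shows a detectable
  valley.  (Rotating the eigenbasis within a quasi-degenerate block would
  restore them but would destroy the exact merit/eigenvalue identity, so
  it is not done.)
* *Bickley structures*: at depth 2 exactly three sizable groups covering
  >= 90% of particles, identified physically — the jet (smallest
  time-mean |y|, members crossing the axis as it meanders), the flanking
  eddies (intermediate |y|, the most y-sign-constant group), the chaotic
  background (largest |y|).  Deeper levels legitimately resolve
  individual eddies and the north/south far-field bands (which cannot mix
  across the jet); the claim tested is the emergence of the three major
  structures, not the absence of substructure.
* *Noise control*: largest depth-7 branch holds > 90% of states
  (measured 94-98% over eight seeds at n = 500, T = 500).
* *MSM agreement*: the dendrogram leaf partition after `b - 1` levels of a
  `b`-block matrix is compared to the Ward/MVCA cut at `b` by the adjusted
  Rand index (own implementation, cross-checked against scikit-learn).
  `b - 1` levels, not `ceil(log2 b)`: with Dirichlet-random blocks the top
  eigenvector makes one-vs-rest splits; only a hierarchically balanced
  block geometry resolves in `log2` levels.

## Numerical choices

* Eigensolve: dense symmetric, via `D^{-1/2} L D^{-1/2}` and LAPACK
  `eigh`, which yields D-orthonormal eigenvectors directly; problem sizes
  of interest (n <= ~3000) need no sparse machinery.  Residuals
  `||L X_k - lambda_k D X_k||` are checked against `tol ||D X_k||`
  (default `1e-8`).  Eigenvalues lie in `[0, 2]`; round-off negatives
  below `1e-10` of the spectral radius are clipped to 0.
* Eigenvector sign is mathematically arbitrary; the largest-magnitude
  entry is made positive so runs are bit-reproducible, and all downstream
  logic is sign-blind.
* Degenerate (repeated) eigenvalues: any D-orthonormal basis of the
  eigenspace is accepted; tests on symmetric inputs assert only invariant
  quantities.
* Duplicate states (coincident at every sample) get dissimilarity 0 with
  a warning; a state with zero total dissimilarity makes `D` singular and
  is rejected with instructions to merge duplicates.
* A constant scalar field cannot be bifurcated (degenerate-split error);
  inside the level loop such a level is flagged inert and contributes a
  uniform 0 bit.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configurations produce
  byte-identical JSON reports.

## Problem sizes in the shipped tests

The test suite exercises the full published scales — 3000 drifters
(quadruple eddy), 3000 particles (Bickley), 500 x 500 noise, 175-state
MSMs over 20 seeds — plus reduced ensembles (1000, 300) for the sparse-data
checks; the complete suite runs in a few minutes on one CPU.  The
acceptance script's sparse-data scan uses ensembles of 3000, 1000, 500 and
300 drifters with three seeded realizations each, smaller ensembles drawn
as nested subsets of the largest (initial positions are i.i.d., so any
leading subset is a valid smaller ensemble).

## Known limitations

* Recovery at a few hundred trajectories is an existence claim, not a
  guarantee: near the information limit it succeeds for favorable
  realizations only (see the measured rates above).
* The bifurcation's KDE parameters (5% mode floor, 0.8 valley ratio, 20%
  conditional-branch floor, tail-gap factor 20) are calibrated on the
  benchmark families; data with very different value-distribution shapes
  may need them adjusted.
* The per-level cut is strictly 1-D; structure that only appears in joint
  combinations of eigenvectors within a numerically degenerate eigenvalue
  cluster is invisible to it.
* Branch lengths reuse the global eigenvector restricted to the subset;
  no local re-solve of the eigenproblem per branch is attempted.
* k-way (base-k) splitting per level is not implemented; every level is
  binary.
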