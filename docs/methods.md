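# Methods

This note records the models behind each stage, the tunable parameters
and their defaults, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Geometry and the ensemble classifier

Superposition is the Kabsch least-squares fit on the alignment atom set,
all atoms weighted equally (the analysis protocol specifies *which* atoms
to fit, not weights). The rotation is constrained proper (det = +1) via
the usual sign correction on the smallest singular vector. Alignment sets
whose centered coordinates have a vanishing second singular value
(collinear or coincident atoms) are rejected: the rotation about the
common axis would be undetermined.

The all-pairs RMSD matrix evaluates every unordered frame pair, so no
frame is privileged as a common reference. It is computed row-wise with
batched 3×3 SVDs (O(n²) pairs; ~12 s for 2000 frames × 50 atoms on one
core), then symmetrized exactly so downstream arithmetic cannot depend on
evaluation order.

Final-state classification takes the mean of the last `tail_fraction` of
the ligand-RMSD series (default 0.1 — the final metastable stretch of a
converged run; the choice of window is the one free parameter, exposed in
the config) and maps it to: A < 1.25 Å, intermediate [1.25, 2) Å,
B [2, 3) Å, C [3, 4) Å, unbound ≥ 4 Å. The 1.25–2 Å gap gets an explicit
`intermediate` label rather than being forced into A or B.

## k-medoids and the elbow rule

The objective is the summed distance of frames to their cluster medoid.
Three layers make every run reproducible and well-converged:

1. **Ranked seeding.** Score each point j by
   v_j = Σ_i D(i,j)/Σ_l D(i,l) and seed with the k smallest (ties to the
   lowest index). Deterministic, and biased toward points central to
   dense regions.
2. **Voronoi alternation.** Assign to the nearest medoid (ties to the
   lowest medoid index), recompute each cluster's in-cluster cost
   minimizer, repeat until the medoid set is stable. A cluster emptied by
   assignment (possible with duplicate points) is re-seeded with the
   non-medoid point farthest from all medoids, with a log record.
3. **Greedy exchange refinement.** The ranked seeding scores global
   centrality, so on data with unequal basin populations it can place
   several seeds in one large basin — a start the Voronoi updates cannot
   escape (measured on small separated-blob instances: about a quarter of
   runs missed the enumeration optimum without refinement). After the
   alternation converges, the single best medoid/non-medoid exchange is
   applied repeatedly until no exchange lowers the cost, ties again to
   the lowest indices. This restores the enumeration optimum on every
   tested separated-blob instance while preserving determinism, the
   non-increasing cost trace, and O(n²·k) cost per pass.

**Automatic k.** k grows from 1; at the first k whose relative decrement
(cost(k−1) − cost(k))/cost(k−1) falls below the threshold (default 0.01),
the loop stops. A sub-threshold decrement certifies that the step to k
bought essentially nothing, so the clustering at k−1 is returned
(`keep_at_elbow="previous"`; the alternative reading, keeping k itself,
is one flag away). The loop also stops at zero cost or at `k_max`.

The 1% rule is a statement about *relative intra-basin geometry*: the
cost recovered by splitting a genuine basin scales with the spread of its
internal pairwise distances, which concentrates as the number of
coordinates grows. With ~150-dimensional frames (50 atoms) and ~600+
frames per basin the spurious-split decrement sits near 0.9%, safely
below threshold; with very low-dimensional or very short data it can
exceed 1% and the rule then resolves extra clusters (visible in the
bundled demo, which over-splits one basin at 600 frames per replica but
recovers k = 3 at the 2000-frame benchmark length).

## Transition graph and route extraction

Transitions are counted at lag 1 (configurable) within each label
sequence, never across trajectory boundaries; self-transitions are
ignored; (i, j) and (j, i) counts pool onto one undirected edge. The raw
weight −ln(n_ij) would be negative for any edge crossed more than once,
which Dijkstra cannot accept, so weights are normalized:
w_ij = −ln(n_ij/N_tot) ≥ 0 with N_tot the total inter-cluster count. The
normalization preserves the ordering of edges by count (it shifts all
log-weights by the same constant), keeping the free-energy-like
interpretation intact.

Dijkstra runs with lexicographic tie-breaking on node order, so equal-
weight alternatives resolve identically regardless of insertion order.
Route extraction loops per sink: record the shortest path, delete its
interior nodes *and its edges* (edge deletion prevents a direct
source–sink edge from being returned twice — a case the interior-node
rule alone misses), repeat until unreachable. Deletions only lengthen
later paths, so routes come out in non-decreasing weight order, pairwise
interior-disjoint.

## Path collective variables

With D_i the MSD to reference i after superposition and indices starting
at 1 (s spans [1, N]):

    s = Σ i·e^(−λD_i) / Σ e^(−λD_i),   z = −(1/λ) ln Σ e^(−λD_i).

Both are evaluated through a max-shifted exponential (log-sum-exp), so
λ·D up to 1e4 and far beyond produces finite results; only relative
dissimilarities matter numerically. Internally D is nm² and λ nm⁻²
(coordinates on disk are Å; 1 Å² = 0.01 nm²). λ should scale as the
inverse of the typical consecutive reference MSD; `PathDefinition`
reports the coefficient of variation of consecutive reference
dissimilarities as an equidistance diagnostic.

Umbrella centers are chosen greedily against the ideal uniform grid over
[min s, max s]: for each grid node, the closest unused candidate with an
s above the previous choice, ties to the lowest index. Two centers means
the endpoints; equal candidate counts mean all candidates. A manual
center list in the config overrides the selector.

## Mean force, KRLS, integration, bootstrap

The estimator is f̂ = κ(⟨s⟩ − s_c) with standard error κ·sd(s)/√n. Its
sign convention is pinned by the recovery requirement: at stationarity
⟨U′(s)⟩ = −κ(⟨s⟩ − s_c), so F(s) = −∫ f̂ ds reproduces the underlying
potential, and the double-well benchmark verifies this end to end. If
instantaneous restraint-force samples κ(s_t − s_c) are available they can
be averaged instead; the two coincide in expectation for harmonic
restraints. Samples are assumed uncorrelated — thin correlated series
before building windows.

KRLS solves (K + λ_reg I)α = f̂ with K_ij = exp(−(s_i−s_j)²/2σ²).
Defaults σ = 25 and λ_reg = 1e−8, with σ expressed in the S-variable's
own index-like units: umbrella ladders here have centers near the
integers 1…N, so σ = 25 spans the whole ladder and, together with the
tiny ridge, acts as a spectral low-pass — smooth but still data-faithful.
The same number interpreted on an arbitrarily rescaled coordinate would
change the effective smoothing, which is why benchmarks and ladders are
posed on the index-like axis. Integration is composite trapezoid on a
grid of ≥ 100 points anchored F(grid₀) = 0 (the analytic erf integral of
the kernel expansion would differ by < 1e−6 k_BT at a 1000-point grid);
grids beyond the training interval warn and extrapolate.

The bootstrap resamples within windows (windows independent), re-runs
estimate → fit → integrate, and reports percentile bands; it is
seed-reproducible.

## Kinetics

Δt = N_A·V/(n_s·n_l·k_on) — derived by inverting the finite-difference
initial-rate equation with ΔC = 1/(N_A V), P₀ = n_s/(N_A V),
L₀ = n_l/(N_A V) — equals *exactly* the mean of the exponential
first-event time with propensity a0 = k_on·n_s·n_l/(N_A V); the stochastic
generator is therefore a distribution-level twin, not just an asymptotic
one. K_D and K_i are treated interchangeably; k_off may be given
directly, as a residence time (1/τ) or a half-life (ln 2/t½). Volumes are
Å³ with 1 Å³ = 1e−27 L; times come out in seconds.

## Synthetic data: scope and limits

The generators emulate the *statistics* the pipeline consumes, not the
physics that produces them:

* **Mesostate trajectories** — isotropic Gaussian scatter (σ default
  0.5 Å) around per-state reference conformations visited by a first-order
  Markov chain, optional uniform random rigid motions (quaternion
  rotations, translations in a 20 Å box) to exercise alignment
  invariance. References are drawn as independent Gaussian conformations
  and rescaled so the minimum pairwise aligned RMSD equals the requested
  separation (states differing by a rigid motion alone would be invisible
  to an RMSD metric, so separation must live in internal geometry). The
  benchmark condition is 3 Å separation at σ = 0.5 Å — the regime of
  inter-ensemble RMSDs of a few Å against sub-Å thermal scatter — with
  50-atom frames.
* **Restrained sampling** — closed-form Boltzmann Gaussians for harmonic
  or linear potentials; overdamped Langevin (Euler–Maruyama, unit
  friction, dt = 0.1/max|U_tot″| over the domain, 10% burn-in, default
  stride 10) for anything else, including the double-well
  U = h(s²−1)² used in the recovery benchmark.
* **Binding events** — single-draw exponential waiting times at the
  closed-form propensity.

What passing tests therefore show: the estimators recover what they are
defined to recover under clean, well-separated, Markovian, isotropic
conditions. What they do not show: robustness to non-Markovian memory,
anisotropic or state-dependent fluctuations, overlapping basins,
force-field error, or sampling bias in real MD — the generators have none
of these by construction.

k_BT is an explicit parameter wherever energies meet samples (default
0.596 kcal/mol, ≈300 K); the benchmarks work in reduced units k_BT = 1.

## Benchmark problem sizes

Chosen so the full chain runs comfortably on one core: 20 enumeration
instances (n ≤ 12, k ≤ 3) for clustering optimality; one 3-state,
2000-frame trajectory for automatic-k recovery; 50 random ≤ 8-node graphs
for path enumeration; 15 windows × 5000 Langevin samples for the
double-well recovery (measured reconstruction error ≈ 0.1–0.5 k_BT
against the 3 k_BT barrier, dominated by residual correlation in the
Langevin means); 10⁵ replicates for the first-binding-time check; the
demo pipeline at 2 × 600 frames.

## Known limitations

* The elbow rule needs enough frames and enough coordinates for
  intra-basin distance concentration; short or low-dimensional data
  over-split at the 1% threshold (see above).
* Route extraction is greedy: it guarantees independence (node-disjoint
  interiors) and ranked weights, not a globally optimal disjoint-path
  set.
* The mean-force estimator assumes stiff harmonic restraints and
  decorrelated samples; no WHAM/MBAR-style reweighting is attempted.
* The transition graph is a count graph, not a Markov state model: no lag
  analysis, no detailed-balance estimation.
* PDB/XYZ are the only trajectory formats; binary MD formats are out of
  scope.
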