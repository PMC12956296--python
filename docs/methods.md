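# Methods

## Model and procedure

`connalign` aligns two subjects' brain networks by estimating a region
permutation. A brain network is a symmetric N×N connectome over a
parcellation with two equal hemispheres (indices 0..N/2−1 left,
N/2..N−1 right); structural connectomes (SC) hold non-negative
streamline counts, functional connectomes (FC) Pearson correlations.
Only symmetric matrices are supported: current MRI techniques do not
resolve connection direction reliably.

The estimator minimizes a convex combination of squared Frobenius
distances between permuted and reference connectomes over modalities,
equivalently (for symmetric matrices, up to a P-independent constant)
the trace form −Σᵢ βᵢ Tr(P Cᵢ Pᵀ Cᵢ,ref). One permutation is shared
across modalities: the parcellation is common, and a region is assumed
to play one role per subject regardless of the imaging view.

The combinatorial problem is relaxed to the Birkhoff polytope and solved
by Frank–Wolfe descent (the FAQ scheme):

1. gradient of the trace form: −2 Σᵢ βᵢ Cᵢ,ref P Cᵢ;
2. search direction: the permutation minimizing ⟨grad, Q⟩, a linear sum
   assignment problem solved with scipy's Jonker–Volgenant
   implementation; forbidden assignments carry `np.inf` cost, which the
   solver handles natively — the hard-constraint limit of an infinitely
   weighted penalty. Because feasible iterates keep the penalty term at
   exactly zero, no penalty weight ever needs a numeric value;
3. exact line search on the segment γP + (1−γ)Q (γ is the weight of the
   *current* iterate); the trace objective restricted to the segment is
   the scalar quadratic aγ² + bγ + c with, for D = P − Q,
   a = −Σ βᵢ Tr(D Cᵢ Dᵀ Cᵢ,ref) and
   b = −Σ βᵢ [Tr(D Cᵢ Qᵀ Cᵢ,ref) + Tr(Q Cᵢ Dᵀ Cᵢ,ref)].
   For a > 0 the interior minimizer −b/2a is clamped to [0, 1]; for
   a ≤ 0 the cheaper endpoint is taken. Since γ = 1 keeps the iterate,
   the objective trace is non-increasing by construction;
4. final projection onto the permutation group: maximize ⟨P_final, Q⟩
   by linear assignment, again with infinite cost at forbidden entries so
   a zero-valued tie can never select a forbidden cell.

A deliberate interpretation: the line search uses the trace form. On
permutation matrices the Frobenius and trace forms differ by a constant,
but on the relaxed polytope the Frobenius form is quartic in the iterate;
the trace form is the standard FAQ choice and is the functional whose
gradient drives steps 1–2. Both forms agree at the endpoints γ ∈ {0, 1}.

Initialization is the identity (perform no permutation); a barycenter
option exists but is off by default and is unavailable under a
constraint mask (the flat matrix is infeasible there). Iterations are
capped at 50 with a relative early stop of 1e-9 on the objective
decrease; in practice the descent settles within a handful of
iterations. Ties inside the assignment subproblem are resolved
deterministically (fixed row-major cost layout, deterministic solver)
but arbitrarily.

### Strategies and constraint masks

* `ha` — hemispheric alignment: two independent unconstrained descents on
  the N/2 diagonal blocks, assembled block-diagonally. Inter-hemispheric
  connectivity is invisible to this variant.
* `wba` — whole-brain alignment with the hemisphere mask R_hemi
  (anti-diagonal blocks forbidden): inter-hemispheric edges inform the
  objective while cross-hemisphere moves remain impossible.
* `wbanc` — whole-brain alignment with the neighborhood mask R_neigh:
  only self-assignments and moves between spatially adjacent regions are
  allowed. R_neigh's feasible set is contained in R_hemi's; a
  cross-hemisphere adjacency edge is rejected as a contract violation
  rather than silently dropped, precisely to preserve this nesting.

Masks are symmetric binary matrices with zero diagonal
(self-assignment must stay feasible — the identity is both the witness
of feasibility and the initial iterate). An asymmetric custom mask is a
hard error, not auto-symmetrized: OR- versus AND-symmetrization change
the semantics and the caller must decide. Feasibility (the allowed
entries contain at least one permutation) is certified by maximum
bipartite matching; infeasibility is reported as a Hall-violating row
set found by alternating-path search.

### Assessment

Alignment gain η(P, a, b) = ‖C_a − C_b‖_F − ‖P C_a Pᵀ − C_b‖_F, computed
per modality — including modalities held out of the optimization, which
measures whether a permutation generalizes. Significance: one-sided
Wilcoxon signed-rank test ("gains stochastically greater than a
symmetric null"), exact null for n ≤ 25 after discarding exact zeros
(Wilcoxon's original zero treatment; ties among absolute values fall
back to the normal approximation), normal approximation with continuity
correction otherwise. The family threshold is Bonferroni-corrected; the
full-design hypothesis count is 11 α-values × 3 strategies × 4
connectome types × 2 training datasets = 264, giving 0.001/264 ≈
3.79e-6. A significant *decrease* is reported from the complementary
one-sided test. Spatial characterization classifies each label's move by
shortest-path distance on the region adjacency graph: self (0), local
(1), remote (≥ 2, including unreachable, which is flagged).

Reference variability: the mean gain per reference subject, and the
standard deviation of those means across references, with the population
denominator (ddof = 0) by default and a flag for the sample convention —
the field uses both and the default is documented rather than implied.
Permutation agreement between two runs reports the fraction of labels
placed identically, overall and restricted to labels moved by at least
one of the two permutations (union denominator; an intersection
denominator would ignore labels that only one run moves, which is
exactly the disagreement of interest). When both permutations are the
identity the restricted metric is defined as 1.

## Signal processing choices

Band-pass filtering of region time series uses a Butterworth design
(default order 8, 0.06–0.125 Hz) applied forward–backward
(`sosfiltfilt`): correlation-based FC must not introduce relative phase
shifts between regions, at the cost of doubling the effective
attenuation order. Runs are concatenated in caller order with no per-run
demeaning by default (an optional per-run z-scoring flag exists). A
zero-variance region signal is a hard error naming the region — it
signals upstream corruption, and silently mapping NaN correlations to 0
would poison the alignment unnoticed. Matrices asymmetric beyond 1e-10
are rejected; within tolerance they are exactly symmetrized on load.

SC and FC live on incommensurate scales, so each SC is rescaled to the
Frobenius norm of the same subject's FC — a pure rescaling that
preserves zero patterns and relative weights and makes α a genuine
balance between modalities. When a subject has several FCs, the FC
paired with the SC in the active training dataset sets the target norm
(configurable).

## Synthetic cohorts

The generator emulates the *inputs* of the pipeline, not the biophysics
of BOLD or tractography. Each hemisphere is a rows×cols grid graph; the
region coordinates are jittered (±0.35 grid units) because real
parcellations are geometrically irregular — a perfectly regular grid has
mirror symmetries that make distinct regions' profiles nearly identical
and the alignment problem artificially degenerate.

Structural connectome (base, shared across subjects):

* spatially adjacent regions connect weakly (U(0.02, 0.08));
* every non-adjacent within-hemisphere pair carries a long-range
  "bundle" of variable strength (U(0.3, 1.2)) — in real matrices
  association tracts dominate streamline counts and give each region a
  distinctive long-range profile;
* the cross-hemisphere block is a_i + b_j + U(0, 0.15) with per-region
  strengths a, b ~ U(0.2, 1.2): counts dominated by regional strength
  marginals, with small pair-specific variation.

Functional connectome: the exact correlation matrix of a latent factor
model — Gaussian spatial kernel loadings exp(−d²/4) on the jittered
coordinates (adjacent regions strongly correlated, smooth decay),
factors shared homotopically across hemispheres at weight 0.5, and
per-region idiosyncratic noise standard deviations U(0.05, 0.30)
(regional SNR differences). As a normalized factor-model covariance the
FC is symmetric, unit-diagonal and PSD by construction, and identical
across subjects in the noiseless limit.

Per-subject noise: symmetric non-negative SC perturbations scaled by
`sc_noise_sd` times the mean edge weight, and loading perturbations
scaled by `fc_noise_sd`. Planted ground truth: a composition of
`n_planted_swaps` transpositions, each drawn among the swaps allowed by
the active constraint mask at the time of application. This is not
uniform sampling over the feasible set (intractable under the
neighborhood mask) and is documented as a bias. The base construction
guarantees pairwise-distinct region profiles, hence no nontrivial
automorphism and a unique noiseless optimum; this is checked at
generation time.

### What the generator does and does not show

These structural choices are not only realism: they are what makes small
synthetic instances *identifiable*. A first-order analysis of the
descent explains why. At the identity, the linearized gain of a
transposition (u, v) is Σ_{j≠u,v} (C[u,j] − C[v,j])² − 2(d − C[u,v])²
per modality, with d the diagonal value (0 for SC, 1 for FC). The solver
can therefore only leave the identity when swapped regions' profiles
differ by more than (twice) the squared coupling between them — for the
FC, when mutually *well-correlated* regions (small 1 − r) have visibly
different correlation patterns to third regions. At the paper-scale
N = 1000 these sums have hundreds of terms and the condition holds
essentially always; at desk scale (N = 6–50) it holds because the
generator gives regions distinctive long-range structural profiles,
weak direct edges between swappable (adjacent) pairs, and high adjacent
functional correlation with a visible spatial decay. Smooth, homogeneous
toy matrices — however "distinct" numerically — produce instances on
which any identity-initialized Frank–Wolfe descent provably stalls;
passing tests on this generator show the machinery is correct on
identifiable instances, not that real connectomes of arbitrary
smoothness are alignable.

Two further scale effects are handled explicitly in the test conditions:

* tiny instances (N = 6, used where an exhaustive oracle over all
  feasible permutations is affordable) plant *adjacent* (neighborhood-
  class) transpositions for all strategies. With three regions per
  hemisphere a distance-2 swap is mirror-degenerate for the block-only
  hemispheric aligner — the two swapped regions' within-block profiles
  consist of a single shared entry — and no correlation triangle can
  make all three of its pairs escapable (the required inequalities are
  jointly infeasible). Local planted swaps are also the regime the
  method models: misalignments of small neighboring parcels;
* the protocol-scale experiment (10 subjects × 15 permutations,
  α = 0.5) uses N = 50, the smallest size at which all three strategies,
  including the block-only hemispheric variant with hemisphere-class
  (possibly remote) planted swaps, recover exactly at zero noise. These
  problem sizes keep the full suite and the acceptance run in seconds.

## Numerical choices

* symmetry / unit-diagonal tolerance on inputs: 1e-10 absolute;
* doubly stochastic check on explicit initial iterates: 1e-9;
* early stop: relative objective decrease below 1e-9;
* objective monotonicity asserted to 1e-9; oracle-equivalence and
  Frobenius/trace identities to 1e-8;
* brute-force QAP oracle guarded to N ≤ 8 (N! enumeration), ties broken
  lexicographically;
* the exact Wilcoxon null is used up to n = 25 distinct absolute values.

## Known limitations

* The FAQ relaxation is a heuristic: it can stall at first-order
  stationary points (the identity included) and carries no optimality
  guarantee; the oracle-equivalence suite certifies behavior on
  identifiable instances only.
* Hard constraints only: soft, distance-weighted penalties (finite λ)
  are out of scope.
* Directed (asymmetric) connectomes are not supported.
* The permutation sampler is biased relative to the uniform distribution
  over feasible permutations.
* CLI `align` handles one subject pair per invocation; cohort-scale
  sweeps are plain loops over the library API.
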