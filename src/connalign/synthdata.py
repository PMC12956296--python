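"""Synthetic cohorts with planted, constraint-respecting permutations.

The generator emulates the inputs the alignment pipeline consumes: paired
SC/FC connectomes over a parcellation with two equal hemispheres, a region
adjacency graph, and known ground-truth permutations. Each hemisphere is a
``rows x cols`` grid graph whose regions sit at jittered grid coordinates
(real parcellations are geometrically irregular; perfectly regular
geometry creates mirror symmetries that make distinct regions
indistinguishable).

The structural connectome combines three features of real streamline-count
matrices, each of which also makes regional connectivity profiles
distinctive, a property both the uniqueness of the alignment optimum and
the identity-initialized solver rely on:

* weak short-range connectivity between spatially adjacent regions;
* strong, variable long-range bundles between non-adjacent regions of a
  hemisphere (association tracts dominate streamline counts);
* a cross-hemisphere block driven by per-region strength marginals
  (``a_i + b_j``) plus small idiosyncratic variation.

The functional connectome is the exact correlation matrix of a latent
factor model — spatially smooth factor loadings (Gaussian kernel on the
region coordinates, so adjacent regions are strongly correlated), shared
homotopically across hemispheres, plus per-region idiosyncratic noise
variances (regional SNR differences). Being a normalized factor-model
covariance it is symmetric, unit-diagonal and PSD by construction, and in
the noiseless limit identical across subjects.

Planted permutations are compositions of transpositions each allowed by
the active constraint mask; this is not uniform over the feasible set
(uniform sampling under a neighborhood constraint is intractable) but
covers it and is reproducible from the seed.

The module also provides the exhaustive QAP oracle used to certify solver
optimality on small instances, and the planted-permutation validation
protocol: permute a subject's connectomes with a known permutation, align
them back to the originals, and count labels not restored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import permutations as iter_permutations

import numpy as np

from .connectomes import Connectome, SubjectData, rescale_sc
from .constraints import (
    RegionAdjacency,
    RegularizationMatrix,
    build_r_hemi,
    build_r_neigh,
    check_feasible,
)
from .solver import (
    AlignmentWeights,
    PermutationMatrix,
    align,
    frobenius_objective,
)

__all__ = [
    "CohortSpec",
    "RecoveryReport",
    "grid_adjacency",
    "generate_cohort",
    "sample_constrained_permutation",
    "brute_force_qap",
    "run_planted_validation",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Each hemisphere is a ``grid_rows x grid_cols`` grid graph, so
    ``N = 2 * grid_rows * grid_cols`` regions. ``sc_noise_sd`` scales
    per-subject additive SC noise relative to the mean edge weight;
    ``fc_noise_sd`` scales per-subject perturbation of the latent factor
    loadings behind the FC. Each subject's connectomes are scrambled by a
    planted permutation composed of ``n_planted_swaps``
    constraint-respecting transpositions.
    """

    n_subjects: int = 10
    grid_rows: int = 2
    grid_cols: int = 5
    sc_noise_sd: float = 0.05
    fc_noise_sd: float = 0.05
    n_planted_swaps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.grid_rows * self.grid_cols < 2:
            raise ValueError("each hemisphere needs at least 2 regions")
        if self.sc_noise_sd < 0 or self.fc_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")
        if self.n_planted_swaps < 0:
            raise ValueError("n_planted_swaps must be non-negative")

    @property
    def n_regions(self) -> int:
        return 2 * self.grid_rows * self.grid_cols


@dataclass
class RecoveryReport:
    """Outcome of the planted-permutation validation protocol."""

    mismatch_counts: np.ndarray
    strategy: str
    alpha: float

    @property
    def mean_mismatched_labels(self) -> float:
        return float(np.mean(self.mismatch_counts))

    @property
    def exact_recovery_fraction(self) -> float:
        return float(np.mean(self.mismatch_counts == 0))


def grid_adjacency(rows: int, cols: int) -> RegionAdjacency:
    """Adjacency of two mirrored ``rows x cols`` grid hemispheres."""
    h = rows * cols
    edges = set()

    def idx(r, c):
        return r * cols + c

    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.add((idx(r, c), idx(r, c + 1)))
            if r + 1 < rows:
                edges.add((idx(r, c), idx(r + 1, c)))
    edges |= {(k + h, l + h) for k, l in edges}
    return RegionAdjacency(N=2 * h, edges=frozenset(edges))


class _CohortBase:
    """Subject-shared structure drawn once per cohort."""

    def __init__(self, spec: CohortSpec, rng: np.random.Generator):
        rows, cols = spec.grid_rows, spec.grid_cols
        h = rows * cols
        self.h = h
        self.n = 2 * h
        adj = grid_adjacency(rows, cols)
        A = adj.to_matrix()[:h, :h]

        # irregular region geometry
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        coords += rng.uniform(-0.35, 0.35, coords.shape)
        dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)

        # FC latent structure: smooth spatial factors, homotopic sharing,
        # per-region idiosyncratic noise level
        K = np.exp(-(dist**2) / 4.0)
        loadings = np.zeros((self.n, h))
        loadings[:h] = K
        loadings[h:] = 0.5 * K
        self.loadings = loadings
        self.idio = rng.uniform(0.05, 0.30, self.n)

        # SC: weak short-range edges, strong long-range bundles,
        # strength-marginal cross-hemisphere block
        def intra_block():
            short = rng.uniform(0.02, 0.08, (h, h))
            bundles = rng.uniform(0.3, 1.2, (h, h))
            blk = np.where(A == 0, bundles, short)
            blk = np.triu(blk, 1)
            return blk + blk.T

        a = rng.uniform(0.2, 1.2, h)
        b = rng.uniform(0.2, 1.2, h)
        cross = a[:, None] + b[None, :] + rng.uniform(0.0, 0.15, (h, h))
        sc = np.zeros((self.n, self.n))
        sc[:h, :h] = intra_block()
        sc[h:, h:] = intra_block()
        sc[:h, h:] = cross
        sc[h:, :h] = cross.T
        np.fill_diagonal(sc, 0.0)
        self.sc = (sc + sc.T) / 2.0

    def fc_matrix(self, loadings: np.ndarray) -> np.ndarray:
        """Exact correlation matrix of the factor model (PSD, unit diag)."""
        cov = loadings @ loadings.T + np.diag(self.idio**2)
        d = np.sqrt(np.diag(cov))
        fc = cov / np.outer(d, d)
        fc = (fc + fc.T) / 2.0
        np.fill_diagonal(fc, 1.0)
        return np.clip(fc, -1.0, 1.0)


def sample_constrained_permutation(
    R: RegularizationMatrix, n_swaps: int, seed: int | np.random.Generator = 0
) -> PermutationMatrix:
    """Random permutation respecting ``R``, built from allowed transpositions.

    Applies ``n_swaps`` transpositions in sequence; each is drawn uniformly
    among the position pairs whose swap keeps the whole mapping allowed by
    ``R``. If no allowed transposition remains at some step, the
    permutation achieved so far is returned.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = R.n_regions
    mapping = np.arange(n)
    for _ in range(n_swaps):
        candidates = []
        for k in range(n):
            for l in range(k + 1, n):
                new = mapping.copy()
                new[[k, l]] = new[[l, k]]
                if R.allows(new):
                    candidates.append((k, l))
        if not candidates:
            break
        k, l = candidates[rng.integers(len(candidates))]
        mapping[[k, l]] = mapping[[l, k]]
    return PermutationMatrix(mapping)


def generate_cohort(spec: CohortSpec, constraint: RegularizationMatrix | None = None):
    """Generate a cohort of paired SC/FC subjects with planted permutations.

    Every subject derives from a common structured base (see module
    docstring): per-subject symmetric non-negative SC noise of scale
    ``sc_noise_sd`` relative to the mean edge weight, and per-subject
    perturbation of the FC factor loadings of scale ``fc_noise_sd``. The
    subject's planted permutation (``n_planted_swaps`` transpositions
    allowed by ``constraint``, default the neighborhood mask of the grid)
    then scrambles both matrices. SCs are rescaled to the Frobenius norm
    of the paired FC. In the noiseless limit subjects differ only by their
    planted permutations.

    Returns ``(subjects, adjacency, planted)`` where ``planted[i]`` is the
    permutation applied to subject ``i``. Deterministic given the seed.
    The base guarantees pairwise-distinct region connectivity profiles
    (hence no nontrivial automorphism in the noiseless limit); this is
    checked and a degenerate draw raises.
    """
    rng = np.random.default_rng(spec.seed)
    adjacency = grid_adjacency(spec.grid_rows, spec.grid_cols)
    if constraint is None:
        constraint = build_r_neigh(adjacency)
    report = check_feasible(constraint)
    if not report.feasible:
        raise ValueError("infeasible planted-permutation constraint mask")

    base = _CohortBase(spec, rng)
    # distinct-profile guarantee underlies everything downstream
    profiles = base.sc
    gram = np.sum(
        (profiles[:, None, :] - profiles[None, :, :]) ** 2, axis=2
    )
    np.fill_diagonal(gram, np.inf)
    if gram.min() <= 1e-6:
        raise ValueError("degenerate base: two regions share a connectivity profile")

    mean_edge = base.sc[base.sc > 0].mean()
    subjects: list[SubjectData] = []
    planted: list[PermutationMatrix] = []
    for i in range(spec.n_subjects):
        sc_vals = base.sc.copy()
        if spec.sc_noise_sd > 0:
            noise = rng.standard_normal(sc_vals.shape)
            noise = np.abs((noise + noise.T) / 2.0) * spec.sc_noise_sd * mean_edge
            np.fill_diagonal(noise, 0.0)
            sc_vals = sc_vals + noise
        loadings = base.loadings
        if spec.fc_noise_sd > 0:
            loadings = loadings + spec.fc_noise_sd * rng.standard_normal(
                loadings.shape
            )
        fc_vals = base.fc_matrix(loadings)

        pi = sample_constrained_permutation(constraint, spec.n_planted_swaps, rng)
        sc_vals = pi.apply(sc_vals)
        fc_vals = pi.apply(fc_vals)

        sid = f"sub-{i:03d}"
        fc = Connectome(fc_vals, "FC", subject_id=sid)
        sc = rescale_sc(Connectome(sc_vals, "SC", subject_id=sid), fc)
        subjects.append(SubjectData(sc=sc, fc=[fc], subject_id=sid))
        planted.append(pi)
    return subjects, adjacency, planted


def brute_force_qap(
    moving, reference, w: AlignmentWeights,
    R: RegularizationMatrix | None = None, max_n: int = 8,
):
    """Exhaustive minimum of the Frobenius objective over feasible permutations.

    Test oracle only: enumerates all ``N!`` mappings (guarded to
    ``N <= max_n``), keeps those allowed by ``R``, and returns
    ``(PermutationMatrix, objective)`` with ties broken by lexicographic
    mapping order (strict improvement keeps the earlier mapping).
    """
    mov = [c.values if isinstance(c, Connectome) else np.asarray(c, float) for c in moving]
    ref = [c.values if isinstance(c, Connectome) else np.asarray(c, float) for c in reference]
    n = mov[0].shape[0]
    if n > max_n:
        raise ValueError(f"brute force guarded to N <= {max_n}, got N={n}")
    best_map = None
    best_obj = np.inf
    for mapping in iter_permutations(range(n)):
        mapping = np.asarray(mapping, dtype=np.intp)
        if R is not None and not R.allows(mapping):
            continue
        P = PermutationMatrix(mapping)
        obj = frobenius_objective(P, mov, ref, w)
        if obj < best_obj - 1e-15:
            best_obj = obj
            best_map = mapping
    if best_map is None:
        raise ValueError("constraint mask admits no permutation")
    return PermutationMatrix(best_map), float(best_obj)


def run_planted_validation(
    spec: CohortSpec, n_perm_matrices: int = 15, strategy: str = "wba",
    alpha: float = 0.5, max_iter: int = 50,
) -> RecoveryReport:
    """Planted-permutation validation of the alignment algorithm.

    Generates a cohort of unpermuted subjects (the planted-swap count of
    ``spec`` sets the swap budget of the simulated permutations, not of
    the cohort), simulates ``n_perm_matrices`` random permutations
    satisfying the active strategy's constraint class (the hemisphere mask
    for ``ha``/``wba``, the neighborhood mask for ``wbanc``), applies each
    to every subject's connectomes, and aligns the permuted connectomes
    back to the originals. A perfect alignment recovers the inverse of the
    planted permutation; the report counts, per (subject, permutation)
    trial, the labels not restored to their original positions.
    """
    base_spec = replace(spec, n_planted_swaps=0)
    subjects, adjacency, _ = generate_cohort(base_spec)
    n = base_spec.n_regions
    if strategy == "wbanc":
        R_plant = build_r_neigh(adjacency)
    else:
        R_plant = build_r_hemi(n)
    rng = np.random.default_rng(spec.seed + 1)
    swap_budget = max(spec.n_planted_swaps, 1)
    plants = [
        sample_constrained_permutation(R_plant, swap_budget, rng)
        for _ in range(n_perm_matrices)
    ]
    mismatches = []
    for subj in subjects:
        for pi in plants:
            moved = (pi.apply(subj.sc.values), pi.apply(subj.fc[0].values))
            original = (subj.sc.values, subj.fc[0].values)
            res = align(strategy, moved, original, alpha=alpha,
                        adjacency=adjacency, max_iter=max_iter)
            target = pi.inverse()
            mismatches.append(
                int(np.sum(res.permutation.mapping != target.mapping))
            )
    return RecoveryReport(
        mismatch_counts=np.asarray(mismatches), strategy=strategy, alpha=alpha
    )
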