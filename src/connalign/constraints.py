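"""Anatomical constraints on region permutations.

Constraints are encoded as a binary symmetric ``N x N`` regularization
matrix ``R``: ``R[k, l] == 1`` forbids assigning region ``l`` to position
``k``, ``R[k, l] == 0`` allows it. Inside the assignment subproblem of the
solver the forbidden entries carry infinite cost, so ``R`` acts as a hard
constraint (the weight on the penalty is conceptually infinite).

Two standard masks are provided:

* ``build_r_hemi`` — forbid cross-hemisphere moves only (the hemispheres
  occupy the first and second halves of the index range);
* ``build_r_neigh`` — additionally forbid moves between regions that are
  not spatially adjacent on the parcellation.

Feasibility of a mask (the allowed entries must contain at least one full
permutation) is certified by maximum bipartite matching; infeasibility is
reported as a Hall-condition violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching, shortest_path

__all__ = [
    "RegionAdjacency",
    "RegularizationMatrix",
    "FeasibilityReport",
    "build_r_hemi",
    "build_r_neigh",
    "check_feasible",
    "region_graph_distances",
]


@dataclass(frozen=True)
class RegionAdjacency:
    """Spatial-neighborhood graph of parcellation regions.

    ``edges`` holds unordered 0-based index pairs; self-loops are rejected.
    Regions ``0 .. N/2 - 1`` are the left hemisphere, the rest the right.
    """

    N: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.N < 2 or self.N % 2 != 0:
            raise ValueError(f"N must be even and >= 2, got {self.N}")
        norm = set()
        for e in self.edges:
            k, l = e
            if not (0 <= k < self.N and 0 <= l < self.N):
                raise ValueError(f"edge {e} out of range for N={self.N}")
            if k == l:
                raise ValueError(f"self-loop edge {e} is not allowed")
            norm.add((min(k, l), max(k, l)))
        object.__setattr__(self, "edges", frozenset(norm))

    def hemisphere(self, k: int) -> str:
        return "left" if k < self.N // 2 else "right"

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (zero diagonal)."""
        a = np.zeros((self.N, self.N), dtype=int)
        for k, l in self.edges:
            a[k, l] = a[l, k] = 1
        return a


@dataclass
class RegularizationMatrix:
    """Binary symmetric mask of forbidden assignments (1 = forbidden)."""

    R: np.ndarray
    kind: str = "custom"

    def __post_init__(self) -> None:
        r = np.asarray(self.R)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("R must be square")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("R must be binary (0/1 entries)")
        if not np.array_equal(r, r.T):
            raise ValueError(
                "R must be symmetric: forbidding l->k must also forbid k->l"
            )
        if np.any(np.diag(r) != 0):
            raise ValueError("R diagonal must be zero (self-assignment stays allowed)")
        self.R = r.astype(np.int8)

    @property
    def n_regions(self) -> int:
        return self.R.shape[0]

    def allows(self, mapping: np.ndarray) -> bool:
        """True iff the permutation given as a mapping vector respects R."""
        mapping = np.asarray(mapping)
        return not np.any(self.R[np.arange(self.n_regions), mapping])


@dataclass(frozen=True)
class FeasibilityReport:
    """Result of a feasibility check on a regularization matrix.

    ``witness`` is a permutation mapping built from allowed entries when one
    exists; otherwise ``violating_rows`` names a set of rows whose union of
    allowed columns is smaller than the set (a Hall-condition violation).
    """

    feasible: bool
    witness: np.ndarray | None = None
    violating_rows: tuple = ()


def build_r_hemi(N: int) -> RegularizationMatrix:
    """Mask forbidding all cross-hemisphere assignments.

    A 2x2 block matrix with all-zero ``N/2 x N/2`` diagonal blocks and
    all-one anti-diagonal blocks.
    """
    if N < 2 or N % 2 != 0:
        raise ValueError(f"N must be even and >= 2, got {N}")
    h = N // 2
    r = np.ones((N, N), dtype=np.int8)
    r[:h, :h] = 0
    r[h:, h:] = 0
    return RegularizationMatrix(r, kind="hemi")


def build_r_neigh(adj: RegionAdjacency) -> RegularizationMatrix:
    """Mask allowing only self-assignments and spatially adjacent swaps.

    ``R[k, l] == 0`` iff ``k == l`` or ``{k, l}`` is an adjacency edge. The
    adjacency must not contain cross-hemisphere edges: the neighborhood
    constraint is by construction a restriction of the hemisphere
    constraint, so a cross-hemisphere edge is a contract violation and is
    rejected rather than dropped.
    """
    h = adj.N // 2
    for k, l in adj.edges:
        if (k < h) != (l < h):
            raise ValueError(
                f"cross-hemisphere adjacency edge ({k}, {l}): the neighborhood "
                "constraint must forbid everything the hemisphere constraint forbids"
            )
    r = np.ones((adj.N, adj.N), dtype=np.int8)
    np.fill_diagonal(r, 0)
    for k, l in adj.edges:
        r[k, l] = r[l, k] = 0
    return RegularizationMatrix(r, kind="neigh")


def check_feasible(R: RegularizationMatrix | np.ndarray) -> FeasibilityReport:
    """Certify that the allowed entries of ``R`` contain a permutation.

    Accepts a :class:`RegularizationMatrix` or any raw binary square
    matrix (no symmetry or zero-diagonal requirement). Runs maximum
    bipartite matching on the allowed-entry bipartite graph (rows vs.
    columns). A perfect matching is returned as a witness permutation;
    otherwise the rows reachable by alternating paths from an unmatched
    row form a Hall-violating set, which is reported.
    """
    raw = R.R if isinstance(R, RegularizationMatrix) else np.asarray(R)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ValueError("R must be square")
    if not np.isin(raw, (0, 1)).all():
        raise ValueError("R must be binary (0/1 entries)")
    allowed = (raw == 0)
    n = raw.shape[0]
    graph = csr_matrix(allowed)
    match = maximum_bipartite_matching(graph, perm_type="column")
    if np.all(match >= 0):
        return FeasibilityReport(feasible=True, witness=match.astype(np.intp))
    # Hall violator: alternating-path BFS from the unmatched rows.
    col_owner = np.full(n, -1, dtype=int)
    for row, col in enumerate(match):
        if col >= 0:
            col_owner[col] = row
    frontier = [r for r in range(n) if match[r] < 0]
    seen_rows = set(frontier)
    seen_cols: set[int] = set()
    while frontier:
        nxt = []
        for row in frontier:
            for col in np.flatnonzero(allowed[row]):
                if col in seen_cols:
                    continue
                seen_cols.add(col)
                owner = col_owner[col]
                if owner >= 0 and owner not in seen_rows:
                    seen_rows.add(owner)
                    nxt.append(owner)
        frontier = nxt
    return FeasibilityReport(
        feasible=False, violating_rows=tuple(sorted(seen_rows))
    )


def region_graph_distances(adj: RegionAdjacency) -> np.ndarray:
    """All-pairs shortest path lengths on the region adjacency graph.

    Returns a symmetric matrix of hop counts with zero diagonal;
    unreachable pairs carry ``np.inf``.
    """
    graph = csr_matrix(adj.to_matrix())
    d = shortest_path(graph, method="BF", unweighted=True, directed=False)
    return d
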