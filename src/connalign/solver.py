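"""Constrained multimodal graph matching by Frank-Wolfe descent.

The alignment of two subjects' brain networks is a quadratic assignment
problem: find the permutation ``P`` minimizing a convex combination of
Frobenius distances between permuted and reference connectomes over
modalities ``i``,

    L1(P) = sum_i beta_i * || P C_i P^T - C_{i,ref} ||_F^2 ,

which for symmetric connectomes is equivalent (up to a P-independent
constant) to minimizing the trace form

    L1'(P) = - sum_i beta_i * Tr(P C_i P^T C_{i,ref}) .

The QAP is NP-hard; following the fast approximate QAP (FAQ) scheme the
problem is relaxed to the Birkhoff polytope of doubly stochastic matrices
and solved by Frank-Wolfe descent: at each iteration the gradient

    grad L1'(P) = -2 sum_i beta_i * C_{i,ref} P C_i

is linearized, the search direction is the permutation minimizing
``<grad, Q>`` (a linear sum assignment problem), an exact line search picks
the step, and the final iterate is projected back onto the permutation
group. Anatomical constraints enter as a binary mask of forbidden
assignments whose entries receive infinite cost in the assignment
subproblem — a hard constraint needing no penalty weight — so every
iterate, every search direction and the projected output stay feasible.

Three strategies are exposed: hemispheric alignment (``ha``, two
independent unconstrained runs on the hemispheric blocks), whole-brain
alignment with the hemisphere mask (``wba``), and whole-brain alignment
restricted to spatially adjacent regions (``wbanc``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin

from .connectomes import Connectome, SubjectData
from .constraints import (
    RegionAdjacency,
    RegularizationMatrix,
    build_r_hemi,
    build_r_neigh,
    check_feasible,
)

__all__ = [
    "AlignmentWeights",
    "PermutationMatrix",
    "AlignmentResult",
    "ConnectomeAligner",
    "multimodal_objective",
    "frobenius_objective",
    "objective_gradient",
    "search_direction",
    "exact_line_search",
    "frank_wolfe_align",
    "align",
]

STRATEGIES = ("ha", "wba", "wbanc")


@dataclass(frozen=True)
class AlignmentWeights:
    """Non-negative modality weights summing to one.

    For the standard two-modality case the shorthand ``alpha`` weighs the
    SC term and ``1 - alpha`` the FC term: ``AlignmentWeights.from_alpha``.
    """

    betas: tuple

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b.ndim != 1 or b.size == 0:
            raise ValueError("betas must be a non-empty vector")
        if np.any(b < 0):
            raise ValueError("betas must be non-negative")
        if abs(b.sum() - 1.0) > 1e-12:
            raise ValueError(f"betas must sum to 1, got {b.sum()!r}")
        object.__setattr__(self, "betas", tuple(b))

    @classmethod
    def from_alpha(cls, alpha: float) -> "AlignmentWeights":
        """Two-modality weights ``(alpha, 1 - alpha)`` for (SC, FC)."""
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
        return cls((alpha, 1.0 - alpha))


class PermutationMatrix:
    """A permutation of region labels, stored as a mapping vector.

    ``mapping[k] = l`` means the matrix entry ``P[k, l]`` is one: position
    ``k`` of the permuted connectome takes row/column ``l`` of the
    original, i.e. ``(P C P^T)[k, k'] = C[mapping[k], mapping[k']]``.
    """

    def __init__(self, mapping: np.ndarray):
        mapping = np.asarray(mapping, dtype=np.intp)
        n = mapping.size
        if mapping.ndim != 1 or not np.array_equal(np.sort(mapping), np.arange(n)):
            raise ValueError("mapping must be a permutation of 0..N-1")
        self.mapping = mapping

    @classmethod
    def identity(cls, n: int) -> "PermutationMatrix":
        return cls(np.arange(n))

    @classmethod
    def from_matrix(cls, P: np.ndarray) -> "PermutationMatrix":
        P = np.asarray(P)
        n = P.shape[0]
        if P.shape != (n, n) or not np.isin(P, (0, 1)).all():
            raise ValueError("P must be a binary square matrix")
        if np.any(P.sum(axis=0) != 1) or np.any(P.sum(axis=1) != 1):
            raise ValueError("P must have exactly one 1 per row and per column")
        return cls(np.argmax(P, axis=1))

    @property
    def n(self) -> int:
        return self.mapping.size

    def matrix(self) -> np.ndarray:
        P = np.zeros((self.n, self.n))
        P[np.arange(self.n), self.mapping] = 1.0
        return P

    def apply(self, C: np.ndarray) -> np.ndarray:
        """Permute rows and columns: returns ``P C P^T``."""
        return np.asarray(C)[np.ix_(self.mapping, self.mapping)]

    def inverse(self) -> "PermutationMatrix":
        return PermutationMatrix(np.argsort(self.mapping))

    def compose(self, other: "PermutationMatrix") -> "PermutationMatrix":
        """Matrix product ``self @ other`` as a permutation."""
        return PermutationMatrix(other.mapping[self.mapping])

    def is_identity(self) -> bool:
        return bool(np.array_equal(self.mapping, np.arange(self.n)))

    def __eq__(self, other) -> bool:
        return isinstance(other, PermutationMatrix) and np.array_equal(
            self.mapping, other.mapping
        )

    def __repr__(self) -> str:
        return f"PermutationMatrix({self.mapping.tolist()})"


@dataclass
class AlignmentResult:
    """Output of one alignment run.

    ``objective_trace`` records the trace-form objective value at each
    Frank-Wolfe iterate (index 0 is the initial matrix); it is
    non-increasing. ``converged_at`` is the iteration at which the early
    stop fired, or ``None`` if the iteration cap was reached.
    """

    permutation: PermutationMatrix
    objective_trace: np.ndarray
    strategy: str
    alpha: float | None = None
    n_iter: int = 0
    converged_at: int | None = None
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# objective, gradient, search direction, line search


def _as_arrays(connectomes) -> list[np.ndarray]:
    out = []
    for c in connectomes:
        out.append(c.values if isinstance(c, Connectome) else np.asarray(c, dtype=float))
    return out


def multimodal_objective(P, moving, reference, w: AlignmentWeights) -> float:
    """Trace-form objective ``-sum_i beta_i Tr(P C_i P^T C_{i,ref})``.

    ``P`` may be a :class:`PermutationMatrix` or any (doubly stochastic)
    matrix; ``moving`` and ``reference`` are equal-length sequences of
    connectomes (or raw arrays), one per modality.
    """
    Cs, Rs = _as_arrays(moving), _as_arrays(reference)
    if len(Cs) != len(Rs) or len(Cs) != len(w.betas):
        raise ValueError("moving, reference and weights must have equal modality count")
    Pm = P.matrix() if isinstance(P, PermutationMatrix) else np.asarray(P, dtype=float)
    total = 0.0
    for beta, C, Cr in zip(w.betas, Cs, Rs):
        if C.shape != Pm.shape or Cr.shape != Pm.shape:
            raise ValueError("dimension mismatch between P and connectomes")
        if beta == 0.0:
            continue
        total -= beta * np.trace(Pm @ C @ Pm.T @ Cr)
    return float(total)


def frobenius_objective(P, moving, reference, w: AlignmentWeights) -> float:
    """Frobenius-form objective ``sum_i beta_i ||P C_i P^T - C_{i,ref}||_F^2``."""
    Cs, Rs = _as_arrays(moving), _as_arrays(reference)
    total = 0.0
    for beta, C, Cr in zip(w.betas, Cs, Rs):
        if beta == 0.0:
            continue
        PC = P.apply(C) if isinstance(P, PermutationMatrix) else P @ C @ np.asarray(P).T
        total += beta * np.linalg.norm(PC - Cr) ** 2
    return float(total)


def objective_gradient(
    P, moving, reference, w: AlignmentWeights,
    R: RegularizationMatrix | None = None,
) -> np.ndarray:
    """Gradient of the trace-form objective, with forbidden entries at +inf.

    The data term is ``-2 sum_i beta_i C_{i,ref} P C_i``; entries forbidden
    by ``R`` are overwritten with ``np.inf``, the hard-constraint limit of
    an infinitely weighted penalty term.
    """
    Cs, Rs = _as_arrays(moving), _as_arrays(reference)
    Pm = P.matrix() if isinstance(P, PermutationMatrix) else np.asarray(P, dtype=float)
    grad = np.zeros_like(Pm)
    for beta, C, Cr in zip(w.betas, Cs, Rs):
        if beta == 0.0:
            continue
        grad -= 2.0 * beta * (Cr @ Pm @ C)
    if R is not None:
        grad = np.where(R.R == 1, np.inf, grad)
    return grad


def search_direction(grad: np.ndarray) -> PermutationMatrix:
    """Permutation minimizing ``<grad, Q>`` over the Birkhoff polytope.

    By Birkhoff's theorem the minimum of a linear form over doubly
    stochastic matrices is attained at a permutation, so this is a linear
    sum assignment problem; ``np.inf`` entries (forbidden assignments) are
    handled natively by the scipy Jonker-Volgenant solver. Ties are
    resolved deterministically by the solver given the fixed row-major cost
    layout.
    """
    grad = np.asarray(grad, dtype=float)
    try:
        rows, cols = linear_sum_assignment(grad)
    except ValueError as exc:
        raise ValueError(
            "no feasible assignment: the constraint mask admits no permutation"
        ) from exc
    mapping = np.empty(grad.shape[0], dtype=np.intp)
    mapping[rows] = cols
    return PermutationMatrix(mapping)


def exact_line_search(P, Q: PermutationMatrix, moving, reference,
                      w: AlignmentWeights) -> float:
    """Minimize the trace-form objective along ``gamma P + (1-gamma) Q``.

    Along the segment the objective is the scalar quadratic
    ``g(gamma) = a gamma^2 + b gamma + c`` with ``D = P - Q``,

        a = -sum_i beta_i Tr(D C_i D^T C_{i,ref})
        b = -sum_i beta_i [Tr(D C_i Q^T C_{i,ref}) + Tr(Q C_i D^T C_{i,ref})].

    Returns the interior minimizer clamped to [0, 1] when ``a > 0``, else
    whichever endpoint has the smaller value. ``gamma = 1`` keeps the
    current iterate, so the step never increases the objective.
    """
    Cs, Rs = _as_arrays(moving), _as_arrays(reference)
    Pm = P.matrix() if isinstance(P, PermutationMatrix) else np.asarray(P, dtype=float)
    Qm = Q.matrix()
    D = Pm - Qm
    if not np.any(D):
        return 1.0
    a = b = 0.0
    for beta, C, Cr in zip(w.betas, Cs, Rs):
        if beta == 0.0:
            continue
        DC = D @ C
        a -= beta * np.trace(DC @ D.T @ Cr)
        b -= beta * (np.trace(DC @ Qm.T @ Cr) + np.trace(Qm @ C @ D.T @ Cr))
    if a > 0.0:
        gamma = float(np.clip(-b / (2.0 * a), 0.0, 1.0))
    else:
        # concave or linear in gamma: an endpoint is optimal
        gamma = 1.0 if a + b <= 0.0 else 0.0
    return gamma


# ---------------------------------------------------------------------------
# Frank-Wolfe descent


def _project_to_permutation(
    P: np.ndarray, R: RegularizationMatrix | None
) -> PermutationMatrix:
    """Closest feasible permutation: maximize ``<P, Q>`` over allowed Q.

    Cast as assignment on ``-P`` with infinite cost at forbidden entries,
    so a zero-valued tie can never select a forbidden cell.
    """
    cost = -np.asarray(P, dtype=float)
    if R is not None:
        cost = np.where(R.R == 1, np.inf, cost)
    rows, cols = linear_sum_assignment(cost)
    mapping = np.empty(cost.shape[0], dtype=np.intp)
    mapping[rows] = cols
    return PermutationMatrix(mapping)


def frank_wolfe_align(
    moving, reference, w: AlignmentWeights,
    R: RegularizationMatrix | None = None,
    max_iter: int = 50, tol: float = 1e-9,
    init: np.ndarray | str = "identity",
) -> AlignmentResult:
    """Run constrained Frank-Wolfe descent and project to a permutation.

    Parameters
    ----------
    moving, reference : sequences of connectomes (or arrays), one per modality
    w : AlignmentWeights
        Modality weights.
    R : RegularizationMatrix, optional
        Forbidden-assignment mask; ``None`` means unconstrained.
    max_iter : int
        Iteration cap; the descent typically settles well before 50.
    tol : float
        Relative early-stop threshold on the objective decrease.
    init : "identity", "barycenter", or an explicit doubly stochastic matrix
        Starting iterate. Identity (perform no permutation) is the default;
        an explicit matrix must be feasible (zero at forbidden entries).

    Returns
    -------
    AlignmentResult
        With the projected feasible permutation, the per-iteration
        trace-form objective values, and convergence metadata.
    """
    Cs = _as_arrays(moving)
    n = Cs[0].shape[0]
    if R is not None:
        if R.n_regions != n:
            raise ValueError("constraint mask size does not match connectomes")
        report = check_feasible(R)
        if not report.feasible:
            raise ValueError(
                "infeasible constraint mask: no permutation uses only allowed "
                f"entries (Hall violation at rows {report.violating_rows})"
            )
    if isinstance(init, str):
        if init == "identity":
            P = np.eye(n)
        elif init == "barycenter":
            P = np.full((n, n), 1.0 / n)
            if R is not None:
                raise ValueError(
                    "barycenter initialization is not feasible under a constraint mask"
                )
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        P = np.asarray(init, dtype=float)
        if P.shape != (n, n):
            raise ValueError("init matrix has wrong shape")
        rows_ok = np.allclose(P.sum(axis=1), 1.0, atol=1e-9)
        cols_ok = np.allclose(P.sum(axis=0), 1.0, atol=1e-9)
        if not (rows_ok and cols_ok) or np.any(P < -1e-12):
            raise ValueError("init must be doubly stochastic")
        if R is not None and np.any(P[R.R == 1] > 1e-12):
            raise ValueError("init must be zero at forbidden entries")

    trace = [multimodal_objective(P, moving, reference, w)]
    converged_at = None
    it = 0
    for it in range(1, max_iter + 1):
        grad = objective_gradient(P, moving, reference, w, R)
        Q = search_direction(grad)
        gamma = exact_line_search(P, Q, moving, reference, w)
        P = gamma * P + (1.0 - gamma) * Q.matrix()
        obj = multimodal_objective(P, moving, reference, w)
        trace.append(obj)
        prev = trace[-2]
        if prev - obj < tol * max(1.0, abs(prev)):
            converged_at = it
            break
    permutation = _project_to_permutation(P, R)
    return AlignmentResult(
        permutation=permutation,
        objective_trace=np.asarray(trace),
        strategy="custom",
        n_iter=it,
        converged_at=converged_at,
    )


# ---------------------------------------------------------------------------
# strategy wrappers


def _subject_pair(moving, reference, fc_index: int):
    """Extract matched (SC, FC) modality lists from SubjectData or pairs."""
    def pick(s):
        if isinstance(s, SubjectData):
            return [s.sc.values, s.fc[fc_index].values]
        sc, fc = s
        return _as_arrays([sc, fc])

    return pick(moving), pick(reference)


def align(
    strategy: str,
    moving,
    reference,
    alpha: float = 0.5,
    adjacency: RegionAdjacency | None = None,
    fc_index: int = 0,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> AlignmentResult:
    """Align one subject's connectomes to a reference subject's.

    Parameters
    ----------
    strategy : {"ha", "wba", "wbanc"}
        ``ha`` runs two independent unconstrained descents on the
        hemispheric diagonal blocks and assembles the block-diagonal
        whole-brain permutation; ``wba`` runs one whole-brain descent under
        the hemisphere mask; ``wbanc`` restricts further to spatially
        adjacent regions (requires ``adjacency``).
    moving, reference : SubjectData or (sc, fc) pairs
        The subject to be aligned and the subject of reference. Regions
        must be ordered left hemisphere first, right hemisphere last.
    alpha : float in [0, 1]
        SC weight; the FC weight is ``1 - alpha``.
    fc_index : int
        Which FC of a multi-FC subject enters the objective (default: the
        first, e.g. resting-state run 1).
    """
    strategy = strategy.lower()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    w = AlignmentWeights.from_alpha(alpha)
    mov, ref = _subject_pair(moving, reference, fc_index)
    n = mov[0].shape[0]
    if n % 2 != 0:
        raise ValueError("whole-brain connectomes must have an even region count")
    h = n // 2

    if strategy == "ha":
        mappings = []
        traces = []
        iters = 0
        conv = []
        for sl in (slice(0, h), slice(h, n)):
            mov_b = [C[sl, sl] for C in mov]
            ref_b = [C[sl, sl] for C in ref]
            res = frank_wolfe_align(mov_b, ref_b, w, R=None,
                                    max_iter=max_iter, tol=tol)
            mappings.append(res.permutation.mapping + sl.start)
            traces.append(res.objective_trace)
            iters = max(iters, res.n_iter)
            conv.append(res.converged_at)
        permutation = PermutationMatrix(np.concatenate(mappings))
        trace_len = max(len(t) for t in traces)
        padded = [np.pad(t, (0, trace_len - len(t)), mode="edge") for t in traces]
        result = AlignmentResult(
            permutation=permutation,
            objective_trace=padded[0] + padded[1],
            strategy="ha",
            alpha=alpha,
            n_iter=iters,
            converged_at=None if None in conv else max(c for c in conv),
        )
        return result

    if strategy == "wba":
        R = build_r_hemi(n)
    else:  # wbanc
        if adjacency is None:
            raise ValueError("strategy 'wbanc' requires a region adjacency graph")
        if adjacency.N != n:
            raise ValueError("adjacency region count does not match connectomes")
        R = build_r_neigh(adjacency)
    res = frank_wolfe_align(mov, ref, w, R=R, max_iter=max_iter, tol=tol)
    res.strategy = strategy
    res.alpha = alpha
    return res


class ConnectomeAligner(TransformerMixin, BaseEstimator):
    """Scikit-learn style estimator wrapping the constrained FAQ solver.

    ``fit(moving, reference)`` estimates the region permutation aligning
    the moving subject's connectomes to the reference subject's;
    ``transform`` then applies the learned permutation ``P C P^T`` to any
    connectome of the moving subject — including modalities not used in the
    fit, which is how generalization of a permutation is assessed.

    Parameters
    ----------
    strategy : {"ha", "wba", "wbanc"}
        Constraint regime (see :func:`align`).
    alpha : float in [0, 1]
        Weight of the SC term; ``1 - alpha`` weighs the FC term.
    adjacency : RegionAdjacency, optional
        Spatial neighborhood graph; required for ``wbanc``.
    fc_index : int
        Index of the FC used in the objective when a subject has several.
    max_iter : int
        Frank-Wolfe iteration cap.
    tol : float
        Relative early-stop threshold.

    Attributes
    ----------
    permutation_ : PermutationMatrix
        The estimated feasible permutation.
    objective_trace_ : ndarray
        Trace-form objective value per iteration (non-increasing).
    n_iter_ : int
        Iterations actually run.
    converged_at_ : int or None
        Iteration of early convergence, if any.
    """

    def __init__(self, strategy: str = "wba", alpha: float = 0.5,
                 adjacency: RegionAdjacency | None = None, fc_index: int = 0,
                 max_iter: int = 50, tol: float = 1e-9):
        self.strategy = strategy
        self.alpha = alpha
        self.adjacency = adjacency
        self.fc_index = fc_index
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        """Estimate the permutation aligning subject ``X`` to reference ``y``.

        ``X`` and ``y`` are :class:`~connalign.connectomes.SubjectData`
        instances or ``(sc, fc)`` pairs of connectomes/arrays.
        """
        result = align(
            self.strategy, X, y, alpha=self.alpha, adjacency=self.adjacency,
            fc_index=self.fc_index, max_iter=self.max_iter, tol=self.tol,
        )
        self.permutation_ = result.permutation
        self.objective_trace_ = result.objective_trace
        self.n_iter_ = result.n_iter
        self.converged_at_ = result.converged_at
        self.result_ = result
        return self

    def transform(self, X):
        """Apply the learned permutation to connectomes of the moving subject.

        Accepts a single connectome/array, a sequence of them, or a
        :class:`SubjectData`; returns permuted arrays of the same layout.
        """
        if not hasattr(self, "permutation_"):
            raise AttributeError("this ConnectomeAligner instance is not fitted yet")
        P = self.permutation_
        if isinstance(X, SubjectData):
            return [P.apply(X.sc.values)] + [P.apply(c.values) for c in X.fc]
        if isinstance(X, Connectome):
            return P.apply(X.values)
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            return P.apply(X)
        return np.stack([P.apply(c) for c in X])
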