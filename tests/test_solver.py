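"""Constrained Frank-Wolfe solver: objective, directions, descent, strategies."""

import numpy as np
import pytest
from sklearn.base import clone

from connalign import (
    AlignmentWeights,
    CohortSpec,
    ConnectomeAligner,
    PermutationMatrix,
    align,
    brute_force_qap,
    build_r_hemi,
    build_r_neigh,
    exact_line_search,
    frank_wolfe_align,
    frobenius_objective,
    generate_cohort,
    grid_adjacency,
    multimodal_objective,
    objective_gradient,
    search_direction,
)
from conftest import random_correlation, random_symmetric


def planted_instance(seed, rows=1, cols=3, n_swaps=1, noise=0.0):
    """One noiseless (or noisy) subject and a constraint-respecting scramble."""
    spec = CohortSpec(
        n_subjects=1, grid_rows=rows, grid_cols=cols,
        sc_noise_sd=noise, fc_noise_sd=noise,
        n_planted_swaps=n_swaps, seed=seed,
    )
    subjects, adjacency, planted = generate_cohort(spec)
    s = subjects[0]
    return (s.sc.values, s.fc[0].values), adjacency, planted[0]


class TestWeights:
    def test_alpha_shorthand(self):
        w = AlignmentWeights.from_alpha(0.3)
        assert w.betas == pytest.approx((0.3, 0.7))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            AlignmentWeights((0.5, 0.6))
        with pytest.raises(ValueError):
            AlignmentWeights((-0.1, 1.1))
        with pytest.raises(ValueError):
            AlignmentWeights.from_alpha(1.5)


class TestPermutationMatrix:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.permutations(list(range(6))))
    @settings(max_examples=50, deadline=None)
    def test_group_action_properties(self, mapping):
        """Inverse undoes apply; composition acts as matrix product."""
        local = np.random.default_rng(0)
        C = random_symmetric(6, local)
        P = PermutationMatrix(np.asarray(mapping))
        Q = PermutationMatrix(local.permutation(6))
        assert np.allclose(P.inverse().apply(P.apply(C)), C)
        assert np.allclose(P.compose(Q).apply(C), P.apply(Q.apply(C)))
        assert np.allclose(
            P.compose(Q).matrix(), P.matrix() @ Q.matrix()
        )

    def test_matrix_mapping_round_trip(self, rng):
        mapping = rng.permutation(8)
        P = PermutationMatrix(mapping)
        assert PermutationMatrix.from_matrix(P.matrix()) == P
        assert P.compose(P.inverse()).is_identity()

    def test_apply_permutes_rows_and_columns(self, rng):
        C = random_symmetric(4, rng)
        P = PermutationMatrix([1, 0, 3, 2])
        direct = P.matrix() @ C @ P.matrix().T
        assert np.allclose(P.apply(C), direct)

    def test_invalid_mapping_rejected(self):
        with pytest.raises(ValueError):
            PermutationMatrix([0, 0, 1])


class TestObjective:
    def test_frobenius_trace_identity(self, rng):
        """||PCP^T - Cref||_F^2 == ||C||^2 + ||Cref||^2 - 2 Tr(PCP^T Cref)."""
        for _ in range(10):
            C = random_symmetric(6, rng)
            Cr = random_symmetric(6, rng)
            P = PermutationMatrix(rng.permutation(6))
            w = AlignmentWeights((1.0,))
            frob = frobenius_objective(P, [C], [Cr], w)
            trace = multimodal_objective(P, [C], [Cr], w)
            const = np.linalg.norm(C) ** 2 + np.linalg.norm(Cr) ** 2
            assert frob == pytest.approx(2 * trace + const, abs=1e-8)

    def test_self_alignment_at_identity(self, rng):
        C = random_symmetric(5, rng)
        # N=5 arrays are fine below the Connectome layer
        P = np.eye(5)
        w = AlignmentWeights((1.0,))
        assert multimodal_objective(P, [C], [C], w) == pytest.approx(
            -np.trace(C @ C)
        )
        Pp = PermutationMatrix.identity(5)
        assert frobenius_objective(Pp, [C], [C], w) == pytest.approx(0.0)

    def test_degenerate_weight_ignores_modality(self, rng):
        sc = random_symmetric(4, rng)
        fc1 = random_correlation(4, rng)
        fc2 = random_correlation(4, np.random.default_rng(99))
        w = AlignmentWeights.from_alpha(1.0)
        P = np.eye(4)
        a = multimodal_objective(P, [sc, fc1], [sc, fc1], w)
        b = multimodal_objective(P, [sc, fc2], [sc, fc2], w)
        assert a == pytest.approx(b)

    def test_planted_swap_zeroes_frobenius_form(self):
        C_b = np.array([[0.0, 1, 0], [1, 0, 2], [0, 2, 0]])
        Pi = PermutationMatrix([1, 0, 2])
        C_a = Pi.apply(C_b)
        w = AlignmentWeights((1.0,))
        assert frobenius_objective(Pi.inverse(), [C_a], [C_b], w) == pytest.approx(0.0)
        assert frobenius_objective(
            PermutationMatrix.identity(3), [C_a], [C_b], w
        ) > 0


class TestGradient:
    def test_matches_finite_differences(self, rng):
        """Central-difference oracle on the trace objective at a random P."""
        C = random_symmetric(5, rng)
        Cr = random_symmetric(5, rng)
        fc = random_correlation(5, rng)
        fcr = random_correlation(5, rng)
        w = AlignmentWeights.from_alpha(0.4)
        P = rng.random((5, 5))
        grad = objective_gradient(P, [C, fc], [Cr, fcr], w)
        eps = 1e-6
        for k in range(5):
            for l in range(5):
                Pp, Pm = P.copy(), P.copy()
                Pp[k, l] += eps
                Pm[k, l] -= eps
                num = (
                    multimodal_objective(Pp, [C, fc], [Cr, fcr], w)
                    - multimodal_objective(Pm, [C, fc], [Cr, fcr], w)
                ) / (2 * eps)
                assert grad[k, l] == pytest.approx(num, abs=1e-5)

    def test_sentinels_at_forbidden_entries_only(self):
        z = np.zeros((4, 4))
        R = build_r_hemi(4)
        grad = objective_gradient(np.eye(4), [z], [z], AlignmentWeights((1.0,)), R)
        assert np.all(np.isinf(grad[R.R == 1]))
        assert np.all(grad[R.R == 0] == 0)

    def test_bilinearity_in_connectomes(self, rng):
        C = random_symmetric(4, rng)
        Cr = random_symmetric(4, rng)
        w = AlignmentWeights((1.0,))
        g1 = objective_gradient(np.eye(4), [C], [Cr], w)
        g4 = objective_gradient(np.eye(4), [2 * C], [2 * Cr], w)
        assert np.allclose(g4, 4 * g1)


class TestSearchDirection:
    def test_two_by_two_enumeration(self):
        Q = search_direction(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert Q.is_identity()

    def test_sentinels_force_identity(self, rng):
        grad = rng.normal(size=(5, 5))
        grad[~np.eye(5, dtype=bool)] = np.inf
        assert search_direction(grad).is_identity()

    def test_matches_exhaustive_minimum(self, rng):
        """Assignment cost equals the minimum over all 720 permutations."""
        from itertools import permutations

        for _ in range(5):
            cost = rng.normal(size=(6, 6))
            Q = search_direction(cost)
            achieved = cost[np.arange(6), Q.mapping].sum()
            best = min(
                sum(cost[k, p[k]] for k in range(6))
                for p in permutations(range(6))
            )
            assert achieved == pytest.approx(best, abs=1e-12)

    def test_infeasible_mask_raises(self):
        grad = np.full((3, 3), np.inf)
        with pytest.raises(ValueError, match="feasible"):
            search_direction(grad)


class TestLineSearch:
    def test_degenerate_direction_keeps_current(self, rng):
        P = PermutationMatrix(rng.permutation(5))
        C = random_symmetric(5, rng)
        w = AlignmentWeights((1.0,))
        assert exact_line_search(P.matrix(), P, [C], [C], w) == 1.0

    def test_matches_grid_search(self, rng):
        """Returned step agrees with a dense scan of the segment objective."""
        w = AlignmentWeights.from_alpha(0.5)
        for seed in range(10):
            local = np.random.default_rng(seed)
            C = [random_symmetric(5, local), random_correlation(5, local)]
            Cr = [random_symmetric(5, local), random_correlation(5, local)]
            P = local.random((5, 5))
            P = P / P.sum(axis=1, keepdims=True)  # row-stochastic is enough here
            Q = PermutationMatrix(local.permutation(5))
            gamma = exact_line_search(P, Q, C, Cr, w)
            grid = np.linspace(0, 1, 10001)
            vals = [
                multimodal_objective(g * P + (1 - g) * Q.matrix(), C, Cr, w)
                for g in grid
            ]
            best = grid[int(np.argmin(vals))]
            achieved = multimodal_objective(
                gamma * P + (1 - gamma) * Q.matrix(), C, Cr, w
            )
            assert achieved <= min(vals) + 1e-9
            if 0.0 < best < 1.0:
                assert gamma == pytest.approx(best, abs=1e-3)

    def test_concave_case_returns_endpoint(self, rng):
        # engineered concave segment: minimize -Tr over a direction with a<0
        w = AlignmentWeights((1.0,))
        for seed in range(20):
            local = np.random.default_rng(seed)
            C = random_symmetric(4, local)
            Cr = random_symmetric(4, local)
            P = np.full((4, 4), 0.25)
            Q = PermutationMatrix(local.permutation(4))
            D = P - Q.matrix()
            a = -np.trace(D @ C @ D.T @ Cr)
            if a >= 0:
                continue
            gamma = exact_line_search(P, Q, [C], [Cr], w)
            assert gamma in (0.0, 1.0)


class TestFrankWolfe:
    def test_self_alignment_reaches_zero(self, rng):
        C = random_symmetric(6, rng)
        fc = random_correlation(6, rng)
        w = AlignmentWeights.from_alpha(0.5)
        res = frank_wolfe_align([C, fc], [C, fc], w)
        assert frobenius_objective(
            res.permutation, [C, fc], [C, fc], w
        ) == pytest.approx(0.0, abs=1e-10)

    def test_only_identity_feasible(self, rng):
        from connalign import RegularizationMatrix

        C = random_symmetric(4, rng)
        R = RegularizationMatrix(1 - np.eye(4, dtype=int))
        res = frank_wolfe_align([C], [random_symmetric(4, rng)],
                                AlignmentWeights((1.0,)), R)
        assert res.permutation.is_identity()

    def test_iterates_monotone_and_feasible(self):
        for seed in range(5):
            moving, adjacency, pi = planted_instance(seed, rows=2, cols=3,
                                                     n_swaps=2)
            original = (pi.inverse().apply(moving[0]), pi.inverse().apply(moving[1]))
            R = build_r_neigh(adjacency)
            w = AlignmentWeights.from_alpha(0.5)
            res = frank_wolfe_align(list(moving), list(original), w, R)
            assert np.all(np.diff(res.objective_trace) <= 1e-9)
            assert R.allows(res.permutation.mapping)

    def test_infeasible_init_rejected(self, rng):
        C = random_symmetric(4, rng)
        R = build_r_hemi(4)
        bad = np.full((4, 4), 0.25)
        with pytest.raises(ValueError, match="forbidden"):
            frank_wolfe_align([C], [C], AlignmentWeights((1.0,)), R, init=bad)


class TestStrategies:
    def test_oracle_equivalence_on_noiseless_planted_instances(self):
        """Solver attains the exhaustive constrained optimum at N=6."""
        w = AlignmentWeights.from_alpha(0.5)
        for strategy in ("ha", "wba", "wbanc"):
            for seed in range(20):
                moving, adjacency, pi = planted_instance(seed, n_swaps=1)
                original = (
                    pi.inverse().apply(moving[0]),
                    pi.inverse().apply(moving[1]),
                )
                res = align(strategy, moving, original, alpha=0.5,
                            adjacency=adjacency)
                R = (build_r_neigh(adjacency) if strategy == "wbanc"
                     else build_r_hemi(6))
                _, best = brute_force_qap(moving, original, w, R)
                achieved = frobenius_objective(
                    res.permutation, list(moving), list(original), w
                )
                assert achieved == pytest.approx(best, abs=1e-8)

    def test_never_beats_oracle_on_noisy_instances(self):
        w = AlignmentWeights.from_alpha(0.5)
        for seed in range(10):
            moving, adjacency, pi = planted_instance(seed, n_swaps=1, noise=0.3)
            original = (
                pi.inverse().apply(moving[0]),
                pi.inverse().apply(moving[1]),
            )
            res = align("wba", moving, original, alpha=0.5)
            _, best = brute_force_qap(moving, original, w, build_r_hemi(6))
            achieved = frobenius_objective(
                res.permutation, list(moving), list(original), w
            )
            assert achieved >= best - 1e-8

    def test_nested_feasibility_ordering(self):
        """Smaller feasible sets cannot achieve better optima (brute force)."""
        w = AlignmentWeights.from_alpha(0.5)
        for seed in range(5):
            moving, adjacency, _ = planted_instance(seed, n_swaps=2, noise=0.2)
            local = np.random.default_rng(1000 + seed)
            reference = (
                random_symmetric(6, local, scale=2.0),
                random_correlation(6, local),
            )
            _, f_neigh = brute_force_qap(moving, reference, w,
                                         build_r_neigh(adjacency))
            _, f_hemi = brute_force_qap(moving, reference, w, build_r_hemi(6))
            _, f_free = brute_force_qap(moving, reference, w, None)
            assert f_neigh >= f_hemi - 1e-10
            assert f_hemi >= f_free - 1e-10

    def test_wba_equals_ha_without_interhemispheric_data(self, rng):
        """Zero cross-hemisphere blocks make the problem block-separable."""
        w = AlignmentWeights.from_alpha(0.5)
        for seed in range(5):
            local = np.random.default_rng(seed)
            def blocked(maker):
                m = np.zeros((6, 6))
                m[:3, :3] = maker()
                m[3:, 3:] = maker()
                return m

            sc = blocked(lambda: random_symmetric(3, local, scale=2.0))
            fc_full = random_correlation(6, local)
            fc = np.where(build_r_hemi(6).R == 1, 0.0, fc_full)
            sc_ref = blocked(lambda: random_symmetric(3, local, scale=2.0))
            fc_ref = np.where(build_r_hemi(6).R == 1, 0.0, fc_full + 0.0)
            res_wba = align("wba", (sc, fc), (sc_ref, fc_ref), alpha=0.5)
            res_ha = align("ha", (sc, fc), (sc_ref, fc_ref), alpha=0.5)
            f_wba = frobenius_objective(res_wba.permutation, [sc, fc],
                                        [sc_ref, fc_ref], w)
            f_ha = frobenius_objective(res_ha.permutation, [sc, fc],
                                       [sc_ref, fc_ref], w)
            assert f_wba == pytest.approx(f_ha, abs=1e-8)

    def test_outputs_never_cross_hemispheres(self, small_cohort):
        _, subjects, adjacency, _ = small_cohort
        n = subjects[0].n_regions
        h = n // 2
        for strategy in ("ha", "wba", "wbanc"):
            res = align(strategy, subjects[0], subjects[1], alpha=0.5,
                        adjacency=adjacency)
            mapping = res.permutation.mapping
            assert np.all((mapping[:h] < h) & (mapping[h:] >= h))
            # exactly one 1 per row/column
            assert np.array_equal(np.sort(mapping), np.arange(n))

    def test_wbanc_requires_adjacency(self, subject_pair):
        a, b = subject_pair
        with pytest.raises(ValueError, match="adjacency"):
            align("wbanc", a, b, alpha=0.5)

    def test_self_alignment_any_strategy(self, tiny_cohort):
        _, subjects, adjacency, _ = tiny_cohort
        s = subjects[0]
        w = AlignmentWeights.from_alpha(0.5)
        for strategy in ("ha", "wba", "wbanc"):
            res = align(strategy, s, s, alpha=0.5, adjacency=adjacency)
            assert frobenius_objective(
                res.permutation, [s.sc.values, s.fc[0].values],
                [s.sc.values, s.fc[0].values], w
            ) == pytest.approx(0.0, abs=1e-10)


class TestConnectomeAligner:
    def test_sklearn_params_round_trip(self):
        est = ConnectomeAligner(strategy="wbanc", alpha=0.3, max_iter=25)
        params = est.get_params()
        assert params["strategy"] == "wbanc"
        assert params["alpha"] == 0.3
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(alpha=0.7)
        assert est.alpha == 0.7

    def test_fit_transform_recovers_planted_permutation(self):
        moving, adjacency, pi = planted_instance(4, rows=2, cols=3, n_swaps=2)
        original = (pi.inverse().apply(moving[0]), pi.inverse().apply(moving[1]))
        est = ConnectomeAligner(strategy="wbanc", alpha=0.5,
                                adjacency=adjacency)
        est.fit(moving, original)
        assert est.permutation_ == pi.inverse()
        assert np.allclose(est.transform(moving[0]), original[0])
        assert est.n_iter_ >= 1
        assert np.all(np.diff(est.objective_trace_) <= 1e-9)

    def test_unfitted_transform_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            ConnectomeAligner().transform(np.eye(4))
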