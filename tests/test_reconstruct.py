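"""Distance-geometry engine: bounds, smoothing, embedding, refinement."""

import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from contactsr import (
    Contact,
    ContactMap,
    DistanceBounds,
    DistillerConfig,
    SseAnnotation,
    compile_bounds,
    embed,
    kabsch_rmsd,
    reconstruct,
    refine,
    score_with_mirror,
    smooth_bounds,
)
from contactsr.errors import InfeasibleBoundsError, ParameterError
from contactsr.reconstruct import (
    CONTACT_LOWER,
    HELIX_I3,
    HELIX_I4,
    SEQ_LOWER,
    SEQ_UPPER,
    _violation_energy,
)


class TestCompileBounds:
    def test_minimal_chain_has_only_sequential_bound(self):
        bounds = compile_bounds(2, ContactMap(2))
        assert bounds.lower[0, 1] == SEQ_LOWER
        assert bounds.upper[0, 1] == SEQ_UPPER

    def test_contact_pair_bounded_by_cutoff(self):
        bounds = compile_bounds(10, ContactMap(10, [Contact(0, 6)]), cutoff=8.0)
        assert bounds.upper[0, 6] <= 8.0
        assert bounds.lower[0, 6] >= CONTACT_LOWER

    def test_all_helix_annotation_adds_canonical_windows(self):
        L = 10
        bounds = compile_bounds(L, ContactMap(L), sse=SseAnnotation("H" * L))
        for i in range(L - 3):
            assert bounds.upper[i, i + 3] <= HELIX_I3[1]
            assert bounds.lower[i, i + 3] >= HELIX_I3[0]
        for i in range(L - 4):
            assert bounds.upper[i, i + 4] <= HELIX_I4[1]
            assert bounds.lower[i, i + 4] >= HELIX_I4[0]

    def test_sse_length_mismatch(self):
        with pytest.raises(ParameterError):
            compile_bounds(10, ContactMap(10), sse=SseAnnotation("H" * 9))


class TestSmoothBounds:
    def _bounds(self, upper, lower=None):
        upper = np.asarray(upper, dtype=float)
        if lower is None:
            lower = np.zeros_like(upper)
        np.fill_diagonal(upper, 0.0)
        np.fill_diagonal(lower, 0.0)
        return DistanceBounds(lower, upper)

    def test_triangle_inequality_forces_transitive_upper(self):
        big = 1e6
        bounds = self._bounds([[0, 8, big], [8, 0, 8], [big, 8, 0]])
        assert smooth_bounds(bounds).upper[0, 2] == pytest.approx(16.0)

    def test_idempotent_on_consistent_bounds(self, bundle):
        first = compile_bounds(len(bundle.trace), bundle.contact_map)
        second = smooth_bounds(first)
        np.testing.assert_allclose(second.upper, first.upper)
        np.testing.assert_allclose(second.lower, first.lower)

    @pytest.mark.parametrize("seed", range(5))
    def test_upper_smoothing_matches_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        L = 20
        upper = rng.uniform(2, 30, size=(L, L))
        upper = (upper + upper.T) / 2
        np.fill_diagonal(upper, 0.0)
        smoothed = smooth_bounds(self._bounds(upper.copy()))
        reference = shortest_path(upper, method="FW", directed=False)
        np.testing.assert_allclose(smoothed.upper, reference, atol=1e-9)

    def test_infeasible_bounds_detected(self):
        upper = np.array([[0.0, 2.0, 10.0], [2.0, 0.0, 2.0], [10.0, 2.0, 0.0]])
        lower = np.array([[0.0, 0.0, 9.0], [0.0, 0.0, 0.0], [9.0, 0.0, 0.0]])
        # u(0,2) smooths to 4 < l(0,2) = 9
        with pytest.raises(InfeasibleBoundsError):
            smooth_bounds(DistanceBounds(lower, upper))


class TestEmbed:
    def test_exact_for_unit_square(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        dist = squareform(pdist(square))
        trace = embed(DistanceBounds(dist, dist), rng_seed=0)
        assert score_with_mirror(trace.coords, square).rmsd < 1e-6

    def test_planar_set_has_vanishing_third_dimension(self):
        rng = np.random.default_rng(1)
        points = np.column_stack([rng.uniform(-5, 5, (10, 2)), np.zeros(10)])
        dist = squareform(pdist(points))
        trace = embed(DistanceBounds(dist, dist), rng_seed=0)
        # third principal axis carries no variance for a planar Gram matrix
        centered = trace.coords - trace.coords.mean(axis=0)
        assert np.linalg.svd(centered, compute_uv=False)[2] < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_random_point_sets(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.uniform(-10, 10, size=(5, 3))
        dist = squareform(pdist(points))
        trace = embed(DistanceBounds(dist, dist), rng_seed=seed)
        assert score_with_mirror(trace.coords, points).rmsd < 1e-6


class TestRefine:
    def test_satisfying_coords_unchanged(self, helix30):
        dist = squareform(pdist(helix30.coords))
        upper = dist + 0.5
        np.fill_diagonal(upper, 0.0)
        bounds = DistanceBounds(np.maximum(dist - 0.5, 0), upper)
        refined, energy = refine(helix30, bounds)
        assert energy == 0.0
        np.testing.assert_array_equal(refined.coords, helix30.coords)

    def test_single_violation_resolved(self):
        from contactsr.model import CaTrace

        trace = CaTrace("A", [1, 2], ("ALA",) * 2, [[0, 0, 0], [10, 0, 0]])
        bounds = DistanceBounds(np.zeros((2, 2)), np.array([[0.0, 8.0], [8.0, 0.0]]))
        refined, energy = refine(trace, bounds, n_project=0)
        d = np.linalg.norm(refined.coords[1] - refined.coords[0])
        assert d <= 8.0 + 1e-3
        assert energy < 1e-4

    def test_full_distance_constraints_recover_ground_truth(self, bundle):
        """Degenerate (exact) bounds pull a random embedding onto the native
        structure to sub-0.5 Å after mirror resolution."""
        truth = bundle.trace
        dist = squareform(pdist(truth.coords))
        bounds = DistanceBounds(dist, dist)
        loose_upper = dist * 2.0 + 10.0
        np.fill_diagonal(loose_upper, 0.0)
        start = embed(DistanceBounds(np.zeros_like(dist), loose_upper), rng_seed=4)
        refined, _ = refine(start, bounds, steps=2000)
        assert score_with_mirror(refined.coords, truth).rmsd < 0.5

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        L = 6
        x = rng.uniform(-3, 3, size=3 * L)
        lower = rng.uniform(1, 4, size=(L, L))
        lower = (lower + lower.T) / 2
        upper = lower + rng.uniform(0.1, 2, size=(L, L))
        upper = (upper + upper.T) / 2
        np.fill_diagonal(lower, 0.0)
        np.fill_diagonal(upper, 0.0)
        _, grad = _violation_energy(x, lower, upper)
        eps = 1e-6
        for k in range(0, 3 * L, 5):
            xp, xm = x.copy(), x.copy()
            xp[k] += eps
            xm[k] -= eps
            num = (
                _violation_energy(xp, lower, upper)[0]
                - _violation_energy(xm, lower, upper)[0]
            ) / (2 * eps)
            assert grad[k] == pytest.approx(num, abs=1e-4)


class TestReconstruct:
    def test_empty_map_keeps_chain_connectivity(self, fast_config):
        result = reconstruct(ContactMap(20), config=fast_config)
        assert len(result.models) == fast_config.top_k
        for model in result.models:
            steps = np.linalg.norm(np.diff(model.coords, axis=0), axis=1)
            assert np.all(steps >= SEQ_LOWER - 0.05)
            assert np.all(steps <= SEQ_UPPER + 0.05)

    def test_deterministic_under_fixed_seed(self, bundle, fast_config):
        a = reconstruct(bundle.contact_map, sse=bundle.sse, native=bundle.trace,
                        config=fast_config)
        b = reconstruct(bundle.contact_map, sse=bundle.sse, native=bundle.trace,
                        config=fast_config)
        assert a.rmsd == b.rmsd
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.coords, mb.coords)

    def test_kept_models_have_lowest_energies(self, bundle, fast_config):
        result = reconstruct(bundle.contact_map, config=fast_config)
        kept = result.energies
        assert np.all(np.diff(kept) >= 0)
        assert kept[-1] <= result.candidate_energies[fast_config.top_k:].min() + 1e-12

    def test_full_coverage_resembles_native(self, bundle, fast_config):
        result = reconstruct(
            bundle.contact_map, sse=bundle.sse, native=bundle.trace, config=fast_config
        )
        assert result.rmsd < 4.0
        assert result.tm > 0.5
        assert result.satisfied_fraction >= 0.9
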