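import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import special_ortho_group

import craniodim as cd
from craniodim.procrustes import _normalize, _optimal_rotation
from oracles import procrustes_residual_bruteforce


def _random_rigid(rng, scale=1.0):
    rotation = special_ortho_group.rvs(3, random_state=rng)
    translation = rng.uniform(-50, 50, size=3)
    return lambda pts: scale * pts @ rotation.T + translation


class TestCentroidSize:
    def test_unit_square_corners(self):
        corners = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert cd.centroid_size(corners) == pytest.approx(np.sqrt(2))

    def test_scaling_doubles_size(self, template):
        assert cd.centroid_size(2 * template.coords) == pytest.approx(
            2 * cd.centroid_size(template.coords)
        )

    def test_template_matches_arithmetic_oracle(self, template):
        pts = template.coords
        center = pts.sum(axis=0) / len(pts)
        oracle = sum(
            sum((pts[i, j] - center[j]) ** 2 for j in range(3)) for i in range(len(pts))
        ) ** 0.5
        assert cd.centroid_size(pts) == pytest.approx(oracle, abs=1e-9)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            cd.centroid_size(np.ones((24, 3)))


class TestOrdinaryProcrustes:
    def test_similarity_transformed_copy_aligns_exactly(self, template):
        rng = np.random.default_rng(1)
        moved = _random_rigid(rng, scale=2.5)(template.coords)
        _, residual = cd.ordinary_procrustes_align(moved, template.coords)
        assert residual < 1e-10

    def test_reflected_chiral_configuration_never_aligns(self, template):
        reflected = template.coords * np.array([1.0, 1.0, -1.0])
        # break the template's bilateral symmetry so reflection is chiral
        chiral = template.coords.copy()
        chiral[0] += [7.0, 3.0, 11.0]
        reflected = chiral * np.array([1.0, 1.0, -1.0])
        _, residual = cd.ordinary_procrustes_align(reflected, chiral)
        assert residual > 1e-3

    def test_rotation_determinants_are_plus_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = _normalize(rng.normal(size=(5, 3)))
            b = _normalize(rng.normal(size=(5, 3)))
            rotation = _optimal_rotation(b, a)
            assert np.linalg.det(rotation) == pytest.approx(1.0, abs=1e-9)

    def test_random_5_point_residual_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for rep in range(3):
            a = rng.normal(size=(5, 3))
            b = rng.normal(size=(5, 3))
            _, residual = cd.ordinary_procrustes_align(b, a)
            oracle = procrustes_residual_bruteforce(a, b, seed=rep)
            assert residual == pytest.approx(oracle, abs=1e-6)

    def test_degenerate_point_set_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate|rank"):
            cd.ordinary_procrustes_align(line, line)


class TestProcrustesDistance:
    def test_identical_shapes_give_zero(self, template):
        s = _normalize(template.coords)
        assert cd.procrustes_distance(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = _normalize(rng.normal(size=(5, 3)))
        b = _normalize(rng.normal(size=(5, 3)))
        assert cd.procrustes_distance(a, b) == pytest.approx(
            cd.procrustes_distance(b, a), abs=1e-12
        )

    def test_non_normalized_input_rejected(self, template):
        with pytest.raises(ValueError, match="normalize"):
            cd.procrustes_distance(template.coords, template.coords)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        a = _normalize(rng.normal(size=(8, 3)))
        b = _normalize(rng.normal(size=(8, 3)))
        rotation = special_ortho_group.rvs(3, random_state=rng)
        assert cd.procrustes_distance(a, b @ rotation.T) == pytest.approx(
            cd.procrustes_distance(a, b), abs=1e-9
        )


class TestGeneralizedProcrustes:
    def test_similarity_copies_collapse_to_one_shape(self, template):
        rng = np.random.default_rng(6)
        configs = np.stack([
            _random_rigid(rng, scale=s)(template.coords) for s in (0.5, 1.0, 2.0, 3.0)
        ])
        gpa = cd.generalized_procrustes(configs)
        assert gpa.converged
        for shape in gpa.shape_coords:
            np.testing.assert_allclose(shape, gpa.shape_coords[0], atol=1e-8)
        np.testing.assert_allclose(gpa.consensus, gpa.shape_coords[0], atol=1e-8)
        np.testing.assert_allclose(gpa.centroid_sizes,
                                   cd.centroid_size(template.coords) * np.array([0.5, 1, 2, 3]))

    def test_consensus_of_two_shapes_is_equidistant(self, template):
        rng = np.random.default_rng(7)
        other = template.coords + rng.normal(0, 2.0, size=(24, 3))
        gpa = cd.generalized_procrustes(np.stack([template.coords, other]))
        d0 = cd.procrustes_distance(gpa.consensus, gpa.shape_coords[0])
        d1 = cd.procrustes_distance(gpa.consensus, gpa.shape_coords[1])
        assert d0 == pytest.approx(d1, abs=1e-8)

    def test_idempotence_on_aligned_shapes(self, small_cohort_arrays):
        _, configs, *_ = small_cohort_arrays
        first = cd.generalized_procrustes(configs)
        second = cd.generalized_procrustes(first.shape_coords)
        np.testing.assert_allclose(second.shape_coords, first.shape_coords, atol=1e-9)

    def test_shape_coords_invariant_under_input_similarity(self, small_cohort_arrays):
        _, configs, *_ = small_cohort_arrays
        rng = np.random.default_rng(8)
        moved = np.stack([_random_rigid(rng, scale=1.7)(c) for c in configs])
        a = cd.generalized_procrustes(configs)
        b = cd.generalized_procrustes(moved)
        # same shapes up to a common rotation of the whole frame
        for sa, sb in zip(a.shape_coords, b.shape_coords):
            assert cd.procrustes_distance(sa, sb) < 1e-8

    def test_unit_size_and_centering_invariants(self, small_cohort_arrays):
        _, configs, *_ = small_cohort_arrays
        gpa = cd.generalized_procrustes(configs)
        for shape in gpa.shape_coords:
            assert abs((shape ** 2).sum() - 1) < 1e-9
            assert np.abs(shape.mean(axis=0)).max() < 1e-9
        assert abs((gpa.consensus ** 2).sum() - 1) < 1e-9

    def test_noisy_copies_consensus_near_template(self, template):
        rng = np.random.default_rng(9)
        configs = np.stack([
            template.coords + rng.normal(0, 0.1, size=(24, 3)) for _ in range(50)
        ])
        gpa = cd.generalized_procrustes(configs)
        assert cd.procrustes_distance(gpa.consensus, _normalize(template.coords)) < 1e-3


class TestAdjustment:
    def test_exact_linear_function_of_size_leaves_no_residual(self, small_cohort_arrays):
        _, configs, _, ages, _ = small_cohort_arrays
        gpa = cd.generalized_procrustes(configs)
        sizes = gpa.centroid_sizes
        field = np.random.default_rng(10).normal(size=(24, 3))
        shaped = gpa.consensus[None] + sizes[:, None, None] * field[None] * 1e-4
        fake = cd.procrustes.GpaResult(None, shaped, sizes, gpa.consensus, 1, True)
        adjusted = cd.adjust_for_size_and_age(fake, ages=ages)
        assert np.abs(adjusted.residuals).max() < 1e-9

    def test_residuals_orthogonal_to_covariates(self, small_cohort_arrays):
        _, configs, _, ages, _ = small_cohort_arrays
        gpa = cd.generalized_procrustes(configs)
        adjusted = cd.adjust_for_size_and_age(gpa, ages=ages)
        flat = adjusted.residuals.reshape(len(ages), -1)
        assert np.abs(flat.mean(axis=0)).max() < 1e-9
        for cov in (gpa.centroid_sizes, ages):
            centered = cov - cov.mean()
            assert np.abs(centered @ flat).max() / np.linalg.norm(centered) < 1e-9

    def test_constant_covariate_rejected(self, small_cohort_arrays):
        _, configs, _, ages, _ = small_cohort_arrays
        gpa = cd.generalized_procrustes(configs)
        with pytest.raises(ValueError, match="constant"):
            cd.adjust_for_size_and_age(gpa, sizes=np.ones(len(ages)), ages=ages)

    def test_adjusted_coords_reconstitute_consensus_plus_residuals(self, small_cohort_arrays):
        _, configs, _, ages, _ = small_cohort_arrays
        gpa = cd.generalized_procrustes(configs)
        adjusted = cd.adjust_for_size_and_age(gpa, ages=ages)
        np.testing.assert_allclose(
            adjusted.adjusted_coords, adjusted.consensus[None] + adjusted.residuals
        )
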