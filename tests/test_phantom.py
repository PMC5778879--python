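"""Sphere-phantom geometry: shell nesting, perturbation, electrodes, sources."""

import numpy as np
import pytest

import headfield as hf
from headfield.exceptions import (
    BoundsError,
    CapacityError,
    InvalidGeometryError,
    InvalidTransformError,
    PlacementError,
)
from headfield.phantom import AIR, CSF, GM, SCALP, SKULL, WM, fibonacci_directions

from conftest import SMALL_RADII


class TestMakeSphereHead:
    def test_label_follows_distance_rule(self):
        head = hf.make_sphere_head((10, 8, 6, 4, 2), voxel_size=1.0)
        center = tuple(d // 2 for d in head.dims)
        assert head.labels[center] == WM
        # voxel centre at distance 9 mm along x lies in the scalp shell
        assert head.labels[center[0] + 9, center[1], center[2]] == SCALP

    def test_shell_voxel_counts_ordered_by_nesting(self):
        head = hf.make_sphere_head((92, 86, 80, 78, 70), voxel_size=4.0)
        counts = {code: np.sum(head.labels == code) for code in (SCALP, SKULL, CSF, GM, WM)}
        assert all(counts[code] > 0 for code in counts)
        assert counts[WM] > counts[GM]  # thin GM shell around a solid WM ball
        assert head.conducting_component_count() == 1

    @pytest.mark.parametrize("voxel_size", [4.0, 2.0])
    def test_conducting_volume_approaches_analytic_sphere(self, voxel_size):
        head = hf.make_sphere_head(SMALL_RADII, voxel_size)
        volume = head.conducting_mask.sum() * voxel_size**3
        analytic = 4 / 3 * np.pi * SMALL_RADII[0] ** 3
        rel = abs(volume - analytic) / analytic
        # discretization error scales with voxel size over radius
        assert rel < 3 * voxel_size / SMALL_RADII[0]

    def test_volume_error_decreases_with_resolution(self):
        analytic = 4 / 3 * np.pi * SMALL_RADII[0] ** 3
        errors = []
        for v in (4.0, 2.0):
            head = hf.make_sphere_head(SMALL_RADII, v)
            errors.append(abs(head.conducting_mask.sum() * v**3 - analytic))
        assert errors[1] < errors[0]

    def test_labels_non_increasing_along_rays(self, small_head):
        rng = np.random.default_rng(0)
        directions = rng.normal(size=(20, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radii = np.linspace(0.0, SMALL_RADII[0] - 1.0, 40)
        inv = np.linalg.inv(small_head.affine)
        for d in directions:
            points = radii[:, None] * d
            idx = np.rint(points @ inv[:3, :3].T + inv[:3, 3]).astype(int)
            labels = small_head.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
            conducting = labels[np.isin(labels, (SCALP, SKULL, CSF, GM, WM))]
            assert np.all(np.diff(conducting.astype(int)) <= 0)

    def test_air_pocket_carved_from_skull_only(self):
        head_plain = hf.make_sphere_head(SMALL_RADII, 2.0)
        head = hf.make_sphere_head(SMALL_RADII, 2.0, air_pocket=((0, 0, 41.5), 3.0))
        assert np.sum(head.labels == AIR) > 0
        changed = head.labels != head_plain.labels
        assert np.all(head_plain.labels[changed] == SKULL)

    def test_non_decreasing_radii_rejected(self):
        with pytest.raises(InvalidGeometryError):
            hf.make_sphere_head((92, 86, 86, 78, 70), 4.0)

    def test_grid_too_small_raises_bounds_error(self):
        with pytest.raises(BoundsError):
            hf.make_sphere_head(SMALL_RADII, 4.0, dims=(11, 11, 11))


class TestPerturbAnatomy:
    def test_identity_affine_preserves_labels(self, small_head):
        out, transform = hf.perturb_anatomy(small_head, affine=np.eye(4))
        lo = (np.array(out.dims) - np.array(small_head.dims)) // 2
        hi = lo + np.array(small_head.dims)
        core = out.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.testing.assert_array_equal(core, small_head.labels)
        np.testing.assert_allclose(transform.matrix, np.eye(4))

    def test_translation_by_one_voxel_shifts_grid(self, small_head):
        v = small_head.voxel_size
        affine = np.eye(4)
        affine[0, 3] = v
        out, _ = hf.perturb_anatomy(small_head, affine=affine)
        lo = (np.array(out.dims) - np.array(small_head.dims)) // 2
        hi = lo + np.array(small_head.dims)
        core = out.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.testing.assert_array_equal(core[1:], small_head.labels[:-1])

    def test_seeded_perturbation_is_deterministic(self, small_head):
        out1, t1 = hf.perturb_anatomy(small_head, seed=7, magnitude=0.05)
        out2, t2 = hf.perturb_anatomy(small_head, seed=7, magnitude=0.05)
        np.testing.assert_array_equal(out1.labels, out2.labels)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)

    def test_singular_affine_rejected(self, small_head):
        bad = np.eye(4)
        bad[0, 0] = 0.0
        with pytest.raises(InvalidTransformError):
            hf.perturb_anatomy(small_head, affine=bad)

    def test_scaled_head_remains_connected_and_labeled(self, small_head):
        out, _ = hf.perturb_anatomy(small_head, seed=1, magnitude=0.1)
        assert out.conducting_component_count() == 1
        assert set(np.unique(out.labels)) <= {0, SCALP, SKULL, CSF, GM, WM}


class TestPlaceElectrodes:
    def test_deterministic_and_disjoint(self, small_head):
        e1 = hf.place_electrodes(small_head, 12, 160.0)
        e2 = hf.place_electrodes(small_head, 12, 160.0)
        np.testing.assert_array_equal(e1.positions, e2.positions)
        assert e1.names == e2.names
        patches = {tuple(p[0]) for p in e1.patch_voxels}
        assert len(patches) == 12

    def test_two_electrodes_roughly_antipodal(self, small_head):
        e = hf.place_electrodes(small_head, 2, 180.0)
        u = e.positions / np.linalg.norm(e.positions, axis=1, keepdims=True)
        assert u[0] @ u[1] < 0

    def test_coverage_cap_respected(self, small_head):
        coverage = 120.0
        e = hf.place_electrodes(small_head, 24, coverage)
        u = e.positions / np.linalg.norm(e.positions, axis=1, keepdims=True)
        polar = np.degrees(np.arccos(np.clip(u[:, 2], -1, 1)))
        # snapping can move an ideal direction by at most ~a voxel
        slack = np.degrees(small_head.voxel_size * np.sqrt(3) / SMALL_RADII[0])
        assert polar.max() <= coverage + slack

    def test_snapped_positions_align_with_spiral_directions(self, small_head):
        m, coverage = 24, 160.0
        e = hf.place_electrodes(small_head, m, coverage)
        ideal = fibonacci_directions(m, coverage)
        u = e.positions / np.linalg.norm(e.positions, axis=1, keepdims=True)
        gaps = np.linalg.norm(
            e.positions - np.linalg.norm(e.positions, axis=1, keepdims=True) * ideal,
            axis=1,
        )
        assert gaps.max() <= small_head.voxel_size * np.sqrt(3) * 2
        assert np.all(np.sum(u * ideal, axis=1) > 0.97)

    def test_ground_is_most_inferior_and_named(self, small_head):
        e = hf.place_electrodes(small_head, 12, 160.0, ground_name="Iz")
        u = e.positions / np.linalg.norm(e.positions, axis=1, keepdims=True)
        polar = np.arccos(np.clip(u[:, 2], -1, 1))
        assert e.ground_index == np.argmax(polar)
        assert e.ground_name == "Iz"

    def test_too_many_electrodes_raise_placement_error(self):
        tiny = hf.make_sphere_head((10, 8, 6, 4, 2), 2.0)
        with pytest.raises(PlacementError):
            hf.place_electrodes(tiny, 200, 180.0)


class TestSourceSpace:
    def test_unperturbed_normals_are_radial_unit_vectors(self, small_sources):
        n = small_sources.normals
        r = small_sources.locations
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-12)
        cosines = np.sum(n * r, axis=1) / np.linalg.norm(r, axis=1)
        np.testing.assert_allclose(cosines, 1.0, atol=1e-12)

    def test_full_extraction_returns_every_gm_voxel(self, small_head):
        count = int(np.sum(small_head.labels == GM))
        space = hf.extract_source_space(small_head, count)
        assert len(space) == count

    def test_subsampling_is_a_deterministic_stride(self, small_head):
        s1 = hf.extract_source_space(small_head, 50)
        s2 = hf.extract_source_space(small_head, 50)
        np.testing.assert_array_equal(s1.locations, s2.locations)
        assert len(s1) == 50

    def test_over_capacity_raises(self, small_head):
        count = int(np.sum(small_head.labels == GM))
        with pytest.raises(CapacityError):
            hf.extract_source_space(small_head, count + 1)

    def test_scaled_anatomy_normals_follow_inverse_transpose(self, small_head):
        # pure scaling 2x along z: ellipsoid level-set gradient gives the
        # independent closed form n ∝ (x0_x, x0_y, x0_z/2) at y = A x0
        affine = np.diag([1.0, 1.0, 2.0, 1.0])
        out, transform = hf.perturb_anatomy(small_head, affine=affine)
        space = hf.extract_source_space(out, 40)
        x0 = transform.inverse().apply(space.locations)
        expected = x0 / np.linalg.norm(x0, axis=1, keepdims=True)
        expected = expected @ np.diag([1.0, 1.0, 0.5])
        expected /= np.linalg.norm(expected, axis=1, keepdims=True)
        np.testing.assert_allclose(space.normals, expected, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(space.normals, axis=1), 1.0, atol=1e-12)
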