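"""Finite-volume operator, bipolar solves, lead fields, re-referencing."""

import numpy as np
import pytest

import headfield as hf
from headfield.exceptions import (
    EvaluationError,
    InvalidSubsetError,
    SolverError,
    TopologyError,
)
from headfield.phantom import GM, WM
from headfield.solver import assemble_system, solve_injection


def bar_head(length, voxel_size=1.0, labels=None):
    """1x1xL conducting bar embedded in background, for textbook checks."""
    grid = np.zeros((3, 3, length + 2), dtype=np.int16)
    if labels is None:
        labels = [GM] * length
    grid[1, 1, 1:length + 1] = labels
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -voxel_size * (np.array(grid.shape) - 1) / 2
    return hf.VoxelHead(labels=grid, voxel_size=voxel_size, affine=affine)


def bar_electrodes(head, length):
    return hf.ElectrodeSet(
        names=["stim", "gnd"],
        positions=head.voxel_to_world(np.array([[1, 1, 1], [1, 1, length]], dtype=float)),
        patch_voxels=[np.array([[1, 1, 1]]), np.array([[1, 1, length]])],
        ground_index=1,
    )


class TestAssembly:
    def test_uniform_bar_matches_1d_laplacian_stencil(self):
        sigma = 0.5
        table = hf.TissueConductivityTable.uniform(sigma)
        head = bar_head(3)
        system = assemble_system(head, table)
        g = sigma * 1e-3  # sigma * area / pitch for 1 mm voxels
        expected = g * np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]])
        np.testing.assert_allclose(system.laplacian.toarray(), expected, rtol=1e-12)

    def test_face_conductance_is_harmonic_mean(self):
        head = bar_head(2, labels=[GM, WM])
        table = hf.TissueConductivityTable({1: 0.33, 2: 0.041, 3: 0.33, GM: 1.0, WM: 3.0})
        system = assemble_system(head, table)
        # harmonic mean of 1 and 3 is 1.5; conductance = 1.5 * h (metres)
        np.testing.assert_allclose(system.laplacian[0, 1], -1.5e-3, rtol=1e-12)

    def test_operator_symmetric_with_zero_row_sums(self, small_head, shell_sigma):
        system = assemble_system(small_head, shell_sigma)
        lap = system.laplacian
        asym = (lap - lap.T)
        assert abs(asym).max() == 0.0
        row_sums = np.asarray(lap.sum(axis=1)).ravel()
        assert np.abs(row_sums).max() < 1e-15

    def test_disconnected_conductor_rejected(self):
        grid = np.zeros((3, 3, 7), dtype=np.int16)
        grid[1, 1, 1] = GM
        grid[1, 1, 5] = GM  # two blobs separated by background
        head = hf.VoxelHead(labels=grid, voxel_size=1.0, affine=np.eye(4))
        with pytest.raises(TopologyError):
            assemble_system(head, hf.TissueConductivityTable.uniform())


class TestSolveInjection:
    def test_bar_obeys_ohms_law(self):
        sigma, length, current_mA = 0.5, 20, 1.0
        head = bar_head(length)
        table = hf.TissueConductivityTable.uniform(sigma)
        system = assemble_system(head, table)
        sol = solve_injection(system, bar_electrodes(head, length), 0, current_mA)
        # series resistance of the (length-1) inter-voxel faces
        r_face = (1e-3) / (sigma * 1e-6)
        expected_dv = current_mA * 1e-3 * (length - 1) * r_face
        v = sol.potential_grid()
        np.testing.assert_allclose(v[1, 1, 1] - v[1, 1, length], expected_dv, rtol=1e-8)

    def test_potentials_scale_linearly_with_current(self, small_head, small_electrodes, shell_sigma):
        system = assemble_system(small_head, shell_sigma)
        s1 = solve_injection(system, small_electrodes, 0, 1.0)
        s2 = solve_injection(system, small_electrodes, 0, 2.0)
        scale = np.abs(s1.potentials).max()
        np.testing.assert_allclose(s2.potentials, 2.0 * s1.potentials,
                                   rtol=0, atol=2e-6 * scale)

    def test_superposition_of_two_injections(self, small_head, small_electrodes, shell_sigma):
        system = assemble_system(small_head, shell_sigma)
        sol_a = solve_injection(system, small_electrodes, 0)
        sol_b = solve_injection(system, small_electrodes, 3)
        # combined right-hand side: inject at both electrodes simultaneously
        combined = hf.ElectrodeSet(
            names=["both", "gnd"],
            positions=np.vstack([small_electrodes.positions[0],
                                 small_electrodes.positions[small_electrodes.ground_index]]),
            patch_voxels=[
                np.vstack([small_electrodes.patch_voxels[0],
                           small_electrodes.patch_voxels[3]]),
                small_electrodes.patch_voxels[small_electrodes.ground_index],
            ],
            ground_index=1,
        )
        sol_ab = solve_injection(system, combined, 0, total_current_mA=2.0)
        scale = np.abs(sol_ab.potentials).max()
        np.testing.assert_allclose(
            sol_ab.potentials, sol_a.potentials + sol_b.potentials,
            rtol=0, atol=1e-6 * scale,
        )

    def test_swapping_stim_and_ground_negates_up_to_constant(self, small_head, shell_sigma):
        elec = hf.place_electrodes(small_head, 2, 180.0)
        system = assemble_system(small_head, shell_sigma)
        v_ab = solve_injection(system, elec, 0).potentials
        swapped = hf.ElectrodeSet(
            names=[elec.names[1], elec.names[0]],
            positions=elec.positions[::-1].copy(),
            patch_voxels=[elec.patch_voxels[1], elec.patch_voxels[0]],
            ground_index=1,
        )
        v_ba = solve_injection(system, swapped, 0).potentials
        total = v_ab + v_ba  # should be a constant field
        assert np.ptp(total) < 1e-6 * np.ptp(v_ab)

    def test_net_current_and_conservation(self, small_head, small_electrodes, shell_sigma):
        system = assemble_system(small_head, shell_sigma)
        sol = solve_injection(system, small_electrodes, 2, 1.0)
        assert sol.residual <= 1e-8
        assert abs(sol.net_current_mA - 1.0) < 1e-6
        nodal = system.laplacian @ sol.potentials
        ground_nodes = system.node_of_voxels(
            small_electrodes.patch_voxels[small_electrodes.ground_index])
        assert abs(nodal[ground_nodes].sum() * 1e3 + 1.0) < 1e-6
        assert abs(nodal.sum()) < 1e-8 * 1e-3  # total nodal current vs 1 mA

    def test_stim_equal_ground_rejected(self, small_head, small_electrodes, shell_sigma):
        system = assemble_system(small_head, shell_sigma)
        with pytest.raises(SolverError):
            solve_injection(system, small_electrodes, small_electrodes.ground_index)


class TestLeadField:
    def test_ground_row_identically_zero(self, small_leadfield, small_electrodes):
        assert np.all(small_leadfield.matrices[:, small_electrodes.ground_index, :] == 0)
        assert small_leadfield.reference_mode == "ground"

    def test_two_electrode_leadfield_has_single_nonzero_row(
            self, small_head, small_sources, shell_sigma):
        elec = hf.place_electrodes(small_head, 2, 180.0)
        lf = hf.compute_leadfield(small_head, shell_sigma, elec, small_sources)
        nonzero_rows = np.any(lf.matrices != 0, axis=(0, 2))
        assert nonzero_rows.tolist() == [True, False]

    def test_montage_field_consistent_with_leadfield_row(self, small_leadfield):
        montage = hf.Montage(
            currents=np.eye(small_leadfield.n_electrodes)[1]
            - np.eye(small_leadfield.n_electrodes)[small_leadfield.ground_index],
            electrode_names=list(small_leadfield.electrode_names),
            target_index=0, objective_value=0.0, limit_mA=2.0,
        )
        field = hf.apply_montage(small_leadfield, montage)
        np.testing.assert_allclose(field.fields, small_leadfield.matrices[:, 1, :], rtol=1e-12)

    def test_reciprocity_of_bipolar_pairs(self, small_head, shell_sigma, small_sources):
        # dipole potential p.(row_a - row_b) must not depend on which
        # electrode of the pair served as the solver's injection site
        elec = hf.place_electrodes(small_head, 2, 180.0)
        lf_ab = hf.compute_leadfield(small_head, shell_sigma, elec, small_sources)
        swapped = hf.ElectrodeSet(
            names=[elec.names[1], elec.names[0]],
            positions=elec.positions[::-1].copy(),
            patch_voxels=[elec.patch_voxels[1], elec.patch_voxels[0]],
            ground_index=1,
        )
        lf_ba = hf.compute_leadfield(small_head, shell_sigma, swapped, small_sources)
        p = np.array([1.0, -0.5, 2.0])
        d_ab = (lf_ab.matrices[:, 0, :] - lf_ab.matrices[:, 1, :]) @ p
        d_ba = (lf_ba.matrices[:, 1, :] - lf_ba.matrices[:, 0, :]) @ p
        scale = np.abs(d_ab).max()
        np.testing.assert_allclose(d_ab, d_ba, rtol=0, atol=1e-5 * scale)

    def test_source_outside_conductor_rejected(self, small_head, shell_sigma, small_electrodes):
        bad = hf.CorticalSourceSpace(
            locations=np.array([[0.0, 0.0, 60.0]]),  # outside the scalp shell
            normals=np.array([[0.0, 0.0, 1.0]]),
        )
        with pytest.raises(EvaluationError):
            hf.compute_leadfield(small_head, shell_sigma, small_electrodes, bad)


class TestCommonAverage:
    def test_columns_sum_to_zero_and_idempotent(self, small_leadfield):
        ca = hf.rereference_common_average(small_leadfield)
        col_sums = ca.matrices.sum(axis=1)
        scale = np.linalg.norm(ca.matrices)
        assert np.abs(col_sums).max() < 1e-10 * max(scale, 1.0)
        twice = hf.rereference_common_average(ca)
        np.testing.assert_allclose(twice.matrices, ca.matrices, atol=1e-15)
        assert ca.reference_mode == "common_average"

    def test_two_electrode_mean_subtraction(self, toy_leadfield):
        mats = np.zeros((3, 2, 3))
        mats[:, 0, :] = np.arange(9).reshape(3, 3)
        lf = hf.LeadField(
            matrices=mats, electrode_names=["a", "b"],
            source_space=toy_leadfield.source_space.__class__(
                locations=toy_leadfield.source_space.locations[:3],
                normals=toy_leadfield.source_space.normals[:3]),
        )
        ca = hf.rereference_common_average(lf)
        np.testing.assert_allclose(ca.matrices[:, 0, :], mats[:, 0, :] / 2)
        np.testing.assert_allclose(ca.matrices[:, 1, :], -mats[:, 0, :] / 2)

    def test_subset_restriction(self, small_leadfield):
        ca = hf.rereference_common_average(small_leadfield, subset=[0, 2, 5])
        assert ca.n_electrodes == 3
        assert ca.electrode_names == [small_leadfield.electrode_names[i] for i in (0, 2, 5)]
        with pytest.raises(InvalidSubsetError):
            hf.rereference_common_average(small_leadfield, subset=[1])
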