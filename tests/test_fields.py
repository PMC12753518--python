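"""Field solver: analytic point source, finite-volume Poisson oracle checks,
sampling, and carrier-potential profiles."""

import numpy as np
import pytest

from cochsim import point_source_potential, sample_potential, solve_field, voxelize
from cochsim.fields import (AnalyticPointSource, FieldSolution,
                            FieldSolverError, enclosed_current,
                            potential_along_carrier)
from cochsim.geometry import ConductivityMap, LABEL_INDEX


class TestPointSource:
    def test_hand_evaluated_reference(self):
        # I/(4 pi sigma r) at 1 uA, perilymph, 255 um
        assert point_source_potential(1.0, 1.43, 255.0) == pytest.approx(0.21823, abs=5e-5)

    def test_inverse_r_scaling(self):
        v1 = point_source_potential(1.0, 1.43, 100.0)
        assert point_source_potential(1.0, 1.43, 1000.0) == pytest.approx(v1 / 10)

    def test_inverse_sigma_scaling(self):
        v1 = point_source_potential(1.0, 0.7, 100.0)
        assert point_source_potential(1.0, 1.4, 100.0) == pytest.approx(v1 / 2)

    def test_singularity_and_bad_sigma(self):
        with pytest.raises(ZeroDivisionError):
            point_source_potential(1.0, 1.43, 0.0)
        with pytest.raises(ValueError):
            point_source_potential(1.0, -1.0, 100.0)


@pytest.fixture(scope="module")
def uniform_solution(uniform_map):
    """Manufactured-solution solve: free-space analytic values prescribed on
    the boundary, so the interior is comparable to I/(4 pi sigma r)."""
    n = uniform_map.shape[0]
    ax = uniform_map.axes()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    v_free = point_source_potential(1.0, 1.43, np.maximum(r, 1.0))
    c = np.array([n // 2] * 3)
    sol = solve_field(uniform_map, source_voxels=c[None, :], boundary_values=v_free)
    return sol, v_free, r, c


class TestFiniteVolume:
    def test_uniform_medium_matches_analytic_in_shell(self, uniform_solution):
        sol, v_free, r, _ = uniform_solution
        sp = sol.cond_map.spacing
        n = sol.cond_map.shape[0]
        shell = (r >= 5 * sp) & (r <= n * sp / 4)
        err = np.abs(sol.ve[shell] - v_free[shell]) / v_free[shell]
        assert err.max() < 0.05

    def test_discrete_current_conservation(self, uniform_solution):
        sol, _, _, c = uniform_solution
        assert enclosed_current(sol, c, 4) == pytest.approx(1.0, rel=1e-6)

    def test_linearity_in_conductivity(self, uniform_map):
        n = uniform_map.shape[0]
        c = np.array([n // 2] * 3)[None, :]
        v1 = solve_field(uniform_map, source_voxels=c).ve
        v2 = solve_field(uniform_map.with_sigma(ST=14.3), source_voxels=c).ve
        assert np.allclose(v2, v1 / 10, rtol=1e-5, atol=1e-9)

    def test_reciprocity(self, uniform_map):
        n = uniform_map.shape[0]
        a = np.array([n // 2] * 3)
        b = a + np.array([6, -3, 4])
        va = solve_field(uniform_map, source_voxels=a[None, :]).ve
        vb = solve_field(uniform_map, source_voxels=b[None, :]).ve
        assert va[tuple(b)] == pytest.approx(vb[tuple(a)], rel=1e-6)

    def test_maximum_at_source(self, uniform_map):
        n = uniform_map.shape[0]
        c = np.array([n // 2] * 3)
        sol = solve_field(uniform_map, source_voxels=c[None, :])
        assert np.unravel_index(np.argmax(np.abs(sol.ve)), sol.ve.shape) == tuple(c)

    def test_zero_on_grounded_boundary(self, uniform_map):
        n = uniform_map.shape[0]
        c = np.array([n // 2] * 3)
        sol = solve_field(uniform_map, source_voxels=c[None, :])
        assert np.all(sol.ve[0] == 0) and np.all(sol.ve[-1] == 0)

    def test_missing_contact_rejected(self, uniform_map):
        with pytest.raises(KeyError):
            solve_field(uniform_map, "EL1")


class TestSampling:
    def test_grid_nodes_reproduced_exactly(self, uniform_map):
        n = uniform_map.shape[0]
        sol = solve_field(uniform_map, source_voxels=np.array([[n // 2] * 3]))
        idx = np.array([[10, 12, 14], [20, 20, 20]])
        pts = sol.cond_map.index_to_world(idx)
        assert np.allclose(sol.sample(pts), sol.ve[tuple(idx.T)])

    def test_midpoint_of_linear_field_is_mean(self, uniform_map):
        sol = FieldSolution(
            ve=np.fromfunction(lambda i, j, k: 1.0 * i, uniform_map.shape),
            cond_map=uniform_map, contact_id="lin")
        p1 = uniform_map.index_to_world([10, 10, 10])
        p2 = uniform_map.index_to_world([11, 10, 10])
        mid = sol.sample(((p1 + p2) / 2)[None, :])
        assert mid[0] == pytest.approx(10.5)

    def test_point_outside_grid_named_in_error(self, uniform_map):
        n = uniform_map.shape[0]
        sol = solve_field(uniform_map, source_voxels=np.array([[n // 2] * 3]))
        with pytest.raises(ValueError, match="outside"):
            sample_potential(sol, np.array([[1e6, 0.0, 0.0]]))

    def test_fiber_sampling_length_bookkeeping(self, uniform_map, fibers):
        from cochsim import assemble_chain

        n = uniform_map.shape[0]
        sol = solve_field(uniform_map, source_voxels=np.array([[n // 2] * 3]))
        chain = assemble_chain(fibers[0])
        # sample at chain centers translated into the small grid
        pts = chain.centers - chain.centers.mean(axis=0)
        pts = pts / (np.abs(pts).max() / (n // 3 * uniform_map.spacing))
        assert len(sol.sample(pts)) == chain.n


@pytest.fixture(scope="module")
def carrier_setup(geometry, centerlines):
    from cochsim import place_contacts

    cl = centerlines["pmST"]
    arr = place_contacts(cl, [320.0])
    cmap = voxelize(geometry, [arr], spacing=300.0)
    return cl, cmap


class TestCarrierProfile:
    def test_normalized_with_peak_at_active_contact(self, carrier_setup):
        cl, cmap = carrier_setup
        sol = solve_field(cmap, "EL320")
        alphas, prof = potential_along_carrier(sol, cl, 320.0)
        assert prof.max() == pytest.approx(1.0)
        a_peak = alphas[int(np.argmax(prof))]
        assert abs(a_peak - 320.0) <= 25.0

    def test_monotone_decay_near_contact_in_homogeneous_medium(self, carrier_setup):
        cl, cmap = carrier_setup
        uni = cmap.with_sigma(**{k: 1.43 for k in cmap.sigma_by_label})
        sol = solve_field(uni, "EL320")
        alphas, prof = potential_along_carrier(sol, cl, 320.0)
        # 1/r decay along the curve within the active turn, both directions
        near = (alphas >= 335) & (alphas <= 440)
        assert np.all(np.diff(prof[near]) < 0)
        near = (alphas >= 200) & (alphas <= 305)
        assert np.all(np.diff(prof[near]) > 0)

    def test_zero_field_rejected(self, carrier_setup, uniform_map):
        cl, cmap = carrier_setup
        sol = solve_field(cmap, "EL320")
        sol.ve = np.zeros_like(sol.ve)
        with pytest.raises(FieldSolverError):
            potential_along_carrier(sol, cl, 320.0)


class TestAnalyticSource:
    def test_matches_formula(self):
        src = AnalyticPointSource(position=np.zeros(3), sigma=1.43)
        v = src.sample(np.array([[255.0, 0, 0]]))
        assert v[0] == pytest.approx(point_source_potential(1.0, 1.43, 255.0))
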