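"""Electrode arrays: centerline constraint satisfaction, carrier taper,
contact placement and distance profiles."""

import numpy as np
import pytest

from cochsim import fit_centerline, min_distance_profile, place_contacts
from cochsim.arrays import TARGET_MIN_DISTANCE, _fiber_cloud, _min_distances
from cochsim.geometry import ANFPath


def _per_fiber_min(cl, fibers):
    cloud, owner = _fiber_cloud(fibers)
    d, _, _ = _min_distances(cl.points, cloud, owner, len(fibers))
    return d


class TestCenterlineFit:
    def test_constraint_satisfaction_all_arrays(self, centerlines, fibers):
        """Per-fiber minimum distance within 10% of 255 um, all four arrays."""
        for tag, cl in centerlines.items():
            d = _per_fiber_min(cl, fibers)
            assert np.max(np.abs(d - TARGET_MIN_DISTANCE)) <= 0.10 * TARGET_MIN_DISTANCE, tag

    def test_total_length_within_bounds(self, centerlines):
        for tag, cl in centerlines.items():
            assert 23000.0 <= cl.total_length <= 27000.0, (tag, cl.total_length)

    def test_smoothness(self, centerlines):
        # spline interpolation: bounded curvature, no kinks at fine sampling
        cl = centerlines["lwST"]
        seg = np.diff(cl.points, axis=0)
        cosang = np.sum(seg[:-1] * seg[1:], axis=1) / (
            np.linalg.norm(seg[:-1], axis=1) * np.linalg.norm(seg[1:], axis=1))
        assert np.all(cosang > 0.99)

    def test_invalid_arguments(self, geometry, fibers):
        with pytest.raises(ValueError):
            fit_centerline(geometry, fibers, "XX", "lw")
        with pytest.raises(ValueError):
            fit_centerline(geometry, [], "ST", "lw")

    def test_stability_under_perturbed_initialization(self, geometry, fibers):
        cl1 = fit_centerline(geometry, fibers, "ST", "lw")
        cl2 = fit_centerline(geometry, fibers, "ST", "lw", init_frac=0.7)
        diff = np.max(np.linalg.norm(cl1.points - cl2.points, axis=1))
        assert diff < 60.0  # below the default voxel spacing

    def test_lateral_coupling_shares_radial_coordinate(self, geometry, fibers):
        st = fit_centerline(geometry, fibers, "ST", "lw", couple_lateral=True)
        sv = fit_centerline(geometry, fibers, "SV", "lw", couple_lateral=True)
        rho_st = np.hypot(st.points[:, 0], st.points[:, 1])
        rho_sv = np.hypot(sv.points[:, 0], sv.points[:, 1])
        assert np.allclose(rho_st, rho_sv, atol=1e-6)


class TestCarrier:
    def test_taper_monotone_with_exact_endpoints(self, arrays):
        arr = arrays["lwST"]
        arc = np.linspace(0, arr.centerline.total_length, 200)
        r = arr.carrier_radius(arc)
        assert r[0] == 300.0 and r[-1] == 150.0
        assert np.all(np.diff(r) < 0)


class TestContacts:
    def test_one_contact_per_angle_nearest_to_its_fiber(self, arrays, fibers):
        arr = arrays["lwST"]
        assert len(arr.contacts) == 25
        centers = np.array([c.center for c in arr.contacts])
        for i, f in enumerate(fibers):
            d = np.min(np.linalg.norm(
                centers[:, None, :] - f.polyline[None, ::5, :], axis=2), axis=1)
            assert int(np.argmin(d)) == i

    def test_empty_contact_list(self, centerlines):
        arr = place_contacts(centerlines["lwST"], [])
        assert arr.contacts == []

    def test_angle_beyond_tip_rejected(self, centerlines):
        with pytest.raises(ValueError, match="beyond"):
            place_contacts(centerlines["lwST"], [800.0])

    def test_alternative_orientation_increases_lw_distances(self, centerlines, fibers):
        """Contacts turned toward the cochlear axis sit farther from their
        target fibers than fiber-facing contacts, for both lw arrays."""
        for tag in ("lwST", "lwSV"):
            cl = centerlines[tag]
            angles = [f.alpha_deg for f in fibers]
            default = place_contacts(cl, angles, orientation_mode="default")
            alt = place_contacts(cl, angles, orientation_mode="alternative")
            for f, cd, ca in zip(fibers, default.contacts, alt.contacts):
                _, _, dmin_d, _ = min_distance_profile(default, f, cd.id)
                _, _, dmin_a, _ = min_distance_profile(alt, f, ca.id)
                assert dmin_a >= dmin_d, (tag, f.id)

    def test_contact_center_on_carrier_surface(self, arrays):
        arr = arrays["pmST"]
        for ct in arr.contacts:
            p = arr.centerline.point_at_alpha(ct.alpha_deg)
            arc = arr.centerline.arc_at_alpha(ct.alpha_deg)
            assert np.linalg.norm(ct.center - p) == pytest.approx(
                float(arr.carrier_radius(arc)), rel=1e-6)


class TestMinDistanceProfile:
    def test_toy_fiber_hand_computed(self, arrays):
        arr = arrays["lwST"]
        ct = arr.contacts[0]
        # 3-point fiber with known distances from the contact center
        pts = ct.center + np.array([[0, 0, 400.0], [0, 300.0, 400.0],
                                    [0, 600.0, 400.0]])
        fiber = ANFPath(id="toy", alpha_deg=23.0, polyline=pts,
                        dendrite_length=100.0, soma_arc_pos=110.0)
        arc, d, dmin, argmin = min_distance_profile(arr, fiber, ct.id)
        assert d == pytest.approx([400.0, 500.0, np.hypot(600, 400)])
        assert dmin == 400.0 and argmin == 0.0

    def test_uniform_translation_shifts_min_exactly(self, arrays):
        arr = arrays["lwST"]
        ct = arr.contacts[0]
        p0 = ct.center + np.array([0, 0, 250.0])
        for off in (0.0, 100.0):
            fiber = ANFPath(id="pt", alpha_deg=23.0,
                            polyline=np.vstack([p0 + [0, 0, off]] * 2 + [p0 + [0, 0, off + 1]]),
                            dendrite_length=1.0, soma_arc_pos=1.0)
            _, _, dmin, _ = min_distance_profile(arr, fiber, ct.id)
            if off == 0.0:
                base = dmin
        assert dmin == pytest.approx(base + 100.0, abs=1e-6)

    def test_tie_breaks_toward_terminal(self, arrays):
        arr = arrays["lwST"]
        ct = arr.contacts[0]
        pts = ct.center + np.array([[0, 0, 300.0], [300.0, 0, 0], [0, 0, -300.0]])
        fiber = ANFPath(id="tie", alpha_deg=23.0, polyline=pts,
                        dendrite_length=100.0, soma_arc_pos=110.0)
        _, _, dmin, argmin = min_distance_profile(arr, fiber, ct.id)
        assert dmin == 300.0 and argmin == 0.0

    def test_lw_contacts_closest_at_terminal(self, arrays, fibers):
        """Lateral-wall contacts approach their fibers at the dendritic tip."""
        arr = arrays["lwST"]
        argmins = []
        for f, ct in zip(fibers, arr.contacts):
            _, _, _, argmin = min_distance_profile(arr, f, ct.id)
            argmins.append(argmin)
        assert np.median(argmins) < 100.0

    def test_pm_contacts_often_closest_mid_dendrite(self, arrays, fibers):
        """Peri-modiolar contacts approach a substantial share of their fibers
        at a mid-dendritic site rather than at the terminal."""
        arr = arrays["pmST"]
        argmins = []
        for f, ct in zip(fibers, arr.contacts):
            _, _, _, argmin = min_distance_profile(arr, f, ct.id)
            argmins.append(argmin)
        assert np.mean(np.asarray(argmins) > 200.0) >= 0.2

    def test_missing_contact_rejected(self, arrays, fibers):
        with pytest.raises(KeyError):
            min_distance_profile(arrays["lwST"], fibers[0], "EL9999")
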