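"""Contact constitutive laws and penetration queries."""

import numpy as np
import pytest
import trimesh

from elbowsim.contact import (
    ContactParameters,
    DishSurface,
    ElasticFoundationInputs,
    NotchSurface,
    PlaneSurface,
    contact_map,
    contact_normal_force,
    damping_coefficient,
    element_penetration,
    foundation_stiffness,
)
from elbowsim.contact import ContactState
from elbowsim.geometry import ContactElement, GeometryConfig


PARAMS_UH = ContactParameters(kc=126.0)
PARAMS_RH = ContactParameters(kc=105.0)


class TestDampingCoefficient:
    @pytest.mark.parametrize("delta, params, expected", [
        (-0.01, ContactParameters(), 0.0),                      # separation
        (0.1, ContactParameters(Bmax=2.0, dmax=0.1), 2.0),      # saturation
        (0.5, ContactParameters(Bmax=2.0, dmax=0.1), 2.0),      # beyond dmax
        # smoothstep midpoint: s = 0.5 -> Bmax * 0.25 * 2 = 0.5 * Bmax
        (0.05, ContactParameters(Bmax=2.0, dmax=0.1), 1.0),
    ])
    def test_values(self, delta, params, expected):
        assert damping_coefficient(delta, params) == pytest.approx(expected, abs=1e-12)

    def test_c1_continuity_at_boundaries(self):
        """The ramp joins its constant branches with matching slope."""
        params = ContactParameters(Bmax=2.0, dmax=0.1)
        h = 1e-7
        for edge in (0.0, params.dmax):
            lo = damping_coefficient(edge - h, params)
            hi = damping_coefficient(edge + h, params)
            assert hi - lo == pytest.approx(0.0, abs=1e-5)
            slope_lo = (damping_coefficient(edge - h, params)
                        - damping_coefficient(edge - 2 * h, params)) / h
            slope_hi = (damping_coefficient(edge + 2 * h, params)
                        - damping_coefficient(edge + h, params)) / h
            # one-sided slopes differ only by curvature * h, not by a jump
            assert slope_hi - slope_lo == pytest.approx(0.0, abs=1e-3)


class TestContactNormalForce:
    @pytest.mark.parametrize("delta, delta_dot, params, expected", [
        (0.0, 123.0, PARAMS_UH, 0.0),
        (-1.0, 5.0, PARAMS_UH, 0.0),
        (0.05, 0.0, PARAMS_UH, 6.3),                 # 126 * 0.05
        # saturated damping: 105 * 0.2 + 2 * 1
        (0.2, 1.0, PARAMS_RH, 23.0),
    ])
    def test_values(self, delta, delta_dot, params, expected):
        assert contact_normal_force(delta, delta_dot, params) == pytest.approx(expected)

    def test_no_adhesion(self):
        """A fast-separating contact cannot pull: the force clamps at zero."""
        f = contact_normal_force(0.01, -1000.0, PARAMS_UH)
        assert f == 0.0

    def test_force_continuous_in_delta(self):
        """No jump at first touch or at damping saturation (any rate)."""
        for ddot in (0.0, 5.0):
            for edge in (0.0, PARAMS_UH.dmax):
                lo = contact_normal_force(edge - 1e-9, ddot, PARAMS_UH)
                hi = contact_normal_force(edge + 1e-9, ddot, PARAMS_UH)
                assert hi - lo == pytest.approx(0.0, abs=1e-5)

    def test_passivity_in_compression(self):
        """For approaching contact the damper only adds force."""
        deltas = np.linspace(1e-4, 0.5, 50)
        f = contact_normal_force(deltas, 2.0, PARAMS_UH)
        assert np.all(f >= PARAMS_UH.kc * deltas - 1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="kc"):
            ContactParameters(kc=0.0).validate()
        with pytest.raises(ValueError, match="dmax"):
            ContactParameters(dmax=0.0).validate()


class TestFoundationStiffness:
    def test_adopted_material_values(self):
        """E = 0.7 MPa, nu = 0.495, h = 4 mm, 25 mm^2 element -> 147.8 N/mm.

        Note this is the formula output; the adopted ulnohumeral default of
        126 N/mm is a configuration constant, not a formula result.
        """
        k = foundation_stiffness(ElasticFoundationInputs(E=0.7, nu=0.495, h=4.0,
                                                         element_area=25.0))
        assert k == pytest.approx(147.8, abs=0.05)

    def test_unit_factors(self):
        k = foundation_stiffness(ElasticFoundationInputs(E=1.0, nu=0.0, h=1.0,
                                                         element_area=1.0))
        assert k == pytest.approx(1.0)

    def test_inverse_thickness(self):
        k1 = foundation_stiffness(ElasticFoundationInputs(E=0.7, nu=0.3, h=4.0))
        k2 = foundation_stiffness(ElasticFoundationInputs(E=0.7, nu=0.3, h=2.0))
        assert k2 == pytest.approx(2.0 * k1)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError, match="nu"):
            foundation_stiffness(ElasticFoundationInputs(E=0.7, nu=0.5, h=4.0))


class TestElementPenetration:
    def _element_at(self, point):
        return ContactElement(id=0, center=np.asarray(point, float),
                              normal=np.array([0.0, 0.0, 1.0]), area=25.0,
                              map_uv=(0.0, 0.0), region="trochlea")

    def test_outside_sphere_sign(self):
        """A point 1 mm outside a unit sphere reads delta = -1."""
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        delta, _ = element_penetration(self._element_at([0.0, 0.0, 2.0]), sphere)
        assert delta == pytest.approx(-1.0, abs=2e-3)

    def test_depth_inside_plane_sheet(self):
        """Signed depth against an open oriented sheet matches the closed form."""
        plane = trimesh.Trimesh(
            vertices=[[-5, -5, 0], [5, -5, 0], [5, 5, 0], [-5, 5, 0]],
            faces=[[0, 1, 2], [0, 2, 3]], process=False,
        )
        # face normals point +z; material below
        delta, _ = element_penetration(self._element_at([0.3, -0.2, -0.07]), plane)
        assert delta == pytest.approx(0.07, abs=1e-9)

    def test_against_brute_force_nearest_point(self):
        """Distance agrees with an exhaustive per-triangle nearest-point scan."""
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=3.0)  # 320 faces
        rng = np.random.default_rng(7)
        pts = rng.normal(scale=2.0, size=(12, 3))

        def brute_distance(p):
            best = np.inf
            for tri in mesh.triangles:
                q = _closest_point_on_triangle(p, tri)
                best = min(best, np.linalg.norm(p - q))
            return best

        for p in pts:
            delta, _ = element_penetration(self._element_at(p), mesh)
            assert abs(delta) == pytest.approx(brute_distance(p), abs=1e-6)

    def test_penetration_rate_sign(self):
        """Approaching the surface reads a positive rate."""
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        _, rate = element_penetration(
            self._element_at([0.0, 0.0, 2.0]), sphere,
            element_velocity=[0.0, 0.0, -3.0],
        )
        assert rate == pytest.approx(3.0, abs=5e-2)

    def test_unoriented_surface_rejected(self):
        bad = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]],
            faces=[[0, 1, 2], [1, 3, 2][::-1]], process=False,
        )
        assert not bad.is_winding_consistent
        with pytest.raises(ValueError, match="orientation"):
            element_penetration(self._element_at([0.2, 0.2, 1.0]), bad)


class TestAnalyticPatches:
    """The solver's analytic penetration fields: values and exact gradients."""

    @pytest.mark.parametrize("patch, scale, offset", [
        (NotchSurface(GeometryConfig()), 13.0, (0.0, 0.0, 0.0)),
        (DishSurface(GeometryConfig()), 11.0, (0.0, 0.0, 9.0)),
        (PlaneSurface([0, 0, 0], [0, 0, 1]), 5.0, (0.0, 0.0, 0.0)),
    ])
    def test_gradient_matches_finite_differences(self, patch, scale, offset):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(300, 3)) * scale * 0.6 + np.asarray(offset)
        delta, grad = patch.penetration(pts)
        h = 1e-6
        checked = 0
        for i in np.where(delta > -1e5)[0]:
            gfd = np.zeros(3)
            valid = True
            for j in range(3):
                pp, pm = pts[i].copy(), pts[i].copy()
                pp[j] += h
                pm[j] -= h
                dp = patch.penetration(pp[None])[0][0]
                dm = patch.penetration(pm[None])[0][0]
                if dp < -1e5 or dm < -1e5:
                    valid = False
                    break
                gfd[j] = (dp - dm) / (2 * h)
            if valid:
                assert np.allclose(gfd, grad[i], atol=5e-5)
                checked += 1
        assert checked > 30

    def test_notch_congruence_at_reference(self):
        """Trochlear elements nest in the notch with uniform clearance."""
        from elbowsim.geometry import generate_elbow
        import math

        cfg = GeometryConfig()
        geom = generate_elbow(cfg)
        notch = NotchSurface(cfg)
        th = math.radians(cfg.initial_flexion)
        c, s = math.cos(th), math.sin(th)
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        centers = np.stack([e.center for e in geom.elements_in("trochlea")])
        local = centers @ R  # = R.T applied to rows
        delta, _ = notch.penetration(local)
        # restrict to elements inside the notch wrap sector (outside it the
        # flared margins legitimately fall away from the trochlea)
        y, z = local[:, 1], local[:, 2]
        by, bz = notch.bisector
        ang = np.arctan2(by * z - bz * y, y * by + z * bz)
        in_sector = np.abs(ang) <= notch.half_wrap
        assert in_sector.sum() > 10
        assert np.all(np.abs(delta[in_sector] + cfg.notch_clearance) < 0.02)


class TestContactMap:
    def _state(self, delta, fc):
        return ContactState(delta=delta, delta_dot=0.0, Fc=fc, p=0.0)

    def _element(self, i, area=25.0):
        return ContactElement(id=i, center=np.zeros(3), normal=np.array([0, 0, 1.0]),
                              area=area, map_uv=(float(i), 0.0), region="trochlea")

    def test_no_contact(self):
        states = [(self._element(i), self._state(-0.1, 0.0)) for i in range(5)]
        _, summary = contact_map(states)
        assert summary.contact_area == 0.0
        assert summary.peak_pressure == 0.0

    def test_area_counts_loaded_elements(self):
        states = [(self._element(i), self._state(0.01, 1.0)) for i in range(4)]
        states += [(self._element(9), self._state(-0.01, 0.0))]
        _, summary = contact_map(states)
        assert summary.contact_area == pytest.approx(100.0)   # 4 x 25 mm^2
        assert summary.n_active == 4

    def test_pressure_is_force_over_area(self):
        table, summary = contact_map([(self._element(0), self._state(0.05, 6.3))])
        assert summary.peak_pressure == pytest.approx(0.252)
        assert table["p"].iloc[0] == pytest.approx(6.3 / 25.0)


def _closest_point_on_triangle(p, tri):
    """Reference implementation: closest point on one triangle (Ericson)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)
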