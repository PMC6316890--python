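"""Ligament constitutive law, wrapping geometry and sectioning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elbowsim.geometry import GeometryConfig, WrapPrimitive, generate_elbow
from elbowsim.ligament import (
    SCENARIOS,
    LigamentBundle,
    LigamentState,
    build_bundles,
    bundle_elastic_energy,
    bundle_elastic_force,
    bundle_total_force,
    engineering_strain,
    section_bundles,
    wrap_route,
)


class TestEngineeringStrain:
    @pytest.mark.parametrize("l, l0, expected", [
        (10.0, 10.0, 0.0),
        (15.0, 10.0, 0.5),
        (9.0, 10.0, -0.1),
    ])
    def test_values(self, l, l0, expected):
        assert engineering_strain(l, l0) == pytest.approx(expected)

    def test_invalid_l0(self):
        with pytest.raises(ValueError):
            engineering_strain(10.0, 0.0)


class TestElasticForce:
    @pytest.mark.parametrize("eps, k, eps_l, expected", [
        (-0.05, 100.0, 0.03, 0.0),            # slack
        (0.06, 100.0, 0.03, 3.0),             # toe/linear junction, both branches
        (0.10, 100.0, 0.03, 7.0),             # linear branch: 100 * 0.07
        (0.03, 100.0, 0.03, 0.75),            # toe: 0.25 * 100 * 0.0009 / 0.03
    ])
    def test_values(self, eps, k, eps_l, expected):
        assert bundle_elastic_force(eps, k, eps_l) == pytest.approx(expected)

    @given(k=st.floats(1.0, 1e4), eps_l=st.floats(1e-3, 0.2))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_c1_at_toe_end(self, k, eps_l):
        """Value k*eps_l and slope k match across eps = 2 eps_l for all params."""
        e0 = 2.0 * eps_l
        assert bundle_elastic_force(e0, k, eps_l) == pytest.approx(k * eps_l, rel=1e-9)
        h = 1e-7 * max(eps_l, 1e-3)
        slope_lo = (bundle_elastic_force(e0, k, eps_l)
                    - bundle_elastic_force(e0 - h, k, eps_l)) / h
        slope_hi = (bundle_elastic_force(e0 + h, k, eps_l)
                    - bundle_elastic_force(e0, k, eps_l)) / h
        assert slope_lo == pytest.approx(k, rel=1e-4)
        assert slope_hi == pytest.approx(k, rel=1e-4)

    @given(eps_l=st.floats(0.005, 0.1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_nondecreasing(self, eps_l):
        eps = np.linspace(-0.2, 0.6, 400)
        f = bundle_elastic_force(eps, 200.0, eps_l)
        assert np.all(np.diff(f) >= -1e-12)

    def test_zero_at_zero_load_length(self):
        assert bundle_elastic_force(0.0, 500.0, 0.03) == 0.0

    def test_energy_is_antiderivative(self):
        """The stored energy differentiates back to the force (solver contract)."""
        k, eps_l, l0 = 300.0, 0.03, 20.0
        eps = np.linspace(0.001, 0.4, 200)
        h = 1e-7
        dU = (bundle_elastic_energy(eps + h, k, eps_l, l0)
              - bundle_elastic_energy(eps - h, k, eps_l, l0)) / (2 * h)
        # dU/d eps = f * l0
        assert np.allclose(dU, bundle_elastic_force(eps, k, eps_l) * l0, rtol=1e-5)


class TestTotalForce:
    def _bundle(self, active=True, c=0.5):
        return LigamentBundle(
            name="b", complex="MCL_AB", origin_body="humerus",
            origin=np.zeros(3), insertion_body="ulna", insertion=np.ones(3),
            k=100.0, eps_l=0.03, l0=10.0, c=c, active=active,
        )

    def test_slack_is_zero(self):
        state = LigamentState(l=9.0, l_dot=0.0, eps=-0.1, f=0.0)
        assert bundle_total_force(state, self._bundle()) == 0.0

    def test_damper_adds_to_elastic(self):
        state = LigamentState(l=10.6, l_dot=2.0, eps=0.06, f=0.0)
        assert bundle_total_force(state, self._bundle()) == pytest.approx(4.0)

    def test_clamped_no_compression(self):
        state = LigamentState(l=10.0, l_dot=-10.0, eps=0.0, f=0.0)
        assert bundle_total_force(state, self._bundle()) == 0.0

    def test_inactive_bundle(self):
        state = LigamentState(l=20.0, l_dot=5.0, eps=1.0, f=0.0)
        assert bundle_total_force(state, self._bundle(active=False)) == 0.0


class TestWrapRoute:
    def test_no_primitives_straight(self):
        length, ta, tb, wrapped = wrap_route([0, 0, 0], [10, 0, 0], [])
        assert length == pytest.approx(10.0)
        assert not wrapped
        assert np.allclose(ta, [1, 0, 0])
        assert np.allclose(tb, [-1, 0, 0])

    def test_far_primitive_inactive(self):
        prim = WrapPrimitive(kind="sphere", body="x", point=(0, 50, 0), radius=3.0)
        length, _, _, wrapped = wrap_route([0, 0, 0], [10, 0, 0], [prim])
        assert length == pytest.approx(10.0)
        assert not wrapped

    def test_antipodal_sphere_closed_form(self):
        """Endpoints diametrically opposed at 2r: two tangents + arc.

        Closed form: 2 * r*sqrt(3) + r * pi/3.
        """
        r = 3.0
        prim = WrapPrimitive(kind="sphere", body="x", point=(0, 0, 0), radius=r)
        length, ta, tb, wrapped = wrap_route([2 * r, 0, 0], [-2 * r, 0, 0], [prim])
        assert wrapped
        expected = 2.0 * r * math.sqrt(3.0) + r * math.pi / 3.0
        assert length == pytest.approx(expected, rel=1e-12)

    def test_sphere_against_dense_graph_oracle(self):
        """Shortest path agrees with a graph search over the obstacle circle.

        For a single sphere the geodesic lies in the plane of the endpoints
        and the centre, so the oracle discretizes the in-plane circle and
        runs a visibility-graph shortest path.
        """
        r = 2.5
        prim = WrapPrimitive(kind="sphere", body="x", point=(0, 0, 0), radius=r)
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(20):
            a = rng.normal(size=3)
            a = a / np.linalg.norm(a) * rng.uniform(1.3 * r, 4 * r)
            # place b roughly opposite a so most pairs engage the obstacle
            b = -a + rng.normal(scale=0.6 * r, size=3)
            b = b / np.linalg.norm(b) * rng.uniform(1.3 * r, 4 * r)
            length, _, _, wrapped = wrap_route(a, b, [prim])
            if not wrapped:
                continue
            assert length == pytest.approx(_circle_graph_oracle(a, b, r), rel=5e-3)
            checked += 1
        assert checked >= 3

    def test_cylinder_wrap_reduces_to_circle_in_plane(self):
        """Coplanar endpoints around a cylinder match the 2-D closed form."""
        r = 2.0
        prim = WrapPrimitive(kind="cylinder", body="x", point=(0, 0, 0),
                             radius=r, axis=(0, 0, 1))
        length, _, _, wrapped = wrap_route([2 * r, 0, 0], [-2 * r, 0, 0], [prim])
        assert wrapped
        assert length == pytest.approx(2 * r * math.sqrt(3.0) + r * math.pi / 3.0,
                                       rel=1e-12)

    def test_endpoint_inside_primitive_identified(self):
        prim = WrapPrimitive(kind="sphere", body="x", point=(0, 0, 0), radius=5.0)
        with pytest.raises(ValueError, match="sphere"):
            wrap_route([1.0, 0, 0], [10.0, 0, 0], [prim])

    def test_length_continuous_under_small_motion(self):
        """No jump as the path transitions between straight and wrapped."""
        r = 2.0
        prim = WrapPrimitive(kind="cylinder", body="x", point=(0, 0, 0),
                             radius=r, axis=(0, 0, 1))
        lengths = []
        for y in np.linspace(1.8, 2.2, 81):
            lengths.append(wrap_route([-8, y, 0], [8, y, 1.0], [prim])[0])
        assert np.max(np.abs(np.diff(lengths))) < 0.02


class TestSectioning:
    @pytest.fixture()
    def atlas(self):
        geom = generate_elbow(GeometryConfig())
        lengths = {name: 20.0 for name in geom.attachments}
        return build_bundles(geom.attachments, lengths)

    def test_intact_has_fourteen_active(self, atlas):
        out = section_bundles(atlas, "intact")
        assert sum(b.active for b in out.values()) == 14

    @pytest.mark.parametrize("scenario, inactive", [
        ("MCL_AB_deficient", 3),
        ("MCL_PB_deficient", 3),
        ("both_MCL_deficient", 6),
    ])
    def test_deficiency_counts(self, atlas, scenario, inactive):
        out = section_bundles(atlas, scenario)
        assert sum(not b.active for b in out.values()) == inactive
        removed = SCENARIOS[scenario]
        for b in out.values():
            assert b.active == (b.complex not in removed)

    def test_idempotent(self, atlas):
        once = section_bundles(atlas, "MCL_AB_deficient")
        twice = section_bundles(once, "MCL_AB_deficient")
        assert {n: b.active for n, b in once.items()} == \
               {n: b.active for n, b in twice.items()}

    def test_other_bundles_untouched(self, atlas):
        out = section_bundles(atlas, "both_MCL_deficient")
        for name, b in out.items():
            if b.complex not in ("MCL_AB", "MCL_PB"):
                assert b.k == atlas[name].k
                assert np.allclose(b.origin, atlas[name].origin)

    def test_unknown_scenario(self, atlas):
        with pytest.raises(ValueError, match="valid scenarios"):
            section_bundles(atlas, "everything_cut")


def _circle_graph_oracle(a, b, r, n=720):
    """Dense shortest path in the plane spanned by a, b and the centre."""
    import heapq

    e1 = a / np.linalg.norm(a)
    nrm = np.cross(a, b)
    if np.linalg.norm(nrm) < 1e-12:
        probe = np.array([1.0, 0, 0]) if abs(e1[0]) < 0.9 else np.array([0, 1.0, 0])
        nrm = np.cross(e1, probe)
    nrm = nrm / np.linalg.norm(nrm)
    e2 = np.cross(nrm, e1)
    to2 = lambda v: np.array([v @ e1, v @ e2])
    p, q = to2(a), to2(b)

    angles = np.linspace(0, 2 * math.pi, n, endpoint=False)
    ring = np.column_stack([r * np.cos(angles), r * np.sin(angles)])
    nodes = [p, q] + list(ring)

    def visible(u, v):
        d = v - u
        ls = d @ d
        if ls == 0:
            return True
        t = np.clip(-(u @ d) / ls, 0.0, 1.0)
        return np.linalg.norm(u + t * d) >= r - 1e-9

    # edges: endpoints to ring & each other if visible; ring neighbours
    dist = {0: 0.0}
    heap = [(0.0, 0)]
    adj = {}

    def neighbours(i):
        if i in adj:
            return adj[i]
        out = []
        u = nodes[i]
        if i in (0, 1):
            for j in range(len(nodes)):
                if j != i and visible(u, nodes[j]):
                    out.append((j, float(np.linalg.norm(nodes[j] - u))))
        else:
            k = i - 2
            for dk in (-1, 1):
                j = 2 + (k + dk) % n
                out.append((j, float(np.linalg.norm(nodes[j] - u))))
            for j in (0, 1):
                if visible(u, nodes[j]):
                    out.append((j, float(np.linalg.norm(nodes[j] - u))))
        adj[i] = out
        return out

    while heap:
        d0, i = heapq.heappop(heap)
        if i == 1:
            return d0
        if d0 > dist.get(i, np.inf):
            continue
        for j, w in neighbours(i):
            nd = d0 + w
            if nd < dist.get(j, np.inf):
                dist[j] = nd
                heapq.heappush(heap, (nd, j))
    raise RuntimeError("no path")
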