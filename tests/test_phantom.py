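"""Phantom generator tests against analytic oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from cochleafit import phantom
from cochleafit.errors import ParameterError


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"spiral_scale": -1.0},
        {"total_turn": 0.0},
        {"duct_radius_base": 0.2, "duct_radius_apex": 0.3},
        {"side": "up"},
        {"decay_rate": np.nan},
        {"height_profile": (0.1, np.inf, 0.0)},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            phantom.PhantomParams(**kwargs)


class TestGroundTruth:
    def test_flat_height_profile_gives_zero_non_planarity(self):
        p = phantom.PhantomParams(height_profile=(0.0, 0.0, 0.0))
        gt = phantom.generate_specimen(p).ground_truth
        assert gt.non_planarity < 1e-9

    def test_side_flip_preserves_all_measurements(self, default_specimen):
        left = default_specimen
        right = phantom.generate_specimen(
            dataclasses.replace(left.params, side="right"))
        for m in ("non_planarity", "reach", "duct_length"):
            assert np.isclose(getattr(left.ground_truth, m),
                              getattr(right.ground_truth, m), atol=1e-9)
        assert np.allclose(right.ground_truth.centerline,
                           left.ground_truth.centerline * [1, -1, 1])

    def test_duct_length_matches_independent_quadrature(self, default_specimen):
        # independent oracle: integrate the analytic speed |w'(theta)| with
        # adaptive quadrature, never touching the package's polyline code
        p = default_specimen.params
        a, b = p.spiral_scale, p.decay_rate
        c1, c2, c3 = p.height_coeffs
        sf = a / phantom.REF_SCALE

        def speed(t):
            r = a * np.exp(-b * t)
            dz = sf * (c1 + 2 * c2 * t + 3 * c3 * t * t)
            return np.sqrt(r * r * (1 + b * b) + dz * dz)

        oracle, _ = quad(speed, 0.0, p.total_turn, limit=200)
        assert abs(default_specimen.ground_truth.duct_length - oracle) / oracle < 1e-4

    def test_measurements_scale_exactly_with_spiral_scale(self, default_specimen):
        base = default_specimen
        bigger = phantom.generate_specimen(
            dataclasses.replace(base.params,
                                spiral_scale=base.params.spiral_scale * 1.2))
        for m in ("non_planarity", "reach", "duct_length"):
            assert np.isclose(getattr(bigger.ground_truth, m),
                              1.2 * getattr(base.ground_truth, m), rtol=1e-9)

    def test_non_planarity_monotone_in_height_amplitude(self):
        base = np.array(phantom.PhantomParams().height_profile)
        values = []
        for h in (0.0, 0.5, 1.0, 1.5, 2.0):
            p = phantom.PhantomParams(height_profile=tuple(h * base))
            values.append(phantom.generate_specimen(p).ground_truth.non_planarity)
        assert np.all(np.diff(values) >= -1e-12)


class TestMesh:
    def test_capsule_mesh_is_watertight_and_consistent(self, default_specimen):
        mesh = default_specimen.mesh
        assert mesh.is_watertight
        assert mesh.is_winding_consistent
        lumen, envelope = phantom.split_capsule(mesh)
        assert lumen.is_watertight and envelope.is_watertight

    def test_specimens_share_one_vertex_topology(self, small_cohort):
        faces0 = small_cohort[0].mesh.faces
        for sp in small_cohort[1:]:
            assert np.array_equal(sp.mesh.faces, faces0)
            assert len(sp.mesh.vertices) == len(small_cohort[0].mesh.vertices)

    def test_outer_wall_vertices_lie_on_analytic_curve(self, default_specimen):
        sp = default_specimen
        theta = np.linspace(0.0, sp.params.total_turn, phantom.N_THETA)
        wall = phantom.outer_wall_curve(sp.params, theta)
        verts = np.asarray(sp.mesh.vertices)[sp.rings[:, 0]]
        assert np.abs(verts - wall).max() < 1e-9


class TestCohort:
    def test_seeded_determinism(self):
        a = phantom.sample_cohort(3, seed=7)
        b = phantom.sample_cohort(3, seed=7)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.mesh.vertices, sb.mesh.vertices)
            assert sa.ground_truth.duct_length == sb.ground_truth.duct_length

    def test_distinct_specimens(self):
        cohort = phantom.sample_cohort(5, seed=1)
        lengths = {round(s.ground_truth.duct_length, 6) for s in cohort}
        assert len(lengths) == 5

    def test_minimum_cohort_size(self):
        with pytest.raises(ParameterError):
            phantom.sample_cohort(1, seed=0)

    def test_duct_length_spread_spans_at_least_four_mm(self):
        cohort = phantom.sample_cohort(18, seed=0)
        lengths = [s.ground_truth.duct_length for s in cohort]
        assert max(lengths) - min(lengths) >= 4.0
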