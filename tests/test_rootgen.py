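"""Root-system generation, markup I/O, spline resampling and rendering."""

import math

import numpy as np
import pytest

from rootmetrics import rootgen
from rootmetrics.errors import (
    InvariantError,
    MarkupParseError,
    MarkupSchemaError,
    ParameterError,
)
from rootmetrics.rootgen import (
    RenderConfig,
    Root,
    RootNode,
    RootSystem,
    generate_root_system,
    parse_root_markup,
    render,
    resample_centerline,
    sigma_from_diameter,
    true_length,
    write_root_markup,
)

from conftest import quarter_circle_root


def straight_root(d=1.0, length=10.0):
    return Root("A1", 0, [RootNode(5.0, 0.0, d), RootNode(5.0, length, d)])


class TestGenerate:
    def test_single_axile_no_laterals(self):
        system = generate_root_system(1, 0.0, (50.0, 60.0), seed=1)
        assert len(system.roots) == 1
        assert system.roots[0].order == 0

    def test_deterministic_for_fixed_seed(self):
        a = generate_root_system(3, 2.0, (100.0, 100.0), seed=7)
        b = generate_root_system(3, 2.0, (100.0, 100.0), seed=7)
        assert len(a.roots) == len(b.roots)
        for ra, rb in zip(a.roots, b.roots):
            assert ra.id == rb.id
            np.testing.assert_array_equal(ra.points, rb.points)
            np.testing.assert_array_equal(ra.diameters, rb.diameters)

    def test_seeds_differ(self):
        a = generate_root_system(2, 1.0, (60.0, 80.0), seed=1)
        b = generate_root_system(2, 1.0, (60.0, 80.0), seed=2)
        assert not np.array_equal(a.roots[0].points, b.roots[0].points)

    def test_lateral_first_node_on_parent_centerline(self):
        """Laterals must attach on the parent spline (nearest-segment oracle)."""
        system = generate_root_system(3, 2.0, (100.0, 100.0), seed=3)
        laterals = [r for r in system.roots if r.order == 1]
        assert laterals, "expected some laterals at 2 per cm"
        for lat in laterals:
            parent = system.root_by_id(lat.parent_id)
            pts, _ = resample_centerline(parent, step=0.01)
            p = np.array([lat.nodes[0].x, lat.nodes[0].y])
            # point-to-segment projection over the dense polyline
            a, b = pts[:-1], pts[1:]
            ab = b - a
            t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0, 1)
            dist = np.linalg.norm(a + t[:, None] * ab - p, axis=1).min()
            assert dist < 1e-6

    def test_diameter_ranges(self):
        system = generate_root_system(3, 2.0, (100.0, 100.0), seed=5)
        for root in system.roots:
            lo, hi = (
                rootgen.AXILE_DIAMETER_RANGE
                if root.order == 0
                else rootgen.LATERAL_DIAMETER_RANGE
            )
            assert lo <= root.diameters.min() <= root.diameters.max() <= hi

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_axile": 0, "laterals_per_cm": 0, "extent": (50, 50), "seed": 1},
            {"n_axile": 1, "laterals_per_cm": -1, "extent": (50, 50), "seed": 1},
            {"n_axile": 1, "laterals_per_cm": 0, "extent": (-5, 50), "seed": 1},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            generate_root_system(**kwargs)


class TestDataModel:
    def test_node_requires_positive_diameter(self):
        with pytest.raises(InvariantError):
            RootNode(0.0, 0.0, -1.0)

    def test_lateral_requires_parent(self):
        with pytest.raises(InvariantError):
            Root("L1", 1, [RootNode(0, 0, 0.3), RootNode(0, 5, 0.3)])

    def test_coincident_nodes_rejected(self):
        with pytest.raises(InvariantError):
            Root("A1", 0, [RootNode(1, 1, 0.5), RootNode(1, 1, 0.5)])

    def test_roots_must_fit_extent(self):
        with pytest.raises(InvariantError):
            RootSystem([straight_root(length=100.0)], extent=(10.0, 50.0))


class TestMarkup:
    def test_parse_minimal_document(self):
        doc = (
            '<rootsystem width_mm="20" height_mm="20">'
            '<root id="r1" order="0">'
            '<point x="0" y="0" diameter="1"/><point x="0" y="10" diameter="1"/>'
            "</root></rootsystem>"
        )
        system = parse_root_markup(doc)
        assert len(system.roots) == 1
        assert len(system.roots[0].nodes) == 2

    def test_round_trip_preserves_data(self):
        system = generate_root_system(2, 1.0, (60.0, 80.0), seed=9)
        doc = write_root_markup(system)
        again = parse_root_markup(doc)
        assert write_root_markup(again) == doc
        for ra, rb in zip(system.roots, again.roots):
            assert ra.id == rb.id and ra.order == rb.order and ra.parent_id == rb.parent_id
            np.testing.assert_allclose(ra.points, rb.points, atol=5e-7)
            np.testing.assert_allclose(ra.diameters, rb.diameters, atol=5e-7)

    def test_malformed_xml(self):
        with pytest.raises(MarkupParseError):
            parse_root_markup("<rootsystem><root></rootsystem>")

    def test_negative_diameter_is_schema_error(self):
        doc = (
            '<rootsystem width_mm="20" height_mm="20">'
            '<root id="r1" order="0">'
            '<point x="0" y="0" diameter="-1"/><point x="0" y="10" diameter="1"/>'
            "</root></rootsystem>"
        )
        with pytest.raises(MarkupSchemaError, match="r1"):
            parse_root_markup(doc)

    def test_missing_diameter_names_element(self):
        doc = (
            '<rootsystem width_mm="20" height_mm="20">'
            '<root id="r7" order="0"><point x="0" y="0"/></root></rootsystem>'
        )
        with pytest.raises(MarkupSchemaError, match="r7"):
            parse_root_markup(doc)


class TestResample:
    def test_straight_root_stays_on_axis(self):
        pts, dia = resample_centerline(straight_root(d=0.3), step=0.1)
        assert np.allclose(pts[:, 0], 5.0)
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc == pytest.approx(10.0, rel=1e-9)
        assert np.allclose(dia, 0.3)  # constant diameter interpolates constant

    def test_quarter_circle_arc_length(self):
        root = quarter_circle_root(radius=20.0)
        pts, _ = resample_centerline(root, step=0.05)
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc == pytest.approx(math.pi / 2 * 20.0, rel=0.01)

    def test_spacing_and_endpoints(self):
        root = quarter_circle_root()
        pts, _ = resample_centerline(root, step=0.2)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert steps.max() <= 0.2
        np.testing.assert_allclose(pts[0], root.points[0], atol=1e-12)
        np.testing.assert_allclose(pts[-1], root.points[-1], atol=1e-12)

    def test_step_must_be_positive(self):
        with pytest.raises(ParameterError):
            resample_centerline(straight_root(), step=0.0)


class TestTrueLength:
    def test_straight_root(self):
        _, total = true_length(RootSystem([straight_root()], (20.0, 20.0)))
        assert total == pytest.approx(10.0, rel=1e-6)

    def test_additivity_over_roots(self):
        r1 = straight_root()
        r2 = Root("A2", 0, [RootNode(10, 0, 1.0), RootNode(10, 10, 1.0)])
        _, total = true_length(RootSystem([r1, r2], (20.0, 20.0)))
        assert total == pytest.approx(20.0, rel=1e-6)

    def test_quarter_circle(self):
        root = quarter_circle_root(radius=20.0)
        _, total = true_length(RootSystem([root], (50.0, 50.0)))
        assert total == pytest.approx(math.pi / 2 * 20.0, rel=0.01)

    def test_invariant_under_step_refinement(self):
        system = RootSystem([quarter_circle_root()], (50.0, 50.0))
        _, a = true_length(system, step=0.1)
        _, b = true_length(system, step=0.05)
        assert abs(a - b) / b < 1e-3


class TestRender:
    def test_sigma_matches_fwhm_relation(self):
        # 3-px FWHM at 0.13 mm/px: sigma = 3 / (2 sqrt(2 ln 2)) px
        expected = 3.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        assert expected == pytest.approx(1.274, abs=0.01)
        assert sigma_from_diameter(0.3926, 0.13) == pytest.approx(1.274, rel=0.01)
        assert sigma_from_diameter(3 * 0.13, 0.13) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("d", [0.3926, 0.6, 1.0])
    def test_fwhm_of_rendered_profile_equals_diameter(self, d):
        root = Root("A1", 0, [RootNode(10.0, 2.0, d), RootNode(10.0, 38.0, d)])
        image, _ = render(RootSystem([root], (20.0, 40.0), seed=1), RenderConfig())
        row = image.pixels[100]
        half = 40.0 + 200.0 / 2.0
        above = np.nonzero(row > half)[0]
        lo, hi = above[0], above[-1]
        # subpixel crossings by linear interpolation on both flanks
        x_left = (lo - 1) + (half - row[lo - 1]) / (row[lo] - row[lo - 1])
        x_right = hi + (row[hi] - half) / (row[hi] - row[hi + 1])
        width_px = x_right - x_left
        assert width_px == pytest.approx(d / 0.13, abs=0.5)

    def test_intensity_at_half_diameter_is_half_amplitude(self):
        d = 0.6
        x = 0.13 * 77.5  # centerline exactly on the center of column 77
        root = Root("A1", 0, [RootNode(x, 2.0, d), RootNode(x, 38.0, d)])
        image, _ = render(RootSystem([root], (20.0, 40.0)), RenderConfig())
        row = image.pixels[100]
        assert row[77] == pytest.approx(240.0, abs=1.0)
        at_edge = np.interp(77.5 + d / 2 / 0.13, np.arange(len(row)) + 0.5, row)
        assert at_edge == pytest.approx(40.0 + 200.0 / 2.0, abs=2.0)

    def test_column_symmetry_of_vertical_root(self):
        # centerline placed exactly on the center of pixel column 77
        x = 0.13 * 77.5
        root = Root("A1", 0, [RootNode(x, 2.0, 0.8), RootNode(x, 38.0, 0.8)])
        image, _ = render(RootSystem([root], (20.0, 40.0)), RenderConfig())
        px = image.pixels
        for k in range(1, 25):
            np.testing.assert_allclose(px[50:250, 77 - k], px[50:250, 77 + k], atol=1.0)

    def test_ground_truth_matches_resampled_arc_length(self, straight_root_render):
        gt = straight_root_render["gt"]
        assert gt.total_length_mm == pytest.approx(36.0, rel=1e-6)
        assert gt.total_length_px == pytest.approx(36.0 / 0.13, rel=1e-6)

    def test_render_deterministic(self):
        system = generate_root_system(2, 1.0, (40.0, 50.0), seed=3)
        cfg = RenderConfig(noise_sd=2.0, ragged_edges=True)
        img1, _ = render(system, cfg)
        img2, _ = render(system, cfg)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)

    def test_sub_resolution_root_warns(self):
        thin = Root("T1", 0, [RootNode(5, 2, 0.05), RootNode(5, 20, 0.05)])
        _, gt = render(RootSystem([thin], (10.0, 25.0)), RenderConfig())
        assert any("sub-resolution" in w for w in gt.warnings)

    def test_ragged_edges_perturb_boundary(self):
        system = RootSystem(
            [Root("A1", 0, [RootNode(10, 2, 0.8), RootNode(10, 38, 0.8)])],
            (20.0, 40.0),
            seed=4,
        )
        smooth_img, _ = render(system, RenderConfig())
        ragged_img, _ = render(system, RenderConfig(ragged_edges=True))
        assert not np.array_equal(smooth_img.pixels, ragged_img.pixels)
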