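import numpy as np
import pytest
from shapely.geometry import Polygon, box

from spatialtme.io_tables import TissueClass
from spatialtme.spatial import (
    LBL_EPI,
    LBL_OUTSIDE,
    LBL_STROMA,
    ContactRule,
    NoBoundaryError,
    TissueGeometry,
    band_areas,
    count_contacts,
    density_profile,
    nearest_distance,
    signed_distance,
)

from conftest import make_cell, random_cells


# ---------------------------------------------------------------------------
# signed distances
# ---------------------------------------------------------------------------

class TestSignedDistance:
    def test_disc_closed_form(self, disc_geometry):
        cells = [
            make_cell("center", 500, 500),
            make_cell("outside", 650, 500),
            make_cell("inside", 550, 500),
        ]
        d = signed_distance(cells, disc_geometry)
        assert d["center"] == pytest.approx(-100.0, abs=0.2)
        assert d["outside"] == pytest.approx(50.0, abs=0.2)
        assert d["inside"] == pytest.approx(-50.0, abs=0.2)

    def test_halfplane_closed_form(self, halfplane_geometry):
        cells = [make_cell("a", 400, 500), make_cell("b", 700, 500)]
        d = signed_distance(cells, halfplane_geometry)
        assert d["a"] == pytest.approx(-100.0, abs=1e-9)
        assert d["b"] == pytest.approx(200.0, abs=1e-9)

    def test_out_of_frame_excluded(self, disc_geometry):
        cells = [make_cell("in", 10, 10), make_cell("out", 2000, 2000)]
        d = signed_distance(cells, disc_geometry)
        assert "in" in d and "out" not in d

    def test_no_boundary_raises(self):
        geom = TissueGeometry.from_polygons("S0", None, box(0, 0, 1000, 1000))
        with pytest.raises(NoBoundaryError, match="no boundary"):
            signed_distance([make_cell()], geom)

    def test_irregular_polygon_matches_dense_boundary_oracle(self, rng):
        # star-shaped irregular polygon
        angles = np.sort(rng.uniform(0, 2 * np.pi, 17))
        radii = rng.uniform(100, 250, len(angles))
        pts = np.column_stack(
            [500 + radii * np.cos(angles), 500 + radii * np.sin(angles)]
        )
        poly = Polygon(pts)
        assert poly.is_valid
        geom = TissueGeometry.from_polygons("S0", [poly], box(0, 0, 1000, 1000))
        cells = random_cells(rng, 300)
        result = signed_distance(cells, geom)

        # oracle: brute-force min over the boundary densely resampled at 0.05 um
        ring = poly.exterior
        n_pts = int(np.ceil(ring.length / 0.05))
        bnd = np.array(
            [ring.interpolate(i * ring.length / n_pts).coords[0] for i in range(n_pts)]
        )
        for cell in cells:
            d_oracle = np.min(
                np.hypot(bnd[:, 0] - cell.x_um, bnd[:, 1] - cell.y_um)
            )
            assert abs(result[cell.cell_id]) == pytest.approx(d_oracle, abs=0.2)

    def test_sign_agrees_with_polygon_membership(self, rng):
        poly = box(200, 200, 800, 800)
        geom = TissueGeometry.from_polygons("S0", [poly], box(0, 0, 1000, 1000))
        cells = random_cells(rng, 500)
        d = signed_distance(cells, geom)
        for c in cells:
            inside = 200 < c.x_um < 800 and 200 < c.y_um < 800
            if abs(d[c.cell_id]) > 1e-6:
                assert (d[c.cell_id] < 0) == inside

    def test_mask_file_roundtrip(self, tmp_path, disc_geometry):
        path = tmp_path / "mask.png"
        disc_geometry.to_mask_file(path, resolution=2.0)
        back = TissueGeometry.from_mask_file(path, um_per_px=2.0, sample_id="S0")
        assert back.is_mask
        assert back.epi_area_mm2() == pytest.approx(
            disc_geometry.epi_area_mm2(), rel=0.02
        )
        d = signed_distance([make_cell("c", 650, 500)], back)
        assert d["c"] == pytest.approx(50.0, abs=3.0)

    def test_geojson_roundtrip_preserves_discs(self, tmp_path, disc_geometry):
        path = tmp_path / "geom.geojson"
        disc_geometry.to_geojson(path)
        back = TissueGeometry.from_geojson(path)
        assert back.discs == disc_geometry.discs
        assert back.sample_id == "S0"
        d = signed_distance([make_cell("c", 500, 500)], back)
        assert d["c"] == pytest.approx(-100.0, abs=1e-9)

    def test_mask_geometry_within_raster_tolerance(self):
        # half-plane mask at 2 um/px: epi rows x < 500
        mask = np.full((500, 500), LBL_STROMA, dtype=np.uint8)
        mask[:, :250] = LBL_EPI
        geom = TissueGeometry.from_mask("S0", mask, um_per_px=2.0)
        cells = [make_cell("a", 400, 500), make_cell("b", 700, 500)]
        d = signed_distance(cells, geom)
        assert d["a"] == pytest.approx(-100.0, abs=3.0)
        assert d["b"] == pytest.approx(200.0, abs=3.0)


# ---------------------------------------------------------------------------
# band areas
# ---------------------------------------------------------------------------

class TestBandAreas:
    def test_halfplane_band(self, halfplane_geometry):
        areas = band_areas(halfplane_geometry, [0.0, 100.0])
        assert areas[0] == pytest.approx(0.1, rel=0.02)

    def test_band_outside_frame_is_zero(self, halfplane_geometry):
        areas = band_areas(halfplane_geometry, [5000.0, 6000.0], resolution=2.0)
        assert areas[0] == 0.0

    def test_disc_bands_match_analytic(self, disc_geometry):
        edges = [-100.0, 0.0, 25.0, 50.0]
        areas = band_areas(disc_geometry, edges)
        analytic = [
            np.pi * 100**2 / 1e6,
            np.pi * (125**2 - 100**2) / 1e6,
            np.pi * (150**2 - 125**2) / 1e6,
        ]
        for a, b in zip(areas, analytic):
            assert a == pytest.approx(b, rel=0.02)

    def test_resolution_guard(self, disc_geometry):
        with pytest.raises(ValueError, match="coarser"):
            band_areas(disc_geometry, [0.0, 4.0], resolution=2.0)

    def test_polygon_edt_path_halfplane(self, halfplane_geometry):
        # generic polygon path (no disc shortcut) at several bands
        areas = band_areas(halfplane_geometry, [-200.0, -100.0, 0.0, 100.0, 200.0])
        for a in areas:
            assert a == pytest.approx(0.1, rel=0.05)


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

class TestDensityProfile:
    def test_zero_cells(self, disc_geometry):
        prof = density_profile([], {"S0": disc_geometry}, distance_range=(-100, 100))
        assert prof.counts.sum() == 0
        assert np.nansum(prof.density) == 0

    def test_regular_grid_uniform_density(self, halfplane_geometry):
        # one cell per 50x50 um cell => 400 cells/mm^2 in every stromal bin
        cells = []
        i = 0
        for x in np.arange(25, 1000, 50):
            for y in np.arange(25, 1000, 50):
                cells.append(make_cell(f"c{i}", float(x), float(y)))
                i += 1
        prof = density_profile(
            cells, {"S0": halfplane_geometry}, bin_width=50, distance_range=(-500, 500)
        )
        stromal = (prof.bin_centers > 0) & (prof.bin_centers < 500)
        np.testing.assert_allclose(prof.density[stromal], 400.0, rtol=0.05)

    def test_handmade_fixture_against_analytic_areas(self, disc_geometry):
        # 20 cells at known signed distances on the disc geometry
        placements = [(-70.0, 4), (-20.0, 6), (12.5, 5), (60.0, 5)]
        cells = []
        i = 0
        for d, n in placements:
            r = 100 + d  # radial position giving signed distance d
            for k in range(n):
                ang = 2 * np.pi * k / n + 0.1
                cells.append(
                    make_cell(
                        f"c{i}", 500 + r * np.cos(ang), 500 + r * np.sin(ang)
                    )
                )
                i += 1
        prof = density_profile(
            cells, {"S0": disc_geometry}, bin_width=25, distance_range=(-100, 100)
        )
        centers = prof.bin_centers

        def analytic_area(lo, hi):
            lo_r, hi_r = max(0.0, 100 + lo), max(0.0, 100 + hi)
            return np.pi * (hi_r**2 - lo_r**2) / 1e6

        expected_counts = {-87.5: 0, -62.5: 4, -37.5: 0, -12.5: 6, 12.5: 5, 37.5: 0, 62.5: 5, 87.5: 0}
        for j, c in enumerate(centers):
            assert prof.counts[j] == expected_counts[float(c)]
            area = analytic_area(c - 12.5, c + 12.5)
            assert prof.density[j] == pytest.approx(
                expected_counts[float(c)] / area, rel=0.02
            )

    def test_count_conservation(self, rng, disc_geometry):
        cells = random_cells(rng, 400)
        prof = density_profile(
            cells, {"S0": disc_geometry}, bin_width=25, distance_range=(-100, 100)
        )
        d = signed_distance(cells, disc_geometry)
        in_range = sum(1 for v in d.values() if -100 < v <= 100)
        assert prof.counts.sum() == in_range

    def test_cross_sample_mean_and_se(self, rng):
        g1 = TissueGeometry.from_discs("S1", [(500, 500, 100)], box(0, 0, 1000, 1000))
        g2 = TissueGeometry.from_discs("S2", [(500, 500, 100)], box(0, 0, 1000, 1000))
        cells = random_cells(rng, 200, sample_id="S1", prefix="a") + random_cells(
            rng, 100, sample_id="S2", prefix="b"
        )
        prof = density_profile(
            cells, {"S1": g1, "S2": g2}, bin_width=50, distance_range=(-100, 200)
        )
        assert prof.n_samples == 2
        d1 = prof.per_sample_density["S1"]
        d2 = prof.per_sample_density["S2"]
        np.testing.assert_allclose(prof.mean_density, np.nanmean([d1, d2], axis=0))
        expected_se = np.nanstd([d1, d2], axis=0, ddof=1) / np.sqrt(2)
        np.testing.assert_allclose(prof.se, expected_se)

    def test_no_samples_raises(self):
        with pytest.raises(ValueError, match="no samples"):
            density_profile([], {})


# ---------------------------------------------------------------------------
# nearest distances
# ---------------------------------------------------------------------------

class TestNearestDistance:
    def test_345_triangle(self):
        res = nearest_distance(
            [make_cell("f", 0, 0)],
            [make_cell("t1", 3, 4), make_cell("t2", 6, 8)],
        )
        assert res.per_cell["f"] == pytest.approx(5.0)
        assert res.mnd == pytest.approx(5.0)

    def test_self_exclusion(self, rng):
        cells = random_cells(rng, 50)
        res = nearest_distance(cells, cells)
        assert all(v > 0 for v in res.per_cell.values())
        assert len(res.per_cell) == 50

    def test_empty_to_raises(self):
        with pytest.raises(ValueError, match="no reference cells"):
            nearest_distance([make_cell()], [])

    def test_matches_brute_force(self, rng):
        frm = random_cells(rng, 500, prefix="f")
        to = random_cells(rng, 500, prefix="t")
        res = nearest_distance(frm, to)
        to_xy = np.array([[c.x_um, c.y_um] for c in to])
        for c in frm:
            brute = np.min(np.hypot(to_xy[:, 0] - c.x_um, to_xy[:, 1] - c.y_um))
            assert res.per_cell[c.cell_id] == pytest.approx(brute, abs=1e-9)
        assert res.mnd == pytest.approx(np.mean(list(res.per_cell.values())))

    def test_monotone_in_to_set(self, rng):
        frm = random_cells(rng, 100, prefix="f")
        to1 = random_cells(rng, 100, prefix="t")
        to2 = to1 + random_cells(rng, 100, prefix="u")
        r1 = nearest_distance(frm, to1)
        r2 = nearest_distance(frm, to2)
        for cid in r1.per_cell:
            assert r2.per_cell[cid] <= r1.per_cell[cid] + 1e-12


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

class TestCountContacts:
    def test_rule_arithmetic(self):
        # default radius 5 um each + 1 um slack => threshold 11 um
        ref = [make_cell("r", 0, 0)]
        near = {"X": [make_cell("p", 10.5, 0)]}
        far = {"X": [make_cell("p", 11.5, 0)]}
        assert count_contacts(ref, near).per_reference_cell["r"] == {"X": 1}
        assert count_contacts(ref, far).per_reference_cell["r"] == {}

    def test_area_derived_radii(self):
        # r = sqrt(area/pi); areas 100pi and 25pi => radii 10 and 5, slack 1
        ref = [make_cell("r", 0, 0, area=np.pi * 100)]
        partner = make_cell("p", 15.5, 0, area=np.pi * 25)
        res = count_contacts(ref, {"X": [partner]})
        assert res.per_reference_cell["r"] == {"X": 1}
        partner_far = make_cell("p", 16.5, 0, area=np.pi * 25)
        res = count_contacts(ref, {"X": [partner_far]})
        assert res.per_reference_cell["r"] == {}

    def test_negative_slack_rejected(self):
        with pytest.raises(ValueError, match="slack"):
            ContactRule(slack_um=-1.0)

    def test_matches_brute_force(self, rng):
        ref = random_cells(rng, 300, prefix="r")
        partners = random_cells(rng, 300, prefix="p")
        rule = ContactRule()
        res = count_contacts(ref, {"X": partners}, rule)
        for r in ref:
            brute = sum(
                1
                for p in partners
                if np.hypot(p.x_um - r.x_um, p.y_um - r.y_um) <= 11.0
            )
            assert res.per_reference_cell[r.cell_id].get("X", 0) == brute
        frac_oracle = np.mean(
            [
                any(
                    np.hypot(p.x_um - r.x_um, p.y_um - r.y_um) <= 11.0
                    for p in partners
                )
                for r in ref
            ]
        )
        assert res.contact_fraction["X"] == pytest.approx(frac_oracle)

    def test_pair_symmetry(self, rng):
        a = random_cells(rng, 200, prefix="a")
        b = random_cells(rng, 200, prefix="b")
        ab = count_contacts(a, {"B": b}).total_contacts("B")
        ba = count_contacts(b, {"A": a}).total_contacts("A")
        assert ab == ba
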