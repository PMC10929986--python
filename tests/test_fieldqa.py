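"""Aperture rasterization, binarization and Jaccard comparison."""

import numpy as np
import pytest
import shapely

from photonblock.ciao import NoMLCWarning, ciao_polygon
from photonblock.fieldqa import (
    ApertureMask,
    ComparisonEntry,
    EmptyMaskError,
    PortalImage,
    binarize_image,
    ciao_mask,
    compare_apertures,
    jaccard_distance,
    rasterize_blocks,
    summarize,
)
from photonblock.fixtures import FixtureSpec, make_field
from photonblock.plan import (
    BlockOutline,
    FieldDefinition,
    JawSet,
    MLCControlPoint,
    MLCState,
)


def _mask(pix, spacing=1.0, origin=(0.0, 0.0), prov="TPS"):
    return ApertureMask(np.asarray(pix, bool), spacing, origin, prov)


def mlc_field(bank_a, bank_b, boundaries, jaws=(-50, 50, -50, 50), blocks=()):
    return FieldDefinition(
        patient_id="p", field_id="f",
        jaws=JawSet(x1_mm=jaws[0], x2_mm=jaws[1], y1_mm=jaws[2], y2_mm=jaws[3]),
        mlc=MLCState(
            leaf_boundaries_mm=boundaries,
            control_points=(MLCControlPoint(bank_a_mm=bank_a,
                                            bank_b_mm=bank_b),),
        ),
        blocks=blocks,
    )


class TestRasterize:
    def test_square_pixel_count(self):
        """A 10x10 mm square at 1 mm spacing covers exactly 100 pixel
        centers (half-open placement avoids edge centers)."""
        f = FieldDefinition(
            patient_id="p", field_id="f",
            jaws=JawSet(x1_mm=-20, x2_mm=20, y1_mm=-20, y2_mm=20),
            blocks=(BlockOutline(
                vertices_mm=((0.25, 0.25), (10.25, 0.25),
                             (10.25, 10.25), (0.25, 10.25))),),
        )
        mask = rasterize_blocks(f, 1.0)
        assert mask.count == 100

    def test_refinement_bound(self):
        """Halving the spacing changes the area estimate by less than one
        perimeter-thick band of pixels."""
        f = make_field(FixtureSpec(archetype="pelvis_ovaries", rng_seed=2))
        coarse = rasterize_blocks(f, 1.0)
        fine = rasterize_blocks(f, 0.5)
        perimeter = sum(b.polygon().perimeter_mm() for b in f.blocks)
        assert abs(coarse.area_mm2 - fine.area_mm2) < perimeter * 1.0

    def test_empty_block_list_rejected(self):
        f = FieldDefinition(
            patient_id="p", field_id="f",
            jaws=JawSet(x1_mm=-20, x2_mm=20, y1_mm=-20, y2_mm=20))
        with pytest.raises(EmptyMaskError):
            rasterize_blocks(f, 1.0)

    def test_zero_spacing_rejected(self, round_field):
        with pytest.raises(ValueError):
            rasterize_blocks(round_field, 0.0)


class TestCiao:
    def test_wide_open_equals_jaw_rectangle(self):
        f = mlc_field(bank_a=(-60.0,) * 10, bank_b=(60.0,) * 10,
                      boundaries=tuple(np.linspace(-50, 50, 11)))
        m = ciao_mask(f, 1.0)
        jaw_only = FieldDefinition(patient_id="p", field_id="f", jaws=f.jaws)
        with pytest.warns(NoMLCWarning):
            jaw_mask = ciao_mask(jaw_only, 1.0)
        assert np.array_equal(m.pixels, jaw_mask.pixels)

    def test_closed_pair_excluded(self):
        open_a = [-60.0] * 10
        open_b = [60.0] * 10
        open_a[4] = open_b[4] = 0.0  # abutted pair -> strip closed
        f = mlc_field(tuple(open_a), tuple(open_b),
                      tuple(np.linspace(-50, 50, 11)))
        geom = ciao_polygon(f)
        assert geom.area == pytest.approx(100.0 * 100.0 - 100.0 * 10.0)

    def test_matches_brute_force_pixel_openness(self):
        """CIAO raster equals a per-pixel test against each leaf pair."""
        rng = np.random.default_rng(4)
        bounds = tuple(np.linspace(-50, 50, 11))
        a = tuple(rng.uniform(-45, -5, 10))
        b = tuple(rng.uniform(5, 45, 10))
        f = mlc_field(a, b, bounds)
        m = ciao_mask(f, 2.0)
        xs, ys = m.pixel_centers()
        brute = np.zeros_like(m.pixels)
        for i, y in enumerate(ys):
            for j, x in enumerate(xs):
                # a pixel center is open iff it is interior to the union:
                # strictly inside the jaws and either strictly inside one
                # strip, or on a strip boundary with both neighbours open
                if not (f.jaws.x1_mm < x < f.jaws.x2_mm
                        and f.jaws.y1_mm < y < f.jaws.y2_mm):
                    continue
                for k in range(10):
                    if bounds[k] < y < bounds[k + 1] and a[k] < x < b[k]:
                        brute[i, j] = True
                for k in range(1, 10):
                    if y == bounds[k] and a[k - 1] < x < b[k - 1] \
                            and a[k] < x < b[k]:
                        brute[i, j] = True
        assert np.array_equal(m.pixels, brute)


class TestBinarize:
    def _two_level(self, lo=0.05, hi=1.0):
        img = np.full((40, 40), hi)
        img[10:30, 10:30] = lo
        return PortalImage(img, spacing_mm=1.0)

    def test_two_level_midpoint_exact_recovery(self):
        mask = binarize_image(self._two_level(), "midpoint")
        expected = np.zeros((40, 40), bool)
        expected[10:30, 10:30] = True
        assert np.array_equal(mask.pixels, expected)

    def test_invert_flips(self):
        a = binarize_image(self._two_level(), "midpoint")
        b = binarize_image(self._two_level(), "midpoint", invert=True)
        assert np.array_equal(a.pixels, ~b.pixels)

    def test_otsu_near_midpoint_on_bimodal(self):
        """Otsu's threshold on a clean bimodal 16-bit image lands between
        the modes, within one gray level of the midpoint."""
        img = np.full((64, 64), 60000, dtype=float)
        img[16:48, 16:48] = 3000
        pi = PortalImage(img, spacing_mm=1.0)
        a = binarize_image(pi, "otsu")
        b = binarize_image(pi, "midpoint")
        assert np.array_equal(a.pixels, b.pixels)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            binarize_image(PortalImage(np.ones((8, 8)), 1.0), "midpoint")

    def test_spacing_rescaled_to_reference_plane(self):
        img = self._two_level()
        img = PortalImage(img.pixels, spacing_mm=0.4, imager_z_cm=160.0,
                          reference_z_cm=100.0)
        mask = binarize_image(img)
        assert mask.spacing_mm == pytest.approx(0.25)

    def test_numeric_threshold(self):
        mask = binarize_image(self._two_level(), 0.5)
        assert mask.count == 400


class TestJaccard:
    def test_identical_masks_zero(self):
        m = _mask(np.eye(5))
        assert jaccard_distance(m, m) == 0.0

    def test_disjoint_masks_one(self):
        a = np.zeros((4, 4), bool); a[0, :] = True
        b = np.zeros((4, 4), bool); b[2, :] = True
        assert jaccard_distance(_mask(a), _mask(b)) == 1.0

    def test_shifted_square_hand_count(self):
        """4x4 squares offset by 2 columns: |A^B| = 8, |AuB| = 24."""
        a = np.zeros((8, 8), bool); a[0:4, 0:4] = True
        b = np.zeros((8, 8), bool); b[0:4, 2:6] = True
        assert jaccard_distance(_mask(a), _mask(b)) == pytest.approx(16 / 24)

    def test_both_empty_undefined(self):
        z = _mask(np.zeros((4, 4)))
        with pytest.raises(EmptyMaskError):
            jaccard_distance(z, z)

    def test_metric_axioms_on_random_masks(self):
        """Symmetry, identity of indiscernibles and the triangle inequality
        on random nonempty mask triples."""
        rng = np.random.default_rng(99)
        for _ in range(300):
            trip = []
            for _k in range(3):
                pix = rng.random((12, 12)) < rng.uniform(0.2, 0.8)
                if not pix.any():
                    pix[0, 0] = True
                trip.append(_mask(pix))
            a, b, c = trip
            dab = jaccard_distance(a, b)
            assert dab == jaccard_distance(b, a)
            assert 0.0 <= dab <= 1.0
            if np.array_equal(a.pixels, b.pixels):
                assert dab == 0.0
            assert dab <= jaccard_distance(a, c) + jaccard_distance(c, b) + 1e-12

    def test_matches_sklearn_oracle(self):
        """Cross-check against an independent library implementation."""
        from sklearn.metrics import jaccard_score

        rng = np.random.default_rng(17)
        for _ in range(20):
            a = rng.random((10, 10)) < 0.5
            b = rng.random((10, 10)) < 0.5
            if not (a | b).any():
                continue
            ours = jaccard_distance(_mask(a), _mask(b))
            theirs = 1.0 - jaccard_score(a.ravel(), b.ravel(),
                                         zero_division=0)
            assert ours == pytest.approx(theirs)


class TestCompare:
    def _masks(self):
        planned = np.zeros((20, 20), bool); planned[5:15, 5:15] = True
        ciao = np.zeros((20, 20), bool); ciao[2:18, 2:18] = True
        return _mask(planned), _mask(ciao)

    def test_identical_zero(self):
        planned, ciao = self._masks()
        e = compare_apertures(planned, planned, ciao, case="A", group="3D")
        assert e.dj == 0.0

    def test_fully_displaced_outside_ciao_is_one(self):
        planned, ciao = self._masks()
        moved = np.zeros((20, 20), bool); moved[0:2, 0:2] = True  # outside CIAO
        e = compare_apertures(_mask(moved), planned, ciao)
        assert e.dj == 1.0

    def test_out_of_ciao_pixels_ignored(self):
        """Cerrobend-style extensions beyond the CIAO must not change dj."""
        planned, ciao = self._masks()
        measured = planned.pixels.copy()
        extended = measured.copy()
        extended[18:, :] = True  # extension fully outside the CIAO
        d1 = compare_apertures(_mask(measured), planned, ciao).dj
        d2 = compare_apertures(_mask(extended), planned, ciao).dj
        assert d1 == d2 == 0.0

    def test_empty_ciao_rejected(self):
        planned, _ = self._masks()
        with pytest.raises(EmptyMaskError):
            compare_apertures(planned, planned, _mask(np.zeros((20, 20))))


class TestSummarize:
    def test_group_means(self):
        entries = [
            ComparisonEntry("A", "3D", 0.036),
            ComparisonEntry("B", "3D", 0.058),
            ComparisonEntry("C", "3D", 0.108),
            ComparisonEntry("A", "CB", 0.143),
            ComparisonEntry("B", "CB", 0.090),
            ComparisonEntry("C", "CB", 0.239),
        ]
        rep = summarize(entries)
        assert rep.group_means["3D"] == pytest.approx(0.067)
        assert rep.group_means["CB"] == pytest.approx(0.157)
        assert rep.ratios_pct == {"A": 397, "B": 155, "C": 221}

    def test_zero_denominator_undefined(self):
        entries = [ComparisonEntry("A", "3D", 0.0),
                   ComparisonEntry("A", "CB", 0.1)]
        rep = summarize(entries)
        assert rep.ratios_pct["A"] is None

    def test_report_renders(self):
        entries = [ComparisonEntry("A", "3D", 0.05),
                   ComparisonEntry("A", "CB", 0.10)]
        rep = summarize(entries)
        assert "dj(3D,TPS)" in rep.to_text() or "dj(CB,TPS)" in rep.to_text()
        frame = rep.to_frame()
        assert "ratio_pct" in frame.columns
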