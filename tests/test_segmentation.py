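"""Segmentation stages checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, Polygon
from skimage.draw import disk

from nucquant.image_io import ChannelImage
from nucquant.segmentation import (
    BinaryMask,
    Particle,
    ParticleFilter,
    SelectionRegion,
    ThresholdSpec,
    analyze_particles,
    apply_threshold,
    auto_threshold,
    binary_dilate,
    binary_watershed,
    clear_outside_selection,
    edit_particles,
    read_imagej_roi,
)


def _channel(values):
    return ChannelImage(np.asarray(values, np.uint8), "red")


def _convex_polygon(rng, shape, n_pts=8):
    """Random simple (convex) polygon with integer vertices inside shape."""
    h, w = shape
    pts = np.column_stack(
        [rng.integers(0, w, n_pts), rng.integers(0, h, n_pts)]
    ).astype(float)
    hull = Polygon(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        return _convex_polygon(rng, shape, n_pts)
    verts = list(hull.exterior.coords)[:-1]
    return SelectionRegion.polygon(verts), Polygon(verts)


class TestSelection:
    def test_whole_image_identity(self, rng):
        img = _channel(rng.integers(0, 256, (12, 12)))
        out = clear_outside_selection(img, SelectionRegion.whole_image())
        assert (out.values == img.values).all()

    def test_left_half_rectangle(self):
        img = _channel(np.full((10, 10), 50))
        sel = SelectionRegion.polygon([(0, 0), (4, 0), (4, 9), (0, 9)])
        out = clear_outside_selection(img, sel)
        assert (out.values[:, :5] == 50).all()
        assert (out.values[:, 5:] == 0).all()

    def test_random_polygons_match_shapely_oracle(self, rng):
        """Rasterization agrees with an independent geometric point test."""
        shape = (24, 24)
        for _ in range(20):
            sel, poly = _convex_polygon(rng, shape)
            mask = sel.to_mask(shape)
            for y in range(shape[0]):
                for x in range(shape[1]):
                    # covers() includes boundary, matching the inclusive rule
                    assert mask[y, x] == poly.covers(Point(x, y)), (x, y)

    def test_degenerate_polygon_rejected(self):
        img = _channel(np.zeros((5, 5)))
        sel = SelectionRegion.polygon([(1, 1), (3, 3), (2, 2)])
        with pytest.raises(ValueError, match="degenerate"):
            clear_outside_selection(img, sel)

    def test_out_of_bounds_vertices_clipped_with_warning(self):
        img = _channel(np.full((6, 6), 9))
        sel = SelectionRegion.polygon([(-5, -5), (20, -5), (20, 20), (-5, 20)])
        with pytest.warns(UserWarning, match="clipped"):
            out = clear_outside_selection(img, sel)
        assert (out.values == 9).all()


class TestAutoThreshold:
    def test_two_valued_separation(self):
        img = np.zeros((10, 10), np.uint8)
        img[:5], img[5:] = 10, 200
        for method in ("default", "otsu"):
            spec = auto_threshold(_channel(img), method=method)
            assert 10 < spec.min_level < 200
            assert spec.max_level == 255
            assert spec.mode == "auto" and spec.method == method

    def test_otsu_matches_exhaustive_search(self, rng):
        """Otsu level equals a brute-force scan over all 255 cut points."""
        for _ in range(10):
            vals = np.concatenate(
                [rng.normal(60, 15, 500), rng.normal(180, 20, 300)]
            )
            img = np.clip(np.round(vals[:800]), 0, 255).astype(np.uint8).reshape(20, 40)
            got = auto_threshold(_channel(img), method="otsu").min_level
            hist = np.bincount(img.ravel(), minlength=256).astype(float)
            best, best_var = None, -1.0
            total = hist.sum()
            for t in range(1, 256):
                w0 = hist[:t].sum()
                w1 = total - w0
                if w0 == 0 or w1 == 0:
                    continue
                mu0 = (np.arange(t) * hist[:t]).sum() / w0
                mu1 = (np.arange(t, 256) * hist[t:]).sum() / w1
                v = w0 * w1 * (mu0 - mu1) ** 2
                if v > best_var:
                    best_var, best = v, t
            assert got == best

    def test_outside_selection_pixels_excluded(self, rng):
        img = np.clip(
            np.concatenate([rng.normal(40, 10, 200), rng.normal(190, 10, 200)]),
            0, 255,
        ).astype(np.uint8).reshape(20, 20)
        sel = SelectionRegion.polygon([(0, 0), (9, 0), (9, 19), (0, 19)])
        level_in = auto_threshold(_channel(img), sel).min_level
        polluted = img.copy()
        polluted[:, 10:] = 255  # outside the selection
        assert auto_threshold(_channel(polluted), sel).min_level == level_in

    def test_constant_selection_errors(self):
        with pytest.raises(ValueError, match="manual"):
            auto_threshold(_channel(np.full((5, 5), 7)))


class TestApplyThreshold:
    def test_full_range_all_true(self):
        img = _channel(np.arange(25).reshape(5, 5))
        assert apply_threshold(img, ThresholdSpec(0, 255)).values.all()

    def test_above_constant_all_false(self):
        img = _channel(np.full((5, 5), 100))
        assert not apply_threshold(img, ThresholdSpec(101, 255)).values.any()

    def test_random_matches_per_pixel_comparison(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        lo, hi = sorted(rng.integers(0, 256, 2).tolist())
        mask = apply_threshold(_channel(img), ThresholdSpec(lo, hi)).values
        for y in range(16):
            for x in range(16):
                assert mask[y, x] == (lo <= img[y, x] <= hi)

    @given(lo1=st.integers(0, 254), delta=st.integers(1, 50), data=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_min_level(self, lo1, delta, data):
        """Raising min_level never adds foreground pixels."""
        img = _channel(np.random.default_rng(data).integers(0, 256, (12, 12)))
        lo2 = min(lo1 + delta, 255)
        m1 = apply_threshold(img, ThresholdSpec(lo1, 255)).values
        m2 = apply_threshold(img, ThresholdSpec(lo2, 255)).values
        assert not (m2 & ~m1).any()


class TestBinaryOps:
    def test_dilate_zero_iterations_identity(self, rng):
        m = BinaryMask(rng.random((10, 10)) < 0.3)
        assert (binary_dilate(m, 0).values == m.values).all()

    def test_dilate_single_pixel_becomes_3x3(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = binary_dilate(BinaryMask(m), 1).values
        assert out.sum() == 9
        assert out[2:5, 2:5].all()

    def test_dilate_matches_neighborhood_union_oracle(self, rng):
        m = rng.random((15, 15)) < 0.15
        out = binary_dilate(BinaryMask(m), 2).values
        ref = m.copy()
        for _ in range(2):  # brute-force union of 3x3 neighborhoods
            nxt = np.zeros_like(ref)
            for y in range(15):
                for x in range(15):
                    y0, y1 = max(0, y - 1), min(15, y + 2)
                    x0, x1 = max(0, x - 1), min(15, x + 2)
                    nxt[y, x] = ref[y0:y1, x0:x1].any()
            ref = nxt
        assert (out == ref).all()

    def test_dilate_monotone(self, rng):
        m = rng.random((20, 20)) < 0.2
        out = binary_dilate(BinaryMask(m), 1).values
        assert (out | m == out).all()

    def test_watershed_single_disk_unchanged(self):
        m = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 10)
        m[rr, cc] = True
        out = binary_watershed(BinaryMask(m)).values
        assert (out == m).all()

    def test_watershed_splits_overlapping_disks(self):
        from scipy import ndimage as ndi

        m = np.zeros((64, 64), bool)
        for cx in (24, 40):
            rr, cc = disk((32, cx), 10)
            m[rr, cc] = True
        assert ndi.label(m, structure=np.ones((3, 3)))[1] == 1
        out = binary_watershed(BinaryMask(m)).values
        assert ndi.label(out, structure=np.ones((3, 3)))[1] == 2

    def test_watershed_never_adds_foreground(self, rng):
        m = rng.random((32, 32)) < 0.25
        out = binary_watershed(BinaryMask(m)).values
        assert out.sum() <= m.sum()
        assert not (out & ~m).any()

    def test_watershed_empty_mask(self):
        out = binary_watershed(BinaryMask(np.zeros((8, 8), bool)))
        assert not out.values.any()


def flood_fill_oracle(mask):
    """Independent BFS connected-components with 8-connectivity.

    Returns a list of sorted pixel lists, in raster order of first pixel.
    """
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack, comp = [(y, x)], []
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    comp.append((cy, cx))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                comps.append(sorted(comp))
    return comps


class TestAnalyzeParticles:
    WIDE_OPEN = ParticleFilter()

    def test_empty_mask(self):
        assert analyze_particles(BinaryMask(np.zeros((8, 8), bool)), self.WIDE_OPEN) == []

    def test_filled_square_area(self):
        m = np.zeros((12, 12), bool)
        m[3:8, 3:8] = True
        ps = analyze_particles(BinaryMask(m), ParticleFilter(min_area=1, max_area=1000))
        assert len(ps) == 1
        assert ps[0].area == 25
        assert ps[0].label == 1
        assert ps[0].centroid == (5.0, 5.0)

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(25):
            m = rng.random((64, 64)) < 0.10
            ps = analyze_particles(BinaryMask(m), self.WIDE_OPEN)
            oracle = flood_fill_oracle(m)
            assert len(ps) == len(oracle)
            for p, comp in zip(ps, oracle):
                assert p.area == len(comp)
                assert sorted(map(tuple, p.coords)) == comp

    def test_translation_invariance(self):
        m = np.zeros((50, 50), bool)
        rr, cc = disk((15, 15), 7)
        m[rr, cc] = True
        p1 = analyze_particles(BinaryMask(m), self.WIDE_OPEN)[0]
        m2 = np.roll(np.roll(m, 11, axis=0), 7, axis=1)
        p2 = analyze_particles(BinaryMask(m2), self.WIDE_OPEN)[0]
        assert p1.area == p2.area
        assert p1.perimeter == pytest.approx(p2.perimeter, abs=1e-12)
        assert p1.circularity == pytest.approx(p2.circularity, abs=1e-12)

    def test_area_filter(self):
        m = np.zeros((20, 20), bool)
        m[1:3, 1:3] = True  # area 4
        m[10:16, 10:16] = True  # area 36
        ps = analyze_particles(BinaryMask(m), ParticleFilter(min_area=10, max_area=100))
        assert [p.area for p in ps] == [36]

    def test_particle_areas_sum_to_mask_pixels_when_unfiltered(self, rng):
        m = rng.random((48, 48)) < 0.15
        ps = analyze_particles(BinaryMask(m), self.WIDE_OPEN)
        assert sum(p.area for p in ps) == int(m.sum())

    def test_disk_circularity_grows_toward_one(self):
        circs = []
        for r in (4, 10, 25):
            m = np.zeros((2 * r + 10, 2 * r + 10), bool)
            rr, cc = disk((r + 5, r + 5), r)
            m[rr, cc] = True
            p = analyze_particles(BinaryMask(m), self.WIDE_OPEN)[0]
            assert p.circularity <= 1.0
            circs.append(p.circularity)
        assert circs[-1] > 0.95

    def test_edge_exclusion_flag(self):
        m = np.zeros((10, 10), bool)
        m[0:3, 0:3] = True
        m[5:8, 5:8] = True
        kept = analyze_particles(BinaryMask(m), ParticleFilter(exclude_edge_particles=True))
        assert len(kept) == 1
        assert kept[0].bbox == (5, 5, 8, 8)


class TestEditParticles:
    def _three(self):
        m = np.zeros((10, 30), bool)
        m[2:5, 2:5] = m[2:5, 12:15] = m[2:5, 22:25] = True
        return analyze_particles(BinaryMask(m), ParticleFilter())

    def test_empty_lists_identity(self):
        ps = self._three()
        assert edit_particles(ps) == ps

    def test_exclude_one(self):
        ps = self._three()
        kept = edit_particles(ps, exclude_ids=[2])
        assert [p.label for p in kept] == [1, 3]

    def test_include_only(self):
        ps = self._three()
        kept = edit_particles(ps, include_ids=[3])
        assert [p.label for p in kept] == [3]

    def test_conflict_refused(self):
        with pytest.raises(ValueError, match="both include and exclude"):
            edit_particles(self._three(), include_ids=[1], exclude_ids=[1])

    def test_unknown_id_named(self):
        with pytest.raises(ValueError, match="99"):
            edit_particles(self._three(), exclude_ids=[99])


class TestImageJRoi:
    def test_polygon_roi_round_trip(self, tmp_path):
        """Parse a minimal polygon .roi binary constructed in-test."""
        import struct

        verts = [(5, 3), (20, 4), (18, 15), (6, 14)]
        left = min(v[0] for v in verts)
        top = min(v[1] for v in verts)
        xs = [v[0] - left for v in verts]
        ys = [v[1] - top for v in verts]
        header = bytearray(64)
        header[0:4] = b"Iout"
        header[4:6] = struct.pack(">h", 227)  # version
        header[6] = 0  # polygon type
        header[8:16] = struct.pack(
            ">hhhh", top, left, max(v[1] for v in verts), max(v[0] for v in verts)
        )
        header[16:18] = struct.pack(">h", len(verts))
        body = struct.pack(f">{len(xs)}h", *xs) + struct.pack(f">{len(ys)}h", *ys)
        path = tmp_path / "sel.roi"
        path.write_bytes(bytes(header) + body)
        sel = read_imagej_roi(str(path))
        assert sel.vertices == tuple((float(x), float(y)) for x, y in verts)

    def test_non_roi_file_rejected(self, tmp_path):
        p = tmp_path / "x.roi"
        p.write_bytes(b"nope")
        with pytest.raises(ValueError, match="not an ImageJ"):
            read_imagej_roi(str(p))
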