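"""Class taxonomy, merge map, polygon rasterization and ROI/manifest I/O."""

import numpy as np
import pytest

from rpcseg.taxonomy import (
    BACKGROUND, CANCER, FAT, IGNORE, NORMAL_DUCTS, OTHER_EPITHELIUM,
    ORIGINAL_CLASS_NAMES, TARGET_CODES,
    AnnotatedROI, CohortManifest, ManifestEntry, MaskValidationError,
    PolygonAnnotation, TaxonomyError, default_taxonomy, load_taxonomy,
    rasterize_annotations, read_asap_xml, read_roi, write_asap_xml, write_roi,
)


@pytest.fixture(scope="module")
def tax():
    return default_taxonomy()


class TestMergeMap:
    @pytest.mark.parametrize("label,target", [
        ("normal_ducts", NORMAL_DUCTS),
        ("cancer", CANCER),
        ("in_situ_neoplasia", CANCER),
        ("islets_of_langerhans", OTHER_EPITHELIUM),
        ("acinar_tissue", OTHER_EPITHELIUM),
        ("atrophic_metaplastic", OTHER_EPITHELIUM),
        ("adipose_tissue", FAT),
        ("vessels", BACKGROUND),
        ("nerves", BACKGROUND),
        ("lymphoid_inflammatory", BACKGROUND),
        ("uncertain", IGNORE),
    ])
    def test_merge_targets(self, tax, label, target):
        assert tax.target_of_label(label) == target

    def test_merge_is_surjective_onto_targets(self, tax):
        assert set(tax.merge_map.values()) >= set(TARGET_CODES)

    def test_merge_idempotent_on_target_codes(self, tax):
        """Applying the merge twice equals applying it once (target codes are fixed points)."""
        rng = np.random.default_rng(0)
        codes = np.array(list(tax.original_labels.values()) + list(TARGET_CODES) + [IGNORE])
        mask = rng.choice(codes, size=(40, 40)).astype(np.uint8)
        once = tax.merge_codes(mask)
        assert np.array_equal(tax.merge_codes(once), once)

    def test_unknown_code_rejected(self, tax):
        with pytest.raises(TaxonomyError, match="outside the taxonomy"):
            tax.merge_codes(np.array([[7]], dtype=np.uint8))

    def test_load_taxonomy_requires_all_twelve(self):
        with pytest.raises(TaxonomyError, match="missing"):
            load_taxonomy({"original_classes": list(ORIGINAL_CLASS_NAMES[:-1])})

    def test_load_taxonomy_rejects_duplicates(self):
        names = list(ORIGINAL_CLASS_NAMES) + ["cancer"]
        with pytest.raises(TaxonomyError, match="duplicated"):
            load_taxonomy({"original_classes": names})

    def test_load_taxonomy_roundtrip(self, tax):
        loaded = load_taxonomy({"original_classes": list(ORIGINAL_CLASS_NAMES)})
        assert loaded.merge_map == tax.merge_map


def _point_in_polygon(px: float, py: float, verts: np.ndarray) -> bool:
    """Independent even-odd ray-casting containment test."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xcross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xcross:
                inside = not inside
    return inside


class TestRasterize:
    def test_empty_set_gives_background(self):
        mask = rasterize_annotations([], 64, 64)
        assert mask.shape == (64, 64) and not mask.any()

    def test_axis_aligned_square_has_exact_area(self):
        """A 10x10 cancer rectangle at the origin covers exactly 100 pixel centers."""
        poly = PolygonAnnotation("cancer", [(0, 0), (10, 0), (10, 10), (0, 10)])
        mask = rasterize_annotations([poly], 64, 64)
        assert int((mask == CANCER).sum()) == 100
        assert mask[:10, :10].min() == CANCER

    def test_cancer_inside_vessel_is_preserved(self):
        cancer = PolygonAnnotation("cancer", [(10, 10), (20, 10), (20, 20), (10, 20)])
        vessel = PolygonAnnotation("vessels", [(5, 5), (30, 5), (30, 30), (5, 30)])
        mask = rasterize_annotations([cancer, vessel], 40, 40)
        assert mask[15, 15] == CANCER
        assert mask[7, 7] == BACKGROUND

    def test_later_polygon_overwrites_earlier(self):
        a = PolygonAnnotation("normal_ducts", [(0, 0), (20, 0), (20, 20), (0, 20)])
        b = PolygonAnnotation("cancer", [(5, 5), (15, 5), (15, 15), (5, 15)])
        mask = rasterize_annotations([a, b], 32, 32)
        assert mask[10, 10] == CANCER and mask[2, 2] == NORMAL_DUCTS

    def test_lumen_takes_enclosing_structure_class(self):
        duct = PolygonAnnotation("normal_ducts", [(0, 0), (30, 0), (30, 30), (0, 30)])
        lumen = PolygonAnnotation("lumina", [(10, 10), (20, 10), (20, 20), (10, 20)])
        mask = rasterize_annotations([duct, lumen], 40, 40)
        assert mask[15, 15] == NORMAL_DUCTS

    def test_free_standing_lumen_is_background(self):
        lumen = PolygonAnnotation("lumina", [(10, 10), (20, 10), (20, 20), (10, 20)])
        mask = rasterize_annotations([lumen], 40, 40)
        assert not mask.any()

    def test_out_of_bounds_polygon_clipped_with_warning(self):
        poly = PolygonAnnotation("cancer", [(50, 50), (80, 50), (80, 80), (50, 80)])
        with pytest.warns(UserWarning, match="clipped"):
            mask = rasterize_annotations([poly], 64, 64)
        assert (mask == CANCER).sum() == 14 * 14

    def test_unknown_label_raises(self):
        poly = PolygonAnnotation("mystery", [(0, 0), (5, 0), (5, 5)])
        with pytest.raises(TaxonomyError, match="unknown annotation class"):
            rasterize_annotations([poly], 16, 16)

    def test_agrees_with_brute_force_point_in_polygon(self):
        """Rasterization matches an independent ray-casting oracle on random polygons."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_vert = rng.integers(3, 9)
            # star-shaped polygon with non-integer vertices (no center-on-edge ties)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            radii = rng.uniform(4, 28, n_vert)
            cx, cy = rng.uniform(10, 54, 2)
            verts = np.c_[cx + radii * np.cos(angles), cy + radii * np.sin(angles)]
            verts += rng.uniform(0.01, 0.09, verts.shape)  # keep off pixel centers
            verts = np.clip(verts, 0.2, 63.8)
            mask = rasterize_annotations(
                [PolygonAnnotation("cancer", verts)], 64, 64)
            expected = np.zeros((64, 64), dtype=bool)
            for r in range(64):
                for c in range(64):
                    expected[r, c] = _point_in_polygon(c + 0.5, r + 0.5, verts)
            assert np.array_equal(mask == CANCER, expected)


class TestAsapXml:
    def test_xml_roundtrip(self, tmp_path):
        polys = [
            PolygonAnnotation("cancer", [(1.5, 2.5), (20.0, 3.0), (12.25, 18.75)]),
            PolygonAnnotation("vessels", [(30, 30), (40, 31), (41, 44), (29, 43)]),
        ]
        path = tmp_path / "ann.xml"
        write_asap_xml(polys, path)
        loaded = read_asap_xml(path)
        assert [p.label for p in loaded] == ["cancer", "vessels"]
        for a, b in zip(polys, loaded):
            assert np.allclose(a.coords, b.coords)


class TestRoiIO:
    def test_roundtrip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(3)
        image = rng.integers(0, 256, size=(128, 128, 3), dtype=np.uint8)
        mask = rng.choice(np.array(list(TARGET_CODES) + [IGNORE], dtype=np.uint8),
                          size=(128, 128))
        roi = AnnotatedROI(image=image, mask=mask, case_id="rt", scanner_type="leica")
        write_roi(roi, tmp_path / "img.png", tmp_path / "mask.png")
        back = read_roi(tmp_path / "img.png", tmp_path / "mask.png",
                        scanner_type="leica")
        assert np.array_equal(back.image, image)
        assert np.array_equal(back.mask, mask)

    def test_invalid_mask_code_rejected(self):
        image = np.zeros((8, 8, 3), dtype=np.uint8)
        mask = np.full((8, 8), 250, dtype=np.uint8)
        with pytest.raises(MaskValidationError, match="non-target codes"):
            AnnotatedROI(image=image, mask=mask, case_id="bad")

    def test_shape_mismatch_names_both_shapes(self):
        with pytest.raises(MaskValidationError, match=r"\(8, 8\).*\(8, 9\)"):
            AnnotatedROI(image=np.zeros((8, 8, 3), dtype=np.uint8),
                         mask=np.zeros((8, 9), dtype=np.uint8), case_id="bad")

    def test_annotated_area_from_foreground(self):
        mask = np.zeros((100, 100), dtype=np.uint8)
        mask[:20, :20] = CANCER  # 400 px at 4 px^2/um^2
        roi = AnnotatedROI(image=np.zeros((100, 100, 3), dtype=np.uint8),
                           mask=mask, case_id="a")
        assert roi.annotated_area_mm2 == pytest.approx(400 / 4e6)


class TestManifest:
    def test_csv_roundtrip_and_scanner_parsing(self, tmp_path):
        entries = [ManifestEntry("c1", "ctr", "leica", "i1.png", "m1.png"),
                   ManifestEntry("c2", "ctr", "philips", "i2.png", "m2.png")]
        m = CohortManifest(entries)
        m.to_csv(tmp_path / "m.csv")
        back = CohortManifest.from_csv(tmp_path / "m.csv")
        assert back.entries == entries
        assert back.by_scanner("leica")[0].scanner_type == "leica"

    def test_duplicate_case_ids_rejected(self):
        e = ManifestEntry("c1", "ctr", "leica", "i.png", "m.png")
        with pytest.raises(ValueError, match="duplicated case_ids"):
            CohortManifest([e, e])

    def test_unknown_scanner_rejected(self):
        with pytest.raises(ValueError, match="unknown scanner"):
            CohortManifest([ManifestEntry("c1", "ctr", "zeiss", "i.png", "m.png")])
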