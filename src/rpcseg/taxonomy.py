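"""Annotation class system, class merging, and file I/O for ROIs, masks and manifests.

Pathologists annotate rectangular regions of interest (ROIs) on H&E slides of
treated pancreatic cancer resection specimens and assign each structure one of
twelve original classes (ducts, cancer, in situ neoplasia, islets, acini,
atrophic/metaplastic parenchyma, fat, vessels, nerves, uncertain, lumina,
lymphoid infiltrates).  For segmentation these are merged into four foreground
classes plus background:

====  =================  =========================================================
code  target class       merged original classes
====  =================  =========================================================
0     background         stroma/unannotated, vessels, nerves, lymphoid infiltrates
1     normal_ducts       non-neoplastic ducts
2     cancer             invasive cancer and in situ neoplasia
3     other_epithelium   islets of Langerhans, acinar tissue, atrophic/metaplastic
4     fat                adipose tissue
255   (ignore)           uncertain structures; excluded from loss and metrics
====  =================  =========================================================

Images are 24-bit RGB PNGs at 2 px/um; masks are single-channel 8-bit PNGs
holding the target codes above.  Polygon annotations use an ASAP-style XML
dialect; a cohort manifest CSV assigns every case to a center and scanner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import yaml
from lxml import etree
from PIL import Image
from shapely.geometry import Polygon as ShapelyPolygon

BACKGROUND, NORMAL_DUCTS, CANCER, OTHER_EPITHELIUM, FAT = 0, 1, 2, 3, 4
IGNORE = 255

TARGET_LABELS: dict[int, str] = {
    BACKGROUND: "background",
    NORMAL_DUCTS: "normal_ducts",
    CANCER: "cancer",
    OTHER_EPITHELIUM: "other_epithelium",
    FAT: "fat",
}
TARGET_CODES: tuple[int, ...] = tuple(TARGET_LABELS)
FOREGROUND_CODES: tuple[int, ...] = (NORMAL_DUCTS, CANCER, OTHER_EPITHELIUM, FAT)

SCANNER_TYPES: tuple[str, ...] = ("philips", "hamamatsu", "3dhistech", "leica")

#: pixels per micrometre of the working resolution ("20x")
PIXELS_PER_UM = 2.0
#: pixels per mm^2 at the working resolution
PIXELS_PER_MM2 = (PIXELS_PER_UM * 1000.0) ** 2

# Original annotation codes live in 10..21 so they can never collide with the
# target-code space {0..4, 255}; the merge LUT is then idempotent by design.
ORIGINAL_CLASS_NAMES: tuple[str, ...] = (
    "normal_ducts",
    "cancer",
    "in_situ_neoplasia",
    "islets_of_langerhans",
    "acinar_tissue",
    "atrophic_metaplastic",
    "adipose_tissue",
    "vessels",
    "nerves",
    "uncertain",
    "lumina",
    "lymphoid_inflammatory",
)

_DEFAULT_ORIGINAL_CODES = {name: 10 + i for i, name in enumerate(ORIGINAL_CLASS_NAMES)}

#: merge target by original class *name*; lumina get a contextual rule at
#: rasterization time (class of the smallest enclosing structure) and fall
#: back to background when free-standing.
MERGE_BY_NAME: dict[str, int] = {
    "normal_ducts": NORMAL_DUCTS,
    "cancer": CANCER,
    "in_situ_neoplasia": CANCER,
    "islets_of_langerhans": OTHER_EPITHELIUM,
    "acinar_tissue": OTHER_EPITHELIUM,
    "atrophic_metaplastic": OTHER_EPITHELIUM,
    "adipose_tissue": FAT,
    "vessels": BACKGROUND,
    "nerves": BACKGROUND,
    "uncertain": IGNORE,
    "lumina": BACKGROUND,
    "lymphoid_inflammatory": BACKGROUND,
}

#: background-class structures that must never erase previously painted cancer
#: (cancer annotated within vessels/nerves remains cancer)
_CANCER_PRESERVING = {"vessels", "nerves", "lymphoid_inflammatory"}


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy configuration or unknown class labels."""


@dataclass(frozen=True)
class ClassTaxonomy:
    """The 12-class original annotation system and its merge onto 5 target codes."""

    original_labels: dict[str, int]
    merge_map: dict[int, int]
    target_labels: dict[int, str] = field(default_factory=lambda: dict(TARGET_LABELS))
    ignore_code: int = IGNORE

    def __post_init__(self) -> None:
        if set(self.original_labels) != set(ORIGINAL_CLASS_NAMES):
            missing = set(ORIGINAL_CLASS_NAMES) - set(self.original_labels)
            extra = set(self.original_labels) - set(ORIGINAL_CLASS_NAMES)
            raise TaxonomyError(
                f"taxonomy must list the 12 original classes; missing={sorted(missing)}, "
                f"unknown={sorted(extra)}"
            )
        codes = list(self.original_labels.values())
        if len(set(codes)) != len(codes):
            raise TaxonomyError("duplicated original class codes")
        if any(c in TARGET_LABELS or c == self.ignore_code for c in codes):
            raise TaxonomyError(
                "original class codes must not collide with target codes {0..4, ignore}"
            )
        valid_targets = set(TARGET_LABELS) | {self.ignore_code}
        for code, tgt in self.merge_map.items():
            if tgt not in valid_targets:
                raise TaxonomyError(f"merge target {tgt} for code {code} not a target code")
        if set(self.merge_map) != set(codes) | {self.ignore_code}:
            raise TaxonomyError("merge_map must be total over the original codes plus ignore")
        if set(self.merge_map.values()) < set(TARGET_LABELS):
            raise TaxonomyError("merge must be surjective onto the 5 target codes")

    @property
    def code_of(self) -> dict[str, int]:
        return dict(self.original_labels)

    def target_of_label(self, label: str) -> int:
        """Merge target code for an original class *name*."""
        try:
            return self.merge_map[self.original_labels[label]]
        except KeyError:
            raise TaxonomyError(f"unknown annotation class {label!r}") from None

    def lut(self) -> np.ndarray:
        """256-entry merge lookup table; target codes and ignore are fixed points."""
        table = np.full(256, -1, dtype=np.int16)
        for code in TARGET_CODES:
            table[code] = code
        table[self.ignore_code] = self.ignore_code
        for code, tgt in self.merge_map.items():
            table[code] = tgt
        return table

    def merge_codes(self, mask: np.ndarray) -> np.ndarray:
        """Apply the class merge to a mask of original (or already-merged) codes."""
        table = self.lut()
        out = table[np.asarray(mask, dtype=np.uint8)]
        if (out < 0).any():
            bad = sorted(np.unique(np.asarray(mask)[out < 0]).tolist())
            raise TaxonomyError(f"mask contains codes outside the taxonomy: {bad}")
        return out.astype(np.uint8)


def default_taxonomy() -> ClassTaxonomy:
    """The built-in 12-class taxonomy with its standard merge map."""
    merge = {_DEFAULT_ORIGINAL_CODES[n]: MERGE_BY_NAME[n] for n in ORIGINAL_CLASS_NAMES}
    merge[IGNORE] = IGNORE
    return ClassTaxonomy(original_labels=dict(_DEFAULT_ORIGINAL_CODES), merge_map=merge)


def load_taxonomy(config: Mapping | str | Path) -> ClassTaxonomy:
    """Build a :class:`ClassTaxonomy` from a config mapping or YAML file.

    The config must carry ``original_classes``, either a name->code mapping or a
    list of the 12 canonical names (codes then default to 10..21).  Merge
    targets follow the standard map; ``merge_overrides`` (name -> target name or
    code) may adjust them.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or "original_classes" not in config:
        raise TaxonomyError("taxonomy config must define 'original_classes'")
    spec = config["original_classes"]
    if isinstance(spec, Mapping):
        originals = {str(k): int(v) for k, v in spec.items()}
    else:
        names = [str(n) for n in spec]
        if len(set(names)) != len(names):
            raise TaxonomyError("duplicated original class name")
        originals = {n: _DEFAULT_ORIGINAL_CODES.get(n, -1) for n in names}
        if any(c < 0 for c in originals.values()):
            unknown = [n for n, c in originals.items() if c < 0]
            raise TaxonomyError(f"unknown original class names: {unknown}")
    target_by_name = {v: k for k, v in TARGET_LABELS.items()}
    merge_by_name = dict(MERGE_BY_NAME)
    for name, tgt in dict(config.get("merge_overrides", {})).items():
        if name not in merge_by_name:
            raise TaxonomyError(f"merge override for unknown class {name!r}")
        merge_by_name[name] = target_by_name.get(tgt, tgt) if isinstance(tgt, str) else int(tgt)
    try:
        merge = {originals[n]: merge_by_name[n] for n in originals}
    except KeyError as exc:
        raise TaxonomyError(f"no merge target for class {exc}") from None
    merge[IGNORE] = IGNORE
    return ClassTaxonomy(original_labels=originals, merge_map=merge)


# ---------------------------------------------------------------------------
# polygon annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolygonAnnotation:
    """A labeled closed polygon in pixel coordinates (x, y vertex columns)."""

    label: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
            raise ValueError("polygon needs an (n>=3, 2) vertex array")
        object.__setattr__(self, "coords", c)

    def shapely(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.coords)


def rasterize_annotations(
    polygons: Sequence[PolygonAnnotation],
    height: int,
    width: int,
    taxonomy: ClassTaxonomy | None = None,
) -> np.ndarray:
    """Rasterize labeled polygons to a merged target-code mask.

    Pixel convention: 0-based indices, a pixel (row r, col c) is painted iff
    its center (c + 0.5, r + 0.5) lies in the polygon interior.  Later
    polygons in file order overwrite earlier ones, with two structural rules:
    background-class structures (vessels, nerves, lymphoid infiltrates) never
    erase cancer pixels, and a lumen takes the target class of the smallest
    enclosing annotated structure (background when free-standing).

    Polygons extending beyond the image are clipped with a warning; unknown
    labels raise :class:`TaxonomyError`.
    """
    taxonomy = taxonomy or default_taxonomy()
    mask = np.zeros((height, width), dtype=np.uint8)
    shapes = []
    for ann in polygons:
        taxonomy.target_of_label(ann.label)  # validate label early
        shapes.append(ann.shapely())

    for ann, poly in zip(polygons, shapes):
        if ann.label == "lumina":
            target = _lumen_target(ann, poly, polygons, shapes, taxonomy)
        else:
            target = taxonomy.target_of_label(ann.label)
        x0, y0, x1, y1 = poly.bounds
        if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
            warnings.warn(
                f"polygon {ann.label!r} extends beyond the {height}x{width} image; clipped",
                stacklevel=2,
            )
        c0 = max(int(np.floor(x0)), 0)
        c1 = min(int(np.ceil(x1)), width)
        r0 = max(int(np.floor(y0)), 0)
        r1 = min(int(np.ceil(y1)), height)
        if c1 <= c0 or r1 <= r0:
            continue
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        inside = shapely.contains_xy(poly, cols + 0.5, rows + 0.5)
        if not inside.any():
            continue
        window = mask[r0:r1, c0:c1]
        paint = inside
        if ann.label in _CANCER_PRESERVING:
            paint = inside & (window != CANCER)
        window[paint] = target
    return mask


def _lumen_target(
    lumen: PolygonAnnotation,
    lumen_poly: ShapelyPolygon,
    polygons: Sequence[PolygonAnnotation],
    shapes: Sequence[ShapelyPolygon],
    taxonomy: ClassTaxonomy,
) -> int:
    """Target class of the smallest annotated structure enclosing the lumen."""
    probe = lumen_poly.representative_point()
    best_area, best_target = np.inf, BACKGROUND
    for other, poly in zip(polygons, shapes):
        if other is lumen or other.label == "lumina":
            continue
        if poly.covers(probe) and poly.area < best_area:
            best_area = poly.area
            best_target = taxonomy.target_of_label(other.label)
    return best_target


def read_asap_xml(path: str | Path) -> list[PolygonAnnotation]:
    """Read polygon annotations from an ASAP-dialect XML file.

    Each ``Annotation`` element contributes one polygon; the class name is the
    ``PartOfGroup`` attribute and vertices come from ``Coordinate`` elements
    ordered by their ``Order`` attribute (pixel units).
    """
    tree = etree.parse(str(path))
    out: list[PolygonAnnotation] = []
    for ann in tree.iter("Annotation"):
        group = ann.get("PartOfGroup") or ann.get("Name") or ""
        coords = sorted(
            ((int(c.get("Order", i)), float(c.get("X")), float(c.get("Y")))
             for i, c in enumerate(ann.iter("Coordinate"))),
        )
        pts = np.array([(x, y) for _, x, y in coords], dtype=float)
        out.append(PolygonAnnotation(label=group, coords=pts))
    return out


def write_asap_xml(polygons: Sequence[PolygonAnnotation], path: str | Path) -> None:
    """Write polygons in the same ASAP XML dialect :func:`read_asap_xml` reads."""
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    for i, ann in enumerate(polygons):
        el = etree.SubElement(
            anns, "Annotation",
            Name=f"Annotation {i}", Type="Polygon", PartOfGroup=ann.label,
        )
        coords = etree.SubElement(el, "Coordinates")
        for j, (x, y) in enumerate(ann.coords):
            etree.SubElement(coords, "Coordinate", Order=str(j),
                             X=repr(float(x)), Y=repr(float(y)))
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True,
                                  encoding="utf-8")


# ---------------------------------------------------------------------------
# ROI and manifest I/O
# ---------------------------------------------------------------------------

class MaskValidationError(ValueError):
    """Raised when an image/mask pair is inconsistent or holds invalid codes."""


@dataclass
class AnnotatedROI:
    """An RGB ROI at 2 px/um with its target-code label mask and provenance."""

    image: np.ndarray
    mask: np.ndarray
    case_id: str
    center_id: str = ""
    scanner_type: str = "philips"
    annotated_area_mm2: float | None = None
    class_fractions: dict[int, float] | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise MaskValidationError(f"image must be HxWx3 RGB, got {self.image.shape}")
        if self.image.shape[:2] != self.mask.shape:
            raise MaskValidationError(
                f"image shape {self.image.shape[:2]} != mask shape {self.mask.shape}"
            )
        valid = set(TARGET_CODES) | {IGNORE}
        present = set(np.unique(self.mask).tolist())
        if not present <= valid:
            raise MaskValidationError(
                f"mask holds non-target codes {sorted(present - valid)}"
            )
        if self.scanner_type not in SCANNER_TYPES:
            raise MaskValidationError(
                f"unknown scanner_type {self.scanner_type!r}; expected one of {SCANNER_TYPES}"
            )
        if self.annotated_area_mm2 is None:
            fg = np.count_nonzero((self.mask != BACKGROUND) & (self.mask != IGNORE))
            self.annotated_area_mm2 = fg / PIXELS_PER_MM2
        if self.annotated_area_mm2 < 0:
            raise MaskValidationError("annotated_area_mm2 must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def write_roi(roi: AnnotatedROI, image_path: str | Path, mask_path: str | Path) -> None:
    """Write the ROI as a 24-bit RGB PNG plus an 8-bit single-channel mask PNG."""
    Image.fromarray(roi.image.astype(np.uint8), mode="RGB").save(str(image_path))
    Image.fromarray(roi.mask.astype(np.uint8), mode="L").save(str(mask_path))


def read_roi(
    image_path: str | Path,
    mask_path: str | Path,
    case_id: str = "",
    center_id: str = "",
    scanner_type: str = "philips",
) -> AnnotatedROI:
    """Read an image/mask PNG pair back into an :class:`AnnotatedROI`.

    The write -> read round trip is bit-identical for both planes.
    """
    image = np.asarray(Image.open(str(image_path)).convert("RGB"))
    mask = np.asarray(Image.open(str(mask_path)))
    if mask.ndim != 2:
        raise MaskValidationError(f"mask PNG must be single-channel, got shape {mask.shape}")
    return AnnotatedROI(image=image, mask=mask, case_id=case_id or Path(image_path).stem,
                        center_id=center_id, scanner_type=scanner_type)


@dataclass(frozen=True)
class ManifestEntry:
    case_id: str
    center_id: str
    scanner_type: str
    image_path: str
    mask_path: str


@dataclass
class CohortManifest:
    """One representative annotated ROI per case, with center and scanner."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.case_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicated case_ids in manifest: {dupes}")
        for e in self.entries:
            if e.scanner_type not in SCANNER_TYPES:
                raise ValueError(
                    f"case {e.case_id}: unknown scanner {e.scanner_type!r}; "
                    f"expected one of {SCANNER_TYPES}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def scanners(self) -> list[str]:
        return sorted({e.scanner_type for e in self.entries})

    def by_scanner(self, scanner_type: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.scanner_type == scanner_type]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([e.__dict__ for e in self.entries]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path, dtype=str)
        required = {"case_id", "center_id", "scanner_type", "image_path", "mask_path"}
        if not required <= set(df.columns):
            raise ValueError(f"manifest missing columns {sorted(required - set(df.columns))}")
        return cls([ManifestEntry(r.case_id, r.center_id, r.scanner_type,
                                  r.image_path, r.mask_path)
                    for r in df.itertuples(index=False)])

    def load_roi(self, entry: ManifestEntry, root: str | Path | None = None) -> AnnotatedROI:
        root = Path(root) if root is not None else Path(".")
        return read_roi(root / entry.image_path, root / entry.mask_path,
                        case_id=entry.case_id, center_id=entry.center_id,
                        scanner_type=entry.scanner_type)
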