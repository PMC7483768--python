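"""Polygon annotations: ASAP-style XML I/O, rasterization and dataset manifests.

Annotation files follow the ASAP dialect::

    <ASAP_Annotations>
      <Annotations>
        <Annotation Name="..." Type="Polygon" PartOfGroup="G4 cribriform">
          <Coordinates>
            <Coordinate Order="0" X="col" Y="row"/>
            ...

The group name carries the tissue label (matched case-insensitively against a
:class:`~cribnet.labels.LabelSet`).  Coordinates are stored at the working
resolution (0.92 um/pixel by default) with X = column and Y = row.

Conventions used throughout the package: 0-based (row, col) indexing, pixel
centers at integer coordinates, and point-in-polygon tests that include pixels
whose center lies exactly on the polygon boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from lxml import etree
from PIL import Image

from .labels import LabelSet

logger = logging.getLogger(__name__)

#: working resolution in micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.92


def shoelace_area(polygon: np.ndarray) -> float:
    """Unsigned polygon area in px^2 by the shoelace formula."""
    p = np.asarray(polygon, dtype=np.float64)
    r, c = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


@dataclass
class AnnotationRegion:
    """A labelled polygonal region in working-resolution pixel coordinates.

    ``polygon`` is an (V, 2) array of (row, col) vertices, V >= 3.
    ``area_mm2`` is derived from the shoelace area and the pixel size.
    """

    polygon: np.ndarray
    label: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    name: str = ""
    area_mm2: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=np.float64)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2:
            raise ValueError("polygon must be an (V, 2) array of (row, col) vertices")
        if len(self.polygon) < 3:
            raise ValueError(
                f"malformed polygon in annotation {self.name!r}: "
                f"{len(self.polygon)} vertices (need >= 3)"
            )
        area = shoelace_area(self.polygon) * (self.pixel_size_um * 1e-3) ** 2
        if self.area_mm2 is None:
            self.area_mm2 = float(area)
        elif area > 0 and abs(self.area_mm2 - area) > 0.01 * area:
            raise ValueError(
                f"stored area {self.area_mm2} inconsistent with polygon area {area}"
            )

    @property
    def area_px(self) -> float:
        return shoelace_area(self.polygon)


def parse_annotations(path: str | Path, labelset: LabelSet,
                      pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> list[AnnotationRegion]:
    """Read an ASAP-style XML file into a list of :class:`AnnotationRegion`.

    Raises ``KeyError`` for a group name outside the label set and
    ``ValueError`` for polygons with fewer than 3 vertices.
    """
    tree = etree.parse(str(path))
    regions: list[AnnotationRegion] = []
    for ann in tree.findall(".//Annotations/Annotation"):
        name = ann.get("Name", "")
        group = ann.get("PartOfGroup", "")
        label = labelset.canonical(group)  # KeyError for unknown groups
        coords = ann.findall(".//Coordinates/Coordinate")
        coords.sort(key=lambda el: int(el.get("Order", "0")))
        verts = np.array(
            [[float(el.get("Y")), float(el.get("X"))] for el in coords],
            dtype=np.float64,
        ).reshape(-1, 2)
        if len(verts) < 3:
            raise ValueError(
                f"malformed polygon in annotation {name!r}: "
                f"{len(verts)} vertices (need >= 3)"
            )
        regions.append(AnnotationRegion(verts, label, pixel_size_um, name=name))
    return regions


def write_annotations(regions: list[AnnotationRegion], path: str | Path,
                      labelset: LabelSet | None = None) -> None:
    """Write regions as ASAP-style XML (vertices kept to 1e-4 px)."""
    root = etree.Element("ASAP_Annotations")
    anns = etree.SubElement(root, "Annotations")
    groups_seen: list[str] = []
    for i, region in enumerate(regions):
        ann = etree.SubElement(
            anns, "Annotation",
            Name=region.name or f"Annotation {i}",
            Type="Polygon", PartOfGroup=region.label, Color="#F4FA58",
        )
        coords = etree.SubElement(ann, "Coordinates")
        for order, (row, col) in enumerate(region.polygon):
            etree.SubElement(
                coords, "Coordinate",
                Order=str(order), X=f"{col:.4f}", Y=f"{row:.4f}",
            )
        if region.label not in groups_seen:
            groups_seen.append(region.label)
    groups_el = etree.SubElement(root, "AnnotationGroups")
    names = list(labelset) if labelset is not None else groups_seen
    for g in names:
        etree.SubElement(groups_el, "Group", Name=g, PartOfGroup="None", Color="#64FE2E")
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def polygon_mask(polygon: np.ndarray, height: int, width: int) -> np.ndarray:
    """Boolean mask of pixels whose center lies inside or on the polygon.

    Pixel centers sit at integer (row, col); the test is restricted to the
    polygon's bounding box for speed and clipped to the image bounds.
    """
    poly = shapely.Polygon(np.asarray(polygon, dtype=np.float64))
    if not poly.is_valid:
        poly = poly.buffer(0)
    r0 = max(0, int(np.floor(poly.bounds[0])))
    c0 = max(0, int(np.floor(poly.bounds[1])))
    r1 = min(height - 1, int(np.ceil(poly.bounds[2])))
    c1 = min(width - 1, int(np.ceil(poly.bounds[3])))
    out = np.zeros((height, width), dtype=bool)
    if r1 < r0 or c1 < c0:
        return out
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = shapely.points(np.stack([rr.ravel(), cc.ravel()], axis=1))
    shapely.prepare(poly)
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    out[r0:r1 + 1, c0:c1 + 1] = inside
    return out


def rasterize_annotations(regions: list[AnnotationRegion], height: int, width: int,
                          labelset: LabelSet) -> np.ndarray:
    """Rasterize polygons into an (L, H, W) uint8 one-hot mask stack.

    Every pixel carries exactly one class; pixels inside no polygon get the
    non-labelled class.  Overlapping polygons of different labels are resolved
    last-drawn-wins with a logged warning.
    """
    n_l = len(labelset)
    stack = np.zeros((n_l, height, width), dtype=np.uint8)
    stack[labelset.non_labelled_index] = 1
    claimed = np.full((height, width), labelset.non_labelled_index, dtype=np.int8)
    for region in regions:
        idx = labelset.index(region.label)
        mask = polygon_mask(region.polygon, height, width)
        prev = claimed[mask]
        overlap = prev[(prev != labelset.non_labelled_index) & (prev != idx)]
        if overlap.size:
            logger.warning(
                "annotation %r (%s) overwrites %d pixel(s) of other labels "
                "(last-drawn wins)", region.name, region.label, overlap.size,
            )
        claimed[mask] = idx
    for l in range(n_l):
        stack[l] = claimed == l
    return stack


@dataclass
class BiopsyRecord:
    """One biopsy image with its annotation regions and per-label tallies."""

    image_path: str
    regions: list[AnnotationRegion] | None = None
    annotation_path: str | None = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    region_counts: dict[str, int] = field(default=None)  # type: ignore[assignment]
    biopsy_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.biopsy_id:
            self.biopsy_id = Path(self.image_path).stem
        if self.region_counts is None:
            self.region_counts = self._tally()
        elif self.regions is not None and self.region_counts != self._tally():
            raise ValueError("region_counts inconsistent with regions")

    def _tally(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for region in self.regions or []:
            counts[region.label] = counts.get(region.label, 0) + 1
        return counts

    def count(self, label: str) -> int:
        return self.region_counts.get(label, 0)

    def load_regions(self, labelset: LabelSet) -> list[AnnotationRegion]:
        """Regions, parsing the annotation file on demand."""
        if self.regions is None:
            if self.annotation_path is None:
                raise ValueError(f"record {self.biopsy_id} has no annotation source")
            self.regions = parse_annotations(self.annotation_path, labelset,
                                             self.pixel_size_um)
        return self.regions


def save_manifest(records: list[BiopsyRecord], path: str | Path) -> None:
    payload = [
        {
            "biopsy_id": r.biopsy_id,
            "image_path": r.image_path,
            "annotation_path": r.annotation_path,
            "pixel_size_um": r.pixel_size_um,
            "region_counts": r.region_counts,
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_manifest(path: str | Path) -> list[BiopsyRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        BiopsyRecord(
            image_path=item["image_path"],
            annotation_path=item.get("annotation_path"),
            pixel_size_um=item["pixel_size_um"],
            region_counts=dict(item["region_counts"]),
            biopsy_id=item["biopsy_id"],
        )
        for item in payload
    ]


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Save a float [0,1] RGB array as an 8-bit PNG/TIFF."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(str(path))


def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit RGB image as float32 in [0,1]."""
    with Image.open(str(path)) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32)
    return arr / 255.0


def save_mask_png(masks: np.ndarray, path: str | Path) -> None:
    """Export an (L, H, W) one-hot stack as a single-channel indexed PNG."""
    index = np.argmax(masks, axis=0).astype(np.uint8)
    im = Image.fromarray(index, mode="P")
    palette = [0] * 768
    base = [(255, 255, 255), (64, 160, 64), (64, 64, 200), (200, 160, 64),
            (160, 64, 200), (64, 200, 200), (200, 64, 64)]
    for i, (r, g, b) in enumerate(base):
        palette[3 * i:3 * i + 3] = [r, g, b]
    im.putpalette(palette)
    im.save(str(path))


def load_mask_png(path: str | Path, n_classes: int = 7) -> np.ndarray:
    with Image.open(str(path)) as im:
        index = np.asarray(im, dtype=np.uint8)
    stack = np.zeros((n_classes,) + index.shape, dtype=np.uint8)
    for l in range(n_classes):
        stack[l] = index == l
    return stack
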