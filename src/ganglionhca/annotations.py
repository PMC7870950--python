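"""Polygon annotations and ASAP-dialect XML I/O.

Ground-truth objects (ganglion cells, mimics, vessels, Schwann-cell
context) are stored as simple polygons in 0-based pixel coordinates
(x right, y down), implicitly closed (the last vertex is not repeated).
Files use the ASAP viewer's ``Annotation``/``Coordinates`` XML dialect so
they can be overlaid on slides in standard pathology viewers; coordinates
are printed with two decimals, which is the round-trip precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from lxml import etree
from shapely.geometry import Polygon as ShapelyPolygon

#: Recognised annotation classes.
ANNOTATION_CLASSES: tuple[str, ...] = (
    "mature_ganglion",
    "immature_ganglion",
    "mimic",
    "vessel",
    "schwann_cluster",
)

#: Ganglion classes: the truth unit of cell-level metrics.
GANGLION_CLASSES: frozenset[str] = frozenset(
    {"mature_ganglion", "immature_ganglion"}
)

_GROUP_COLORS = {
    "mature_ganglion": "#64FE2E",
    "immature_ganglion": "#F4FA58",
    "mimic": "#FA5858",
    "vessel": "#5882FA",
    "schwann_cluster": "#BE81F7",
}


class AnnotationParseError(ValueError):
    """Raised when an annotation XML file cannot be interpreted."""


@dataclass
class Annotation:
    """A single closed polygon with a class label."""

    label: str
    coords: np.ndarray  # (n_vertices, 2) float array of (x, y)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n, 2)")
        if len(self.coords) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.label not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.label!r}")
        poly = self.polygon
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(
                f"{self.label} polygon is not simple or has zero area"
            )

    @property
    def polygon(self) -> ShapelyPolygon:
        return ShapelyPolygon(self.coords)

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)

    def contains_point(self, x: float, y: float) -> bool:
        """Point-in-polygon test, boundary inclusive."""
        from shapely.geometry import Point

        return bool(self.polygon.covers(Point(x, y)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return (self.label == other.label
                and self.coords.shape == other.coords.shape
                and bool(np.allclose(self.coords, other.coords, atol=5e-3)))


@dataclass
class AnnotationSet:
    """An ordered collection of polygon annotations for one slide."""

    annotations: list[Annotation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(self.annotations)

    def by_class(self, *labels: str) -> "AnnotationSet":
        wanted = set(labels)
        return AnnotationSet(
            [a for a in self.annotations if a.label in wanted]
        )

    @property
    def ganglia(self) -> "AnnotationSet":
        return self.by_class(*GANGLION_CLASSES)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.annotations == other.annotations


# --------------------------------------------------------------------------
# ASAP XML dialect
# --------------------------------------------------------------------------

_HEADER_COMMENT = (
    "Coordinates are 0-based pixel positions, x right, y down; polygons are "
    "implicitly closed (last vertex differs from the first)."
)


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Write an :class:`AnnotationSet` as ASAP-style XML."""
    root = etree.Element("ASAP_Annotations")
    root.append(etree.Comment(_HEADER_COMMENT))
    anns = etree.SubElement(root, "Annotations")
    groups_used: list[str] = []
    for i, ann in enumerate(annotations):
        el = etree.SubElement(
            anns,
            "Annotation",
            Name=f"Annotation {i}",
            Type="Polygon",
            PartOfGroup=ann.label,
            Color=_GROUP_COLORS.get(ann.label, "#F4FA58"),
        )
        coords = etree.SubElement(el, "Coordinates")
        for order, (x, y) in enumerate(ann.coords):
            etree.SubElement(
                coords,
                "Coordinate",
                Order=str(order),
                X=f"{x:.2f}",
                Y=f"{y:.2f}",
            )
        if ann.label not in groups_used:
            groups_used.append(ann.label)
    groups = etree.SubElement(root, "AnnotationGroups")
    for name in groups_used:
        g = etree.SubElement(
            groups,
            "Group",
            Name=name,
            PartOfGroup="None",
            Color=_GROUP_COLORS.get(name, "#F4FA58"),
        )
        etree.SubElement(g, "Attributes")
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="utf-8")


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read ASAP-style XML back into an :class:`AnnotationSet`.

    Raises
    ------
    AnnotationParseError
        Naming the offending element when the file is malformed.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationParseError(f"not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "ASAP_Annotations":
        raise AnnotationParseError(
            f"root element is <{root.tag}>, expected <ASAP_Annotations>"
        )
    result: list[Annotation] = []
    for el in root.iter("Annotation"):
        name = el.get("Name", "<unnamed>")
        label = el.get("PartOfGroup")
        if label is None:
            raise AnnotationParseError(
                f"<Annotation Name={name!r}> lacks a PartOfGroup attribute"
            )
        coords_el = el.find("Coordinates")
        if coords_el is None:
            raise AnnotationParseError(
                f"<Annotation Name={name!r}> lacks a <Coordinates> element"
            )
        pts: list[tuple[int, float, float]] = []
        for c in coords_el.iter("Coordinate"):
            try:
                pts.append(
                    (int(c.get("Order")), float(c.get("X")),
                     float(c.get("Y")))
                )
            except (TypeError, ValueError) as exc:
                raise AnnotationParseError(
                    f"bad <Coordinate> in <Annotation Name={name!r}>: "
                    f"{etree.tostring(c, encoding='unicode').strip()}"
                ) from exc
        pts.sort(key=lambda t: t[0])
        coords = np.array([(x, y) for _, x, y in pts], dtype=float)
        try:
            result.append(Annotation(label=label, coords=coords))
        except ValueError as exc:
            raise AnnotationParseError(
                f"<Annotation Name={name!r}>: {exc}"
            ) from exc
    return AnnotationSet(result)
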