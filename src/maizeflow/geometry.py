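"""Field geometry: the Self-Protection Index and ring/centre partitions.

A maize field competes with incoming foreign pollen through the pollen
cloud it produces itself.  The amount of foreign pollen that can enter is
proportional to the field perimeter ``p`` while the amount of competing
local pollen is proportional to the field area ``A``; the ratio

    I = A / p        (metres)

is the field's *Self-Protection Index*: the larger ``I``, the more the
field dilutes adventitious cross-fertilization.  Two fields with the same
``I`` under equivalent external pollen pressure carry the same overall
%GM, which lets every field be mapped onto an *equivalent square* of side
``a = 4 I`` for closed-form work.

All coordinates are planar metres; polygons are simple closed rings
without holes (orientation-insensitive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import shapely
from shapely.geometry import Polygon, shape

__all__ = [
    "InvalidGeometryError",
    "FieldGeometry",
    "RingPartition",
    "self_protection_index",
    "equivalent_square_side",
    "ring_partition",
]

#: Relative tolerance for agreement between stored area/perimeter and the
#: values recomputed from an attached polygon.
_POLYGON_CONSISTENCY_RTOL = 1e-3


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or inconsistent polygon data."""


@dataclass(frozen=True)
class FieldGeometry:
    """A field described by its area, perimeter and (optionally) outline.

    Parameters
    ----------
    area_m2:
        Total field area :math:`A_T` in m², strictly positive.
    perimeter_m:
        Field perimeter :math:`p` in m, strictly positive.
    polygon:
        Optional planar outline (metre coordinates).  When given, its
        shoelace area and edge length must agree with ``area_m2`` and
        ``perimeter_m`` to within 0.1%, and exact inner-offset ring areas
        become available.
    """

    area_m2: float
    perimeter_m: float
    polygon: Polygon | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (self.area_m2 > 0 and math.isfinite(self.area_m2)):
            raise InvalidGeometryError(f"area_m2 must be > 0, got {self.area_m2}")
        if not (self.perimeter_m > 0 and math.isfinite(self.perimeter_m)):
            raise InvalidGeometryError(
                f"perimeter_m must be > 0, got {self.perimeter_m}"
            )
        # No simple closed curve can beat the circle: A <= p^2 / (4 pi).
        if self.area_m2 > self.perimeter_m**2 / (4.0 * math.pi) * (1.0 + 1e-9):
            raise InvalidGeometryError(
                "area exceeds the isoperimetric bound p^2/(4*pi): "
                f"A={self.area_m2}, p={self.perimeter_m}"
            )
        if self.polygon is not None:
            poly = self.polygon
            if not poly.is_valid or poly.is_empty:
                raise InvalidGeometryError("polygon is not a valid simple ring")
            if list(poly.interiors):
                raise InvalidGeometryError("polygons with holes are not supported")
            if not math.isclose(
                poly.area, self.area_m2, rel_tol=_POLYGON_CONSISTENCY_RTOL
            ):
                raise InvalidGeometryError(
                    f"polygon area {poly.area:.4g} disagrees with area_m2 "
                    f"{self.area_m2:.4g} beyond 0.1%"
                )
            if not math.isclose(
                poly.length, self.perimeter_m, rel_tol=_POLYGON_CONSISTENCY_RTOL
            ):
                raise InvalidGeometryError(
                    f"polygon perimeter {poly.length:.4g} disagrees with "
                    f"perimeter_m {self.perimeter_m:.4g} beyond 0.1%"
                )

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_polygon(cls, polygon: Polygon) -> "FieldGeometry":
        """Build from a shapely polygon, taking A and p from its shape."""
        return cls(area_m2=polygon.area, perimeter_m=polygon.length, polygon=polygon)

    @classmethod
    def from_wkt(cls, wkt: str) -> "FieldGeometry":
        geom = shapely.from_wkt(wkt)
        if not isinstance(geom, Polygon):
            raise InvalidGeometryError(f"expected a WKT Polygon, got {geom.geom_type}")
        return cls.from_polygon(geom)

    @classmethod
    def from_geojson(cls, geojson: str | dict) -> "FieldGeometry":
        obj = json.loads(geojson) if isinstance(geojson, str) else geojson
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        geom = shape(obj)
        if not isinstance(geom, Polygon):
            raise InvalidGeometryError(
                f"expected a GeoJSON Polygon, got {obj.get('type')!r}"
            )
        return cls.from_polygon(geom)

    @classmethod
    def rectangle(cls, length_m: float, width_m: float) -> "FieldGeometry":
        """Axis-aligned rectangular field with one corner at the origin."""
        if length_m <= 0 or width_m <= 0:
            raise InvalidGeometryError("rectangle sides must be positive")
        poly = Polygon(
            [(0, 0), (length_m, 0), (length_m, width_m), (0, width_m)]
        )
        return cls.from_polygon(poly)

    @classmethod
    def from_index(cls, index_m: float) -> "FieldGeometry":
        """The equivalent square of a field with Self-Protection Index I."""
        a = equivalent_square_side(index_m)
        return cls.rectangle(a, a)

    # ------------------------------------------------------------------ #
    # derived quantities

    @property
    def index(self) -> float:
        """Self-Protection Index I = A/p in metres."""
        return self_protection_index(self)

    @property
    def equivalent_side(self) -> float:
        """Side a = 4I of the equivalent square."""
        return equivalent_square_side(self.index)

    def equivalent_rectangle_sides(self) -> tuple[float, float]:
        """Sides (L, W), L >= W, of the rectangle with this A and p.

        Solves x^2 - (p/2) x + A = 0.  When no rectangle realizes the
        (A, p) pair (p^2 < 16 A cannot happen for a valid rectangle but
        can for other shapes), falls back to the equivalent square of
        side 4I, which preserves the Self-Protection Index rather than
        the raw perimeter.
        """
        half = self.perimeter_m / 2.0
        disc = half * half - 4.0 * self.area_m2
        if disc < 0:
            a = self.equivalent_side
            return a, a
        root = math.sqrt(disc)
        length = (half + root) / 2.0
        width = (half - root) / 2.0
        return length, width

    def summary(self) -> dict:
        """JSON-serializable summary of the geometry."""
        return {
            "area_m2": self.area_m2,
            "perimeter_m": self.perimeter_m,
            "self_protection_index_m": self.index,
            "equivalent_square_side_m": self.equivalent_side,
            "has_polygon": self.polygon is not None,
        }


def self_protection_index(geom: FieldGeometry) -> float:
    """Self-Protection Index I = A/p (metres).

    Examples
    --------
    A 100 m x 150 m field has I = 15000/500 = 30 m; a square of side
    ``a`` has I = a/4.
    """
    return geom.area_m2 / geom.perimeter_m


def equivalent_square_side(index_m: float) -> float:
    """Side a = 4I of the square sharing the field's overall %GM."""
    if not index_m > 0:
        raise InvalidGeometryError(f"Self-Protection Index must be > 0, got {index_m}")
    return 4.0 * index_m


@dataclass(frozen=True)
class RingPartition:
    """Split of a field into a peripheral ring and a central portion.

    ``ring_area_m2`` (:math:`A_R`) is the area of the outermost strip of
    width ``ring_width_m`` and ``central_area_m2`` (:math:`A_C`) the rest;
    they always sum to the total field area.
    """

    ring_width_m: float
    ring_area_m2: float
    central_area_m2: float

    @property
    def total_area_m2(self) -> float:
        return self.ring_area_m2 + self.central_area_m2


def ring_partition(
    geom: FieldGeometry, w: float = 10.0, *, exact: bool | None = None
) -> RingPartition:
    """Partition the field into a ``w``-wide peripheral ring and a centre.

    In the default approximation mode, A_R = w*p - 4*w**2 (exact for a
    square field, where the ring is the frame between the outer square and
    the inward-offset square).  For small fields the approximation can
    exceed the total area, in which case the ring is clamped to the whole
    field (A_C = 0), which reduces the two-part weighted average to the
    single-ring value.

    When the geometry carries a polygon, ``exact=True`` (the default in
    that case) computes A_R as the area lost by offsetting the outline
    inwards by ``w`` — the GIS route.

    Raises
    ------
    InvalidGeometryError
        If ``w <= 0`` or the approximation w*p - 4*w^2 is negative
        (ring width too large for this perimeter).
    """
    if not w > 0:
        raise InvalidGeometryError(f"ring width must be > 0, got {w}")
    if exact is None:
        exact = geom.polygon is not None
    if exact:
        if geom.polygon is None:
            raise InvalidGeometryError("exact ring areas require a polygon")
        inner = geom.polygon.buffer(-w, join_style="mitre")
        central = inner.area if not inner.is_empty else 0.0
        ring = geom.area_m2 - central
        return RingPartition(ring_width_m=w, ring_area_m2=ring, central_area_m2=central)
    approx = w * geom.perimeter_m - 4.0 * w * w
    if approx < 0:
        raise InvalidGeometryError(
            f"ring width {w} m too large for perimeter {geom.perimeter_m} m "
            "(w*p - 4*w^2 < 0)"
        )
    ring = min(approx, geom.area_m2)
    return RingPartition(
        ring_width_m=w, ring_area_m2=ring, central_area_m2=geom.area_m2 - ring
    )
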