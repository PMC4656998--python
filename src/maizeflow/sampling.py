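"""Sampling designs: the 28-sample standard grid and the 9-sample simplified plan.

The *standard* design lays 4 transects (two perpendicular pairs) through
the field, samples each transect end at depths 0, 3 and 10 m from the
border plus the transect crossing near the field centre — 28 three-cob
samples — and aggregates them as an area-weighted mean of ring x sector
sub-areas, each valued at the mean of its 4 vertex samples.  It is the
reference survey but needs 28 qPCR analyses.

The *simplified* design takes 8 equidistant 20-cob samples around the
perimeter at depth d (3 m by default, adaptable to 6 or 8) plus one
20-cob centre sample.  The 8 periphery samples are ground separately and
an equal aliquot of each is mixed into a single pooled sample, so a
field estimate needs only one or two qPCR analyses; the individual
periphery samples are kept for donor-direction work.

This module also hosts the transect normalization used to check the
1/(d+1)-based decay model against grouped survey data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .estimators import GMEstimate
from .geometry import FieldGeometry
from .model import SquareFlowModel

__all__ = [
    "SamplePoint",
    "SampleSet",
    "TransectProfile",
    "IncompleteDataError",
    "NoInformativeTransectsError",
    "design_standard",
    "design_simplified",
    "aggregate_standard",
    "pool_periphery",
    "normalize_transects",
]

STANDARD_DEPTHS = (0.0, 3.0, 10.0)
STANDARD_COBS_PER_SAMPLE = 3
SIMPLIFIED_COBS_PER_SAMPLE = 20
N_PERIPHERY_SIMPLIFIED = 8


class IncompleteDataError(ValueError):
    """An aggregation was requested before all samples were measured."""


class NoInformativeTransectsError(ValueError):
    """Every transect was all-zero; nothing to normalize."""


@dataclass
class SamplePoint:
    """One physical sample: a group of cobs taken at a single spot."""

    id: str
    role: str  # perimeter | transect | center | pooled
    x: float
    y: float
    depth_d: float
    n_cobs: int
    perimeter_position: float | None = None  # arc-length fraction in [0, 1)
    transect: int | None = None  # transect index for standard design
    arm: int | None = None  # half-transect index, ordered by angle
    value_pct: float | None = None

    def __post_init__(self) -> None:
        if self.depth_d < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth_d}")
        if self.value_pct is not None and self.value_pct < 0:
            raise ValueError(f"%GM value must be >= 0, got {self.value_pct}")


@dataclass
class SampleSet:
    """A sampling design instance bound to a field geometry."""

    design: str  # "standard" | "simplified"
    points: list[SamplePoint]
    geometry: FieldGeometry

    def measured(self) -> bool:
        return all(p.value_pct is not None for p in self.points)

    def by_role(self, role: str) -> list[SamplePoint]:
        return [p for p in self.points if p.role == role]

    @property
    def depth(self) -> float:
        """Periphery sampling depth (simplified design)."""
        peri = self.by_role("perimeter")
        if not peri:
            raise ValueError("sample set has no periphery points")
        return peri[0].depth_d


# ---------------------------------------------------------------------- #
# geometry plumbing


def _as_polygon(geom: FieldGeometry) -> Polygon:
    """Field outline; the equivalent rectangle when only (A, p) is known."""
    if geom.polygon is not None:
        return geom.polygon
    length, width = geom.equivalent_rectangle_sides()
    return Polygon([(0, 0), (length, 0), (length, width), (0, width)])


def _depth_of(poly: Polygon, pt: Point) -> float:
    return poly.exterior.distance(pt)


def _point_at_depth_along(
    poly: Polygon, start: Point, inward: Point, target_d: float
) -> Point:
    """Point on the segment start->inward whose distance to the border is
    ``target_d`` (distance grows monotonically inward for convex fields)."""
    seg = LineString([start, inward])
    lo, hi = 0.0, seg.length
    if _depth_of(poly, inward) < target_d:  # field too shallow: clamp inward
        return inward
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _depth_of(poly, seg.interpolate(mid)) < target_d:
            lo = mid
        else:
            hi = mid
    return seg.interpolate(0.5 * (lo + hi))


def _transect_chords(poly: Polygon) -> list[LineString]:
    """Four chords through the centroid, two perpendicular pairs.

    Angles are offset from the axes (22.5 deg steps) so border
    intersections land on generic side positions rather than the corners
    of rectangular fields, spreading the 8 entry points around the
    perimeter much like the field protocol's 50-60 m spacing."""
    c = poly.centroid
    span = 4.0 * math.sqrt(poly.area) + poly.length  # safely crosses the field
    chords = []
    for ang in (22.5, 67.5, 112.5, 157.5):
        t = math.radians(ang)
        dx, dy = math.cos(t) * span, math.sin(t) * span
        line = LineString([(c.x - dx, c.y - dy), (c.x + dx, c.y + dy)])
        chord = line.intersection(poly)
        if chord.is_empty or chord.geom_type != "LineString":
            raise ValueError("transect does not cross the field in one piece")
        chords.append(chord)
    return chords


# ---------------------------------------------------------------------- #
# designs


def design_standard(geom: FieldGeometry) -> SampleSet:
    """The 28-sample reference design.

    Four transects through the field centre (two perpendicular pairs) give
    8 border intersections; each transect end is sampled at depths 0, 3
    and 10 m (24 three-cob samples, 8 per depth) and each transect
    contributes one crossing sample at the centre, whose depth is the
    actual centre-to-border distance (the field half-width for a
    rectangle).  Fields too shallow for the 10 m depth trigger a
    degenerate-design warning and the deep samples collapse inward.
    """
    poly = _as_polygon(geom)
    c = poly.centroid
    center_depth = _depth_of(poly, c)
    if center_depth < STANDARD_DEPTHS[-1]:
        warnings.warn(
            f"field half-width {center_depth:.1f} m is below the 10 m sampling "
            "depth: standard design is degenerate",
            stacklevel=2,
        )
    chords = _transect_chords(poly)
    # half-transect arms, one per border intersection, ordered by angle
    arms: list[tuple[int, Point]] = []
    for t_idx, chord in enumerate(chords):
        for end in (Point(chord.coords[0]), Point(chord.coords[-1])):
            arms.append((t_idx, end))
    arms.sort(key=lambda te: math.atan2(te[1].y - c.y, te[1].x - c.x))

    pts: list[SamplePoint] = []
    for arm_idx, (t_idx, end) in enumerate(arms):
        for d in STANDARD_DEPTHS:
            p = end if d == 0.0 else _point_at_depth_along(poly, end, c, d)
            pts.append(
                SamplePoint(
                    id=f"T{t_idx}A{arm_idx}d{d:g}",
                    role="perimeter" if d == 0.0 else "transect",
                    x=p.x,
                    y=p.y,
                    depth_d=min(d, center_depth),
                    n_cobs=STANDARD_COBS_PER_SAMPLE,
                    transect=t_idx,
                    arm=arm_idx,
                )
            )
    for t_idx in range(len(chords)):
        pts.append(
            SamplePoint(
                id=f"C{t_idx}",
                role="center",
                x=c.x,
                y=c.y,
                depth_d=center_depth,
                n_cobs=STANDARD_COBS_PER_SAMPLE,
                transect=t_idx,
            )
        )
    return SampleSet(design="standard", points=pts, geometry=geom)


def design_simplified(geom: FieldGeometry, d: float = 3.0) -> SampleSet:
    """The 9-sample design: 8 equidistant periphery points at depth ``d``
    (20 cobs each) plus one 20-cob centre sample.

    Periphery points sit at equal arc-length spacing p/8 around the
    border (offset by half a gap so rectangle corners are avoided), each
    moved inward to depth ``d``.
    """
    poly = _as_polygon(geom)
    c = poly.centroid
    center_depth = _depth_of(poly, c)
    if not d < center_depth:
        raise ValueError(
            f"sampling depth {d} m must be below the centre depth "
            f"{center_depth:.1f} m"
        )
    ring = poly.exterior
    p = ring.length
    pts: list[SamplePoint] = []
    for k in range(N_PERIPHERY_SIMPLIFIED):
        frac = (k + 0.5) / N_PERIPHERY_SIMPLIFIED
        border_pt = ring.interpolate(frac * p)
        inner = _point_at_depth_along(poly, border_pt, c, d)
        pts.append(
            SamplePoint(
                id=f"P{k}",
                role="perimeter",
                x=inner.x,
                y=inner.y,
                depth_d=d,
                n_cobs=SIMPLIFIED_COBS_PER_SAMPLE,
                perimeter_position=frac,
            )
        )
    pts.append(
        SamplePoint(
            id="C",
            role="center",
            x=c.x,
            y=c.y,
            depth_d=center_depth,
            n_cobs=SIMPLIFIED_COBS_PER_SAMPLE,
        )
    )
    return SampleSet(design="simplified", points=pts, geometry=geom)


# ---------------------------------------------------------------------- #
# aggregation


def aggregate_standard(ss: SampleSet, geom: FieldGeometry | None = None) -> GMEstimate:
    """Area-weighted grid mean of a measured standard sample set.

    The field is cut into rings bounded by the depth contours (0, 3,
    10 m and the centre) and into 8 angular sectors bounded by adjacent
    half-transects.  Every ring x sector sub-area takes the mean of the
    4 samples at its vertices (two arms x two depths; the innermost
    sub-areas use the two arm samples at 10 m plus the two crossing
    samples), and the estimate is the sub-area-weighted mean.  Ring
    areas come from inward polygon offsets; each ring is split evenly
    across the 8 sectors.
    """
    if ss.design != "standard":
        raise ValueError(f"expected a standard sample set, got {ss.design!r}")
    if not ss.measured():
        missing = [p.id for p in ss.points if p.value_pct is None]
        raise IncompleteDataError(f"unmeasured samples: {missing}")
    geom = geom or ss.geometry
    poly = _as_polygon(geom)
    total = poly.area

    depths = list(STANDARD_DEPTHS)
    offsets = [poly]
    for d in depths[1:]:
        inner = poly.buffer(-d, join_style="mitre")
        offsets.append(inner if not inner.is_empty else Polygon())
    # ring k lies between depth contours k and k+1; the last "ring" is the
    # whole region beyond the deepest contour, reaching the centre.
    ring_areas = [offsets[j].area - offsets[j + 1].area for j in range(len(depths) - 1)]
    ring_areas.append(offsets[-1].area)

    # arm points sorted by depth align positionally with the design depths
    # (robust to clamping in shallow fields)
    arm_points: dict[int, list[SamplePoint]] = {}
    for p in ss.points:
        if p.arm is not None:
            arm_points.setdefault(p.arm, []).append(p)
    for plist in arm_points.values():
        plist.sort(key=lambda p: p.depth_d)
        if len(plist) != len(depths):
            raise ValueError("each arm must carry one sample per design depth")
    centers = {p.transect: p for p in ss.by_role("center")}
    arms = sorted(arm_points)
    n_arms = len(arms)
    arm_transect = {a: arm_points[a][0].transect for a in arms}

    weighted = 0.0
    for j, area_j in enumerate(ring_areas):
        for s in range(n_arms):
            a1, a2 = arms[s], arms[(s + 1) % n_arms]
            if j < len(depths) - 1:
                vals = [
                    arm_points[a1][j].value_pct,
                    arm_points[a1][j + 1].value_pct,
                    arm_points[a2][j].value_pct,
                    arm_points[a2][j + 1].value_pct,
                ]
            else:  # innermost: deepest transect samples + the crossings
                vals = [
                    arm_points[a1][-1].value_pct,
                    arm_points[a2][-1].value_pct,
                    centers[arm_transect[a1]].value_pct,
                    centers[arm_transect[a2]].value_pct,
                ]
            weighted += (area_j / n_arms) * float(np.mean(vals))
    value = weighted / total
    return GMEstimate(
        value=value,
        method="standard_grid",
        inputs_echo={"n_samples": len(ss.points), "area_m2": geom.area_m2},
    )


def pool_periphery(ss: SampleSet) -> float:
    """Pooled perimeter mean K_d: equal-aliquot mix of the 8 periphery
    samples, i.e. their arithmetic mean.  Permutation-invariant."""
    peri = ss.by_role("perimeter")
    if len(peri) != N_PERIPHERY_SIMPLIFIED:
        raise IncompleteDataError(
            f"pooling needs {N_PERIPHERY_SIMPLIFIED} periphery samples, "
            f"found {len(peri)}"
        )
    if any(p.value_pct is None for p in peri):
        raise IncompleteDataError("unmeasured periphery samples")
    return float(np.mean([p.value_pct for p in peri]))


# ---------------------------------------------------------------------- #
# transect normalization (model-validation curve)


@dataclass(frozen=True)
class TransectProfile:
    """Grouped decay profile from many transects, on the border = 1 scale."""

    depths: tuple[float, ...]
    mean: tuple[float, ...]  # normalized per-depth means, border-scaled
    se: tuple[float, ...]
    n_transects: int
    n_discarded: int
    theory: tuple[float, ...] | None = None  # perimeter_mean(d)/perimeter_mean(0)


def normalize_transects(
    transects: list[list[tuple[float, float]]],
    model: SquareFlowModel | None = None,
) -> TransectProfile:
    """Normalize per-transect decay data and average across transects.

    Each transect is a list of (depth, %GM) pairs on a common depth grid.
    Transects that are zero at every depth carry no pattern information
    and are discarded (their count is reported).  Every remaining value
    is divided by its transect mean so all transects weigh equally, the
    per-depth mean and standard error are computed, and the profile is
    rescaled so the shallowest depth reads 1 — directly comparable with
    the model curve perimeter_mean(d)/perimeter_mean(0), returned
    alongside when a model is given.
    """
    if not transects:
        raise NoInformativeTransectsError("no transects supplied")
    depths = tuple(d for d, _ in transects[0])
    rows = []
    n_discarded = 0
    for tr in transects:
        if tuple(d for d, _ in tr) != depths:
            raise ValueError("all transects must share the same depth grid")
        vals = np.array([v for _, v in tr], dtype=float)
        if np.all(vals == 0.0):
            n_discarded += 1
            continue
        rows.append(vals / vals.mean())
    if not rows:
        raise NoInformativeTransectsError(
            f"all {n_discarded} transects were zero at every depth"
        )
    arr = np.vstack(rows)
    mean = arr.mean(axis=0)
    se = (
        arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
        if arr.shape[0] > 1
        else np.zeros_like(mean)
    )
    scale = mean[0]
    theory = None
    if model is not None:
        k0 = model.perimeter_mean(depths[0])
        theory = tuple(model.perimeter_mean(d) / k0 for d in depths)
    return TransectProfile(
        depths=depths,
        mean=tuple(mean / scale),
        se=tuple(se / scale),
        n_transects=arr.shape[0],
        n_discarded=n_discarded,
        theory=theory,
    )
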