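"""Fixed shape templates for classical 2-6 set Venn diagrams.

Circles for 2-3 sets, the classical four- and five-ellipse layouts for 4-5
sets, and a six-triangle arrangement for 6 sets (six ellipses cannot form a
Venn diagram: two ellipses meet in at most four points, too few for the 63
required regions; a triangle arrangement can, and this one was verified
numerically so that all 63 membership regions have positive area).

Label anchors are not hard-coded: at plot time each of the 2^n - 1 regions
is constructed with shapely and its ``representative_point`` — guaranteed
to lie inside the region — is used as the count anchor.
"""

from __future__ import annotations

from functools import lru_cache

from shapely import affinity
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

__all__ = ["venn_shapes", "region_geometry", "region_anchor"]

# (kind, params): circle (cx, cy, r); ellipse (cx, cy, a, b, angle_deg);
# triangle (x1, y1, x2, y2, x3, y3)
_TEMPLATES: dict[int, list[tuple[str, tuple[float, ...]]]] = {
    2: [
        ("circle", (-0.25, 0.0, 0.55)),
        ("circle", (0.25, 0.0, 0.55)),
    ],
    3: [
        ("circle", (-0.25, -0.144, 0.55)),
        ("circle", (0.25, -0.144, 0.55)),
        ("circle", (0.0, 0.289, 0.55)),
    ],
    4: [
        ("ellipse", (0.350, 0.400, 0.36, 0.225, 140.0)),
        ("ellipse", (0.450, 0.500, 0.36, 0.225, 140.0)),
        ("ellipse", (0.544, 0.500, 0.36, 0.225, 40.0)),
        ("ellipse", (0.644, 0.400, 0.36, 0.225, 40.0)),
    ],
    5: [
        ("ellipse", (0.428, 0.449, 0.435, 0.25, 155.0)),
        ("ellipse", (0.469, 0.543, 0.435, 0.25, 82.0)),
        ("ellipse", (0.558, 0.523, 0.435, 0.25, 10.0)),
        ("ellipse", (0.578, 0.432, 0.435, 0.25, 118.0)),
        ("ellipse", (0.489, 0.383, 0.435, 0.25, 46.0)),
    ],
    6: [
        ("triangle", (0.6380, 0.9181, 0.6388, 0.2466, 0.2005, 0.6718)),
        ("triangle", (0.9544, 0.7549, 0.3411, 0.1936, 0.3786, 0.6694)),
        ("triangle", (0.9477, 0.3776, 0.3021, 0.4675, 0.4482, 0.7588)),
        ("triangle", (0.6561, 0.1122, 0.3131, 0.5410, 0.6462, 0.7065)),
        ("triangle", (0.3074, 0.0836, 0.3778, 0.7192, 0.6750, 0.4787)),
        ("triangle", (0.0373, 0.6236, 0.7165, 0.6946, 0.5254, 0.3349)),
    ],
}


def _build(kind: str, params: tuple[float, ...]) -> BaseGeometry:
    if kind == "circle":
        cx, cy, r = params
        return affinity.translate(Point(0, 0).buffer(r, quad_segs=128), cx, cy)
    if kind == "ellipse":
        cx, cy, a, b, angle = params
        e = affinity.scale(Point(0, 0).buffer(1, quad_segs=128), a, b)
        e = affinity.rotate(e, angle, origin=(0, 0))
        return affinity.translate(e, cx, cy)
    if kind == "triangle":
        x1, y1, x2, y2, x3, y3 = params
        return Polygon([(x1, y1), (x2, y2), (x3, y3)])
    raise ValueError(kind)


@lru_cache(maxsize=None)
def venn_shapes(n: int) -> tuple[BaseGeometry, ...]:
    """The n template shapes as shapely geometries (2 <= n <= 6)."""
    if n not in _TEMPLATES:
        raise ValueError(f"no venn template for n={n}; supported: 2-6")
    return tuple(_build(kind, params) for kind, params in _TEMPLATES[n])


@lru_cache(maxsize=None)
def region_geometry(n: int, mask: int) -> BaseGeometry:
    """The exclusive membership region of ``mask`` within the n-set template."""
    shapes = venn_shapes(n)
    region: BaseGeometry | None = None
    for i in range(n):
        if mask >> i & 1:
            region = shapes[i] if region is None else region.intersection(shapes[i])
    if region is None:
        raise ValueError("mask 0 has no region")
    for i in range(n):
        if not (mask >> i & 1):
            region = region.difference(shapes[i])
    return region


@lru_cache(maxsize=None)
def region_anchor(n: int, mask: int) -> tuple[float, float]:
    """A point guaranteed to lie inside the membership region of ``mask``."""
    region = region_geometry(n, mask)
    if region.is_empty:
        raise ValueError(f"template for n={n} has empty region for mask {mask}")
    p = region.representative_point()
    return (p.x, p.y)
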