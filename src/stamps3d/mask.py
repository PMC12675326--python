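"""The 12-region plantar mask: template, registration, point assignment.

The template lives in a normalised foot frame — AP coordinate 0 (heel)
to 1 (toe tip), ML coordinate in [-0.5, 0.5] with medial positive — and
partitions the unit foot domain into 11 anatomical regions following the
Pedar-style multimask layout: heel band, medial/lateral midfoot, five
metatarsal-head columns, and hallux / 2nd toe / toes 3-5.  ``global`` is
their union.  The exact commercial boundary percentages are proprietary;
the defaults here are declared and fully configurable, and all behaviour
is driven by the configuration rather than hard-coded numbers.

Registration maps the template onto an insole outline with anisotropic
scaling (AP and ML extents scaled independently), rotation into the
anatomical frame and an implicit mirror for left feet (the anatomical
ML axis already points medially on both sides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from .errors import InvalidTemplateConfig, RegistrationFailed
from .regions import OUTSIDE, REGIONS
from .strain import AnatomicalFrame

__all__ = [
    "MaskTemplateConfig",
    "MaskTemplate",
    "RegionTransform",
    "RegionAssignment",
    "build_default_template",
    "register_mask",
    "assign_regions",
]


@dataclass(frozen=True)
class MaskTemplateConfig:
    """Boundary fractions generating the template polygons.

    AP bands run heel to toe as fractions of foot length; ML splits are
    fractions of foot width measured from the medial edge.
    """

    heel_band: tuple[float, float] = (0.0, 0.27)
    midfoot_band: tuple[float, float] = (0.27, 0.55)
    mth_band: tuple[float, float] = (0.55, 0.73)
    toe_band: tuple[float, float] = (0.73, 1.0)
    midfoot_medial_width: float = 0.45
    mth_widths: tuple[float, ...] = (0.30, 0.20, 0.175, 0.175, 0.15)
    toe_widths: tuple[float, float, float] = (0.35, 0.20, 0.45)

    def __post_init__(self):
        bands = [self.heel_band, self.midfoot_band, self.mth_band, self.toe_band]
        for lo, hi in bands:
            if not (0.0 <= lo < hi <= 1.0):
                raise InvalidTemplateConfig("invalid template config: bad band bounds")
        for (_, hi), (lo, _) in zip(bands, bands[1:]):
            if not np.isclose(hi, lo):
                raise InvalidTemplateConfig(
                    "invalid template config: AP bands must be contiguous")
        if not (0.0 < self.midfoot_medial_width < 1.0):
            raise InvalidTemplateConfig("invalid template config: midfoot split")
        for widths, nm in ((self.mth_widths, "mth"), (self.toe_widths, "toe")):
            if any(w <= 0 for w in widths) or not np.isclose(sum(widths), 1.0):
                raise InvalidTemplateConfig(
                    f"invalid template config: {nm} widths must be positive and sum to 1")


@dataclass
class MaskTemplate:
    """Normalised 11-region mask; ``regions`` is ordered by precedence."""

    regions: dict[str, Polygon]
    config: MaskTemplateConfig

    @property
    def domain(self) -> Polygon:
        return box(0.0, -0.5, 1.0, 0.5)


def _ml_columns(lo_ap, hi_ap, widths):
    """Split a band into ML columns, most medial (y=+0.5) first."""
    cols = []
    y = 0.5
    for w in widths:
        cols.append(box(lo_ap, y - w, hi_ap, y))
        y -= w
    return cols


def build_default_template(config: MaskTemplateConfig | None = None) -> MaskTemplate:
    """Build the region polygons from a boundary-fraction configuration."""
    cfg = config or MaskTemplateConfig()
    regions: dict[str, Polygon] = {}

    toe_cols = _ml_columns(*cfg.toe_band, cfg.toe_widths)
    regions["hallux"], regions["toe2"], regions["toes3_5"] = toe_cols
    mth_cols = _ml_columns(*cfg.mth_band, cfg.mth_widths)
    for i, poly in enumerate(mth_cols, start=1):
        regions[f"mth{i}"] = poly
    lo, hi = cfg.midfoot_band
    split = 0.5 - cfg.midfoot_medial_width
    regions["midfoot_medial"] = box(lo, split, hi, 0.5)
    regions["midfoot_lateral"] = box(lo, -0.5, hi, split)
    regions["heel"] = box(*[cfg.heel_band[0], -0.5, cfg.heel_band[1], 0.5])

    regions = {name: regions[name] for name in REGIONS}
    total = sum(p.area for p in regions.values())
    if not np.isclose(total, 1.0, rtol=1e-9):
        raise InvalidTemplateConfig("invalid template config: regions do not partition")
    return MaskTemplate(regions=regions, config=cfg)


@dataclass(frozen=True)
class RegionTransform:
    """Similarity-with-anisotropic-scale map, template frame -> anatomical frame.

    Template AP [0, 1] maps to the outline's AP extent, template ML
    [-0.5, 0.5] to its ML extent; rotation/translation are those of the
    anatomical frame, and ``mirror`` records that a left foot involves a
    reflection of the world plane into the anatomical frame.
    """

    ap_range: tuple[float, float]
    ml_range: tuple[float, float]
    frame: AnatomicalFrame
    mirror: bool

    @property
    def scale_ap(self) -> float:
        return self.ap_range[1] - self.ap_range[0]

    @property
    def scale_ml(self) -> float:
        return self.ml_range[1] - self.ml_range[0]

    @property
    def rotation_deg(self) -> float:
        """In-plane rotation of the AP axis relative to world +x."""
        return float(np.degrees(np.arctan2(self.frame.ap_axis[1],
                                           self.frame.ap_axis[0])))

    def template_to_frame(self, tpts: np.ndarray) -> np.ndarray:
        t = np.atleast_2d(np.asarray(tpts, dtype=float))
        ap = self.ap_range[0] + t[:, 0] * self.scale_ap
        ml = self.ml_range[0] + (t[:, 1] + 0.5) * self.scale_ml
        return np.column_stack([ap, ml])

    def frame_to_template(self, fpts: np.ndarray) -> np.ndarray:
        f = np.atleast_2d(np.asarray(fpts, dtype=float))
        tx = (f[:, 0] - self.ap_range[0]) / self.scale_ap
        ty = (f[:, 1] - self.ml_range[0]) / self.scale_ml - 0.5
        return np.column_stack([tx, ty])


@dataclass
class RegionAssignment:
    """Point-to-region labels plus the transform and clipped region polygons."""

    labels: np.ndarray  # object array of region names / 'outside'
    transform: RegionTransform
    template: MaskTemplate
    region_polygons_frame: dict[str, Polygon] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        names, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(names.tolist(), cnt.tolist()))


def register_mask(template: MaskTemplate, outline, side: str,
                  frame: AnatomicalFrame) -> RegionTransform:
    """Register the template to an outline already fitted with a frame.

    Returns the transform mapping template coordinates to the frame's
    (AP, ML) plane.  Raises :class:`RegistrationFailed` for degenerate
    outlines (zero AP or ML extent).
    """
    if isinstance(outline, Polygon):
        v = np.asarray(outline.exterior.coords)[:-1]
    else:
        v = np.asarray(outline, dtype=float)
    fc = frame.ap_ml_coords(v)
    ap_range = (float(fc[:, 0].min()), float(fc[:, 0].max()))
    ml_range = (float(fc[:, 1].min()), float(fc[:, 1].max()))
    if ap_range[1] - ap_range[0] < 1e-9 or ml_range[1] - ml_range[0] < 1e-9:
        raise RegistrationFailed("registration failed: degenerate outline")
    return RegionTransform(ap_range=ap_range, ml_range=ml_range,
                           frame=frame, mirror=(side == "left"))


def registered_region_polygons(template: MaskTemplate,
                               transform: RegionTransform,
                               outline) -> dict[str, Polygon]:
    """Region polygons mapped to the frame plane and clipped to the outline."""
    if isinstance(outline, Polygon):
        v = np.asarray(outline.exterior.coords)[:-1]
    else:
        v = np.asarray(outline, dtype=float)
    outline_frame = Polygon(transform.frame.ap_ml_coords(v))
    out = {}
    for name, poly in template.regions.items():
        tv = np.asarray(poly.exterior.coords)
        fv = transform.template_to_frame(tv)
        out[name] = Polygon(fv).intersection(outline_frame)
    return out


def assign_regions(points: np.ndarray, transform: RegionTransform,
                   template: MaskTemplate,
                   outline=None) -> RegionAssignment:
    """Label (N, 2|3) points with anatomical regions.

    3D points are projected onto the frame's AP-ML plane (the mask is 2D
    even on contoured surfaces).  Boundary points resolve by the declared
    region precedence order; points outside the template domain (or the
    outline, if given) are labelled ``outside`` — never an error.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    fc = transform.frame.ap_ml_coords(pts)
    tc = transform.frame_to_template(fc)
    n = len(tc)
    labels = np.full(n, OUTSIDE, dtype=object)

    unassigned = np.ones(n, dtype=bool)
    if outline is not None:
        if isinstance(outline, Polygon):
            v = np.asarray(outline.exterior.coords)[:-1]
        else:
            v = np.asarray(outline, dtype=float)
        outline_frame = Polygon(transform.frame.ap_ml_coords(v))
        inside = shapely.covers(outline_frame,
                                shapely.points(fc[:, 0], fc[:, 1]))
        unassigned &= inside
    for name in REGIONS:
        poly = template.regions[name]
        if not unassigned.any():
            break
        cand = np.flatnonzero(unassigned)
        hit = shapely.covers(poly, shapely.points(tc[cand, 0], tc[cand, 1]))
        labels[cand[hit]] = name
        unassigned[cand[hit]] = False

    polys = registered_region_polygons(template, transform, outline) \
        if outline is not None else {}
    return RegionAssignment(labels=labels, transform=transform,
                            template=template, region_polygons_frame=polys)
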