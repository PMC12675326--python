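"""Synthetic ground-truth generator for the plantar strain pipeline.

Everything the imaging chain consumes can be generated here with a known
truth: speckle textures matching a commercial generator's statistical spec
(density / dot diameter / diameter variation), flat and arch-contoured
insole surfaces with foot-shaped outlines, smooth plastic deformation
fields built from Gaussian bumps (in-plane stretch + normal indentation),
ideal pinhole stereo renders of the deformed surface, and whole synthetic
gait studies (participants x conditions x repeats of regional peak strain
and paired plantar pressure).

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; no global RNG state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from scipy.stats import norm
from shapely.geometry import Polygon

from .errors import (
    BumpOutsideInsole,
    InfeasibleSpeckleSpec,
    InvalidEffectProfile,
    InvalidGeometry,
    SurfaceNotVisible,
)
from .regions import GLOBAL, REGIONS

__all__ = [
    "SpeckleSpec",
    "InsoleSurface",
    "DeformationTruth",
    "CameraModel",
    "StudyDesign",
    "Bump",
    "make_speckle_texture",
    "coverage_fraction",
    "make_insole_surface",
    "make_deformation",
    "uniform_stretch_deformation",
    "rigid_translation_deformation",
    "render_stereo_pair",
    "default_stereo_rig",
    "simulate_study",
    "default_effect_profile",
]


# ---------------------------------------------------------------------------
# Speckle texture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeckleSpec:
    """Statistical description of a stochastic speckle pattern.

    Parameters mirror commercial pattern generators: a target covered-area
    fraction, a nominal dot diameter and a uniform diameter variation
    (diameters drawn from ``dot_diameter_mm * [1 - v, 1 + v]``).

    Attributes
    ----------
    dot_density : float
        Target covered-area fraction in (0, 1).
    dot_diameter_mm : float
        Nominal dot diameter (mm).
    diameter_variation : float
        Fractional half-width of the uniform diameter distribution, in [0, 1).
    mm_per_px : float
        Texture raster scale (mm per texture pixel).
    seed : int
        RNG seed; identical spec + seed gives a bit-identical texture.
    dark_on_light : bool
        Dot polarity (default dark dots on a light background).
    """

    dot_density: float = 0.65
    dot_diameter_mm: float = 0.8
    diameter_variation: float = 0.75
    mm_per_px: float = 0.18
    seed: int = 0
    dark_on_light: bool = True

    def __post_init__(self):
        if not (0.0 < self.dot_density < 1.0):
            raise InfeasibleSpeckleSpec(
                f"infeasible speckle spec: density {self.dot_density} not in (0, 1)"
            )
        if self.dot_diameter_mm <= 0:
            raise InfeasibleSpeckleSpec("dot diameter must be positive")
        if not (0.0 <= self.diameter_variation < 1.0):
            raise InfeasibleSpeckleSpec("diameter variation must lie in [0, 1)")
        if self.mm_per_px <= 0:
            raise InfeasibleSpeckleSpec("mm_per_px must be positive")


def make_speckle_texture(spec: SpeckleSpec, size_px: tuple[int, int]) -> np.ndarray:
    """Render an 8-bit speckle texture of shape ``(rows, cols)``.

    Dots are placed uniformly at random with overlap permitted; the dot
    count is chosen so the expected covered-area fraction after overlap,
    ``1 - (1 - a/A)^n``, equals ``spec.dot_density``.  Edges are rendered
    with ~1 px analytic anti-aliasing so the measured coverage (mean dot
    opacity) matches the geometric covered fraction.
    """
    ny, nx = int(size_px[0]), int(size_px[1])
    if ny <= 0 or nx <= 0:
        raise InvalidGeometry("texture size must be positive")
    rng = np.random.default_rng(spec.seed)

    d_px = spec.dot_diameter_mm / spec.mm_per_px
    v = spec.diameter_variation
    mean_area = np.pi / 4.0 * d_px**2 * (1.0 + v**2 / 3.0)  # E[pi d^2/4], d uniform
    img_area = float(ny * nx)
    frac = mean_area / img_area
    if frac >= 1.0:
        raise InfeasibleSpeckleSpec("infeasible speckle spec: dot larger than image")
    n_dots = int(np.ceil(np.log1p(-spec.dot_density) / np.log1p(-frac)))
    if n_dots > 60 * img_area / mean_area:
        raise InfeasibleSpeckleSpec("infeasible speckle spec: placement cannot terminate")

    r_max = d_px * (1.0 + v) / 2.0
    pad = r_max + 1.0
    cx = rng.uniform(-pad, nx + pad, n_dots)
    cy = rng.uniform(-pad, ny + pad, n_dots)
    radii = 0.5 * d_px * rng.uniform(1.0 - v, 1.0 + v, n_dots)

    cover = np.zeros(ny * nx, dtype=np.float32)
    k = int(np.ceil(2 * r_max)) + 3  # patch half-extent in px
    offs = np.arange(-k, k + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    oy = oy.ravel()[None, :]
    ox = ox.ravel()[None, :]
    chunk = max(1, int(4e6 // offs.size**2))
    for i0 in range(0, n_dots, chunk):
        sl = slice(i0, min(i0 + chunk, n_dots))
        icx = np.round(cx[sl])[:, None]
        icy = np.round(cy[sl])[:, None]
        px = icx + ox
        py = icy + oy
        dist = np.hypot(px - cx[sl, None], py - cy[sl, None])
        alpha = np.clip(radii[sl, None] - dist + 0.5, 0.0, 1.0).astype(np.float32)
        inb = (px >= 0) & (px < nx) & (py >= 0) & (py < ny)
        idx = (py * nx + px)[inb].astype(np.intp)
        np.maximum.at(cover, idx, alpha[inb])

    cover = cover.reshape(ny, nx)
    if spec.dark_on_light:
        img = np.round(255.0 * (1.0 - cover))
    else:
        img = np.round(255.0 * cover)
    return img.astype(np.uint8)


def coverage_fraction(texture: np.ndarray, dark_on_light: bool = True) -> float:
    """Measured covered-area fraction of a speckle texture (mean dot opacity)."""
    t = np.asarray(texture, dtype=np.float64) / 255.0
    return float(np.mean(1.0 - t) if dark_on_light else np.mean(t))


# ---------------------------------------------------------------------------
# Insole geometry
# ---------------------------------------------------------------------------

def _gauss(t, mu, sigma):
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _foot_half_widths(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Medial/lateral half-width profiles (fractions of width/2) for a right foot.

    AP parameter ``t`` runs heel (0) to toe tip (1); medial is +y.  The
    profile has an arch concavity on the medial midfoot and its maximum
    width at the forefoot, so the anterior end is the wider one.
    """
    med = 0.74 + 0.30 * _gauss(t, 0.76, 0.15) - 0.26 * _gauss(t, 0.42, 0.12)
    lat = 0.82 + 0.18 * _gauss(t, 0.68, 0.20)
    cap = np.sqrt(np.clip(1.0 - ((t - 0.5) / 0.5) ** 8, 0.0, 1.0))
    return med * cap, lat * cap


def _foot_outline_polygon(length_mm: float, width_mm: float, side: str,
                          n: int = 256) -> Polygon:
    t = np.linspace(0.0, 1.0, n)
    med, lat = _foot_half_widths(t)
    # normalise so the maximal total width equals width_mm
    scale = 2.0 / np.max(med + lat)
    med = med * scale * width_mm / 2.0
    lat = lat * scale * width_mm / 2.0
    x = t * length_mm
    # medial edge heel->toe, then lateral edge toe->heel (right foot: medial = +y)
    xs = np.concatenate([x[1:-1], x[::-1][1:-1]])
    ys = np.concatenate([med[1:-1], -lat[::-1][1:-1]])
    if side == "left":
        ys = -ys
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid or not poly.is_simple:  # pragma: no cover - by construction
        poly = poly.buffer(0)
    return poly


@dataclass
class InsoleSurface:
    """Reference insole top surface: outline, height field, speckle texture.

    The surface is parameterised over the (x, y) plane in mm: x runs heel
    to toe (anterior positive), y is medio-lateral (medial positive for a
    right foot), z is up (out of the insole plane).  ``height_fn`` returns
    the reference z (mm) at arbitrary (x, y); the speckle texture covers
    the outline bounding box plus a margin at ``spec.mm_per_px``.
    """

    outline: Polygon
    side: str
    thickness_mm: float
    length_mm: float
    width_mm: float
    contoured: bool
    arch_height_mm: float
    spec: SpeckleSpec
    texture: np.ndarray
    tex_origin_mm: tuple[float, float]
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_points: np.ndarray  # (N, 3) points inside the outline
    height_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)

    def heights(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.height_fn(np.asarray(x, float), np.asarray(y, float))


def _contoured_height_builder(outline: Polygon, length_mm: float, width_mm: float,
                              arch_height_mm: float, side: str):
    """Smooth height field: medial arch bulge + heel-cup / lateral rim.

    Built on a coarse grid (distance-to-edge computed with shapely) and
    interpolated with a bicubic spline; normalised so max z equals
    ``arch_height_mm`` over the outline.
    """
    sgn = 1.0 if side == "right" else -1.0
    xmin, ymin, xmax, ymax = outline.bounds
    gx = np.linspace(xmin - 2, xmax + 2, 96)
    gy = np.linspace(ymin - 2, ymax + 2, 64)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    pts = shapely.points(GX.ravel(), GY.ravel())
    d_edge = shapely.distance(pts, outline.exterior).reshape(GX.shape)
    inside = shapely.contains_xy(outline, GX.ravel(), GY.ravel()).reshape(GX.shape)
    d_edge = np.where(inside, d_edge, 0.0)

    t = GX / length_mm
    ml = sgn * GY / (width_mm / 2.0)  # +1 medial edge, -1 lateral edge
    arch = _gauss(t, 0.44, 0.15) * _gauss(ml, 0.75, 0.45)
    rim_profile = np.exp(-0.5 * (d_edge / 7.0) ** 2) * inside
    rim_weight = 0.65 * _gauss(t, 0.10, 0.14) + 0.45 * _gauss(ml, -1.0, 0.5) * _gauss(t, 0.42, 0.28)
    z = arch + rim_profile * rim_weight
    zmax = float(np.max(np.where(inside, z, 0.0)))
    z = z * (arch_height_mm / zmax)
    spl = RectBivariateSpline(gx, gy, z, kx=3, ky=3, s=0)

    def height_fn(x, y):
        return spl.ev(np.clip(x, gx[0], gx[-1]), np.clip(y, gy[0], gy[-1]))

    return height_fn


def make_insole_surface(
    length_mm: float = 260.0,
    width_mm: float = 95.0,
    contoured: bool = False,
    arch_height_mm: float = 0.0,
    side: str = "right",
    spec: SpeckleSpec | None = None,
    thickness_mm: float = 5.0,
    grid_spacing_mm: float = 4.0,
    texture_margin_mm: float = 8.0,
) -> InsoleSurface:
    """Build a reference insole surface with a speckle texture.

    Flat surfaces have z identically zero; contoured surfaces carry a
    smooth medial arch bulge plus a raised heel-cup/lateral rim whose
    maximum height equals ``arch_height_mm``.  The 5 mm default layer
    thickness matches a plasticine mid-layer.
    """
    if length_mm <= 0 or width_mm <= 0 or length_mm <= width_mm:
        raise InvalidGeometry("invalid geometry: require length > width > 0")
    if thickness_mm <= 0:
        raise InvalidGeometry("invalid geometry: thickness must be positive")
    if arch_height_mm < 0:
        raise InvalidGeometry("invalid geometry: arch height must be >= 0")
    if side not in ("left", "right"):
        raise InvalidGeometry(f"side must be 'left' or 'right', got {side!r}")
    if not contoured:
        arch_height_mm = 0.0
    spec = spec or SpeckleSpec()

    outline = _foot_outline_polygon(length_mm, width_mm, side)
    if contoured and arch_height_mm > 0:
        height_fn = _contoured_height_builder(outline, length_mm, width_mm,
                                              arch_height_mm, side)
    else:
        def height_fn(x, y):
            return np.zeros_like(np.asarray(x, dtype=float))

    xmin, ymin, xmax, ymax = outline.bounds
    m = texture_margin_mm
    tex_origin = (xmin - m, ymin - m)
    tex_nx = int(np.ceil((xmax - xmin + 2 * m) / spec.mm_per_px))
    tex_ny = int(np.ceil((ymax - ymin + 2 * m) / spec.mm_per_px))
    texture = make_speckle_texture(spec, (tex_ny, tex_nx))

    gx = np.arange(xmin + grid_spacing_mm, xmax, grid_spacing_mm)
    gy = np.arange(ymin + grid_spacing_mm, ymax, grid_spacing_mm)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    # keep grid points strictly inside (1 mm margin) so they project onto texture
    inner = outline.buffer(-1.0)
    keep = shapely.contains_xy(inner, GX.ravel(), GY.ravel())
    px = GX.ravel()[keep]
    py = GY.ravel()[keep]
    pz = height_fn(px, py)
    grid_points = np.column_stack([px, py, pz])

    return InsoleSurface(
        outline=outline, side=side, thickness_mm=thickness_mm,
        length_mm=length_mm, width_mm=width_mm, contoured=contoured,
        arch_height_mm=arch_height_mm, spec=spec, texture=texture,
        tex_origin_mm=tex_origin, grid_x=gx, grid_y=gy,
        grid_points=grid_points, height_fn=height_fn,
    )


# ---------------------------------------------------------------------------
# Deformation truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bump:
    """One localised plastic deformation feature.

    A Gaussian envelope ``g = exp(-r^2 / 2 radius^2)`` carries a radial
    in-plane stretch (displacement ``peak_inplane_strain * g * (x - c)``,
    giving engineering strain ``peak_inplane_strain`` at the centre) and a
    normal indentation of ``peak_indentation_mm`` at the centre.
    """

    region: str | None
    center: tuple[float, float]
    radius_mm: float
    peak_inplane_strain: float = 0.0
    peak_indentation_mm: float = 0.0


@dataclass
class DeformationTruth:
    """Ground-truth deformation: analytic displacement + derived strain truth.

    ``displacement_fn`` maps (N, 2) reference (x, y) points to (N, 3)
    displacements in mm.  ``strain_truth`` holds per-grid-point true strain
    components on the surface parameterisation plane: in-plane
    Green-Lagrange ``E_ap``/``E_ml``/``E_shear`` (dimensionless), the
    out-of-plane component ``S_Z`` (indentation depth over layer
    thickness, positive into the insole) and ``S_MAG`` in percent.
    """

    surface: InsoleSurface
    displacement: np.ndarray  # (N, 3) at surface.grid_points
    strain_truth: pd.DataFrame
    bump_params: tuple[Bump, ...]
    displacement_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def displacement_at(self, xy: np.ndarray) -> np.ndarray:
        return self.displacement_fn(np.asarray(xy, dtype=float))


def smag_percent(e_ap, e_ml, e_shear, s_z):
    """Scalar strain magnitude in %: in-plane tensor norm (doubled shear) + S_Z in quadrature."""
    return 100.0 * np.sqrt(
        np.asarray(e_ap) ** 2 + np.asarray(e_ml) ** 2
        + 2.0 * np.asarray(e_shear) ** 2 + np.asarray(s_z) ** 2
    )


def _strain_truth_table(surface: InsoleSurface, fn, h: float = 1e-3) -> pd.DataFrame:
    """Differentiate an analytic displacement field to get the truth strain table."""
    pts = surface.grid_points[:, :2]

    def disp(p):
        return fn(p)

    dxp = disp(pts + [h, 0.0])
    dxm = disp(pts - [h, 0.0])
    dyp = disp(pts + [0.0, h])
    dym = disp(pts - [0.0, h])
    g = np.empty((len(pts), 3, 2))
    g[:, :, 0] = (dxp - dxm) / (2 * h)
    g[:, :, 1] = (dyp - dym) / (2 * h)
    F = g[:, :2, :2] + np.eye(2)[None]
    C = np.einsum("nij,nik->njk", F, F)
    E = 0.5 * (C - np.eye(2)[None])
    u = disp(pts)
    s_z = -u[:, 2] / surface.thickness_mm
    df = pd.DataFrame(
        {
            "x": surface.grid_points[:, 0],
            "y": surface.grid_points[:, 1],
            "z": surface.grid_points[:, 2],
            "dx": u[:, 0], "dy": u[:, 1], "dz": u[:, 2],
            "E_ap": E[:, 0, 0], "E_ml": E[:, 1, 1], "E_shear": E[:, 0, 1],
            "S_Z": s_z,
        }
    )
    df["S_MAG"] = smag_percent(df.E_ap, df.E_ml, df.E_shear, df.S_Z)
    return df


def _make_truth(surface: InsoleSurface, fn, bumps=()) -> DeformationTruth:
    disp = fn(surface.grid_points[:, :2])
    return DeformationTruth(
        surface=surface,
        displacement=disp,
        strain_truth=_strain_truth_table(surface, fn),
        bump_params=tuple(bumps),
        displacement_fn=fn,
    )


def make_deformation(surface: InsoleSurface, bumps: Sequence[Bump],
                     seed: int = 0) -> DeformationTruth:
    """Sum-of-Gaussian-bumps plastic deformation with analytic truth.

    An empty bump list yields an identically zero field.  The ``seed``
    parameter is reserved for optional stochastic surface roughness and
    does not affect the default analytic field.
    """
    for b in bumps:
        if b.radius_mm <= 0:
            raise BumpOutsideInsole("bump radius must be positive")
        if not shapely.contains_xy(surface.outline, b.center[0], b.center[1]):
            raise BumpOutsideInsole(f"bump outside insole: centre {b.center}")
    bumps = tuple(bumps)

    def fn(xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))[:, :2]
        out = np.zeros((len(xy), 3))
        for b in bumps:
            dx = xy[:, 0] - b.center[0]
            dy = xy[:, 1] - b.center[1]
            g = np.exp(-0.5 * (dx**2 + dy**2) / b.radius_mm**2)
            out[:, 0] += b.peak_inplane_strain * g * dx
            out[:, 1] += b.peak_inplane_strain * g * dy
            out[:, 2] -= b.peak_indentation_mm * g
        return out

    return _make_truth(surface, fn, bumps)


def uniform_stretch_deformation(surface: InsoleSurface, stretch_ap: float,
                                stretch_ml: float = 1.0,
                                center: tuple[float, float] | None = None) -> DeformationTruth:
    """Homogeneous in-plane stretch about the outline centroid (or ``center``)."""
    if center is None:
        c = surface.outline.centroid
        center = (c.x, c.y)
    cx, cy = center

    def fn(xy):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))[:, :2]
        out = np.zeros((len(xy), 3))
        out[:, 0] = (stretch_ap - 1.0) * (xy[:, 0] - cx)
        out[:, 1] = (stretch_ml - 1.0) * (xy[:, 1] - cy)
        return out

    return _make_truth(surface, fn)


def rigid_translation_deformation(surface: InsoleSurface,
                                  t_mm: Sequence[float]) -> DeformationTruth:
    """Rigid 3D translation of the whole surface (zero strain truth)."""
    t = np.asarray(t_mm, dtype=float)

    def fn(xy):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return np.tile(t, (len(xy), 1))

    return _make_truth(surface, fn)


# ---------------------------------------------------------------------------
# Cameras and rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera: ``x_px = f * (R X + t) / z + c``.

    ``rotation`` maps world to camera coordinates; ``translation_mm`` is the
    world origin in camera coordinates.  Image x is the column coordinate,
    image y the row, with a pixel-centre convention and 0-based indexing.
    """

    focal_px: float
    principal_point_px: tuple[float, float]
    rotation: np.ndarray
    translation_mm: np.ndarray
    image_size_px: tuple[int, int] = (1920, 1200)  # (width, height)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8) \
                or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise InvalidGeometry("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation_mm",
                           np.asarray(self.translation_mm, dtype=float).reshape(3))

    @property
    def center_mm(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.rotation.T @ self.translation_mm

    @property
    def projection_matrix(self) -> np.ndarray:
        K = np.array([
            [self.focal_px, 0.0, self.principal_point_px[0]],
            [0.0, self.focal_px, self.principal_point_px[1]],
            [0.0, 0.0, 1.0],
        ])
        return K @ np.hstack([self.rotation, self.translation_mm[:, None]])

    def project(self, points_mm: np.ndarray) -> np.ndarray:
        """Project (N, 3) world points to (N, 2) pixel coordinates."""
        X = np.atleast_2d(np.asarray(points_mm, dtype=float))
        xc = X @ self.rotation.T + self.translation_mm
        return (self.focal_px * xc[:, :2] / xc[:, 2:3]
                + np.asarray(self.principal_point_px))

    def pixel_rays(self, px: np.ndarray, py: np.ndarray):
        """World-frame ray directions through pixels; returns (origin, dirs (N,3))."""
        d_cam = np.column_stack([
            (np.ravel(px) - self.principal_point_px[0]) / self.focal_px,
            (np.ravel(py) - self.principal_point_px[1]) / self.focal_px,
            np.ones(np.size(px)),
        ])
        return self.center_mm, d_cam @ self.rotation


def _look_at(center: np.ndarray, target: np.ndarray,
             up: np.ndarray = np.array([0.0, 1.0, 0.0])) -> np.ndarray:
    z = target - center
    z = z / np.linalg.norm(z)
    x = np.cross(z, up)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def default_stereo_rig(
    target_mm: Sequence[float] = (130.0, 0.0, 0.0),
    standoff_mm: float = 400.0,
    vergence_deg: float = 15.0,
    image_size_px: tuple[int, int] = (1920, 1200),
    baseline_axis: str = "x",
) -> tuple[CameraModel, CameraModel]:
    """Verged synthetic stereo pair looking down at the insole plane.

    Cameras sit ``standoff_mm`` above the target, separated by
    ``vergence_deg`` total vergence, both aimed at ``target_mm``.  The
    focal length scales with image width so a ~270 mm insole spans ~78% of
    the frame (1500 px of a 1920 px image at full resolution).
    """
    target = np.asarray(target_mm, dtype=float)
    half = np.deg2rad(vergence_deg / 2.0)
    focal = standoff_mm * (1500.0 / 270.0) * (image_size_px[0] / 1920.0)
    pp = ((image_size_px[0] - 1) / 2.0, (image_size_px[1] - 1) / 2.0)
    cams = []
    for s in (-1.0, +1.0):
        if baseline_axis == "x":
            offset = np.array([s * np.sin(half), 0.0, np.cos(half)])
        else:
            offset = np.array([0.0, s * np.sin(half), np.cos(half)])
        C = target + standoff_mm * offset
        R = _look_at(C, target)
        t = -R @ C
        cams.append(CameraModel(focal, pp, R, t, image_size_px))
    return cams[0], cams[1]


def _render_one(surface: InsoleSurface, deformation: DeformationTruth | None,
                cam: CameraModel, background: int, supersample: int,
                n_iter: int = 12) -> np.ndarray:
    W, H = cam.image_size_px
    tex = ndimage.spline_filter(surface.texture.astype(np.float64), order=3,
                                mode="mirror")
    mmpp = surface.spec.mm_per_px
    ox, oy = surface.tex_origin_mm
    flat = (not surface.contoured) or surface.arch_height_mm == 0

    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    acc = np.zeros(H * W, dtype=np.float64)
    pxg, pyg = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    for ou in offs:
        for ov in offs:
            origin, dirs = cam.pixel_rays(pxg.ravel() + ou, pyg.ravel() + ov)
            # intersect the (deformed) surface: joint fixed point on height
            # and material-coordinate inversion; slopes are small and rays
            # near-vertical, so this converges geometrically.
            z = np.zeros(dirs.shape[0])
            s = (z - origin[2]) / dirs[:, 2]
            mx = origin[0] + s * dirs[:, 0]
            my = origin[1] + s * dirs[:, 1]
            for _ in range(1 if (flat and deformation is None) else n_iter):
                if deformation is not None:
                    u = deformation.displacement_at(np.column_stack([mx, my]))
                else:
                    u = None
                zs = np.zeros_like(mx) if flat else np.asarray(surface.height_fn(mx, my))
                if u is not None:
                    zs = zs + u[:, 2]
                s = (zs - origin[2]) / dirs[:, 2]
                X = origin[0] + s * dirs[:, 0]
                Y = origin[1] + s * dirs[:, 1]
                if u is not None:
                    mx = X - u[:, 0]
                    my = Y - u[:, 1]
                else:
                    mx, my = X, Y
            inside = shapely.contains_xy(surface.outline, mx, my)
            tj = (mx - ox) / mmpp - 0.5
            ti = (my - oy) / mmpp - 0.5
            vals = ndimage.map_coordinates(tex, [ti, tj], order=3,
                                           prefilter=False, mode="constant",
                                           cval=float(background))
            acc += np.where(inside, vals, float(background))
    img = (acc / supersample**2).reshape(H, W)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_stereo_pair(
    surface: InsoleSurface,
    deformation: DeformationTruth | None,
    cam1: CameraModel,
    cam2: CameraModel,
    background: int = 80,
    supersample: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the (optionally deformed) surface into both cameras.

    Pure function of its inputs: pinhole projection, texture looked up at
    the *material* point of each pixel with ``supersample**2`` sub-pixel
    samples and bicubic interpolation, pixels off the insole set to a
    uniform background grey.  ``deformation=None`` renders the reference
    (pre-walk) state.

    Raises
    ------
    SurfaceNotVisible
        If the projected outline leaves either camera's image bounds.
    """
    verts = np.asarray(surface.outline.exterior.coords)
    verts3 = np.column_stack([verts, surface.heights(verts[:, 0], verts[:, 1])])
    for cam in (cam1, cam2):
        uv = cam.project(verts3)
        W, H = cam.image_size_px
        if (uv[:, 0].min() < 0 or uv[:, 0].max() > W - 1
                or uv[:, 1].min() < 0 or uv[:, 1].max() > H - 1):
            raise SurfaceNotVisible("surface not fully visible in a camera view")
    img1 = _render_one(surface, deformation, cam1, background, supersample)
    img2 = _render_one(surface, deformation, cam2, background, supersample)
    return img1, img2


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Gait study layout: participants x walking conditions x repeats."""

    n_participants: int = 5
    conditions: tuple[str, ...] = ("low_stiffness", "high_stiffness", "flat")
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 1:
            raise InvalidEffectProfile("n_repeats must be >= 1")
        if len(self.conditions) == 0 or len(set(self.conditions)) != len(self.conditions):
            raise InvalidEffectProfile("conditions must be non-empty and unique")
        object.__setattr__(self, "conditions", tuple(self.conditions))


def default_effect_profile(
    conditions: Sequence[str] = ("low_stiffness", "high_stiffness", "flat"),
) -> pd.DataFrame:
    """A plausible per-region x per-condition true peak-strain profile (%).

    Contoured conditions load the heel, lateral midfoot and lesser toes
    more; the flat condition loads the hallux and medial forefoot more —
    the qualitative pattern expected when an arch profile redistributes
    load.  Values are round numbers chosen for synthetic studies, not
    measurements.
    """
    base = {
        "hallux": (8.0, 10.0, 12.0),
        "toe2": (7.0, 7.0, 8.5),
        "toes3_5": (20.0, 12.0, 11.5),
        "mth1": (4.0, 4.0, 7.5),
        "mth2": (4.5, 5.5, 5.5),
        "mth3": (4.5, 4.0, 5.5),
        "mth4": (8.5, 8.0, 12.0),
        "mth5": (15.0, 14.0, 13.0),
        "midfoot_medial": (3.0, 3.0, 2.0),
        "midfoot_lateral": (5.0, 5.5, 3.0),
        "heel": (19.0, 21.0, 12.0),
    }
    df = pd.DataFrame(base, index=list(conditions)[:3]).T
    df.columns = list(conditions)[:3]
    for c in conditions[3:]:
        df[c] = df[conditions[0]]
    return df[list(conditions)]


def simulate_study(
    design: StudyDesign,
    effect_profile: pd.DataFrame | Mapping[str, Mapping[str, float]],
    noise_cv: float = 0.0,
    target_rho: float | None = 0.5,
    pressure_condition: str | None = None,
    pressure_cv: float = 0.05,
    pressure_scale_kpa: float = 180.0,
    pressure_log_sd: float = 0.6,
    between_participant_sd: float = 0.0,
    pressure_link: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw a full synthetic study table of regional peak strain and pressure.

    Each regional record is ``truth * participant_factor * (1 + eps)`` with
    ``eps ~ N(0, noise_cv)`` independent across repeats, so the noise has
    coefficient of variation ``noise_cv`` about the cell truth.  A paired
    peak-plantar-pressure record is generated for the flattest condition
    (``pressure_condition``, default the last condition) either through a
    Gaussian copula that imposes a target Spearman correlation
    ``target_rho`` with the realised mean strains, or, when ``target_rho``
    is None, through a deterministic monotone link ``pressure_link``.

    Returns the long-format study table (one row per participant x
    condition x repeat x region, including a ``global`` row holding the
    across-region maximum) and a dict of ground truth.
    """
    if noise_cv < 0:
        raise InvalidEffectProfile("noise_cv must be >= 0")
    profile = pd.DataFrame(effect_profile).astype(float)
    missing = set(REGIONS) - set(profile.index)
    if missing:
        raise InvalidEffectProfile(f"invalid effect profile: missing regions {sorted(missing)}")
    missing_c = set(design.conditions) - set(profile.columns)
    if missing_c:
        raise InvalidEffectProfile(f"invalid effect profile: missing conditions {sorted(missing_c)}")
    profile = profile.loc[list(REGIONS), list(design.conditions)]
    if (profile.values < 0).any():
        raise InvalidEffectProfile("invalid effect profile: negative truth values")

    P, K = design.n_participants, design.n_repeats
    C = len(design.conditions)
    R = len(REGIONS)
    rng = np.random.default_rng(design.seed)
    pf = np.exp(rng.normal(0.0, between_participant_sd, P)) if between_participant_sd > 0 \
        else np.ones(P)
    truth = profile.values.T  # (C, R)
    eps = rng.normal(0.0, 1.0, (P, C, K, R)) * noise_cv
    strain = truth[None, :, None, :] * pf[:, None, None, None] * (1.0 + eps)
    g = strain.max(axis=3)  # (P, C, K) global peaks

    pc = pressure_condition or design.conditions[-1]
    ci = design.conditions.index(pc)
    # mean across repeats for the pressure-paired condition, regions + global
    m = np.concatenate([strain[:, ci].mean(axis=1), g[:, ci].mean(axis=1)[:, None]],
                       axis=1)  # (P, R+1)
    flat_m = m.ravel()
    if target_rho is not None:
        ranks = pd.Series(flat_m).rank(method="average").values
        z_s = norm.ppf((ranks - 0.5) / flat_m.size)
        rho_z = 2.0 * np.sin(np.pi * target_rho / 6.0)
        z_p = rho_z * z_s + np.sqrt(1.0 - rho_z**2) * rng.normal(0.0, 1.0, flat_m.size)
        base = pressure_scale_kpa * np.exp(pressure_log_sd * z_p)
    else:
        link = pressure_link or (lambda s: 40.0 * np.maximum(s, 0.0) ** 0.85)
        base = link(flat_m)
    base = base.reshape(P, R + 1)
    ppp = base[:, None, :] * (1.0 + rng.normal(0.0, 1.0, (P, K, R + 1)) * pressure_cv)

    participants = [f"P{i + 1:02d}" for i in range(P)]
    rows = []
    labels = list(REGIONS) + [GLOBAL]
    for p in range(P):
        for c in range(C):
            for k in range(K):
                vals = np.concatenate([strain[p, c, k], [g[p, c, k]]])
                for r, label in enumerate(labels):
                    rows.append((
                        participants[p], design.conditions[c], k + 1, label,
                        vals[r],
                        ppp[p, k, r] if c == ci else np.nan,
                    ))
    table = pd.DataFrame(rows, columns=[
        "participant", "condition", "repeat", "region", "peak_smag_pct", "ppp_kpa",
    ])
    table.attrs["design"] = dataclasses.asdict(design)
    table.attrs["pressure_condition"] = pc
    truth_out = {
        "effect_profile": profile,
        "participant_factor": pf,
        "pressure_base": pd.DataFrame(base, index=participants, columns=labels),
        "pressure_condition": pc,
        "target_rho": target_rho,
    }
    return table, truth_out
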