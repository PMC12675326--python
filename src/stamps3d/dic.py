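"""Subset-based stereo digital image correlation.

Matching uses the zero-normalised criterion (ZNCC / ZNSSD), which is
invariant to affine intensity changes, with an integer-pixel initial
search followed by inverse-compositional Gauss-Newton (IC-GN) refinement
of a first-order (affine) subset shape function on bicubic-interpolated
intensities.  Stereo correspondence at the reference and deformed states
is triangulated linearly (DLT) to produce a 3D displacement field on the
reference image grid.

Conventions: image coordinates are 0-based with a pixel-centre
convention; ``x`` is the column coordinate, ``y`` the row; displacements
are reported as ``(dx, dy)`` in pixels.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.feature import match_template

from .errors import (
    CorrelationFailure,
    DegenerateTriangulation,
    SubsetOutsideImage,
)
from .synthetic import CameraModel

__all__ = [
    "DicConfig",
    "MatchResult",
    "DisplacementField",
    "SplineImage",
    "match_subset",
    "stereo_triangulate",
    "triangulate_points",
    "run_stereo_dic",
    "reconstruct_surface",
    "roi_from_speckle",
]


@dataclass(frozen=True)
class DicConfig:
    """Correlation settings.  Everything is exposed: DIC parameters are
    tuned to the optics and speckle of a given rig, so nothing here is
    prescribed by the measurement principle itself.

    Attributes
    ----------
    subset_px : int
        Odd subset window size, >= 9.
    step_px : int
        Grid spacing of correlation nodes in the reference image.
    search_radius_px : int
        Half-width of the integer-pixel initial search.
    min_zncc : float
        Quality threshold; nodes below it are marked invalid.
    max_iterations : int
        IC-GN iteration cap.
    convergence_tol : float
        Threshold on the (subset-scaled) parameter-update norm.
    """

    subset_px: int = 21
    step_px: int = 10
    search_radius_px: int = 30
    min_zncc: float = 0.8
    max_iterations: int = 50
    convergence_tol: float = 1e-4

    def __post_init__(self):
        if self.subset_px < 9 or self.subset_px % 2 == 0:
            raise ValueError("subset_px must be odd and >= 9")
        if self.step_px < 1:
            raise ValueError("step_px must be >= 1")
        if not (0.0 < self.min_zncc < 1.0):
            raise ValueError("min_zncc must lie in (0, 1)")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


class SplineImage:
    """Image wrapped with a precomputed cubic-spline representation.

    ``sample`` evaluates bicubic-interpolated intensities at arbitrary
    (x, y); gradients are interpolated from centred-difference gradient
    images (adequate for IC-GN steepest-descent images).
    """

    def __init__(self, img: np.ndarray):
        self.img = np.asarray(img, dtype=np.float64)
        self.shape = self.img.shape
        self._coeffs = ndimage.spline_filter(self.img, order=3, mode="mirror")
        gy, gx = np.gradient(self.img)
        self._gx = gx
        self._gy = gy

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(self._coeffs, [y, x], order=3,
                                       prefilter=False, mode="mirror")

    def gradient_at(self, x: np.ndarray, y: np.ndarray):
        gx = ndimage.map_coordinates(self._gx, [y, x], order=1, mode="nearest")
        gy = ndimage.map_coordinates(self._gy, [y, x], order=1, mode="nearest")
        return gx, gy


@dataclass
class MatchResult:
    """Converged subset match: subpixel displacement, affine shape, quality."""

    displacement_px: np.ndarray  # (2,) = (dx, dy)
    shape_params: np.ndarray     # (6,) = (u, ux, uy, v, vx, vy)
    zncc: float
    converged: bool
    n_iterations: int


def _as_spline(img) -> SplineImage:
    return img if isinstance(img, SplineImage) else SplineImage(img)


def _subset_offsets(subset_px: int):
    m = subset_px // 2
    r = np.arange(-m, m + 1, dtype=np.float64)
    eta, xi = np.meshgrid(r, r, indexing="ij")
    return xi.ravel(), eta.ravel()


def _zncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _integer_search(ref: SplineImage, tgt: SplineImage, center, config) -> np.ndarray:
    """ZNCC-optimal integer displacement within the search radius."""
    cx, cy = int(round(center[0])), int(round(center[1]))
    m = config.subset_px // 2
    r = config.search_radius_px
    tpl = ref.img[cy - m:cy + m + 1, cx - m:cx + m + 1]
    y0 = max(cy - m - r, 0)
    x0 = max(cx - m - r, 0)
    y1 = min(cy + m + r + 1, tgt.shape[0])
    x1 = min(cx + m + r + 1, tgt.shape[1])
    win = tgt.img[y0:y1, x0:x1]
    if win.shape[0] < tpl.shape[0] or win.shape[1] < tpl.shape[1]:
        raise SubsetOutsideImage("subset outside image")
    score = match_template(win, tpl, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(score), score.shape)
    return np.array([x0 + ix + m - cx, y0 + iy + m - cy], dtype=float)


def _warp_matrix(p: np.ndarray) -> np.ndarray:
    u, ux, uy, v, vx, vy = p
    return np.array([[1.0 + ux, uy, u], [vx, 1.0 + vy, v], [0.0, 0.0, 1.0]])


def _matrix_params(M: np.ndarray) -> np.ndarray:
    return np.array([M[0, 2], M[0, 0] - 1.0, M[0, 1], M[1, 2], M[1, 0], M[1, 1] - 1.0])


def match_subset(
    ref_img,
    target_img,
    center_px,
    config: DicConfig = DicConfig(),
    init_guess: np.ndarray | None = None,
) -> MatchResult:
    """Match one speckle subset from a reference to a target image.

    If ``init_guess`` is None an integer ZNCC search within
    ``config.search_radius_px`` seeds the refinement; otherwise the guess
    ((2,) displacement or (6,) affine parameters) is used directly, which
    is how neighbour-propagated matching avoids redundant searches.
    IC-GN iterates until the subset-scaled update norm drops below
    ``convergence_tol``; the zero-update fixed point therefore returns the
    initial guess exactly (a self-match yields displacement exactly 0).
    """
    ref = _as_spline(ref_img)
    tgt = _as_spline(target_img)
    cx, cy = float(center_px[0]), float(center_px[1])
    m = config.subset_px // 2
    if (cx - m < 0 or cy - m < 0 or cx + m > ref.shape[1] - 1
            or cy + m > ref.shape[0] - 1):
        raise SubsetOutsideImage("subset outside image")

    xi, eta = _subset_offsets(config.subset_px)
    fx_coords = cx + xi
    fy_coords = cy + eta
    f = ref.sample(fx_coords, fy_coords)
    fbar = f.mean()
    f0 = f - fbar
    nf = np.linalg.norm(f0)
    if nf == 0.0:
        return MatchResult(np.zeros(2), np.zeros(6), 0.0, False, 0)

    gx, gy = ref.gradient_at(fx_coords, fy_coords)
    J = np.column_stack([gx, gx * xi, gx * eta, gy, gy * xi, gy * eta])
    H = J.T @ J
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return MatchResult(np.zeros(2), np.zeros(6), 0.0, False, 0)

    if init_guess is None:
        d0 = _integer_search(ref, tgt, (cx, cy), config)
        p = np.array([d0[0], 0.0, 0.0, d0[1], 0.0, 0.0])
    else:
        g = np.asarray(init_guess, dtype=float).ravel()
        p = np.array([g[0], 0.0, 0.0, g[1], 0.0, 0.0]) if g.size == 2 else g.copy()

    M = _warp_matrix(p)
    scale = np.array([1.0, m, m, 1.0, m, m])
    converged = False
    n_it = 0
    zncc = 0.0
    for n_it in range(1, config.max_iterations + 1):
        p = _matrix_params(M)
        x = cx + p[0] + (1.0 + p[1]) * xi + p[2] * eta
        y = cy + p[3] + p[4] * xi + (1.0 + p[5]) * eta
        if (x.min() < 0 or y.min() < 0 or x.max() > tgt.shape[1] - 1
                or y.max() > tgt.shape[0] - 1):
            break
        g = tgt.sample(x, y)
        g0 = g - g.mean()
        ng = np.linalg.norm(g0)
        if ng == 0.0:
            break
        zncc = float(np.dot(f0, g0) / (nf * ng))
        e = (nf / ng) * g0 - f0
        dp = Hinv @ (J.T @ e)
        if np.linalg.norm(dp * scale) < config.convergence_tol:
            converged = True
            break
        M = M @ np.linalg.inv(_warp_matrix(dp))
    p = _matrix_params(M)
    return MatchResult(np.array([p[0], p[3]]), p, zncc, converged, n_it)


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

def _triangulate_dlt(pts1: np.ndarray, pts2: np.ndarray,
                     P1: np.ndarray, P2: np.ndarray) -> np.ndarray:
    """Vectorised linear (DLT) triangulation of paired pixel observations."""
    n = len(pts1)
    A = np.empty((n, 4, 4))
    A[:, 0] = pts1[:, 0, None] * P1[2] - P1[0]
    A[:, 1] = pts1[:, 1, None] * P1[2] - P1[1]
    A[:, 2] = pts2[:, 0, None] * P2[2] - P2[0]
    A[:, 3] = pts2[:, 1, None] * P2[2] - P2[1]
    _, _, Vt = np.linalg.svd(A)
    X = Vt[:, 3, :]
    return X[:, :3] / X[:, 3:4]


def _check_geometry(cam1: CameraModel, cam2: CameraModel):
    baseline = np.linalg.norm(cam1.center_mm - cam2.center_mm)
    if baseline < 1e-9:
        raise DegenerateTriangulation("degenerate triangulation: zero baseline")


def stereo_triangulate(pt_cam1_px, pt_cam2_px, cam1: CameraModel,
                       cam2: CameraModel,
                       min_ray_angle_deg: float = 0.05):
    """Triangulate one correspondence; returns (3D point mm, mean reprojection error px).

    Raises
    ------
    DegenerateTriangulation
        For a zero baseline or near-parallel rays.
    """
    _check_geometry(cam1, cam2)
    p1 = np.asarray(pt_cam1_px, dtype=float).reshape(1, 2)
    p2 = np.asarray(pt_cam2_px, dtype=float).reshape(1, 2)
    _, d1 = cam1.pixel_rays(p1[:, 0], p1[:, 1])
    _, d2 = cam2.pixel_rays(p2[:, 0], p2[:, 1])
    cosang = np.dot(d1[0] / np.linalg.norm(d1[0]), d2[0] / np.linalg.norm(d2[0]))
    if np.degrees(np.arccos(np.clip(abs(cosang), 0.0, 1.0))) < min_ray_angle_deg:
        raise DegenerateTriangulation("degenerate triangulation: near-parallel rays")
    X = _triangulate_dlt(p1, p2, cam1.projection_matrix, cam2.projection_matrix)
    err = 0.5 * (np.linalg.norm(cam1.project(X) - p1)
                 + np.linalg.norm(cam2.project(X) - p2))
    return X[0], float(err)


def triangulate_points(pts1: np.ndarray, pts2: np.ndarray,
                       cam1: CameraModel, cam2: CameraModel):
    """Vectorised DLT for (N, 2) correspondences; returns ((N, 3), (N,) errors)."""
    _check_geometry(cam1, cam2)
    pts1 = np.atleast_2d(np.asarray(pts1, dtype=float))
    pts2 = np.atleast_2d(np.asarray(pts2, dtype=float))
    X = _triangulate_dlt(pts1, pts2, cam1.projection_matrix, cam2.projection_matrix)
    err = 0.5 * (np.linalg.norm(cam1.project(X) - pts1, axis=1)
                 + np.linalg.norm(cam2.project(X) - pts2, axis=1))
    return X, err


# ---------------------------------------------------------------------------
# Grid DIC driver
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    """3D displacement field on the reference image grid.

    Per node: the reference-image pixel position, the triangulated 3D
    reference coordinate (mm), the 3D displacement (mm), the temporal and
    stereo correlation qualities and a validity flag.  Invalid nodes carry
    NaN coordinates/displacements and are never interpolated.
    """

    node_px: np.ndarray        # (N, 2) grid positions in the reference image
    grid_shape: tuple[int, int]
    ref_points_3d: np.ndarray  # (N, 3) mm
    displacements_3d: np.ndarray  # (N, 3) mm
    zncc_time: np.ndarray
    zncc_stereo: np.ndarray
    valid: np.ndarray
    config: DicConfig
    roi_mask: np.ndarray | None = None  # nodes inside the ROI
    step_mm: float = field(default=float("nan"))

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @property
    def invalid_fraction(self) -> float:
        """Fraction of ROI nodes that failed correlation."""
        n_roi = int(np.count_nonzero(self.roi_mask)) if self.roi_mask is not None \
            else len(self.valid)
        return 1.0 - self.n_valid / max(n_roi, 1)


def roi_from_speckle(img: np.ndarray, std_threshold: float = 8.0,
                     window: int = 15) -> np.ndarray:
    """Boolean mask of speckled (textured) pixels, eroded away from the edge.

    Used when no ROI polygon is supplied: the uniform background has zero
    local contrast, the speckled insole has high local contrast.
    """
    f = np.asarray(img, dtype=np.float64)
    mean = ndimage.uniform_filter(f, window)
    sq = ndimage.uniform_filter(f * f, window)
    std = np.sqrt(np.maximum(sq - mean**2, 0.0))
    mask = std > std_threshold
    mask = ndimage.binary_closing(mask, iterations=2)
    mask = ndimage.binary_erosion(mask, iterations=window)
    return mask


def _grid_nodes(shape, config: DicConfig, roi, margin: int):
    ny, nx = shape
    xs = np.arange(margin, nx - margin, config.step_px)
    ys = np.arange(margin, ny - margin, config.step_px)
    GX, GY = np.meshgrid(xs, ys, indexing="xy")
    pts = np.column_stack([GX.ravel(), GY.ravel()]).astype(float)
    if isinstance(roi, Polygon):
        keep = shapely.contains_xy(roi, pts[:, 0], pts[:, 1])
    elif roi is not None:
        keep = roi[pts[:, 1].astype(int), pts[:, 0].astype(int)]
    else:
        keep = np.ones(len(pts), dtype=bool)
    return pts, keep.reshape(GY.shape), (len(ys), len(xs))


def _propagate_matches(ref: SplineImage, tgt: SplineImage, nodes: np.ndarray,
                       keep: np.ndarray, grid_shape, config: DicConfig,
                       seed_candidates=None):
    """BFS neighbour-guided matching over the node grid.

    The start node is the highest-ZNCC full-search match among a handful
    of candidate seeds; every other node is initialised from its
    already-matched BFS parent (displacement + shape), so only seeds pay
    for an integer search.  Deterministic: ties broken by grid index.
    """
    ny, nx = grid_shape
    n = len(nodes)
    disp = np.full((n, 2), np.nan)
    shape_p = np.zeros((n, 6))
    zncc = np.zeros(n)
    done = np.zeros(n, dtype=bool)
    ok = np.zeros(n, dtype=bool)

    flat_keep = keep.ravel()
    candidates = []
    if seed_candidates is None:
        idxs = np.flatnonzero(flat_keep)
        if idxs.size == 0:
            return disp, shape_p, zncc, ok
        center = nodes[idxs].mean(axis=0)
        order = np.argsort(np.linalg.norm(nodes[idxs] - center, axis=1))
        seed_candidates = idxs[order[:5]]
    for i in seed_candidates:
        try:
            r = match_subset(ref, tgt, nodes[i], config, init_guess=None)
        except SubsetOutsideImage:
            continue
        candidates.append((r.zncc, i, r))
    if not candidates:
        return disp, shape_p, zncc, ok
    candidates.sort(key=lambda t: (-t[0], t[1]))
    best_z, best_i, best_r = candidates[0]

    queue = deque([(best_i, best_r)])
    disp[best_i] = best_r.displacement_px
    shape_p[best_i] = best_r.shape_params
    zncc[best_i] = best_r.zncc
    done[best_i] = True
    ok[best_i] = best_r.converged and best_r.zncc >= config.min_zncc

    def neighbours(i):
        iy, ix = divmod(i, nx)
        for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            jy, jx = iy + dy, ix + dx
            if 0 <= jy < ny and 0 <= jx < nx:
                j = jy * nx + jx
                if flat_keep[j] and not done[j]:
                    yield j

    while queue:
        i, ri = queue.popleft()
        for j in neighbours(i):
            done[j] = True
            try:
                rj = match_subset(ref, tgt, nodes[j], config,
                                  init_guess=ri.shape_params)
                if not rj.converged or rj.zncc < config.min_zncc:
                    rj2 = match_subset(ref, tgt, nodes[j], config, init_guess=None)
                    if rj2.zncc > rj.zncc:
                        rj = rj2
            except SubsetOutsideImage:
                continue
            disp[j] = rj.displacement_px
            shape_p[j] = rj.shape_params
            zncc[j] = rj.zncc
            ok[j] = rj.converged and rj.zncc >= config.min_zncc
            if ok[j]:
                queue.append((j, rj))
    return disp, shape_p, zncc, ok


def _match_at_points(ref: SplineImage, tgt: SplineImage, points: np.ndarray,
                     init: np.ndarray, config: DicConfig):
    """Match subsets at arbitrary (float) centres with per-point init guesses."""
    n = len(points)
    disp = np.full((n, 2), np.nan)
    zncc = np.zeros(n)
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        if not np.all(np.isfinite(points[i])) or not np.all(np.isfinite(init[i])):
            continue
        try:
            r = match_subset(ref, tgt, points[i], config, init_guess=init[i])
        except SubsetOutsideImage:
            continue
        disp[i] = r.displacement_px
        zncc[i] = r.zncc
        ok[i] = r.converged and r.zncc >= config.min_zncc
    return disp, zncc, ok


def reconstruct_surface(pre1, pre2, cam1: CameraModel, cam2: CameraModel,
                        config: DicConfig = DicConfig(), roi=None):
    """Stereo-match a reference pair and triangulate the surface.

    Returns (node_px, points_3d, zncc_stereo, valid, grid_shape); used both
    standalone (shape measurement) and as the first stage of
    :func:`run_stereo_dic`.
    """
    ref = _as_spline(pre1)
    tgt = _as_spline(pre2)
    if roi is None:
        roi = roi_from_speckle(ref.img)
    margin = config.subset_px // 2 + 2
    nodes, keep, grid_shape = _grid_nodes(ref.shape, config, roi, margin)
    disp, _, zncc, ok = _propagate_matches(ref, tgt, nodes, keep, grid_shape, config)
    pts3 = np.full((len(nodes), 3), np.nan)
    if ok.any():
        X, _ = triangulate_points(nodes[ok], nodes[ok] + disp[ok], cam1, cam2)
        pts3[ok] = X
    return nodes, pts3, zncc, ok, grid_shape


def run_stereo_dic(
    pre1, pre2, post1, post2,
    cam1: CameraModel, cam2: CameraModel,
    config: DicConfig = DicConfig(),
    roi=None,
    min_valid_fraction: float = 0.5,
) -> DisplacementField:
    """Full stereo-DIC of a pre/post image quartet.

    Seeds a node grid inside the ROI on ``pre1``, matches
    pre1→pre2 (stereo at reference), pre1→post1 (temporal) and
    post1→post2 (stereo at the deformed state, initialised from the
    reference disparity), triangulates both states and reports
    ``deformed 3D - reference 3D`` per node.  Nodes failing quality are
    flagged invalid and carried as missing downstream.

    Raises
    ------
    CorrelationFailure
        If fewer than ``min_valid_fraction`` of ROI nodes are valid; the
        exception carries a per-node quality map for diagnosis.
    """
    imgs = [np.asarray(i.img if isinstance(i, SplineImage) else i) for i in
            (pre1, pre2, post1, post2)]
    if len({im.shape for im in imgs}) != 1:
        raise ValueError("all four images must share dimensions")
    s_pre1, s_pre2, s_post1, s_post2 = (_as_spline(i) for i in (pre1, pre2, post1, post2))

    if roi is None:
        roi = roi_from_speckle(s_pre1.img)
    margin = config.subset_px // 2 + 2
    nodes, keep, grid_shape = _grid_nodes(s_pre1.shape, config, roi, margin)
    flat_keep = keep.ravel()

    # stereo at reference
    d_st, p_st, z_st_ref, ok_st = _propagate_matches(
        s_pre1, s_pre2, nodes, keep, grid_shape, config)
    # temporal pre1 -> post1
    d_t, p_t, z_t, ok_t = _propagate_matches(
        s_pre1, s_post1, nodes, keep, grid_shape, config)
    # stereo at deformed state: subset centres follow the temporal match,
    # disparity initialised from the reference disparity
    centers = nodes + d_t
    d_st2, z_st2, ok_st2 = _match_at_points(s_pre2, s_post2,
                                            nodes + d_st,
                                            d_t, config)

    valid = ok_st & ok_t & ok_st2 & flat_keep
    ref3 = np.full((len(nodes), 3), np.nan)
    dsp3 = np.full((len(nodes), 3), np.nan)
    if valid.any():
        Xr, _ = triangulate_points(nodes[valid], nodes[valid] + d_st[valid],
                                   cam1, cam2)
        Xd, _ = triangulate_points(centers[valid],
                                   nodes[valid] + d_st[valid] + d_st2[valid],
                                   cam1, cam2)
        ref3[valid] = Xr
        dsp3[valid] = Xd - Xr

    zncc_stereo = np.minimum(z_st_ref, z_st2)
    n_roi = int(np.count_nonzero(flat_keep))
    field_ = DisplacementField(
        node_px=nodes, grid_shape=grid_shape, ref_points_3d=ref3,
        displacements_3d=dsp3, zncc_time=z_t, zncc_stereo=zncc_stereo,
        valid=valid, config=config, roi_mask=flat_keep.copy(),
    )
    if valid.any():
        vpts = ref3[valid]
        if len(vpts) > 1:
            field_.step_mm = float(np.median(
                np.linalg.norm(np.diff(vpts[np.argsort(vpts[:, 0])], axis=0), axis=1)))
    if n_roi == 0 or np.count_nonzero(valid) < min_valid_fraction * n_roi:
        raise CorrelationFailure(
            f"correlation failure: {np.count_nonzero(valid)}/{n_roi} nodes valid",
            quality_map={"node_px": nodes, "zncc_time": z_t,
                         "zncc_stereo": zncc_stereo, "valid": valid},
        )
    return field_
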