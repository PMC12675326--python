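"""Surface strain measures in an anatomically aligned frame.

From a 3D displacement field sampled on the insole surface, a local
deformation gradient is fitted per node by Gaussian-weighted least
squares over its neighbourhood, restricted to the reference tangent
plane.  The Green-Lagrange tensor ``E = (F^T F - I) / 2`` is expressed
on tangent directions aligned with the anatomical anterior-posterior
(AP) and medio-lateral (ML) axes, yielding the six reported measures:

* ``S_ANT``/``S_POST`` — tensile/compressive part of the AP normal strain (%)
* ``S_MED``/``S_LAT`` — tensile/compressive part of the ML normal strain (%)
* ``S_Z`` — out-of-plane component, normal displacement over the layer
  thickness, positive for indentation (dimensionless)
* ``S_MAG`` — scalar magnitude (%),
  ``100 * sqrt(E_ap^2 + E_ml^2 + 2 E_shear^2 + S_Z^2)``, unbounded above.

Because the fit maps reference tangent coordinates to full 3D deformed
offsets, rigid motions carry (to neighbourhood truncation error) no
strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .errors import AmbiguousOrientation, EmptyStrainField
from .synthetic import smag_percent

__all__ = [
    "AnatomicalFrame",
    "StrainField",
    "fit_anatomical_frame",
    "compute_surface_strain",
    "bracket_map",
    "DEFAULT_BRACKET_EDGES",
    "BRACKET_COLORS",
]

#: Strain brackets (%) used for absolute strain maps; the last is open above.
DEFAULT_BRACKET_EDGES: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0)
BRACKET_COLORS: tuple[str, ...] = ("blue", "green", "yellow", "magenta", "red")


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame on the insole plane.

    ``ap_axis`` points anterior (toward the toes), ``ml_axis`` medial,
    ``normal_axis`` out of the insole plane away from it (toward the
    foot).  For left feet the ML axis flips so "medial" remains
    anatomically correct.
    """

    origin: np.ndarray
    ap_axis: np.ndarray
    ml_axis: np.ndarray
    normal_axis: np.ndarray
    side: str = "right"

    def __post_init__(self):
        for name in ("origin", "ap_axis", "ml_axis", "normal_axis"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float).reshape(3))
        M = np.vstack([self.ap_axis, self.ml_axis, self.normal_axis])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-8):
            raise ValueError("frame axes must be mutually orthonormal")

    def ap_ml_coords(self, points: np.ndarray) -> np.ndarray:
        """Project (N, 2|3) points to (N, 2) anatomical (AP, ML) coordinates."""
        P = np.atleast_2d(np.asarray(points, dtype=float))
        if P.shape[1] == 2:
            P = np.column_stack([P, np.zeros(len(P))])
        rel = P - self.origin
        return np.column_stack([rel @ self.ap_axis, rel @ self.ml_axis])


def _outline_vertices(outline) -> np.ndarray:
    if isinstance(outline, Polygon):
        v = np.asarray(outline.exterior.coords)[:-1]
    else:
        v = np.asarray(outline, dtype=float)
    if v.shape[1] == 2:
        v = np.column_stack([v, np.zeros(len(v))])
    return v


def fit_anatomical_frame(outline, side: str = "right",
                         heel_end_hint=None) -> AnatomicalFrame:
    """Fit the anatomical frame to an insole outline.

    The AP axis is the principal (largest-variance) axis of the outline
    vertices; anterior is the end where the outline is wider (a foot is
    widest at the forefoot), overridable with ``heel_end_hint`` (a point
    near the heel).  ML is ``normal x AP`` for right feet and its negation
    for left feet, so medial is positive on both sides.

    Raises
    ------
    AmbiguousOrientation
        If the outline is near-circular (principal-axis extent ratio
        < 1.2) and no hint is given.
    """
    v = _outline_vertices(outline)
    centroid = v.mean(axis=0)
    rel = v - centroid
    # principal axes in-plane; outline normal fixed to +z
    cov = np.cov(rel[:, :2].T)
    w, vec = np.linalg.eigh(cov)
    ap2 = vec[:, np.argmax(w)]
    ap = np.array([ap2[0], ap2[1], 0.0])
    normal = np.array([0.0, 0.0, 1.0])

    t = rel[:, :2] @ ap2
    perp = rel[:, :2] @ np.array([-ap2[1], ap2[0]])
    t_lo, t_hi = t.min(), t.max()
    extent = t_hi - t_lo
    perp_extent = perp.max() - perp.min()
    if extent < 1.2 * perp_extent and heel_end_hint is None:
        raise AmbiguousOrientation("ambiguous orientation: outline near-circular")

    if heel_end_hint is not None:
        hint = np.asarray(heel_end_hint, dtype=float)
        th = (hint[:2] - centroid[:2]) @ ap2
        anterior_positive = th < (t_lo + t_hi) / 2.0
    else:
        band = 0.25 * extent
        w_hi = np.ptp(perp[t > t_hi - band])
        w_lo = np.ptp(perp[t < t_lo + band])
        anterior_positive = w_hi >= w_lo
    if not anterior_positive:
        ap = -ap
    ml = np.cross(normal, ap)
    if side == "left":
        ml = -ml
    return AnatomicalFrame(origin=centroid, ap_axis=ap, ml_axis=ml,
                           normal_axis=normal, side=side)


@dataclass
class StrainField:
    """Per-node strain measures on the reference surface.

    ``E_ap``/``E_ml``/``E_shear`` are dimensionless in-plane
    Green-Lagrange components in the anatomical frame; ``S_Z`` is
    dimensionless; the directional measures and ``S_MAG`` are percent.
    Invalid nodes carry NaN everywhere and ``valid=False``.
    """

    points: np.ndarray  # (N, 3) reference coordinates (mm)
    E_ap: np.ndarray
    E_ml: np.ndarray
    E_shear: np.ndarray
    S_Z: np.ndarray
    S_ANT: np.ndarray
    S_POST: np.ndarray
    S_MED: np.ndarray
    S_LAT: np.ndarray
    S_MAG: np.ndarray
    valid: np.ndarray
    frame: AnatomicalFrame
    thickness_mm: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
            "E_ap": self.E_ap, "E_ml": self.E_ml, "E_shear": self.E_shear,
            "S_Z": self.S_Z, "S_ANT": self.S_ANT, "S_POST": self.S_POST,
            "S_MED": self.S_MED, "S_LAT": self.S_LAT, "S_MAG": self.S_MAG,
            "valid": self.valid,
        })
        return df


def compute_surface_strain(
    field,
    frame: AnatomicalFrame,
    thickness_mm: float = 5.0,
    neighborhood_radius_mm: float | None = None,
    radius_factor: float = 2.5,
    min_neighbors: int = 3,
) -> StrainField:
    """Fit per-node surface strain from a :class:`~stamps3d.dic.DisplacementField`.

    Per valid node, neighbours within ``neighborhood_radius_mm`` (default
    ``radius_factor`` x the median node spacing) enter a Gaussian-weighted
    least-squares fit of the 3x2 tangent deformation gradient; nodes with
    fewer than ``min_neighbors`` non-collinear neighbours are marked
    invalid.  ``field`` may be any object with ``ref_points_3d``,
    ``displacements_3d`` and ``valid`` attributes.
    """
    pts = np.asarray(field.ref_points_3d, dtype=float)
    disp = np.asarray(field.displacements_3d, dtype=float)
    valid_in = np.asarray(field.valid, dtype=bool)
    n = len(pts)
    if not valid_in.any():
        raise EmptyStrainField("empty strain field: no valid displacement nodes")

    vpts = pts[valid_in]
    vdisp = disp[valid_in]
    tree = cKDTree(vpts)
    if neighborhood_radius_mm is None:
        d, _ = tree.query(vpts, k=min(2, len(vpts)))
        spacing = float(np.median(d[:, -1])) if len(vpts) > 1 else 1.0
        neighborhood_radius_mm = radius_factor * spacing
    sigma = neighborhood_radius_mm / 2.0

    out = {k: np.full(n, np.nan) for k in
           ("E_ap", "E_ml", "E_shear", "S_Z", "S_ANT", "S_POST",
            "S_MED", "S_LAT", "S_MAG")}
    valid_out = np.zeros(n, dtype=bool)
    idx_map = np.flatnonzero(valid_in)
    neigh_lists = tree.query_ball_point(vpts, neighborhood_radius_mm)

    for vi, neigh in enumerate(neigh_lists):
        i = idx_map[vi]
        neigh = [j for j in neigh if j != vi]
        if len(neigh) < min_neighbors:
            continue
        dref = vpts[neigh] - vpts[vi]
        ddef = dref + (vdisp[neigh] - vdisp[vi])
        w = np.exp(-0.5 * np.sum(dref**2, axis=1) / sigma**2)

        # local tangent basis: weighted-PCA normal, AP/ML-aligned axes
        Wd = dref * w[:, None]
        C3 = Wd.T @ dref
        ew, ev = np.linalg.eigh(C3)
        n_loc = ev[:, 0]
        if n_loc @ frame.normal_axis < 0:
            n_loc = -n_loc
        if ew[1] < 1e-12 * max(ew[2], 1e-30):  # collinear neighbourhood
            continue
        e1 = frame.ap_axis - (frame.ap_axis @ n_loc) * n_loc
        nrm = np.linalg.norm(e1)
        if nrm < 1e-9:
            continue
        e1 /= nrm
        e2 = np.cross(n_loc, e1)
        if e2 @ frame.ml_axis < 0:
            e2 = -e2

        xi = np.column_stack([dref @ e1, dref @ e2])
        Aw = xi * w[:, None]
        G = Aw.T @ xi
        try:
            F = np.linalg.solve(G, Aw.T @ ddef).T  # (3, 2) tangent gradient
        except np.linalg.LinAlgError:
            continue
        Cm = F.T @ F
        E = 0.5 * (Cm - np.eye(2))
        e_ap, e_ml, e_sh = E[0, 0], E[1, 1], E[0, 1]
        s_z = -(vdisp[vi] @ n_loc) / thickness_mm
        out["E_ap"][i] = e_ap
        out["E_ml"][i] = e_ml
        out["E_shear"][i] = e_sh
        out["S_Z"][i] = s_z
        out["S_ANT"][i] = 100.0 * max(e_ap, 0.0)
        out["S_POST"][i] = 100.0 * max(-e_ap, 0.0)
        out["S_MED"][i] = 100.0 * max(e_ml, 0.0)
        out["S_LAT"][i] = 100.0 * max(-e_ml, 0.0)
        out["S_MAG"][i] = smag_percent(e_ap, e_ml, e_sh, s_z)
        valid_out[i] = True

    if not valid_out.any():
        raise EmptyStrainField("empty strain field: no node had enough neighbours")
    return StrainField(points=pts, valid=valid_out, frame=frame,
                       thickness_mm=thickness_mm, **out)


def bracket_map(strain: StrainField | np.ndarray,
                edges: tuple[float, ...] = DEFAULT_BRACKET_EDGES):
    """Assign each valid node to a half-open strain bracket ``[lo, hi)``.

    Returns ``(labels, fractions)``: per-node bracket index (-1 for
    invalid nodes) and the area fraction of valid nodes per bracket
    (summing to 1).  The last bracket is open above.
    """
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bracket edges must be strictly increasing")
    if isinstance(strain, StrainField):
        values = strain.S_MAG
        valid = strain.valid
    else:
        values = np.asarray(strain, dtype=float)
        valid = np.isfinite(values)
    if not valid.any():
        raise EmptyStrainField("empty strain field")
    labels = np.full(len(values), -1, dtype=int)
    labels[valid] = np.clip(np.digitize(values[valid], edges[1:], right=False),
                            0, len(edges) - 1)
    counts = np.bincount(labels[valid], minlength=len(edges))
    fractions = counts / counts.sum()
    return labels, fractions


def bracket_names(edges: tuple[float, ...] = DEFAULT_BRACKET_EDGES) -> list[str]:
    """Human-readable bracket names, e.g. '2.5-5%', '>10%'."""
    names = [f"{lo:g}-{hi:g}%" for lo, hi in zip(edges, edges[1:])]
    names.append(f">{edges[-1]:g}%")
    return names[: len(edges)]
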