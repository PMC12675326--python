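"""Readers/writers, configuration and run manifests.

All tables are UTF-8 comma-separated CSV with '.' decimals; images are
8-bit PNG/TIFF; metadata is JSON with ISO dates.  Every write is atomic
(write to a temporary file in the target directory, then rename), so a
crashed run never leaves a half-written artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dic import DicConfig, DisplacementField
from .errors import InvalidPressure
from .regions import canonical_region
from .strain import StrainField

__all__ = [
    "PipelineConfig",
    "atomic_write_bytes",
    "write_text",
    "write_image",
    "read_image",
    "write_csv",
    "write_json",
    "config_hash",
    "load_config",
    "read_pressure_csv",
    "write_displacement_field",
    "read_displacement_field",
    "write_strain_field",
]


# ---------------------------------------------------------------------------
# Atomic primitives
# ---------------------------------------------------------------------------

def atomic_write_bytes(path: os.PathLike, data: bytes) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):  # pragma: no cover - only on failure
            os.unlink(tmp)
    return path


def write_text(path, text: str) -> Path:
    return atomic_write_bytes(path, text.encode("utf-8"))


def write_csv(path, df: pd.DataFrame, float_format: str = "%.9g") -> Path:
    return write_text(path, df.to_csv(index=False, float_format=float_format))


def write_json(path, obj) -> Path:
    return write_text(path, json.dumps(obj, indent=2, sort_keys=True,
                                       default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_image(path, img: np.ndarray) -> Path:
    path = Path(path)
    buf = iio.imwrite("<bytes>", np.asarray(img),
                      extension=path.suffix or ".png")
    return atomic_write_bytes(path, buf)


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) renders of grayscale content
        img = img[..., :3].mean(axis=2)
    return np.asarray(img)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpeckleSection(_Strict):
    dot_density: float = 0.65
    dot_diameter_mm: float = 2.2
    diameter_variation: float = 0.5
    mm_per_px: float = 0.35
    dark_on_light: bool = True


class InsoleSection(_Strict):
    length_mm: float = 260.0
    width_mm: float = 95.0
    contoured: bool = False
    arch_height_mm: float = 0.0
    side: Literal["left", "right"] = "right"
    thickness_mm: float = 5.0


class CameraSection(_Strict):
    image_width_px: int = 640
    image_height_px: int = 400
    standoff_mm: float = 400.0
    vergence_deg: float = 15.0


class RenderSection(_Strict):
    background: int = 80
    supersample: int = 2
    n_rendered_trials: int = 1
    bump_radius_mm: float = 12.0
    bump_scale: float = 0.05  # peak indentation mm per % of true regional strain


class DicSection(_Strict):
    subset_px: int = 21
    step_px: int = 12
    search_radius_px: int = 30
    min_zncc: float = 0.8
    max_iterations: int = 50
    convergence_tol: float = 1e-4

    def to_config(self) -> DicConfig:
        return DicConfig(**self.model_dump())


class StrainSection(_Strict):
    radius_factor: float = 2.5
    neighborhood_radius_mm: float | None = None


class MaskSection(_Strict):
    heel_band: tuple[float, float] = (0.0, 0.27)
    midfoot_band: tuple[float, float] = (0.27, 0.55)
    mth_band: tuple[float, float] = (0.55, 0.73)
    toe_band: tuple[float, float] = (0.73, 1.0)
    midfoot_medial_width: float = 0.45
    mth_widths: tuple[float, ...] = (0.30, 0.20, 0.175, 0.175, 0.15)
    toe_widths: tuple[float, float, float] = (0.35, 0.20, 0.45)


class StudySection(_Strict):
    n_participants: int = 5
    conditions: tuple[str, ...] = ("low_stiffness", "high_stiffness", "flat")
    n_repeats: int = 3
    noise_cv: float = 0.23
    target_rho: float | None = 0.5
    pressure_cv: float = 0.05
    between_participant_sd: float = 0.0
    effect_profile: dict[str, dict[str, float]] | None = None


class PipelineConfig(_Strict):
    """Complete nested configuration of a pipeline run.

    Unknown keys anywhere are rejected.  A resolved copy plus its content
    hash is written next to every run's outputs.
    """

    seed: int = 0
    output_dir: str = "stamps3d_run"
    speckle: SpeckleSection = Field(default_factory=SpeckleSection)
    insole: InsoleSection = Field(default_factory=InsoleSection)
    cameras: CameraSection = Field(default_factory=CameraSection)
    render: RenderSection = Field(default_factory=RenderSection)
    dic: DicSection = Field(default_factory=DicSection)
    strain: StrainSection = Field(default_factory=StrainSection)
    mask: MaskSection = Field(default_factory=MaskSection)
    study: StudySection = Field(default_factory=StudySection)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def dump_config(config: PipelineConfig, path) -> Path:
    return write_text(path, yaml.safe_dump(config.model_dump(mode="json"),
                                           sort_keys=True))


# ---------------------------------------------------------------------------
# Pressure tables
# ---------------------------------------------------------------------------

def read_pressure_csv(path) -> pd.DataFrame:
    """Read a Pedar-style regional peak-pressure table.

    Expects a header naming regions (synonyms such as '1st MTH' / 'MTH1'
    are normalised) and optionally a 'participant' column.  Values are
    kPa.  Missing cells stay missing (never zero); unknown region columns
    and negative pressures are errors.
    """
    df = pd.read_csv(path)
    id_cols = [c for c in df.columns
               if c.strip().lower() in ("participant", "subject", "id",
                                        "condition", "repeat", "source")]
    region_cols = [c for c in df.columns if c not in id_cols]
    mapping = {c: canonical_region(c) for c in region_cols}  # raises UnmappedRegion
    out = df.rename(columns=mapping)
    out.columns = [c.strip().lower() if c in id_cols else c for c in out.columns]
    vals = out[[mapping[c] for c in region_cols]]
    if (vals.to_numpy(dtype=float) < 0).any():
        raise InvalidPressure("invalid pressure: negative value in table")
    long = out.melt(id_vars=[c for c in out.columns if c not in set(mapping.values())],
                    var_name="region", value_name="ppp_kpa")
    return long.dropna(subset=["ppp_kpa"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Field tables
# ---------------------------------------------------------------------------

def displacement_to_frame(field: DisplacementField) -> pd.DataFrame:
    return pd.DataFrame({
        "node_id": np.arange(len(field.valid)),
        "u_px": field.node_px[:, 0], "v_px": field.node_px[:, 1],
        "X_mm": field.ref_points_3d[:, 0], "Y_mm": field.ref_points_3d[:, 1],
        "Z_mm": field.ref_points_3d[:, 2],
        "dX_mm": field.displacements_3d[:, 0],
        "dY_mm": field.displacements_3d[:, 1],
        "dZ_mm": field.displacements_3d[:, 2],
        "zncc_time": field.zncc_time, "zncc_stereo": field.zncc_stereo,
        "valid": field.valid.astype(int),
    })


def write_displacement_field(path, field: DisplacementField) -> Path:
    return write_csv(path, displacement_to_frame(field))


def read_displacement_field(path, config: DicConfig | None = None) -> DisplacementField:
    df = pd.read_csv(path)
    n = len(df)
    return DisplacementField(
        node_px=df[["u_px", "v_px"]].to_numpy(float),
        grid_shape=(n, 1),
        ref_points_3d=df[["X_mm", "Y_mm", "Z_mm"]].to_numpy(float),
        displacements_3d=df[["dX_mm", "dY_mm", "dZ_mm"]].to_numpy(float),
        zncc_time=df["zncc_time"].to_numpy(float),
        zncc_stereo=df["zncc_stereo"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        config=config or DicConfig(),
    )


def write_strain_field(path, strain: StrainField,
                       region_labels: np.ndarray | None = None) -> Path:
    df = strain.to_frame()
    if region_labels is not None:
        df["region"] = region_labels
    return write_csv(path, df)
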