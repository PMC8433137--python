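"""File formats and configuration: landmarks, transforms, meshes, DICOM headers.

All tabular formats are plain text (UTF-8, comma separator, '.' decimal):

* landmark CSV with header ``label,x,y,z,frame`` (mm), or equivalent JSON;
* transform JSON with keys ``matrix`` (16 numbers, row-major), ``from_frame``,
  ``to_frame``, ``rigid``;
* study records CSV as produced by the simulator / TRE pipeline.

DICOM reads are header-only (pixel data is never loaded): only the geometry
tags Image Position Patient (0020,0032), Image Orientation Patient
(0020,0037) and Pixel Spacing (0028,0030) are used, with slice spacing taken
from inter-slice position distances when a series directory is given.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .geometry import (
    BL_IMAGE,
    DRF,
    DicomGeometry,
    Frame,
    GeometryError,
    IPS_IMAGE,
    LandmarkSet,
    PATIENT,
    Transform,
    VOXEL,
)
from .registration import SurfaceModel
from .simulator import NoiseModel, StudyDesign

__all__ = [
    "FileFormatError",
    "frame_by_name",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "read_records",
    "write_records",
    "load_surface",
    "save_surface",
    "read_dicom_geometry",
    "StudyConfig",
]

_BUILTIN_FRAMES = {f.name: f for f in (PATIENT, DRF, IPS_IMAGE, BL_IMAGE, VOXEL)}


class FileFormatError(ValueError):
    """Raised for malformed input files; message carries the line number."""


def frame_by_name(name: str) -> Frame:
    """Resolve a frame name against the built-in vocabulary, else user-defined."""
    return _BUILTIN_FRAMES.get(name, Frame(name))


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark set from CSV (``label,x,y,z,frame``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return LandmarkSet(
            data["labels"], np.asarray(data["coordinates"], dtype=float),
            frame_by_name(data["frame"]),
        )
    labels: list[str] = []
    coords: list[list[float]] = []
    frames: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:5]] != ["label", "x", "y", "z", "frame"]:
            raise FileFormatError(f"{path}:1: expected header 'label,x,y,z,frame'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 5 or any(not c.strip() for c in row[:5]):
                raise FileFormatError(f"{path}:{lineno}: malformed landmark row {row!r}")
            try:
                coords.append([float(row[1]), float(row[2]), float(row[3])])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
            labels.append(row[0])
            frames.add(row[4].strip())
    if len(frames) != 1:
        raise FileFormatError(f"{path}: landmark file must use a single frame, got {sorted(frames)}")
    return LandmarkSet(labels, np.asarray(coords), frame_by_name(frames.pop()))


def write_landmarks(pts: LandmarkSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({
            "labels": list(pts.labels),
            "coordinates": pts.coordinates.tolist(),
            "frame": pts.frame.name,
        }, indent=2))
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "x", "y", "z", "frame"])
        for lab, (x, y, z) in zip(pts.labels, pts.coordinates):
            writer.writerow([lab, repr(float(x)), repr(float(y)), repr(float(z)), pts.frame.name])


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def read_transform(path) -> Transform:
    data = json.loads(Path(path).read_text())
    matrix = np.asarray(data["matrix"], dtype=float).reshape(4, 4)
    return Transform(
        matrix,
        frame_by_name(data["from_frame"]),
        frame_by_name(data["to_frame"]),
        rigid=bool(data.get("rigid", True)),
    )


def write_transform(t: Transform, path) -> None:
    Path(path).write_text(json.dumps({
        "matrix": [float(v) for v in t.matrix.ravel()],
        "from_frame": t.from_frame.name,
        "to_frame": t.to_frame.name,
        "rigid": t.rigid,
    }, indent=2))


# ---------------------------------------------------------------------------
# Study records
# ---------------------------------------------------------------------------

_RECORD_NUMERIC = ["x", "y", "z", "tre_mm"]


def write_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in _RECORD_NUMERIC:
        if col in df.columns:
            bad = df.index[df[col].isna()]
            if len(bad):
                # +2: one for the header, one for 0- vs 1-based lines.
                raise FileFormatError(
                    f"{path}:{bad[0] + 2}: missing or non-numeric value in column {col!r}"
                )
    return df


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


def load_surface(path, frame: Frame) -> SurfaceModel:
    """Load an STL (binary or ASCII) mesh as a SurfaceModel."""
    import trimesh

    mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    return SurfaceModel.from_trimesh(mesh, frame)


def save_surface(surface: SurfaceModel, path) -> None:
    import trimesh

    mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
    mesh.export(str(path), file_type="stl_ascii")


# ---------------------------------------------------------------------------
# DICOM geometry
# ---------------------------------------------------------------------------

_REQUIRED_TAGS = {
    "ImagePositionPatient": "(0020,0032)",
    "ImageOrientationPatient": "(0020,0037)",
    "PixelSpacing": "(0028,0030)",
}


def _read_slice(path):
    import pydicom

    ds = pydicom.dcmread(str(path), stop_before_pixels=True)
    for attr, tag in _REQUIRED_TAGS.items():
        if getattr(ds, attr, None) is None:
            raise GeometryError(f"{path}: missing required DICOM tag {attr} {tag}")
    return ds


def read_dicom_geometry(path, strict: bool = False) -> DicomGeometry:
    """Extract voxel-to-patient geometry from a DICOM file or series directory.

    For a series, slices are sorted along the volume normal and slice spacing
    is the mean inter-slice position distance; a > 1% spacing variation
    produces a warning (or a GeometryError in strict mode).  Pixel data is
    never read.
    """
    path = Path(path)
    files = (
        sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
        if path.is_dir()
        else [path]
    )
    if not files:
        raise GeometryError(f"{path}: no DICOM files found")
    slices = [_read_slice(p) for p in files]
    first = slices[0]
    iop = np.asarray([float(v) for v in first.ImageOrientationPatient]).reshape(2, 3)
    normal = np.cross(iop[0], iop[1])
    positions = np.asarray(
        [[float(v) for v in s.ImagePositionPatient] for s in slices]
    )
    order = np.argsort(positions @ normal)
    positions = positions[order]
    rows = int(getattr(first, "Rows", 512))
    cols = int(getattr(first, "Columns", 512))

    if len(slices) > 1:
        gaps = np.diff(positions @ normal)
        spacing = float(np.mean(gaps))
        if spacing <= 0:
            raise GeometryError(f"{path}: non-increasing slice positions")
        if np.max(np.abs(gaps - spacing)) > 0.01 * spacing:
            msg = f"{path}: inconsistent slice spacing (>1% variation)"
            if strict:
                raise GeometryError(msg)
            warnings.warn(msg)
    else:
        thickness = getattr(first, "SliceThickness", None)
        spacing = float(thickness) if thickness else 1.0

    ps = [float(v) for v in first.PixelSpacing]
    return DicomGeometry(
        image_position_patient=positions[0],
        image_orientation_patient=iop,
        pixel_spacing=(ps[0], ps[1]),
        slice_spacing=spacing,
        dimensions=(rows, cols, len(slices)),
    )


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


class _DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    methods_by_technique: dict[str, list[str]] | None = None
    n_observers: int = 2
    n_repetitions: int = 5
    n_cadavers: int = 5
    n_targets: int = 14
    missing_records: list[int] = Field(default_factory=list)

    def build(self) -> StudyDesign:
        kwargs = self.model_dump()
        if kwargs["methods_by_technique"] is None:
            kwargs.pop("methods_by_technique")
        return StudyDesign(**kwargs)


class _NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fle_sigma_mm: dict[str, float] | float | None = None
    seating_rot_sd_deg: float = 0.2
    seating_trans_sd_mm: float = 0.3
    pointer_sigma_mm: float = 0.15
    seed: int = 0

    def build(self) -> NoiseModel:
        kwargs = self.model_dump()
        if kwargs["fle_sigma_mm"] is None:
            kwargs.pop("fle_sigma_mm")
        return NoiseModel(**kwargs)


class StudyConfig(BaseModel):
    """Schema-validated study configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    design: _DesignConfig = Field(default_factory=_DesignConfig)
    noise: _NoiseConfig = Field(default_factory=_NoiseConfig)
    phantom_seed: int = 17
    output_dir: str = "results"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})
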