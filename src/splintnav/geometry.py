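"""Frame-aware rigid/affine transform algebra and DICOM patient-coordinate conventions.

Every downstream component (registration, the registration-free chain, the
study simulator) moves points between a small set of named coordinate frames:

``PATIENT``
    physical/tracker space (mm), where the pointer tip and the DRF live.
``DRF``
    the dynamic reference frame rigid body; pointer positions are reported
    relative to it by the tracking system.
``IPS_IMAGE``
    planning-software image space, RAS-oriented millimetres with its origin at
    the first-voxel position.
``BL_IMAGE``
    navigation-software image space, DICOM LPS patient millimetres.
``VOXEL``
    0-based voxel index space ``(col, row, slice)``.

Transforms are homogeneous 4x4 matrices tagged with their ``from`` and ``to``
frames; any composition or application whose frames do not link raises a
:class:`FrameChainError` before numeric work is done.  Rigid transforms are
validated (orthonormal rotation, det = +1) on construction and after every
closure operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Frame",
    "PATIENT",
    "DRF",
    "IPS_IMAGE",
    "BL_IMAGE",
    "VOXEL",
    "Transform",
    "LandmarkSet",
    "DicomGeometry",
    "FrameChainError",
    "RigidityError",
    "GeometryError",
    "compose",
    "invert",
    "apply",
    "ras_lps_flip",
    "voxel_to_patient",
    "ips_to_bl",
    "set_strictness",
]


class FrameChainError(ValueError):
    """Raised when transform/point frames do not link in a chain."""


class RigidityError(ValueError):
    """Raised when a matrix flagged rigid fails the orthonormality check."""


class GeometryError(ValueError):
    """Raised for invalid DICOM geometry or degenerate transforms."""


# Base numeric tolerances.  A single strictness scale is the only knob:
# set_strictness(10.0) loosens every check tenfold, set_strictness(1.0) restores
# the defaults.
_RIGID_TOL = 1e-9
_COSINE_TOL = 1e-6
_strictness = 1.0


def set_strictness(scale: float) -> None:
    """Scale all geometric validation tolerances by ``scale`` (> 0)."""
    global _strictness
    if scale <= 0:
        raise ValueError("strictness scale must be positive")
    _strictness = float(scale)


def _rigid_tol() -> float:
    return _RIGID_TOL * _strictness


def _cosine_tol() -> float:
    return _COSINE_TOL * _strictness


@dataclass(frozen=True)
class Frame:
    """A named coordinate frame, optionally carrying a handedness convention.

    ``handedness`` is ``"RAS"``, ``"LPS"`` or ``None`` (not an anatomical
    patient frame).  Frames compare by name and handedness, so user-defined
    frames interoperate with the built-in vocabulary.
    """

    name: str
    handedness: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("frame name must be non-empty")
        if self.handedness not in (None, "RAS", "LPS"):
            raise ValueError(f"unknown handedness {self.handedness!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


PATIENT = Frame("PATIENT")
DRF = Frame("DRF")
IPS_IMAGE = Frame("IPS_IMAGE", "RAS")
BL_IMAGE = Frame("BL_IMAGE", "LPS")
VOXEL = Frame("VOXEL")


def _check_rigid(matrix: np.ndarray) -> None:
    tol = _rigid_tol()
    r = matrix[:3, :3]
    if np.abs(r.T @ r - np.eye(3)).max() >= tol:
        raise RigidityError("rotation block is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) >= tol:
        raise RigidityError("rotation block determinant is not +1 (reflection?)")


class Transform:
    """A 4x4 homogeneous map between two named frames.

    Parameters
    ----------
    matrix : (4, 4) array_like
        Homogeneous matrix acting on column vectors; last row must be
        (0, 0, 0, 1) exactly.
    from_frame, to_frame : Frame
        Source and destination frames.
    rigid : bool, default True
        If True, the rotation block is validated as a proper rotation.
    """

    __slots__ = ("matrix", "from_frame", "to_frame", "rigid")

    def __init__(
        self,
        matrix: np.ndarray,
        from_frame: Frame,
        to_frame: Frame,
        rigid: bool = True,
    ) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row of a homogeneous transform must be (0,0,0,1)")
        if not np.all(np.isfinite(m)):
            raise ValueError("transform matrix contains non-finite entries")
        if rigid:
            _check_rigid(m)
        self.matrix = m
        self.from_frame = from_frame
        self.to_frame = to_frame
        self.rigid = bool(rigid)

    # ------------------------------------------------------------------ ctors
    @classmethod
    def identity(cls, frame: Frame) -> "Transform":
        return cls(np.eye(4), frame, frame)

    @classmethod
    def from_rotation_translation(
        cls,
        rotation: np.ndarray,
        translation: Sequence[float],
        from_frame: Frame,
        to_frame: Frame,
    ) -> "Transform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m, from_frame, to_frame)

    @classmethod
    def translation(
        cls, offset: Sequence[float], from_frame: Frame, to_frame: Frame
    ) -> "Transform":
        return cls.from_rotation_translation(np.eye(3), offset, from_frame, to_frame)

    # ------------------------------------------------------------- components
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation_vector(self) -> np.ndarray:
        return self.matrix[:3, 3]

    # ------------------------------------------------------------------ verbs
    def then(self, other: "Transform") -> "Transform":
        """``self`` followed by ``other`` (alias of :func:`compose`)."""
        return compose(self, other)

    def inverse(self) -> "Transform":
        return invert(self)

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array without frame bookkeeping (internal use)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "rigid" if self.rigid else "affine"
        return f"<Transform {kind} {self.from_frame.name} -> {self.to_frame.name}>"


@dataclass
class LandmarkSet:
    """Labeled 3-D points (mm, or voxel indices when frame is VOXEL) in one frame."""

    labels: list[str]
    coordinates: np.ndarray
    frame: Frame

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.shape != (len(self.labels), 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if len(self.labels) < 1:
            raise ValueError("a landmark set needs at least one point")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("landmark labels must be unique")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("landmark coordinates contain non-finite values")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, labels: Iterable[str]) -> "LandmarkSet":
        wanted = list(labels)
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in wanted if lab not in index]
        if missing:
            raise KeyError(f"labels not in landmark set: {missing}")
        rows = [index[lab] for lab in wanted]
        return LandmarkSet(wanted, self.coordinates[rows], self.frame)

    def aligned_to(self, other: "LandmarkSet") -> "LandmarkSet":
        """Reorder to match ``other``'s label order (pairing check included)."""
        if set(self.labels) != set(other.labels):
            raise KeyError(
                "landmark sets have different labels: "
                f"{sorted(set(self.labels) ^ set(other.labels))}"
            )
        return self.subset(other.labels)


@dataclass
class DicomGeometry:
    """The DICOM header fields that define the voxel-to-patient mapping.

    ``image_position_patient`` is tag (0020,0032) of the first slice,
    ``image_orientation_patient`` holds the row- and column-direction cosines
    from (0020,0037), ``pixel_spacing`` is (row, col) mm from (0028,0030), and
    ``slice_spacing`` should come from inter-slice position distances rather
    than SliceThickness, which is unreliable for geometry.
    """

    image_position_patient: np.ndarray
    image_orientation_patient: np.ndarray  # (2, 3): row direction, col direction
    pixel_spacing: tuple[float, float]  # (row, col) mm
    slice_spacing: float
    dimensions: tuple[int, int, int] = field(default=(512, 512, 1))  # rows, cols, slices

    def __post_init__(self) -> None:
        self.image_position_patient = np.asarray(
            self.image_position_patient, dtype=float
        ).reshape(3)
        self.image_orientation_patient = np.asarray(
            self.image_orientation_patient, dtype=float
        ).reshape(2, 3)
        tol = _cosine_tol()
        for v in self.image_orientation_patient:
            if abs(np.linalg.norm(v) - 1.0) >= tol:
                raise GeometryError("direction cosines are not unit-norm")
        if (
            abs(np.dot(*self.image_orientation_patient)) >= tol
        ):
            raise GeometryError("direction cosines are not orthogonal")
        if min(self.pixel_spacing) <= 0 or self.slice_spacing <= 0:
            raise GeometryError("spacings must be positive")

    @property
    def row_direction(self) -> np.ndarray:
        """Direction of increasing row index (second IOP triplet)."""
        return self.image_orientation_patient[1]

    @property
    def column_direction(self) -> np.ndarray:
        """Direction of increasing column index (first IOP triplet)."""
        return self.image_orientation_patient[0]

    @property
    def slice_direction(self) -> np.ndarray:
        return np.cross(self.column_direction, self.row_direction)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compose(a: Transform, b: Transform) -> Transform:
    """Return the transform equivalent to applying ``a`` and then ``b``.

    Frames must link: ``a.to_frame == b.from_frame``.  The result is rigid only
    if both inputs are.
    """
    if a.to_frame != b.from_frame:
        raise FrameChainError(
            f"cannot chain {a.from_frame.name}->{a.to_frame.name} with "
            f"{b.from_frame.name}->{b.to_frame.name}: "
            f"{a.to_frame.name} != {b.from_frame.name}"
        )
    return Transform(
        b.matrix @ a.matrix, a.from_frame, b.to_frame, rigid=a.rigid and b.rigid
    )


def invert(t: Transform) -> Transform:
    """Invert a transform, swapping its frames.

    For rigid transforms the inverse is formed analytically as
    ``(R^T, -R^T t)``; affine transforms fall back to a general matrix inverse.
    """
    if t.rigid:
        r = t.matrix[:3, :3]
        m = np.eye(4)
        m[:3, :3] = r.T
        m[:3, 3] = -r.T @ t.matrix[:3, 3]
    else:
        if abs(np.linalg.det(t.matrix[:3, :3])) < 1e-15:
            raise GeometryError("transform is singular and cannot be inverted")
        m = np.linalg.inv(t.matrix)
        m[3] = [0.0, 0.0, 0.0, 1.0]
    return Transform(m, t.to_frame, t.from_frame, rigid=t.rigid)


def apply(t: Transform, pts: LandmarkSet) -> LandmarkSet:
    """Map a landmark set through a transform (homogeneous, w = 1).

    The set's frame must equal ``t.from_frame``; labels are preserved and the
    output is tagged with ``t.to_frame``.
    """
    if pts.frame != t.from_frame:
        raise FrameChainError(
            f"landmarks are in frame {pts.frame.name} but transform expects "
            f"{t.from_frame.name}"
        )
    return LandmarkSet(list(pts.labels), t.transform_points(pts.coordinates), t.to_frame)


def ras_lps_flip(from_frame: Frame = IPS_IMAGE, to_frame: Frame = BL_IMAGE) -> Transform:
    """The involutory RAS <-> LPS axis flip diag(-1, -1, 1) on (x, y, z)."""
    return Transform(np.diag([-1.0, -1.0, 1.0, 1.0]), from_frame, to_frame)


def voxel_to_patient(g: DicomGeometry) -> Transform:
    """Affine map from 0-based voxel index (col, row, slice) to DICOM LPS mm.

    Follows the DICOM plane equation: ``P = IPP + col*dcol*X + row*drow*Y +
    slice*dslice*(X x Y)`` where X, Y are the IOP column/row direction cosines.
    Voxel (0, 0, 0) maps exactly to Image Position Patient.
    """
    drow, dcol = g.pixel_spacing
    m = np.eye(4)
    m[:3, 0] = g.column_direction * dcol
    m[:3, 1] = g.row_direction * drow
    m[:3, 2] = g.slice_direction * g.slice_spacing
    m[:3, 3] = g.image_position_patient
    return Transform(m, VOXEL, BL_IMAGE, rigid=False)


def ips_to_bl(g: DicomGeometry) -> Transform:
    """The planning-to-navigation image-space transform T_IPS->BL.

    The planning software's image space (IPS_IMAGE) is RAS-oriented with its
    origin at the first-voxel position; the navigation software's image space
    (BL_IMAGE) is DICOM LPS patient millimetres.  A point therefore maps as
    ``P_lps = F @ p_ras + IPP`` with F the RAS/LPS flip and IPP the Image
    Position Patient of the first slice.  With IPP = 0 this reduces to the
    bare flip.
    """
    flip = ras_lps_flip()
    shift = Transform.translation(g.image_position_patient, BL_IMAGE, BL_IMAGE)
    return compose(flip, shift)
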