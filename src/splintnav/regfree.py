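"""The registration-free navigation chain: splint-borne DRF pose in image space.

The central idea: a dental splint carries the dynamic reference frame (DRF) in
a pose that is known *by design* relative to the planning image (T_SPL->IPS,
computed when the splint is designed on the fused dentition).  Composing with
the planning-to-navigation image-space transform (T_IPS->BL, derived from the
DICOM header) yields T_SPL->BL: the DRF's pose in navigation image space,
established pre-operatively.  Seating the splint intra-operatively then links
patient space to image space with no registration procedure at all.

Because current navigation systems insist on *some* registration, accuracy
assessment uses a recalculation: acquired coordinates (expressed in image
space via an arbitrary pre-registration T_reg) are pulled back to the DRF
frame with the rigid inverse of T_reg (c'), then pushed into image space with
T_SPL->BL (c'').  The result is provably independent of the pre-registration
used.

Note on the inverse: the recalculation is often written with a transposed
registration matrix.  For a homogeneous 4x4 with nonzero translation the
literal transpose is not a valid rigid map; the operation implemented here is
the rigid inverse (R^T, -R^T t), which coincides with the transpose exactly
when the translation is zero (unit-tested) and is the only reading under
which the correction actually undoes the pre-registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    BL_IMAGE,
    DRF,
    DicomGeometry,
    FrameChainError,
    IPS_IMAGE,
    LandmarkSet,
    RigidityError,
    Transform,
    apply,
    compose,
    invert,
    ips_to_bl,
)

__all__ = [
    "SplintDesign",
    "RegFreeChain",
    "build_chain",
    "correct_preregistration",
    "to_image_space",
    "tre",
]


@dataclass
class SplintDesign:
    """Design-side description of the splint-borne DRF.

    ``drf_pose_ips`` is T_SPL->IPS: the DRF pose in planning image space, fixed
    when the splint is designed on the fused dentition.  ``splint_vertices``
    (planning image space, mm) define the splint centroid used downstream as
    the origin of the target-distance covariate.  ``drf_marker_geometry``
    holds the reflective-sphere / sensor positions in the DRF frame.
    """

    drf_pose_ips: Transform
    splint_vertices: np.ndarray
    drf_marker_geometry: LandmarkSet | None = None

    def __post_init__(self) -> None:
        if not self.drf_pose_ips.rigid:
            raise RigidityError("the designed DRF pose must be rigid")
        if self.drf_pose_ips.from_frame != DRF or self.drf_pose_ips.to_frame != IPS_IMAGE:
            raise FrameChainError(
                "drf_pose_ips must map DRF -> IPS_IMAGE, got "
                f"{self.drf_pose_ips.from_frame.name} -> "
                f"{self.drf_pose_ips.to_frame.name}"
            )
        self.splint_vertices = np.atleast_2d(
            np.asarray(self.splint_vertices, dtype=float)
        )
        if self.splint_vertices.size == 0 or self.splint_vertices.shape[1] != 3:
            raise ValueError("splint_vertices must be a non-empty (N, 3) array")

    @property
    def splint_centroid_ips(self) -> np.ndarray:
        """Arithmetic mean of the splint mesh vertices (planning image mm)."""
        return self.splint_vertices.mean(axis=0)


@dataclass
class RegFreeChain:
    """The transform chain T_SPL->IPS, T_IPS->BL and their composition T_SPL->BL."""

    t_spl_ips: Transform
    t_ips_bl: Transform
    t_spl_bl: Transform

    def __post_init__(self) -> None:
        expected = compose(self.t_spl_ips, self.t_ips_bl)
        if np.abs(expected.matrix - self.t_spl_bl.matrix).max() > 1e-12:
            raise ValueError("t_spl_bl is not the composition of the chain links")
        for t in (self.t_spl_ips, self.t_ips_bl, self.t_spl_bl):
            if not t.rigid:
                raise RigidityError("all chain transforms must be rigid")


def build_chain(design: SplintDesign, g: DicomGeometry) -> RegFreeChain:
    """Compose the pre-operative chain T_SPL->BL = T_IPS->BL o T_SPL->IPS.

    This is the transform a navigation layer could consume directly in place
    of an intra-operatively measured registration.
    """
    t_ips_bl = ips_to_bl(g)
    return RegFreeChain(
        t_spl_ips=design.drf_pose_ips,
        t_ips_bl=t_ips_bl,
        t_spl_bl=compose(design.drf_pose_ips, t_ips_bl),
    )


def correct_preregistration(c: LandmarkSet, t_reg: Transform) -> LandmarkSet:
    """Undo the pre-registration: c' = T_reg^{-1} applied to c, in the DRF frame.

    ``t_reg`` is the (temporary) registration mapping DRF -> image frame under
    which the coordinates ``c`` were acquired; the rigid inverse expresses the
    measured landmarks relative to the DRF.
    """
    if not t_reg.rigid:
        raise RigidityError("the pre-registration must be a rigid transform")
    return apply(invert(t_reg), c)


def to_image_space(c_prime: LandmarkSet, chain: RegFreeChain) -> LandmarkSet:
    """Push DRF-frame landmarks into navigation image space: c'' = T_SPL->BL c'."""
    return apply(chain.t_spl_bl, c_prime)


def tre(c_final: LandmarkSet, targets: LandmarkSet) -> dict[str, float]:
    """Per-target target registration error (Euclidean distance, mm).

    Both sets must carry matching labels and live in the same frame.
    """
    if c_final.frame != targets.frame:
        raise FrameChainError(
            f"measured landmarks are in {c_final.frame.name} but targets are in "
            f"{targets.frame.name}"
        )
    aligned = c_final.aligned_to(targets)
    d = np.linalg.norm(aligned.coordinates - targets.coordinates, axis=1)
    return {lab: float(v) for lab, v in zip(targets.labels, d)}
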