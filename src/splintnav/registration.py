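"""Baseline intra-operative registration: fiducial least squares and surface ICP.

Two registration families are implemented, mirroring how a navigation system
links patient (tracker) space to image space:

* :func:`register_point_based` — closed-form rigid least squares over paired
  fiducials (bone-anchored screws), solved by SVD of the cross-covariance with
  a determinant correction so the solution is always a proper rotation
  (det R = +1), never a reflection.
* :func:`register_surface` — point-to-surface iterative closest point, using
  exact closest points on mesh triangles (not nearest vertices) and the
  point-based solver for the rigid update each iteration.

:func:`register_point_based_numeric` is a deliberately independent numerical
minimizer over a rotation-vector parameterization, kept as a cross-check of
the closed form; it shares no linear-algebra path with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import FrameChainError, Frame, LandmarkSet, Transform

__all__ = [
    "RegistrationResult",
    "SurfaceModel",
    "ConfigurationError",
    "register_point_based",
    "register_point_based_numeric",
    "fre",
    "register_surface",
    "closest_points_on_surface",
]


class ConfigurationError(ValueError):
    """Raised for degenerate fiducial configurations (< 3 points, collinear)."""


@dataclass
class RegistrationResult:
    """Outcome of a registration: the fitted transform plus residual metrics.

    ``fre_mm`` is the root-mean-square fiducial (or surface) residual in mm;
    ``iterations`` is 1 for the closed-form point solver.  ``rms_history``
    records the per-iteration RMS for iterative methods.
    """

    transform: Transform
    fre_mm: float
    n_points_used: int
    converged: bool = True
    iterations: int = 1
    rms_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fre_mm < 0:
            raise ValueError("fre_mm must be non-negative")


@dataclass
class SurfaceModel:
    """A triangle mesh (vertices in mm) tagged with its coordinate frame."""

    vertices: np.ndarray
    faces: np.ndarray
    frame: Frame

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        self.faces = np.atleast_2d(np.asarray(self.faces, dtype=int))
        if self.vertices.shape[0] < 3 or self.vertices.shape[1] != 3:
            raise ValueError("surface needs at least 3 vertices of dimension 3")
        if self.faces.size == 0 or self.faces.shape[1] != 3:
            raise ValueError("surface needs at least one triangular face")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        self.n_degenerate_faces = int(np.sum(areas <= 1e-12))
        if self.n_degenerate_faces > 0.1 * len(self.faces):
            raise ValueError(
                f"{self.n_degenerate_faces}/{len(self.faces)} faces are degenerate"
            )

    @classmethod
    def from_trimesh(cls, mesh, frame: Frame) -> "SurfaceModel":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), frame)

    def _face_centroid_tree(self) -> cKDTree:
        # Cached KD-tree over face centroids for candidate pruning.
        tree = getattr(self, "_centroid_tree", None)
        if tree is None:
            tree = cKDTree(self.vertices[self.faces].mean(axis=1))
            object.__setattr__(self, "_centroid_tree", tree)
        return tree


# ---------------------------------------------------------------------------
# Point-based registration (Kabsch/Umeyama without scaling)
# ---------------------------------------------------------------------------


def _check_configuration(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ConfigurationError(
            f"point-based registration needs >= 3 points, got {len(points)}"
        )
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-6 * s[0]:
        raise ConfigurationError("fiducial configuration is (near-)collinear")


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation taking moving onto fixed."""
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = fc - r @ mc
    return r, t


def register_point_based(
    moving: LandmarkSet, fixed: LandmarkSet
) -> RegistrationResult:
    """Rigid least-squares registration of paired, labeled fiducials.

    Minimizes ``sum_i ||T m_i - f_i||^2`` over proper rigid transforms.  Labels
    pair the points; both sets must carry the same labels.  The returned
    transform maps ``moving.frame`` to ``fixed.frame`` and ``fre_mm`` is the
    RMS residual after alignment (the fiducial registration error).
    """
    moving_aligned = moving.aligned_to(fixed)
    _check_configuration(moving_aligned.coordinates)
    r, t = _kabsch(moving_aligned.coordinates, fixed.coordinates)
    transform = Transform.from_rotation_translation(r, t, moving.frame, fixed.frame)
    resid = transform.transform_points(moving_aligned.coordinates) - fixed.coordinates
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationResult(transform, rms, len(moving_aligned), True, 1)


def register_point_based_numeric(
    moving: LandmarkSet, fixed: LandmarkSet, n_restarts: int = 8, seed: int = 0
) -> RegistrationResult:
    """Brute-force rigid registration via numerical minimization.

    Optimizes the same least-squares objective over a rotation-vector +
    translation parameterization with multiple random restarts.  This is a
    reference/cross-check implementation, independent of the SVD closed form.
    """
    moving_aligned = moving.aligned_to(fixed)
    _check_configuration(moving_aligned.coordinates)
    m = moving_aligned.coordinates
    f = fixed.coordinates

    def residuals(params: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        return (m @ rot.T + params[3:] - f).ravel()

    rng = np.random.default_rng(seed)
    starts = [np.zeros(6)] + [
        np.concatenate([rng.uniform(-np.pi, np.pi, 3), rng.normal(0, 50, 3)])
        for _ in range(n_restarts - 1)
    ]
    best = None
    for x0 in starts:
        res = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    rot = Rotation.from_rotvec(best.x[:3]).as_matrix()
    transform = Transform.from_rotation_translation(
        rot, best.x[3:], moving.frame, fixed.frame
    )
    rms = float(np.sqrt(2.0 * best.cost / len(m)))
    return RegistrationResult(transform, rms, len(m), True, int(best.nfev))


def fre(
    result: RegistrationResult, moving: LandmarkSet, fixed: LandmarkSet
) -> float:
    """Fiducial registration error: RMS post-transform residual, in mm."""
    moving_aligned = moving.aligned_to(fixed)
    _check_configuration(moving_aligned.coordinates)
    resid = (
        result.transform.transform_points(moving_aligned.coordinates)
        - fixed.coordinates
    )
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


# ---------------------------------------------------------------------------
# Surface ICP
# ---------------------------------------------------------------------------

# Above this face count, closest-point queries restrict to KD-tree candidate
# faces instead of testing every triangle.
_FULL_QUERY_MAX_FACES = 256
_KDTREE_CANDIDATES = 64


def _closest_on_triangles(
    p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Exact closest point on each triangle (a, b, c) to each point p.

    All inputs broadcast to (..., 3).  Standard barycentric region walk
    (Ericson), vectorized; degenerate triangles fall back to vertex a.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        den = va + vb + vc
        v_in = np.where(den != 0, vb / den, 0.0)
        w_in = np.where(den != 0, vc / den, 0.0)

    # Start from the interior solution, then overwrite edge/vertex regions.
    out = a + ab * v_in[..., None] + ac * w_in[..., None]

    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(m_bc[..., None], b + (c - b) * w_bc[..., None], out)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m_ac[..., None], a + ac * w_ac[..., None], out)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m_ab[..., None], a + ab * v_ab[..., None], out)
    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[..., None], c, out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[..., None], b, out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[..., None], a, out)
    return out


def closest_points_on_surface(
    points: np.ndarray, surface: SurfaceModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest mesh-surface point for each query point.

    Returns ``(closest, distance, face_index)``.  Ties between equidistant
    faces break to the lowest face index for determinism.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.vertices[surface.faces]  # (F, 3, 3)
    n_faces = len(surface.faces)
    if n_faces <= _FULL_QUERY_MAX_FACES:
        cand = np.broadcast_to(
            np.arange(n_faces), (len(pts), n_faces)
        )  # every face is a candidate
    else:
        k = min(_KDTREE_CANDIDATES, n_faces)
        _, cand = surface._face_centroid_tree().query(pts, k=k)
        cand = np.sort(np.atleast_2d(cand), axis=1)  # keep lowest-index tie-break
    a = tri[cand, 0]
    b = tri[cand, 1]
    c = tri[cand, 2]
    closest = _closest_on_triangles(pts[:, None, :], a, b, c)
    d2 = np.sum((closest - pts[:, None, :]) ** 2, axis=-1)
    best = np.argmin(d2, axis=1)  # first minimum -> lowest face index
    rows = np.arange(len(pts))
    return (
        closest[rows, best],
        np.sqrt(d2[rows, best]),
        cand[rows, best],
    )


def register_surface(
    probe_points: LandmarkSet,
    surface: SurfaceModel,
    init: Transform,
    max_iterations: int = 200,
    tol: float = 1e-6,
    trim_fraction: float = 0.0,
) -> RegistrationResult:
    """Point-to-surface ICP registering probe points onto a mesh.

    Each iteration finds exact closest points on the mesh for the currently
    transformed probes, optionally trims the worst ``trim_fraction`` of
    matches, and re-fits a rigid transform from the original probe points to
    the correspondences.  Stops when the RMS residual changes by less than
    ``tol`` mm or at ``max_iterations``; non-convergence is reported via
    ``converged=False``, not an exception.
    """
    if len(probe_points) < 10:
        raise ConfigurationError(
            f"surface registration needs >= 10 probe points, got {len(probe_points)}"
        )
    if init.from_frame != probe_points.frame or init.to_frame != surface.frame:
        raise FrameChainError(
            f"init maps {init.from_frame.name}->{init.to_frame.name}, expected "
            f"{probe_points.frame.name}->{surface.frame.name}"
        )
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")

    p = probe_points.coordinates
    n_keep = max(10, int(np.ceil((1.0 - trim_fraction) * len(p))))
    current = init
    prev_rms = np.inf
    history: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        moved = current.transform_points(p)
        closest, dist, _ = closest_points_on_surface(moved, surface)
        keep = np.argsort(dist, kind="stable")[:n_keep]
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(rms)
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        r, t = _kabsch(p[keep], closest[keep])
        current = Transform.from_rotation_translation(
            r, t, probe_points.frame, surface.frame
        )
        prev_rms = rms
    return RegistrationResult(
        current, history[-1], n_keep, converged, iteration, rms_history=history
    )
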