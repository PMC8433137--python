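"""Synthetic phantom and Monte-Carlo generator for the cadaver accuracy study.

No measured cadaver dataset is publicly deposited, so this module emulates the
study's structure end to end: a head phantom with 5 near-coplanar maxillary
fiducial screws and 14 cranial target screws at named landmarks, a splint-borne
DRF with a design-side pose in planning image space, an ellipsoidal skin
surface for ICP, and the full factorial acquisition design
(technique x method x observer x repetition x cadaver x target) with an
explicit missing-record list.

Every acquisition is pushed through the *actual* pipeline modules: point-based
registration and ICP fit noisy inputs, and the registration-free arm records
coordinates under an arbitrary pre-registration that is later undone by the
recalculation chain.  With all noise SDs at zero every arm reproduces the
targets exactly — the zero-noise identity that validates the plumbing.

Noise magnitudes are configuration, not study-derived values: the study
reports only the resulting accuracy, never a per-source error budget.
Defaults are chosen to land empirical TRE in the study's ~1-2 mm range.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import (
    BL_IMAGE,
    DRF,
    DicomGeometry,
    IPS_IMAGE,
    LandmarkSet,
    PATIENT,
    Transform,
    apply,
    compose,
    invert,
    ips_to_bl,
)
from .regfree import RegFreeChain, SplintDesign, build_chain, correct_preregistration, to_image_space
from .registration import (
    ConfigurationError,
    SurfaceModel,
    register_point_based,
    register_surface,
)

__all__ = [
    "TARGET_LABELS",
    "FIDUCIAL_LABELS",
    "INFRAORBITAL_LABELS",
    "OPTICAL",
    "EM",
    "BONE_ANCHORED",
    "SURFACE_BASED",
    "REGISTRATION_FREE",
    "PhantomSpec",
    "NoiseModel",
    "StudyDesign",
    "AcquisitionRecord",
    "DesignError",
    "make_phantom",
    "simulate_session",
    "simulate_study",
    "records_to_tre",
    "predict_tre_point_based",
    "simulate_lmm_dataset",
]

OPTICAL = "optical"
EM = "em"
BONE_ANCHORED = "bone_anchored"
SURFACE_BASED = "surface_based"
REGISTRATION_FREE = "registration_free"

TARGET_LABELS = [
    "orbital_rim_L",
    "orbital_rim_R",
    "zygoma_L",
    "zygoma_R",
    "lateral_orbital_wall_L",
    "lateral_orbital_wall_R",
    "porion_L",
    "porion_R",
    "nasion",
    "frontal_L",
    "frontal_R",
    "cranium",
    "occipital_L",
    "occipital_R",
]
FIDUCIAL_LABELS = [f"max_screw_{i}" for i in range(1, 6)]
INFRAORBITAL_LABELS = ["orbital_rim_L", "orbital_rim_R"]

# Nominal target positions (mm) in the phantom PATIENT frame.  Origin near the
# centre of the maxillary dental arch; +x right, +y anterior, +z cranial.
# Right-side screws are mirrored from the left to keep bilateral symmetry.
_TARGET_BASE = {
    "orbital_rim_L": (-33.0, 27.0, 42.0),
    "zygoma_L": (-48.0, 8.0, 33.0),
    "lateral_orbital_wall_L": (-44.0, 14.0, 47.0),
    "porion_L": (-60.0, -38.0, 30.0),
    "nasion": (0.0, 32.0, 55.0),
    "frontal_L": (-26.0, 24.0, 96.0),
    "cranium": (0.0, -32.0, 162.0),
    "occipital_L": (-34.0, -118.0, 82.0),
}

# Maxillary fiducial screws: ~40 x 25 mm patch on the anterior maxilla with
# small craniocaudal spread (near-coplanar, as in clinical placement).
_FIDUCIAL_BASE = np.array(
    [
        (-20.0, 6.0, 10.0),
        (-10.0, 15.0, 12.5),
        (0.0, 19.0, 9.0),
        (10.0, 15.0, 11.5),
        (20.0, 6.0, 10.0),
    ]
)


class DesignError(ValueError):
    """Raised for invalid technique/method pairings or design bookkeeping."""


@dataclass
class NoiseModel:
    """Error-source magnitudes for the Monte-Carlo study.

    ``fle_sigma_mm`` is the per-axis fiducial localization SD by technique,
    ``seating_*`` parameterize the splint seating (DRF pose) perturbation, and
    ``pointer_sigma_mm`` is the per-axis pointer-tip acquisition SD.  All are
    configuration values, not measurements from the cadaver study.
    """

    fle_sigma_mm: dict = field(
        default_factory=lambda: {OPTICAL: 0.25, EM: 0.30}
    )
    seating_rot_sd_deg: float = 0.2
    seating_trans_sd_mm: float = 0.3
    pointer_sigma_mm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.fle_sigma_mm, (int, float)):
            self.fle_sigma_mm = {OPTICAL: float(self.fle_sigma_mm), EM: float(self.fle_sigma_mm)}
        bad = [v for v in (*self.fle_sigma_mm.values(), self.seating_rot_sd_deg,
                           self.seating_trans_sd_mm, self.pointer_sigma_mm) if v < 0]
        if bad:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def zero(cls, seed: int = 0) -> "NoiseModel":
        return cls({OPTICAL: 0.0, EM: 0.0}, 0.0, 0.0, 0.0, seed)


@dataclass
class StudyDesign:
    """Factorial layout of the accuracy study.

    ``missing_records`` are global indices into the deterministic enumeration
    (arm -> cadaver -> observer -> repetition -> target) of the full factorial,
    dropped from the simulated dataset.
    """

    methods_by_technique: dict = field(
        default_factory=lambda: {
            OPTICAL: [BONE_ANCHORED, REGISTRATION_FREE],
            EM: [BONE_ANCHORED, SURFACE_BASED, REGISTRATION_FREE],
        }
    )
    n_observers: int = 2
    n_repetitions: int = 5
    n_cadavers: int = 5
    n_targets: int = 14
    missing_records: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.n_observers, self.n_repetitions, self.n_cadavers, self.n_targets) < 1:
            raise DesignError("all design counts must be positive")
        for technique, methods in self.methods_by_technique.items():
            for m in methods:
                _validate_pairing(technique, m)
        n_total = self.n_records_full
        if len(set(self.missing_records)) != len(self.missing_records):
            raise DesignError("missing record indices must be unique")
        if any(i < 0 or i >= n_total for i in self.missing_records):
            raise DesignError("missing record index out of range")

    @property
    def arms(self) -> list[tuple[str, str]]:
        return [
            (tech, m)
            for tech, methods in self.methods_by_technique.items()
            for m in methods
        ]

    @property
    def records_per_arm(self) -> int:
        return (
            self.n_cadavers * self.n_observers * self.n_repetitions * self.n_targets
        )

    @property
    def n_records_full(self) -> int:
        return len(self.arms) * self.records_per_arm

    @classmethod
    def reference(cls) -> "StudyDesign":
        """The cadaver study's design: 5 arms x 700 records, 4 registration-free
        acquisitions missing (2 optical, 2 electromagnetic)."""
        design = cls()
        per_arm = design.records_per_arm  # 700
        arm_offset = {arm: i * per_arm for i, arm in enumerate(design.arms)}
        missing = [
            arm_offset[(OPTICAL, REGISTRATION_FREE)] + 112,
            arm_offset[(OPTICAL, REGISTRATION_FREE)] + 433,
            arm_offset[(EM, REGISTRATION_FREE)] + 141,
            arm_offset[(EM, REGISTRATION_FREE)] + 507,
        ]
        return replace(design, missing_records=missing)


def _validate_pairing(technique: str, method: str) -> None:
    if technique not in (OPTICAL, EM):
        raise DesignError(f"unknown tracking technique {technique!r}")
    if method not in (BONE_ANCHORED, SURFACE_BASED, REGISTRATION_FREE):
        raise DesignError(f"unknown registration method {method!r}")
    if technique == OPTICAL and method == SURFACE_BASED:
        raise DesignError(
            "surface-based registration is not available with optical tracking"
        )


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic cadaver head.

    All physical geometry lives in the PATIENT frame; ``true_ct_pose`` is the
    ground-truth PATIENT -> BL_IMAGE transform (what a perfect registration
    would recover), and the splint design/DICOM geometry are constructed to be
    exactly consistent with it, so the registration-free chain is error-free
    by design and simulated errors come only from the noise model.
    """

    fiducials: LandmarkSet
    targets: LandmarkSet
    splint_design: SplintDesign
    skin_surface: SurfaceModel
    true_ct_pose: Transform
    dicom_geometry: DicomGeometry
    t_drf: Transform  # ground-truth DRF -> PATIENT pose of the seated splint

    def __post_init__(self) -> None:
        if len(self.fiducials) != 5:
            raise ValueError("phantom must have exactly 5 fiducials")
        if len(self.targets) != 14:
            raise ValueError("phantom must have exactly 14 targets")
        unknown = set(self.targets.labels) - set(TARGET_LABELS)
        if unknown:
            raise ValueError(f"unknown target labels: {sorted(unknown)}")

    @property
    def targets_image(self) -> LandmarkSet:
        """The true target positions l in navigation image space."""
        return apply(self.true_ct_pose, self.targets)

    @property
    def fiducials_image(self) -> LandmarkSet:
        return apply(self.true_ct_pose, self.fiducials)

    @property
    def splint_centroid_patient(self) -> np.ndarray:
        """Splint-mesh centroid mapped back into the PATIENT frame."""
        centroid_ips = LandmarkSet(
            ["splint_centroid"], self.splint_design.splint_centroid_ips, IPS_IMAGE
        )
        t = compose(ips_to_bl(self.dicom_geometry), invert(self.true_ct_pose))
        return apply(t, centroid_ips).coordinates[0]

    def chain(self) -> RegFreeChain:
        return build_chain(self.splint_design, self.dicom_geometry)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


def _small_rigid(rng: np.random.Generator, rot_sd_deg: float, trans_sd_mm: float,
                 frame_from, frame_to) -> Transform:
    rotvec = np.deg2rad(rng.normal(0.0, rot_sd_deg, 3))
    r = Rotation.from_rotvec(rotvec).as_matrix()
    t = rng.normal(0.0, trans_sd_mm, 3)
    return Transform.from_rotation_translation(r, t, frame_from, frame_to)


def _ellipsoid_mesh(center, semi_axes, subdivisions: int = 3) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    sphere = trimesh.creation.icosphere(subdivisions=subdivisions)
    vertices = np.asarray(sphere.vertices) * np.asarray(semi_axes) + np.asarray(center)
    return vertices, np.asarray(sphere.faces)


def make_phantom(seed: int, overrides: dict | None = None) -> PhantomSpec:
    """Build one synthetic head phantom, deterministically for a given seed.

    The fiducial patch spans ~40 x 25 mm with craniocaudal spread <= 5 mm
    (near-coplanar); target distances from the splint centroid span roughly
    40-180 mm with bilateral symmetry.  ``overrides`` may replace any
    PhantomSpec field (e.g. a custom target layout for theory checks) before
    the design-side transforms are derived, keeping the phantom consistent.
    """
    rng = np.random.default_rng(seed)
    overrides = dict(overrides or {})

    # Targets: jitter the left-side/midline bases, mirror to the right.
    labels, coords = [], []
    for label, base in _TARGET_BASE.items():
        jitter = rng.normal(0.0, 1.0, 3)
        pos = np.asarray(base) + jitter
        labels.append(label)
        coords.append(pos)
        if label.endswith("_L"):
            labels.append(label[:-2] + "_R")
            coords.append(pos * np.array([-1.0, 1.0, 1.0]))
    order = [labels.index(lab) for lab in TARGET_LABELS]
    targets = LandmarkSet(TARGET_LABELS, np.asarray(coords)[order], PATIENT)

    fid_coords = _FIDUCIAL_BASE + rng.normal(0.0, [0.8, 0.8, 0.5], (5, 3))
    fiducials = LandmarkSet(FIDUCIAL_LABELS, fid_coords, PATIENT)

    skin_v, skin_f = _ellipsoid_mesh(center=(0.0, -28.0, 62.0), semi_axes=(72.0, 95.0, 110.0))
    skin_surface = SurfaceModel(skin_v, skin_f, PATIENT)

    true_ct_pose = compose(
        _small_rigid(rng, 6.0, 15.0, PATIENT, PATIENT),
        Transform.translation((10.0, -30.0, 40.0), PATIENT, BL_IMAGE),
    )

    dicom_geometry = DicomGeometry(
        image_position_patient=(-100.0, -120.0, -50.0),
        image_orientation_patient=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
        pixel_spacing=(0.5, 0.5),
        slice_spacing=0.6,
        dimensions=(512, 512, 300),
    )

    t_drf = compose(
        _small_rigid(rng, 3.0, 2.0, DRF, DRF),
        Transform.translation((0.0, 28.0, 4.0), DRF, PATIENT),
    )

    targets = overrides.pop("targets", targets)
    fiducials = overrides.pop("fiducials", fiducials)
    skin_surface = overrides.pop("skin_surface", skin_surface)
    true_ct_pose = overrides.pop("true_ct_pose", true_ct_pose)
    dicom_geometry = overrides.pop("dicom_geometry", dicom_geometry)
    t_drf = overrides.pop("t_drf", t_drf)

    # Splint footprint on the dental arch (PATIENT frame), mapped into planning
    # image space, and the designed DRF pose derived consistently with truth.
    t_ips_bl = ips_to_bl(dicom_geometry)
    bl_to_ips = invert(t_ips_bl)
    patient_to_ips = compose(true_ct_pose, bl_to_ips)
    xs = np.array([-22.0, 22.0])
    ys = np.array([0.0, 18.0])
    zs = np.array([-6.0, 2.0])
    splint_patient = np.array([(x, y, z) for x in xs for y in ys for z in zs])
    splint_ips = patient_to_ips.transform_points(splint_patient)
    drf_pose_ips = compose(compose(t_drf, true_ct_pose), bl_to_ips)
    markers = LandmarkSet(
        [f"marker_{i}" for i in range(1, 5)],
        [(0.0, 0.0, 0.0), (95.0, 0.0, 0.0), (0.0, 85.0, 0.0), (55.0, 55.0, 30.0)],
        DRF,
    )
    splint_design = overrides.pop(
        "splint_design",
        SplintDesign(drf_pose_ips, splint_ips, markers),
    )
    if overrides:
        raise TypeError(f"unknown phantom overrides: {sorted(overrides)}")

    return PhantomSpec(
        fiducials=fiducials,
        targets=targets,
        splint_design=splint_design,
        skin_surface=skin_surface,
        true_ct_pose=true_ct_pose,
        dicom_geometry=dicom_geometry,
        t_drf=t_drf,
    )


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionRecord:
    """One pointer acquisition with full design metadata.

    ``coords`` are as recorded by the navigation layer: final image-space
    coordinates for the conventional arms, image-space coordinates *under the
    pre-registration* for the registration-free arm (``t_reg`` then carries
    the pre-registration to undo).
    """

    cadaver: int
    technique: str
    method: str
    observer: int
    repetition: int
    target: str
    coords: np.ndarray
    frame: str = BL_IMAGE.name
    t_reg: Transform | None = None


def _session_rng(master_seed: int, cadaver, technique, method, observer, repetition):
    """Independent, insertion-order-free substream per session."""
    key = f"{cadaver}|{technique}|{method}|{observer}|{repetition}".encode()
    h = int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % 2**31, h]))


def _sample_on_surface(surface: SurfaceModel, n: int, rng: np.random.Generator) -> np.ndarray:
    tri = surface.vertices[surface.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    idx = rng.choice(len(tri), size=n, p=areas / areas.sum())
    u = np.sqrt(rng.random(n))
    v = rng.random(n)
    a, b, c = tri[idx, 0], tri[idx, 1], tri[idx, 2]
    return a * (1 - u)[:, None] + b * (u * (1 - v))[:, None] + c * (u * v)[:, None]


def simulate_session(
    phantom: PhantomSpec,
    technique: str,
    method: str,
    noise: NoiseModel,
    seed: int,
    cadaver: int = 0,
    observer: int = 0,
    repetition: int = 0,
    n_probe_points: int = 40,
) -> list[AcquisitionRecord]:
    """Simulate one registration + target-acquisition session.

    Conventional arms perform an actual registration on noise-perturbed inputs
    (fiducial least squares, or ICP from a perturbed start pose) and map noisy
    pointer readings through the fitted transform.  The registration-free arm
    perturbs the splint seating (DRF pose), records acquisitions under an
    arbitrary rigid pre-registration and leaves the correction to the
    recalculation chain.
    """
    _validate_pairing(technique, method)
    rng = _session_rng(seed, cadaver, technique, method, observer, repetition)
    sigma_fle = noise.fle_sigma_mm[technique]
    sigma_ptr = noise.pointer_sigma_mm
    targets_patient = phantom.targets.coordinates
    meta = dict(cadaver=cadaver, technique=technique, method=method,
                observer=observer, repetition=repetition)

    t_reg_record: Transform | None = None
    if method == BONE_ANCHORED:
        measured = phantom.fiducials.coordinates + rng.normal(0.0, sigma_fle, (5, 3))
        moving = LandmarkSet(list(phantom.fiducials.labels), measured, PATIENT)
        reg = register_point_based(moving, phantom.fiducials_image)
        t_map = reg.transform
    elif method == SURFACE_BASED:
        surface_image = SurfaceModel(
            phantom.true_ct_pose.transform_points(phantom.skin_surface.vertices),
            phantom.skin_surface.faces,
            BL_IMAGE,
        )
        probes = _sample_on_surface(phantom.skin_surface, n_probe_points, rng)
        probes = probes + rng.normal(0.0, sigma_ptr, probes.shape)
        probe_set = LandmarkSet([f"probe_{i}" for i in range(len(probes))], probes, PATIENT)
        init = compose(
            _small_rigid(rng, noise.seating_rot_sd_deg, noise.seating_trans_sd_mm,
                         PATIENT, PATIENT),
            phantom.true_ct_pose,
        )
        reg = register_surface(probe_set, surface_image, init)
        t_map = reg.transform
    else:  # registration-free
        seating = _small_rigid(
            rng, noise.seating_rot_sd_deg, noise.seating_trans_sd_mm, DRF, DRF
        )
        drf_actual = compose(seating, phantom.t_drf)  # DRF -> PATIENT
        # Arbitrary recorded pre-registration (the workaround the system demands).
        r = Rotation.random(rng=rng).as_matrix()
        t_reg_record = Transform.from_rotation_translation(
            r, rng.normal(0.0, 50.0, 3), DRF, BL_IMAGE
        )
        t_map = compose(invert(drf_actual), t_reg_record)  # PATIENT -> BL via prereg

    pointer = targets_patient + rng.normal(0.0, sigma_ptr, targets_patient.shape)
    recorded = t_map.transform_points(pointer)
    return [
        AcquisitionRecord(
            **meta, target=lab, coords=recorded[i], t_reg=t_reg_record
        )
        for i, lab in enumerate(phantom.targets.labels)
    ]


def records_to_tre(
    records: list[AcquisitionRecord],
    phantom: PhantomSpec,
    chain: RegFreeChain | None = None,
) -> pd.DataFrame:
    """Resolve acquisitions to final image-space coordinates and per-target TRE.

    Registration-free records are recalculated (pre-registration undone, then
    mapped by T_SPL->BL); conventional records are already final.
    """
    if chain is None:
        chain = phantom.chain()
    truth = {
        lab: c for lab, c in zip(phantom.targets_image.labels,
                                 phantom.targets_image.coordinates)
    }
    rows = []
    for rec in records:
        if rec.method == REGISTRATION_FREE:
            c = LandmarkSet([rec.target], rec.coords, BL_IMAGE)
            c_final = to_image_space(correct_preregistration(c, rec.t_reg), chain)
            xyz = c_final.coordinates[0]
        else:
            xyz = rec.coords
        rows.append(
            dict(
                cadaver=rec.cadaver,
                technique=rec.technique,
                method=rec.method,
                observer=rec.observer,
                repetition=rec.repetition,
                target=rec.target,
                x=xyz[0],
                y=xyz[1],
                z=xyz[2],
                frame=BL_IMAGE.name,
                tre_mm=float(np.linalg.norm(xyz - truth[rec.target])),
            )
        )
    return pd.DataFrame(rows)


def simulate_study(
    design: StudyDesign,
    phantom_seeds,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Run the full factorial study across cadaver phantoms.

    ``phantom_seeds`` is either one integer (per-cadaver seeds derived from
    it) or a sequence of ``n_cadavers`` seeds.  Session randomness comes from
    ``noise.seed`` via per-session substreams, so record content is
    independent of enumeration order.  Records listed in
    ``design.missing_records`` are dropped after enumeration.
    """
    if np.isscalar(phantom_seeds):
        phantom_seeds = [int(phantom_seeds) + 1000 * c for c in range(design.n_cadavers)]
    phantom_seeds = list(phantom_seeds)
    if len(phantom_seeds) != design.n_cadavers:
        raise DesignError(
            f"need {design.n_cadavers} phantom seeds, got {len(phantom_seeds)}"
        )
    phantoms = [make_phantom(s) for s in phantom_seeds]
    if design.n_targets != len(phantoms[0].targets):
        raise DesignError(
            f"design expects {design.n_targets} targets but phantoms have "
            f"{len(phantoms[0].targets)}"
        )
    chains = [p.chain() for p in phantoms]
    missing = set(design.missing_records)

    frames = []
    index = 0
    for technique, method in design.arms:
        for cadaver in range(design.n_cadavers):
            for observer in range(design.n_observers):
                for repetition in range(design.n_repetitions):
                    keep = [
                        i for i in range(design.n_targets)
                        if index + i not in missing
                    ]
                    if keep:
                        records = simulate_session(
                            phantoms[cadaver], technique, method, noise,
                            noise.seed, cadaver, observer, repetition,
                        )
                        records = [records[i] for i in keep]
                        frames.append(
                            records_to_tre(records, phantoms[cadaver], chains[cadaver])
                        )
                    index += design.n_targets
    df = pd.concat(frames, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# First-order TRE theory (simulation oracle)
# ---------------------------------------------------------------------------


def predict_tre_point_based(
    fiducials: LandmarkSet, target, fle_rms: float
) -> float:
    """Expected RMS TRE of point-based registration at a target position.

    First-order prediction for isotropic fiducial localization error:

        TRE_rms^2(r) = (FLE_rms^2 / N) * (1 + (1/3) * sum_k d_k^2 / f_k^2)

    where d_k is the target's distance from fiducial principal axis k and f_k
    the RMS distance of the fiducials from that axis.  Near-coplanar fiducial
    patches make one f_k small, which is exactly the growing-TRE-with-distance
    mechanism the study observes away from the registration centroid.
    """
    if fle_rms < 0:
        raise ValueError("fle_rms must be non-negative")
    pts = fiducials.coordinates
    if len(pts) < 3:
        raise ConfigurationError("need >= 3 fiducials")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-6 * s[0]:
        raise ConfigurationError("fiducial configuration is (near-)collinear")
    # Principal axes and per-axis mean squared coordinates.
    cov = centered.T @ centered / len(pts)
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    r = eigvec.T @ (np.asarray(target, dtype=float) - pts.mean(axis=0))
    s2 = eigval  # mean squared coordinate along each principal axis
    total = 0.0
    for k in range(3):
        d2 = np.sum(np.delete(r, k) ** 2)
        f2 = np.sum(np.delete(s2, k))
        total += d2 / f2
    return float(fle_rms * np.sqrt((1.0 + total / 3.0) / len(pts)))


# ---------------------------------------------------------------------------
# Model-space data generator (for mixed-model parameter recovery)
# ---------------------------------------------------------------------------


def simulate_lmm_dataset(
    design: StudyDesign,
    group_lines: dict,
    target_distances: dict,
    cadaver_sd: float = 0.10,
    residual_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw sqrt(TRE) data directly from the group-line model.

    ``group_lines`` maps (technique, method) to (intercept, slope) on the
    sqrt-mm scale; ``target_distances`` maps target label to the *centered*
    distance covariate (mm).  Each cadaver gets a Gaussian random intercept
    (SD ``cadaver_sd``) and observations get residual SD ``residual_sd``.
    Used for parameter-recovery checks of the mixed-model fit, bypassing the
    physical simulator.
    """
    rng = np.random.default_rng(seed)
    labels = list(target_distances)
    if len(labels) != design.n_targets:
        raise DesignError("target_distances must cover every design target")
    cadaver_effects = rng.normal(0.0, cadaver_sd, design.n_cadavers)
    missing = set(design.missing_records)
    rows = []
    index = 0
    for technique, method in design.arms:
        intercept, slope = group_lines[(technique, method)]
        for cadaver in range(design.n_cadavers):
            for observer in range(design.n_observers):
                for repetition in range(design.n_repetitions):
                    for target in labels:
                        if index not in missing:
                            d = target_distances[target]
                            sqrt_tre = (
                                intercept
                                + slope * d
                                + cadaver_effects[cadaver]
                                + rng.normal(0.0, residual_sd)
                            )
                            sqrt_tre = max(sqrt_tre, 0.0)
                            rows.append(
                                dict(
                                    cadaver=cadaver,
                                    technique=technique,
                                    method=method,
                                    observer=observer,
                                    repetition=repetition,
                                    target=target,
                                    centered_distance_mm=d,
                                    sqrt_tre=sqrt_tre,
                                    tre_mm=sqrt_tre**2,
                                )
                            )
                        index += 1
    return pd.DataFrame(rows)
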