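"""Simplified stereoradiographic (RSA) gold-standard simulator.

Two X-ray tubes, angled 40 degrees to each other above a uniplanar
detector, project the tantalum beads onto the image plane; 3D marker
positions are then reconstructed as the midpoint of the common
perpendicular of the two back-projected rays.  Calibration is assumed
perfect (the geometry is known exactly); measurement error enters only
as seeded 2D Gaussian noise on the projections, and marker occlusion is
emulated with deterministic per-body masks, mirroring the reduced marker
counts a film reader actually obtains.

The reconstructed examinations feed the same migration pipeline as CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GeometryError, ReconstructionError, ValidationError
from .markers import MarkerSet
from .migration import Examination
from .phantom import PhantomConfig, StudyManifest, _rng
from .rigid import RigidTransform, fit_rigid

#: default SD (mm) of the 2D projection measurement noise
DEFAULT_PROJECTION_NOISE_SD = 0.02


@dataclass(frozen=True)
class StereoGeometry:
    """Two focal spots and a detector plane with an in-plane 2D basis."""

    focus_1: np.ndarray
    focus_2: np.ndarray
    detector_origin: np.ndarray
    detector_normal: np.ndarray
    detector_axes: np.ndarray  # (2, 3) orthonormal in-plane basis
    stage_point: np.ndarray | None = None  # where the phantom is placed
    cage_fiducials: MarkerSet | None = None

    def __post_init__(self) -> None:
        for name in ("focus_1", "focus_2", "detector_origin", "detector_normal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        if self.stage_point is not None:
            object.__setattr__(self, "stage_point", np.asarray(self.stage_point, float).reshape(3))
        axes = np.asarray(self.detector_axes, float).reshape(2, 3)
        object.__setattr__(self, "detector_axes", axes)
        normal = self.detector_normal / np.linalg.norm(self.detector_normal)
        object.__setattr__(self, "detector_normal", normal)
        for focus in (self.focus_1, self.focus_2):
            if abs(np.dot(focus - self.detector_origin, normal)) < 1e-9:
                raise ValidationError("focal spot lies on the detector plane")

    @property
    def tube_angle(self) -> float:
        """Angle (deg) between the central rays (focus -> detector origin)."""
        r1 = self.detector_origin - self.focus_1
        r2 = self.detector_origin - self.focus_2
        cosang = np.dot(r1, r2) / (np.linalg.norm(r1) * np.linalg.norm(r2))
        return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    @property
    def tube_angle_ok(self) -> bool:
        """QC flag: geometry inside the recommended 10-90 degree band."""
        return 10.0 < self.tube_angle < 90.0

    @classmethod
    def from_angle(
        cls,
        tube_angle: float = 40.0,
        source_height: float = 1000.0,
        iso_height: float = 150.0,
    ) -> "StereoGeometry":
        """Symmetric geometry: detector in z=0, central rays crossing at the iso point.

        The two foci sit ``source_height`` mm above the detector, separated
        so that their central rays (through the iso point at
        ``iso_height`` mm, where the phantom is placed) subtend
        ``tube_angle`` degrees.
        """
        if not 0.0 < tube_angle < 180.0:
            raise ValidationError(f"tube_angle must be in (0, 180), got {tube_angle}")
        half = np.radians(tube_angle / 2.0)
        iso = np.array([0.0, 0.0, iso_height])
        reach = (source_height - iso_height) / np.cos(half)
        offset = reach * np.sin(half)
        return cls(
            focus_1=iso + np.array([-offset, 0.0, source_height - iso_height]),
            focus_2=iso + np.array([+offset, 0.0, source_height - iso_height]),
            detector_origin=np.zeros(3),
            detector_normal=np.array([0.0, 0.0, 1.0]),
            detector_axes=np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            stage_point=iso,
        )


@dataclass(frozen=True)
class OcclusionMask:
    """Marker ids hidden in the stereo projections, per rigid body."""

    hidden: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def visible(self, markers: MarkerSet) -> MarkerSet:
        hidden = set(self.hidden.get(markers.body, ()))
        keep = [i for i in markers.ids if i not in hidden]
        if len(keep) < 3:
            raise ValidationError(
                f"occlusion mask leaves only {len(keep)} visible "
                f"{markers.body} markers; need >= 3"
            )
        return markers.subset(keep)


def default_occlusion_mask(config: PhantomConfig) -> OcclusionMask:
    """Marker visibility as observed on film: 7 of 9 pelvic beads, and
    6 (cemented) or 4 (uncemented) cup beads."""
    n_cup_visible = 6 if config.cup_type == "cemented" else 4
    cup_ids = tuple(f"c{k + 1:02d}" for k in range(config.n_cup_markers))
    pelvis_ids = tuple(f"p{k + 1:02d}" for k in range(config.n_pelvis_markers))
    return OcclusionMask(
        hidden={
            "cup": cup_ids[n_cup_visible:],
            "pelvis": pelvis_ids[min(7, len(pelvis_ids)) :],
        }
    )


@dataclass(frozen=True)
class Projections:
    """Matched 2D projections of one marker set from both foci."""

    ids: tuple[str, ...]
    body: str
    image_1: np.ndarray  # (n, 2) detector-frame mm
    image_2: np.ndarray


def _project_from(focus: np.ndarray, points: np.ndarray, geometry: StereoGeometry) -> np.ndarray:
    normal = geometry.detector_normal
    to_plane = np.dot(geometry.detector_origin - focus, normal)
    along = (points - focus) @ normal
    if np.any(np.sign(along) != np.sign(to_plane)) or np.any(
        np.abs(along) >= np.abs(to_plane)
    ):
        raise GeometryError("marker not strictly between focus and detector")
    t = to_plane / along
    hits = focus + t[:, None] * (points - focus)
    rel = hits - geometry.detector_origin
    return rel @ geometry.detector_axes.T


def project_markers(
    geometry: StereoGeometry,
    markers: MarkerSet,
    mask: OcclusionMask | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Projections:
    """Central projection of the visible markers from both foci.

    ``noise_sd`` adds seeded 2D Gaussian measurement noise (mm) on the
    detector coordinates; pass a ``rng`` for reproducibility.
    """
    visible = mask.visible(markers) if mask is not None else markers
    img1 = _project_from(geometry.focus_1, visible.coords, geometry)
    img2 = _project_from(geometry.focus_2, visible.coords, geometry)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        img1 = img1 + noise_sd * rng.standard_normal(img1.shape)
        img2 = img2 + noise_sd * rng.standard_normal(img2.shape)
    return Projections(ids=visible.ids, body=visible.body, image_1=img1, image_2=img2)


def reconstruct_3d(
    projections: Projections,
    geometry: StereoGeometry,
    min_ray_angle: float = 2.0,
    source: str = "reconstructed",
) -> tuple[MarkerSet, np.ndarray]:
    """3D markers as midpoints of the common perpendicular of the ray pairs.

    Returns the reconstructed MarkerSet and the per-marker ray-skew
    distances (mm), a reconstruction-quality diagnostic.

    Raises
    ------
    ReconstructionError
        When any ray pair subtends less than ``min_ray_angle`` degrees.
    """
    basis = geometry.detector_axes
    p1 = geometry.detector_origin + projections.image_1 @ basis
    p2 = geometry.detector_origin + projections.image_2 @ basis
    d1 = p1 - geometry.focus_1
    d2 = p2 - geometry.focus_2

    a = np.sum(d1 * d1, axis=1)
    b = np.sum(d1 * d2, axis=1)
    c = np.sum(d2 * d2, axis=1)
    w0 = geometry.focus_1 - geometry.focus_2
    d = d1 @ w0
    e = d2 @ w0
    denom = a * c - b * b
    sin2 = denom / (a * c)
    min_sin2 = np.sin(np.radians(min_ray_angle)) ** 2
    if np.any(sin2 < min_sin2):
        worst = float(np.degrees(np.arcsin(np.sqrt(np.clip(sin2.min(), 0, 1)))))
        raise ReconstructionError(
            f"ray pair subtends only {worst:.2f} deg (< {min_ray_angle:g} deg); "
            "stereo geometry is ill-conditioned"
        )
    s = (b * e - c * d) / denom
    t = (a * e - b * d) / denom
    q1 = geometry.focus_1 + s[:, None] * d1
    q2 = geometry.focus_2 + t[:, None] * d2
    midpoints = (q1 + q2) / 2.0
    skew = np.linalg.norm(q1 - q2, axis=1)
    return (
        MarkerSet(body=projections.body, ids=projections.ids, coords=midpoints, source=source),
        skew,
    )


def rsa_measure_study(
    manifest: StudyManifest,
    geometry: StereoGeometry | None = None,
    mask: OcclusionMask | None = None,
    noise_sd: float = DEFAULT_PROJECTION_NOISE_SD,
) -> list[Examination]:
    """Simulated RSA examinations of a phantom study (modality "RSA").

    Every (position, series) examination is posed with its RSA
    repositioning pose, occluded, projected with seeded measurement noise
    and reconstructed.  Output feeds the same migration module as CT.
    """
    geometry = geometry if geometry is not None else StereoGeometry.from_angle()
    mask = mask if mask is not None else default_occlusion_mask(manifest.config)
    if geometry.stage_point is not None:
        stage = geometry.stage_point
    else:
        height = 0.5 * (
            abs(np.dot(geometry.focus_1 - geometry.detector_origin, geometry.detector_normal))
            + abs(np.dot(geometry.focus_2 - geometry.detector_origin, geometry.detector_normal))
        )
        stage = geometry.detector_origin + 0.15 * height * geometry.detector_normal
    exams: list[Examination] = []
    for p in range(1, manifest.n_positions + 1):
        for s in (1, 2):
            pelvis, cup = manifest.exam_markers(p, s, modality="RSA")
            # place the (posed) phantom at the stage point: a common rigid
            # translation that the pelvis registration removes again
            offset = stage - np.vstack([pelvis.coords, cup.coords]).mean(axis=0)
            shift = RigidTransform(np.eye(3), offset)
            pelvis, cup = pelvis.transformed(shift), cup.transformed(shift)
            rng = _rng(manifest.config.seed, 17, p, s)
            bodies = {}
            for markers in (pelvis, cup):
                proj = project_markers(geometry, markers, mask, noise_sd, rng)
                recon, _ = reconstruct_3d(proj, geometry)
                bodies[markers.body] = recon
            # anatomical reference frame from the visible pelvic landmarks,
            # so migration components come out along the phantom axes
            anatomy_pose, _ = fit_rigid(
                manifest.pelvis.subset(bodies["pelvis"].ids), bodies["pelvis"]
            )
            exams.append(
                Examination(
                    position=p,
                    series=s,
                    pelvis=bodies["pelvis"],
                    cup=bodies["cup"],
                    modality="RSA",
                    anatomy_pose=anatomy_pose,
                )
            )
    return exams
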