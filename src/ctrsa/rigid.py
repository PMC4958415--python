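"""Least-squares rigid-body fitting, Cardan angles and RSA quality metrics.

The rigid fit is the closed-form Kabsch solution: the rotation minimizing
the sum of squared residuals between two corresponding point sets is
obtained from the SVD of the cross-covariance of the mean-centred
coordinates, with a reflection correction so det(R) = +1.

Rotations are reported as Cardan angles in the intrinsic x -> y -> z
sequence (degrees), the order conventionally used to report implant
rotations about the transverse (x), longitudinal (y) and sagittal (z)
axes.  Migration angles depend on this sequence; it is fixed throughout
the package.

Two quality metrics accompany every fit, mirroring standard RSA practice:

* ``mean_error`` — RMS of the post-fit marker residuals (mm).  Flags
  marker instability; values above ~0.35 mm are conventionally rejected.
* ``condition_number`` — ratio of the largest to smallest singular value
  of the mean-centred marker coordinate matrix.  Flags near-planar or
  near-collinear scatter; values above ~100-110 are conventionally
  considered unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateConfigurationError, GimbalLockError, ValidationError
from .markers import MarkerSet

_ORTHONORMAL_TOL = 1e-8

#: conventional QC bound on the condition number of a marker configuration
CONDITION_NUMBER_LIMIT = 100.0
#: conventional QC bound (mm) on the rigid-body mean error
MEAN_ERROR_LIMIT = 0.35


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-6):
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(rot) < 0:
            raise ValidationError("rotation matrix has negative determinant (reflection)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_cardan(
        cls, rx: float, ry: float, rz: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Build from intrinsic x->y->z Cardan angles in degrees."""
        rot = Rotation.from_euler("XYZ", [rx, ry, rz], degrees=True).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)


@dataclass(frozen=True)
class CardanAngles:
    """Intrinsic x->y->z rotation angles in degrees."""

    rx: float
    ry: float
    rz: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)


@dataclass(frozen=True)
class FitQuality:
    """Rigid-fit QC: RMS residual (mm) and source-set condition number."""

    mean_error: float
    condition_number: float

    @property
    def mean_error_ok(self) -> bool:
        return self.mean_error < MEAN_ERROR_LIMIT

    @property
    def condition_number_ok(self) -> bool:
        return self.condition_number < CONDITION_NUMBER_LIMIT


def _as_coords(points) -> np.ndarray:
    if isinstance(points, MarkerSet):
        return points.coords
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) coordinates, got shape {pts.shape}")
    return pts


def _check_nondegenerate(centered: np.ndarray, what: str) -> np.ndarray:
    """Require >= 3 non-collinear points; return singular values."""
    if centered.shape[0] < 3:
        raise DegenerateConfigurationError(
            f"{what}: need at least 3 markers, got {centered.shape[0]}"
        )
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise DegenerateConfigurationError(f"{what}: markers are (near-)collinear")
    return svals


def _paired_coords(source, target) -> tuple[np.ndarray, np.ndarray]:
    """Align two inputs into corresponding (n,3) arrays, matching ids for MarkerSets."""
    if isinstance(source, MarkerSet) and isinstance(target, MarkerSet):
        shared = source.shared_ids(target)
        if len(shared) < 3:
            raise DegenerateConfigurationError(
                f"only {len(shared)} shared marker ids between "
                f"{source.body} sets; need >= 3"
            )
        return source.subset(shared).coords, target.subset(shared).coords
    src, dst = _as_coords(source), _as_coords(target)
    if src.shape != dst.shape:
        raise ValidationError(f"point sets differ in shape: {src.shape} vs {dst.shape}")
    return src, dst


def fit_rigid(source, target) -> tuple[RigidTransform, FitQuality]:
    """Least-squares rigid transform mapping ``source`` onto ``target``.

    Both arguments are MarkerSets (paired on shared ids) or (n, 3) arrays in
    corresponding order.  Returns the transform T minimizing
    ``sum ||T(s_i) - t_i||^2`` together with its quality metrics
    (RMS residual and the condition number of the source configuration).
    """
    src, dst = _paired_coords(source, target)
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    svals = _check_nondegenerate(src_c, "rigid fit source")

    cross = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(cross)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tra = dst.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform(rot, tra)

    residuals = transform.apply(src) - dst
    mean_error = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else float("inf")
    return transform, FitQuality(mean_error=mean_error, condition_number=cond)


def decompose_cardan(transform: RigidTransform | np.ndarray) -> CardanAngles:
    """Intrinsic x->y->z Cardan angles (degrees) of a rotation.

    Raises
    ------
    GimbalLockError
        When |ry| >= 89 degrees, where rx and rz become degenerate.
    """
    rot = transform.rotation if isinstance(transform, RigidTransform) else np.asarray(transform)
    rx, ry, rz = Rotation.from_matrix(rot).as_euler("XYZ", degrees=True)
    if abs(ry) >= 89.0:
        raise GimbalLockError(
            f"|ry| = {abs(ry):.2f} deg is within 1 deg of gimbal lock; "
            "use a quaternion/rotation-matrix representation instead"
        )
    return CardanAngles(float(rx), float(ry), float(rz))


def compose_cardan(angles: CardanAngles) -> np.ndarray:
    """Rotation matrix of intrinsic x->y->z Cardan angles in degrees."""
    return Rotation.from_euler("XYZ", angles.as_array(), degrees=True).as_matrix()


def condition_number(markers) -> float:
    """sigma_max / sigma_min of the mean-centred marker coordinate matrix.

    Returns +inf for rank-deficient (planar/collinear) configurations.
    Invariant under rigid motion and uniform scaling of the marker set.
    """
    pts = _as_coords(markers)
    if pts.shape[0] < 3:
        raise DegenerateConfigurationError(
            f"condition number needs >= 3 markers, got {pts.shape[0]}"
        )
    centered = pts - pts.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] <= 1e-12 * max(svals[0], 1.0):
        return float("inf")
    return float(svals[0] / svals[-1])


def mean_error_between_exams(body_exam1: MarkerSet, body_exam2: MarkerSet) -> float:
    """RMS rigid-fit residual between two examinations of one rigid body (mm).

    The marker-stability ("mean error") QC metric: if the beads moved
    relative to each other between the examinations the residual grows and
    the body should not be trusted for migration analysis.
    """
    _, quality = fit_rigid(body_exam1, body_exam2)
    return quality.mean_error
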