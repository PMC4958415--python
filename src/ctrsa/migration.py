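"""Cup migration between paired examinations via pelvic-landmark registration.

The two-step procedure: (1) the moving examination is rigidly aligned to
the reference examination using the pelvic bead landmarks only, so that
both are expressed in the reference pelvis frame; (2) the cup beads of
the aligned examination are fitted to the reference cup beads, and that
residual rigid motion *is* the migration — three translations of the cup
marker centroid (mm) and three intrinsic x->y->z Cardan rotations (deg).

Because step (1) removes the whole-body pose, the result is invariant to
how the subject was positioned in the scanner.  QC metrics (registration
mean error, pelvis condition number) annotate the result and flag — but
never abort — suspect measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateConfigurationError, ManifestError
from .markers import MarkerSet
from .rigid import (
    FitQuality,
    MEAN_ERROR_LIMIT,
    RigidTransform,
    condition_number,
    decompose_cardan,
    fit_rigid,
)

COMPONENTS = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass(frozen=True)
class Examination:
    """One acquisition of the phantom/patient: both rigid bodies, labelled.

    ``anatomy_pose`` maps the anatomical reference frame (in which
    migration components are reported) into this examination's world
    frame — typically the pose of the pelvic landmark template estimated
    during labelling.  Without it, components are reported in the
    reference examination's world axes, which are only meaningful when
    the subject was not rotated between acquisitions.
    """

    position: int
    series: int
    pelvis: MarkerSet
    cup: MarkerSet
    modality: str = "CT"
    anatomy_pose: RigidTransform | None = None


@dataclass(frozen=True)
class RegistrationResult:
    """Pelvis-based volume-to-volume alignment with QC annotations."""

    transform: RigidTransform
    quality: FitQuality
    n_markers: int
    flagged: bool  # mean error exceeded the QC bound


@dataclass(frozen=True)
class MigrationResult:
    """Cup motion between two examinations (translations mm, rotations deg)."""

    dx: float
    dy: float
    dz: float
    rx: float
    ry: float
    rz: float
    n_pelvis_used: int
    n_cup_used: int
    registration_quality: FitQuality
    cup_fit_quality: FitQuality
    pelvis_condition_number: float
    qc_flagged: bool
    rotation: np.ndarray = None  # full 3x3 migration rotation
    position_a: int | None = None
    position_b: int | None = None
    series: int | None = None

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    @property
    def components(self) -> np.ndarray:
        """(tx, ty, tz, rx, ry, rz) in mm / deg, the reporting order."""
        return np.array([self.dx, self.dy, self.dz, self.rx, self.ry, self.rz])


def register_exams(
    moving: Examination,
    reference: Examination,
    qc_mean_error: float = MEAN_ERROR_LIMIT,
) -> RegistrationResult:
    """Rigid transform taking the moving exam into the reference frame.

    Fitted on the pelvic markers only (intersection of shared ids).  A
    mean error above ``qc_mean_error`` raises the ``flagged`` annotation,
    not an exception.
    """
    shared = moving.pelvis.shared_ids(reference.pelvis)
    if len(shared) < 3:
        raise DegenerateConfigurationError(
            f"only {len(shared)} shared pelvis markers between examinations"
        )
    transform, quality = fit_rigid(
        moving.pelvis.subset(shared), reference.pelvis.subset(shared)
    )
    return RegistrationResult(
        transform=transform,
        quality=quality,
        n_markers=len(shared),
        flagged=quality.mean_error > qc_mean_error,
    )


def cup_migration(
    exam_a: Examination,
    exam_b: Examination,
    qc_mean_error: float = MEAN_ERROR_LIMIT,
) -> MigrationResult:
    """Cup motion from ``exam_a`` to ``exam_b``.

    Translations are reported at the cup marker centroid (the standard
    rigid-body translation convention); rotations as intrinsic x->y->z
    Cardan angles.  When ``exam_a.anatomy_pose`` is set, components are
    expressed in the anatomical frame; otherwise in exam_a's world axes.
    """
    registration = register_exams(exam_b, exam_a, qc_mean_error)
    shared_cup = exam_a.cup.shared_ids(exam_b.cup)
    if len(shared_cup) < 3:
        raise DegenerateConfigurationError(
            f"only {len(shared_cup)} shared cup markers between examinations"
        )
    cup_a = exam_a.cup.subset(shared_cup)
    cup_b_in_a = exam_b.cup.subset(shared_cup).transformed(registration.transform)
    motion, cup_quality = fit_rigid(cup_a, cup_b_in_a)
    translation = motion.apply(cup_a.centroid) - cup_a.centroid
    rotation = motion.rotation
    if exam_a.anatomy_pose is not None:
        frame = exam_a.anatomy_pose.rotation
        translation = frame.T @ translation
        rotation = frame.T @ rotation @ frame
    angles = decompose_cardan(rotation)
    pelvis_cond = condition_number(
        exam_a.pelvis.subset(exam_a.pelvis.shared_ids(exam_b.pelvis))
    )
    return MigrationResult(
        dx=float(translation[0]),
        dy=float(translation[1]),
        dz=float(translation[2]),
        rx=angles.rx,
        ry=angles.ry,
        rz=angles.rz,
        n_pelvis_used=registration.n_markers,
        n_cup_used=len(shared_cup),
        registration_quality=registration.quality,
        cup_fit_quality=cup_quality,
        pelvis_condition_number=pelvis_cond,
        qc_flagged=registration.flagged,
        rotation=rotation,
        position_a=exam_a.position,
        position_b=exam_b.position,
        series=exam_a.series if exam_a.series == exam_b.series else None,
    )


def _index_study(study: Sequence[Examination]) -> dict[tuple[int, int], Examination]:
    index: dict[tuple[int, int], Examination] = {}
    for exam in study:
        index[(exam.position, exam.series)] = exam
    return index


def double_examination_migrations(
    study: Sequence[Examination], qc_mean_error: float = MEAN_ERROR_LIMIT
) -> list[MigrationResult]:
    """Within-position series1 -> series2 migrations (true motion is zero).

    These are the double-examination differences from which precision is
    computed: one result per position, each component ideally null.
    """
    index = _index_study(study)
    positions = sorted({p for p, _ in index})
    out = []
    for p in positions:
        try:
            exam1, exam2 = index[(p, 1)], index[(p, 2)]
        except KeyError as exc:
            raise ManifestError(f"position {p} lacks a complete double examination") from exc
        out.append(cup_migration(exam1, exam2, qc_mean_error))
    return out


def pairwise_migrations(
    study: Sequence[Examination],
    pairs: Sequence[tuple[int, int]] = ((1, 2), (3, 4), (5, 6)),
    qc_mean_error: float = MEAN_ERROR_LIMIT,
) -> list[MigrationResult]:
    """Independent between-position migrations, series-matched.

    For each position pair (1-2, 3-4, 5-6) and each series, the migration
    from the first to the second position is measured, giving up to six
    independent results per study.
    """
    index = _index_study(study)
    series_levels = sorted({s for _, s in index})
    out = []
    for p, q in pairs:
        for s in series_levels:
            if (p, s) not in index or (q, s) not in index:
                raise ManifestError(
                    f"missing examination for position pair ({p},{q}), series {s}"
                )
            out.append(cup_migration(index[(p, s)], index[(q, s)], qc_mean_error))
    return out
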