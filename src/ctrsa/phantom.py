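"""Synthetic pelvic phantom: marker geometry, jig motions, study design, CT rendering.

The simulator emulates a bench experiment in which an acetabular cup,
marked with 1.0 mm tantalum beads around the periphery of its liner
opening, is mounted on a bead-marked pelvic model via a jig that applies
translations in 1.0 mm and rotations (about the x-axis) in 1.0 degree
increments.  Six cup positions are examined; at each position two CT
scans (a "double examination") are acquired with the whole phantom
repositioned in between, leaving the cup-to-pelvis pose untouched.

Axes follow the RSA reporting convention: x = transverse (medial-lateral),
y = longitudinal (cranial-caudal), z = sagittal (anterior-posterior).
The cup bead circle lies in the z = 0 plane centred on the origin and the
pelvic beads are scattered in a periacetabular block on the -z side.

CT volumes are rendered bead-by-bead: each bead is a solid sphere whose
partial-volume occupancy is evaluated on a supersampled grid, convolved
with an isotropic Gaussian PSF, resampled to the acquisition grid
(default 0.6 x 0.6 mm in-plane, 0.3 mm increments) and superimposed on a
uniform background with optional white Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError, GeometryError, ManifestError
from .markers import MarkerSet
from .rigid import CardanAngles, RigidTransform, decompose_cardan
from .volume import VoxelVolume

#: cup position schedule (cumulative jig settings, mm / deg); pairwise
#: deltas for (1,2), (3,4), (5,6) exercise x, z and y translations plus
#: x rotations, all in 1.0 mm / 1.0 deg increments within +/-3.
DEFAULT_JIG_SCHEDULE: tuple[tuple[float, float, float, float], ...] = (
    (0.0, 0.0, 0.0, 0.0),
    (1.0, 0.0, 0.0, 1.0),
    (1.0, 1.0, 0.0, 1.0),
    (1.0, 1.0, 1.0, 2.0),
    (2.0, 1.0, 1.0, 2.0),
    (2.0, 2.0, 1.0, 3.0),
)

#: independent position pairs used for accuracy ("migration") comparisons
DEFAULT_POSITION_PAIRS: tuple[tuple[int, int], ...] = ((1, 2), (3, 4), (5, 6))

_MODALITY_STREAM = {"CT": 11, "RSA": 13}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry, acquisition and noise parameters.

    The defaults are the simulated study conditions: 9 pelvic beads,
    9 (cemented) or 12 (uncemented) cup beads of 1.0 mm diameter, CT grid
    0.6 x 0.6 x 0.3 mm, tantalum rendered at 3000 HU over a 100 HU plastic
    background with a 0.4 mm PSF and 20 HU acquisition noise.
    """

    cup_type: str = "cemented"
    n_pelvis_markers: int = 9
    n_cup_markers: int | None = None  # resolved from cup_type when None
    cup_radius: float = 25.0
    bead_diameter: float = 1.0
    pelvis_spread: tuple[float, float, float] = (60.0, 60.0, 40.0)
    pelvis_center: tuple[float, float, float] = (0.0, 0.0, -35.0)
    min_marker_separation: float = 8.0
    noise_sd: float = 20.0
    blur_sigma: float = 0.4
    bead_intensity: float = 3000.0
    background_intensity: float = 100.0
    spacing: tuple[float, float, float] = (0.6, 0.6, 0.3)
    fov_size: tuple[float, float, float] | None = None  # None -> fit to markers
    fov_margin: float = 12.0
    reposition_max_rotation: float = 10.0  # deg per axis
    reposition_max_translation: float = 20.0  # mm per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cup_type not in ("cemented", "uncemented"):
            raise ConfigurationError(f"unknown cup_type {self.cup_type!r}")
        if self.n_cup_markers is None:
            object.__setattr__(
                self, "n_cup_markers", 9 if self.cup_type == "cemented" else 12
            )
        if self.n_pelvis_markers < 3 or self.n_cup_markers < 3:
            raise ConfigurationError("each rigid body needs at least 3 markers")
        if self.bead_diameter <= 0:
            raise ConfigurationError("bead_diameter must be positive")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ConfigurationError("noise_sd and blur_sigma must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing components must be positive")


@dataclass(frozen=True)
class JigSetting:
    """Cup displacement applied by the jig: translation (mm) + x rotation (deg)."""

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    rx: float = 0.0

    def as_arrays(self) -> tuple[np.ndarray, float]:
        return np.array([self.dx, self.dy, self.dz], dtype=float), float(self.rx)

    def on_increment_grid(self, increment: float = 1.0, tol: float = 1e-9) -> bool:
        """True when all components are integer multiples of the jig increment."""
        vals = (self.dx, self.dy, self.dz, self.rx)
        return all(abs(v / increment - round(v / increment)) < tol for v in vals)


@dataclass(frozen=True)
class GroundTruthMigration:
    """True cup motion between two positions: centroid translation + Cardan angles."""

    translations: np.ndarray  # (3,) mm
    rotations: np.ndarray  # (3,) deg
    pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "translations", np.asarray(self.translations, float).reshape(3))
        object.__setattr__(self, "rotations", np.asarray(self.rotations, float).reshape(3))


def make_phantom_markers(config: PhantomConfig) -> tuple[MarkerSet, MarkerSet]:
    """Seeded pelvis + cup marker geometry in the phantom frame.

    Pelvic beads are drawn uniformly in the periacetabular block with a
    minimum pairwise separation (beads implanted too close could not be
    told apart in any modality); cup beads are equally spaced on a circle
    of ``cup_radius`` in the liner-opening plane (z = 0).
    """
    rng = _rng(config.seed, 101)
    center = np.asarray(config.pelvis_center, float)
    half = np.asarray(config.pelvis_spread, float) / 2.0
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < config.n_pelvis_markers:
        candidate = center + rng.uniform(-half, half)
        if all(np.linalg.norm(candidate - p) >= config.min_marker_separation for p in points):
            points.append(candidate)
        tries += 1
        if tries > 100_000:
            raise ConfigurationError(
                "could not place pelvis markers with the requested separation"
            )
    pelvis = MarkerSet(
        body="pelvis",
        ids=tuple(f"p{k + 1:02d}" for k in range(config.n_pelvis_markers)),
        coords=np.array(points),
    )
    angles = 2.0 * np.pi * np.arange(config.n_cup_markers) / config.n_cup_markers
    cup_coords = np.column_stack(
        [
            config.cup_radius * np.cos(angles),
            config.cup_radius * np.sin(angles),
            np.zeros_like(angles),
        ]
    )
    cup = MarkerSet(
        body="cup",
        ids=tuple(f"c{k + 1:02d}" for k in range(config.n_cup_markers)),
        coords=cup_coords,
    )
    return pelvis, cup


def jig_transform(setting: JigSetting, pivot) -> RigidTransform:
    """Rigid transform of a jig setting: x rotation about ``pivot``, then translation."""
    d, rx = setting.as_arrays()
    pivot = np.asarray(pivot, dtype=float)
    rot = Rotation.from_euler("x", rx, degrees=True).as_matrix()
    return RigidTransform(rot, pivot - rot @ pivot + d)


def apply_jig(cup: MarkerSet, setting: JigSetting) -> MarkerSet:
    """Move the cup by a jig setting (rotation about the cup centre, then translation)."""
    return cup.transformed(jig_transform(setting, cup.centroid))


@dataclass(frozen=True)
class StudyManifest:
    """A 6-position x 2-series double-examination study with known ground truth.

    The cup-to-pelvis pose is identical within the two series of a
    position; the whole-phantom repositioning pose differs between series
    (and between the CT and RSA acquisitions of the same series).
    """

    config: PhantomConfig
    pelvis: MarkerSet
    cup: MarkerSet
    positions: tuple[JigSetting, ...]
    poses: Mapping[tuple[str, int, int], RigidTransform]
    position_pairs: tuple[tuple[int, int], ...] = DEFAULT_POSITION_PAIRS
    series_per_position: int = 2

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def jig_transform(self, position: int) -> RigidTransform:
        self._check_position(position)
        return jig_transform(self.positions[position - 1], self.cup.centroid)

    def cup_at(self, position: int) -> MarkerSet:
        """Cup markers in the phantom frame at a given jig position."""
        return self.cup.transformed(self.jig_transform(position))

    def pose(self, position: int, series: int, modality: str = "CT") -> RigidTransform:
        self._check_position(position)
        try:
            return self.poses[(modality, position, series)]
        except KeyError as exc:
            raise ManifestError(
                f"no repositioning pose for modality={modality} "
                f"position={position} series={series}"
            ) from exc

    def exam_markers(
        self, position: int, series: int, modality: str = "CT"
    ) -> tuple[MarkerSet, MarkerSet]:
        """Posed (pelvis, cup) ground-truth markers of one examination."""
        pose = self.pose(position, series, modality)
        return self.pelvis.transformed(pose), self.cup_at(position).transformed(pose)

    def true_migration(self, position_a: int, position_b: int) -> GroundTruthMigration:
        """Exact cup motion from ``position_a`` to ``position_b`` (pelvis frame)."""
        j_a = self.jig_transform(position_a)
        j_b = self.jig_transform(position_b)
        motion = j_b.compose(j_a.inverse())
        centroid_a = self.cup_at(position_a).centroid
        translations = motion.apply(centroid_a) - centroid_a
        rotations = decompose_cardan(motion).as_array()
        return GroundTruthMigration(translations, rotations, pair=(position_a, position_b))

    @property
    def ground_truth(self) -> dict[tuple[int, int], GroundTruthMigration]:
        return {pair: self.true_migration(*pair) for pair in self.position_pairs}

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= len(self.positions):
            raise ManifestError(
                f"position {position} outside 1..{len(self.positions)}"
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
            "pelvis": {"ids": list(self.pelvis.ids), "coords": self.pelvis.coords.tolist()},
            "cup": {"ids": list(self.cup.ids), "coords": self.cup.coords.tolist()},
            "positions": [[s.dx, s.dy, s.dz, s.rx] for s in self.positions],
            "poses": [
                {
                    "modality": m,
                    "position": p,
                    "series": s,
                    "rotation": t.rotation.tolist(),
                    "translation": t.translation.tolist(),
                }
                for (m, p, s), t in self.poses.items()
            ],
            "position_pairs": [list(p) for p in self.position_pairs],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "StudyManifest":
        cfg_raw = dict(payload["config"])
        for key in ("pelvis_spread", "pelvis_center", "spacing", "fov_size"):
            if cfg_raw.get(key) is not None:
                cfg_raw[key] = tuple(cfg_raw[key])
        config = PhantomConfig(**cfg_raw)
        pelvis = MarkerSet("pelvis", tuple(payload["pelvis"]["ids"]), np.array(payload["pelvis"]["coords"]))
        cup = MarkerSet("cup", tuple(payload["cup"]["ids"]), np.array(payload["cup"]["coords"]))
        positions = tuple(JigSetting(*vals) for vals in payload["positions"])
        poses = {
            (e["modality"], int(e["position"]), int(e["series"])): RigidTransform(
                np.array(e["rotation"]), np.array(e["translation"])
            )
            for e in payload["poses"]
        }
        pairs = tuple(tuple(p) for p in payload["position_pairs"])
        return cls(config, pelvis, cup, positions, poses, pairs)


def _random_pose(rng: np.random.Generator, config: PhantomConfig) -> RigidTransform:
    angles = rng.uniform(
        -config.reposition_max_rotation, config.reposition_max_rotation, 3
    )
    translation = rng.uniform(
        -config.reposition_max_translation, config.reposition_max_translation, 3
    )
    return RigidTransform(
        Rotation.from_euler("XYZ", angles, degrees=True).as_matrix(), translation
    )


def build_study(
    config: PhantomConfig,
    schedule: Sequence[tuple[float, float, float, float]] = DEFAULT_JIG_SCHEDULE,
) -> StudyManifest:
    """Assemble the 6-position x 2-series study manifest with ground truth.

    Each position adds translation and/or rotation to the cup relative to
    the previous one; every (modality, position, series) gets its own
    seeded whole-phantom repositioning pose.
    """
    pelvis, cup = make_phantom_markers(config)
    positions = tuple(JigSetting(*row) for row in schedule)
    poses: dict[tuple[str, int, int], RigidTransform] = {}
    for modality, stream in _MODALITY_STREAM.items():
        for p in range(1, len(positions) + 1):
            for s in range(1, 3):
                poses[(modality, p, s)] = _random_pose(
                    _rng(config.seed, 103, stream, p, s), config
                )
    return StudyManifest(config, pelvis, cup, positions, poses)


# ---------------------------------------------------------------------------
# CT rendering
# ---------------------------------------------------------------------------


def _bead_support_radius(config: PhantomConfig) -> float:
    return config.bead_diameter / 2.0 + 4.0 * config.blur_sigma + max(config.spacing)


def _render_grid(
    coords: np.ndarray, config: PhantomConfig, origin, shape
) -> tuple[np.ndarray, tuple[int, int, int]]:
    spacing = np.asarray(config.spacing, float)
    if origin is not None and shape is not None:
        return np.asarray(origin, float), tuple(int(n) for n in shape)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    if config.fov_size is not None:
        size = np.asarray(config.fov_size, float)
        center = (lo + hi) / 2.0
        n = np.maximum(np.ceil(size / spacing).astype(int), 2)
        return center - (n - 1) / 2.0 * spacing, tuple(n)
    margin = config.fov_margin
    n = np.maximum(np.ceil((hi - lo + 2 * margin) / spacing).astype(int) + 1, 2)
    return lo - margin, tuple(n)


def render_ct(
    pelvis: MarkerSet,
    cup: MarkerSet,
    phantom_pose: RigidTransform,
    config: PhantomConfig,
    origin=None,
    shape=None,
    noise_stream: int = 0,
) -> VoxelVolume:
    """Render one CT examination of the posed phantom.

    Beads are rendered as partial-volume spheres (supersampled >= 3x per
    axis), blurred by the Gaussian PSF, and added to a uniform background;
    seeded white noise of ``config.noise_sd`` HU is superimposed.  The
    noise realisation is determined by ``(config.seed, noise_stream)`` so
    repeated renders are bit-identical.

    Raises
    ------
    GeometryError
        When a bead (including its PSF support) does not fit in the FOV.
    """
    posed_pelvis = pelvis.transformed(phantom_pose)
    posed_cup = cup.transformed(phantom_pose)
    all_ids = list(posed_pelvis.ids) + list(posed_cup.ids)
    coords = np.vstack([posed_pelvis.coords, posed_cup.coords])

    spacing = np.asarray(config.spacing, float)
    origin, shape = _render_grid(coords, config, origin, shape)
    data = np.full(shape, config.background_intensity, dtype=np.float32)

    radius = config.bead_diameter / 2.0
    support = _bead_support_radius(config)
    contrast = config.bead_intensity - config.background_intensity
    factors = np.maximum(3, np.ceil(spacing / 0.125).astype(int))
    sub_spacing = spacing / factors
    edge_width = float(np.mean(sub_spacing))

    for marker_id, center in zip(all_ids, coords):
        f_idx = (center - origin) / spacing
        lo = np.floor(f_idx - support / spacing).astype(int)
        hi = np.ceil(f_idx + support / spacing).astype(int)
        if np.any(lo < 0) or np.any(hi > np.asarray(shape) - 1):
            raise GeometryError(
                f"marker {marker_id} at {np.round(center, 2)} mm does not fit "
                f"in the rendered FOV (origin {np.round(origin, 2)}, shape {shape})"
            )
        axes_mm = []
        for ax in range(3):
            n_vox = hi[ax] - lo[ax] + 1
            sub = (
                lo[ax]
                - 0.5
                + (np.arange(n_vox * factors[ax]) + 0.5) / factors[ax]
            )
            axes_mm.append(origin[ax] + sub * spacing[ax] - center[ax])
        dx2 = axes_mm[0][:, None, None] ** 2
        dy2 = axes_mm[1][None, :, None] ** 2
        dz2 = axes_mm[2][None, None, :] ** 2
        dist = np.sqrt(dx2 + dy2 + dz2)
        occupancy = np.clip(0.5 + (radius - dist) / edge_width, 0.0, 1.0)
        patch = contrast * occupancy
        if config.blur_sigma > 0:
            patch = ndimage.gaussian_filter(
                patch, sigma=tuple(config.blur_sigma / sub_spacing), mode="constant"
            )
        nx, ny, nz = hi - lo + 1
        patch = patch.reshape(nx, factors[0], ny, factors[1], nz, factors[2]).mean(
            axis=(1, 3, 5)
        )
        data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += patch.astype(
            np.float32
        )

    if config.noise_sd > 0:
        rng = _rng(config.seed, 7, noise_stream)
        data += config.noise_sd * rng.standard_normal(shape, dtype=np.float32)
    return VoxelVolume(data=data, spacing=spacing, origin=origin)


def render_examination(
    manifest: StudyManifest, position: int, series: int, origin=None, shape=None
) -> VoxelVolume:
    """Render the CT volume of one (position, series) examination."""
    pose = manifest.pose(position, series, "CT")
    return render_ct(
        manifest.pelvis,
        manifest.cup_at(position),
        pose,
        manifest.config,
        origin=origin,
        shape=shape,
        noise_stream=position * 10 + series,
    )
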