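"""Subvoxel tantalum-bead detection and template labelling in CT volumes.

Detection thresholds the volume, extracts 26-connected components within a
size window and reports one intensity-weighted centroid per component.
Centroids are then refined to subvoxel precision with a background-
subtracted intensity-weighted centroid over a spherical window: at 2-4
voxels per bead the weighted centroid is the stable "best fit centre"
estimator, and for a symmetric bead-plus-PSF profile it is unbiased.

Labelling matches unordered candidate centroids against an expected
marker template.  Because rigid motion preserves pairwise distances, a
coarse alignment is found by congruent-triangle search (RANSAC over
triplets) and the final correspondence is a one-to-one nearest-neighbour
assignment; candidates from other rigid bodies in the same volume are
tolerated as outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .errors import DetectionError, LabellingError, RefinementError, ValidationError
from .markers import MarkerSet
from .rigid import RigidTransform, fit_rigid
from .volume import VoxelVolume


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding, component-size and refinement parameters.

    ``threshold`` (HU) must lie between the background level and the peak
    of the blurred bead profile; the default 600 HU sits midway between a
    100 HU background and the ~1050 HU peak that a 1.0 mm bead of 3000 HU
    shows after a 0.4 mm PSF.  ``rel_floor`` sets the refinement support:
    voxels below background + rel_floor * (peak - background) are ignored,
    which suppresses the noise contribution far from the bead while
    truncating the symmetric profile tail without bias.
    """

    threshold: float = 600.0
    min_voxels: int = 2
    max_voxels: int = 120
    window_radius: float = 2.0
    rel_floor: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.min_voxels < self.max_voxels:
            raise ValidationError("need 0 < min_voxels < max_voxels")
        if self.window_radius <= 0:
            raise ValidationError("window_radius must be positive")


def detect_beads(volume: VoxelVolume, params: DetectionParams | None = None) -> np.ndarray:
    """Candidate bead centres (world mm) from thresholded connected components.

    Returns an (n, 3) array, one row per surviving component, each the
    intensity-weighted centroid of its component.  Raises
    :class:`DetectionError` with threshold diagnostics when nothing
    survives.
    """
    params = params or DetectionParams()
    data = np.asarray(volume.data)
    mask = data > params.threshold
    labels, n_components = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n_components == 0:
        raise DetectionError(
            f"no voxels above threshold {params.threshold:g} HU "
            f"(volume max {float(data.max()):g} HU)"
        )
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero((sizes >= params.min_voxels) & (sizes <= params.max_voxels)) + 1
    if keep.size == 0:
        raise DetectionError(
            f"{n_components} components above {params.threshold:g} HU but none "
            f"within the size window [{params.min_voxels}, {params.max_voxels}] "
            f"voxels (sizes: {sorted(sizes.tolist())})"
        )
    slices = ndimage.find_objects(labels)
    centers = []
    for lab in keep:
        sl = slices[lab - 1]
        local = np.where(labels[sl] == lab, data[sl], 0.0)
        total = local.sum()
        offsets = [s.start for s in sl]
        idx = [
            (local.sum(axis=tuple(a for a in range(3) if a != ax)) * np.arange(local.shape[ax])).sum()
            / total
            + offsets[ax]
            for ax in range(3)
        ]
        centers.append(idx)
    return volume.voxel_to_world(np.asarray(centers))


def refine_centroid(
    volume: VoxelVolume, seed_point, params: DetectionParams | None = None
) -> np.ndarray:
    """Subvoxel bead centre: background-subtracted weighted centroid near a seed.

    The window is a sphere of ``params.window_radius`` mm around
    ``seed_point``; the background is estimated as the window median and
    only voxels above background + ``rel_floor`` * (peak - background)
    contribute weight.
    """
    params = params or DetectionParams()
    seed = np.asarray(seed_point, dtype=float).reshape(3)
    center_idx = volume.world_to_voxel(seed)
    half = np.ceil(params.window_radius / volume.spacing).astype(int)
    lo = np.maximum(np.round(center_idx).astype(int) - half, 0)
    hi = np.minimum(np.round(center_idx).astype(int) + half, np.asarray(volume.shape) - 1)
    if np.any(hi < lo):
        raise RefinementError(f"window around {seed} mm lies outside the volume")

    window = np.asarray(
        volume.data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1], dtype=float
    )
    idx = np.stack(
        np.meshgrid(
            np.arange(lo[0], hi[0] + 1),
            np.arange(lo[1], hi[1] + 1),
            np.arange(lo[2], hi[2] + 1),
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)
    world = volume.voxel_to_world(idx)
    values = window.reshape(-1)
    in_sphere = np.linalg.norm(world - seed, axis=1) <= params.window_radius
    values = values[in_sphere]
    world = world[in_sphere]

    if values.size == 0 or values.max() <= params.threshold:
        raise RefinementError(
            f"no voxel above threshold {params.threshold:g} HU within "
            f"{params.window_radius:g} mm of {np.round(seed, 2)}"
        )
    background = float(np.median(values))
    floor = background + params.rel_floor * (float(values.max()) - background)
    weights = np.clip(values - floor, 0.0, None)
    total = weights.sum()
    if total <= 0:
        raise RefinementError("refinement window carries no weight above background")
    return (weights[:, None] * world).sum(axis=0) / total


def detect_and_refine(
    volume: VoxelVolume, params: DetectionParams | None = None
) -> np.ndarray:
    """Detection followed by per-candidate subvoxel refinement."""
    params = params or DetectionParams()
    return np.array([refine_centroid(volume, c, params) for c in detect_beads(volume, params)])


# ---------------------------------------------------------------------------
# Template labelling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelResult:
    """Outcome of matching detected candidates to a marker template."""

    markers: MarkerSet  # labelled candidates (source='detected')
    missing: tuple[str, ...]  # template ids with no matching candidate
    unmatched: tuple[int, ...]  # candidate row indices left unassigned
    transform: RigidTransform  # coarse template -> candidate alignment


def _triplet_hypotheses(
    template: np.ndarray, candidates: np.ndarray, side_tol: float
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Congruent (template-triplet, candidate-triplet) pairs, best-first order."""
    from itertools import combinations, permutations

    m, n = len(template), len(candidates)
    t_triplets = sorted(
        combinations(range(m), 3),
        key=lambda t: -min(
            np.linalg.norm(template[a] - template[b])
            for a, b in combinations(t, 2)
        ),
    )[:40]
    c_triplets = list(combinations(range(n), 3))
    c_sides = np.array(
        [
            sorted(
                np.linalg.norm(candidates[a] - candidates[b])
                for a, b in combinations(t, 2)
            )
            for t in c_triplets
        ]
    )
    hypotheses = []
    for tt in t_triplets:
        t_pts = template[list(tt)]
        sides_sorted = np.sort(
            [np.linalg.norm(t_pts[a] - t_pts[b]) for a, b in combinations(range(3), 2)]
        )
        close = np.flatnonzero(np.all(np.abs(c_sides - sides_sorted) < side_tol, axis=1))
        for ci in close:
            c_idx = c_triplets[ci]
            for perm in permutations(c_idx):
                c_pts = candidates[list(perm)]
                ok = all(
                    abs(
                        np.linalg.norm(t_pts[a] - t_pts[b])
                        - np.linalg.norm(c_pts[a] - c_pts[b])
                    )
                    < side_tol
                    for a, b in combinations(range(3), 2)
                )
                if ok:
                    hypotheses.append((t_pts, c_pts))
    return hypotheses


def _mutual_assignment(
    dist: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment, keeping pairs within ``radius``."""
    big = 1e6
    cost = np.where(dist <= radius, dist, big)
    rows, cols = linear_sum_assignment(cost)
    return [(r, c) for r, c in zip(rows, cols) if dist[r, c] <= radius]


def label_markers(
    candidates,
    template: MarkerSet,
    prealigned: bool = False,
    match_radius: float | None = None,
    side_tol: float = 1.0,
) -> LabelResult:
    """Assign template marker ids to detected candidate centres.

    With ``prealigned=False`` (default) a coarse rigid alignment of the
    template onto the candidates is recovered first by congruent-triangle
    search; with ``prealigned=True`` the sets are assumed to be already in
    a common frame (e.g. a template carried through a registration) and
    only nearest-neighbour assignment is performed, gated at
    ``match_radius`` (default 1.5 mm after alignment, 6.0 mm prealigned).

    Raises
    ------
    LabellingError
        When no congruent alignment is found, or when two template ids
        contend for the same candidate (ambiguous assignment).
    """
    cand = np.asarray(candidates, dtype=float).reshape(-1, 3)
    if match_radius is None:
        match_radius = 6.0 if prealigned else 1.5
    if len(cand) < 3:
        raise LabellingError(f"need >= 3 candidates to label, got {len(cand)}")

    tpl = template.coords
    if prealigned:
        transform = RigidTransform.identity()
        aligned = tpl
    else:
        transform, aligned = _coarse_align(tpl, cand, match_radius, side_tol)

    dist = np.linalg.norm(aligned[:, None, :] - cand[None, :, :], axis=2)
    pairs = _mutual_assignment(dist, match_radius)
    assigned_t = {t for t, _ in pairs}
    assigned_c = {c for _, c in pairs}
    # ambiguity: an unassigned template id that still lies within the match
    # radius of some (already taken) candidate
    for t in range(len(tpl)):
        if t in assigned_t:
            continue
        contested = np.flatnonzero(dist[t] <= match_radius)
        for c in contested:
            owner = next((tt for tt, cc in pairs if cc == c), None)
            if owner is not None:
                raise LabellingError(
                    f"templates {template.ids[t]!r} and {template.ids[owner]!r} "
                    f"both match candidate {c} within {match_radius:g} mm"
                )
    pairs.sort(key=lambda p: p[0])
    labelled = MarkerSet(
        body=template.body,
        ids=tuple(template.ids[t] for t, _ in pairs),
        coords=cand[[c for _, c in pairs]],
        source="detected",
    )
    missing = tuple(template.ids[t] for t in range(len(tpl)) if t not in assigned_t)
    unmatched = tuple(c for c in range(len(cand)) if c not in assigned_c)
    return LabelResult(labelled, missing, unmatched, transform)


def _coarse_align(
    tpl: np.ndarray, cand: np.ndarray, match_radius: float, side_tol: float
) -> tuple[RigidTransform, np.ndarray]:
    # fast path: template already on top of the candidates
    ident = RigidTransform.identity()
    inl, rms = _score(tpl, cand, match_radius)
    if inl == len(tpl):
        return ident, tpl

    best: tuple[int, float, RigidTransform] | None = None
    if inl >= 3:
        best = (inl, rms, ident)
    for t_pts, c_pts in _triplet_hypotheses(tpl, cand, side_tol):
        try:
            transform, _ = fit_rigid(t_pts, c_pts)
        except Exception:  # collinear triplet
            continue
        inl, rms = _score(transform.apply(tpl), cand, match_radius)
        if inl >= 3 and (best is None or (inl, -rms) > (best[0], -best[1])):
            best = (inl, rms, transform)
            if inl == len(tpl):
                break
    if best is None:
        raise LabellingError(
            "no rigid alignment of the template onto the candidates found "
            f"(side tolerance {side_tol:g} mm)"
        )
    transform = best[2]
    # polish: refit on the current inlier correspondence
    dist = np.linalg.norm(
        transform.apply(tpl)[:, None, :] - cand[None, :, :], axis=2
    )
    pairs = _mutual_assignment(dist, match_radius)
    if len(pairs) >= 3:
        transform, _ = fit_rigid(tpl[[t for t, _ in pairs]], cand[[c for _, c in pairs]])
    return transform, transform.apply(tpl)


def _score(aligned: np.ndarray, cand: np.ndarray, radius: float) -> tuple[int, float]:
    dist = np.linalg.norm(aligned[:, None, :] - cand[None, :, :], axis=2)
    pairs = _mutual_assignment(dist, radius)
    if not pairs:
        return 0, float("inf")
    rms = float(np.sqrt(np.mean([dist[t, c] ** 2 for t, c in pairs])))
    return len(pairs), rms
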