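"""Labelled fiducial-marker sets grouped into rigid bodies.

A :class:`MarkerSet` holds the 3D world coordinates (mm) of the tantalum
beads belonging to one rigid body — either the periacetabular bone
(``pelvis``) or the implant (``cup``).  Marker tables are read and written
as CSV with columns ``body, marker_id, x_mm, y_mm, z_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

BODIES = ("pelvis", "cup")
SOURCES = ("ground_truth", "detected", "reconstructed")

CSV_COLUMNS = ["body", "marker_id", "x_mm", "y_mm", "z_mm"]


@dataclass(frozen=True)
class MarkerSet:
    """A rigid body's labelled bead coordinates in world mm.

    Parameters
    ----------
    body : {"pelvis", "cup"}
    ids : sequence of str
        Unique marker labels within the set.
    coords : (n, 3) float array
        World coordinates in mm, one row per marker, same order as ``ids``.
    source : {"ground_truth", "detected", "reconstructed"}
    """

    body: str
    ids: tuple[str, ...]
    coords: np.ndarray
    source: str = "ground_truth"

    def __post_init__(self) -> None:
        if self.body not in BODIES:
            raise ValidationError(f"unknown body {self.body!r}, expected one of {BODIES}")
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        ids = tuple(str(i) for i in self.ids)
        coords = np.asarray(self.coords, dtype=float).reshape(len(ids), 3)
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate marker ids in {self.body} set")
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"non-finite coordinates in {self.body} set")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def subset(self, ids: Iterable[str]) -> "MarkerSet":
        ids = [str(i) for i in ids]
        index = {m: k for k, m in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValidationError(f"marker ids {missing} not present in {self.body} set")
        rows = [index[i] for i in ids]
        return replace(self, ids=tuple(ids), coords=self.coords[rows])

    def transformed(self, transform) -> "MarkerSet":
        """Return the set moved by a :class:`~ctrsa.rigid.RigidTransform`."""
        return replace(self, coords=transform.apply(self.coords))

    def with_source(self, source: str) -> "MarkerSet":
        return replace(self, source=source)

    def shared_ids(self, other: "MarkerSet") -> tuple[str, ...]:
        other_ids = set(other.ids)
        return tuple(i for i in self.ids if i in other_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "body": self.body,
                "marker_id": list(self.ids),
                "x_mm": self.coords[:, 0],
                "y_mm": self.coords[:, 1],
                "z_mm": self.coords[:, 2],
            }
        )


def write_markers(sets: Sequence[MarkerSet], path: str | Path) -> None:
    """Write one or more marker sets to a single CSV table."""
    frame = pd.concat([s.to_frame() for s in sets], ignore_index=True)
    frame.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_markers(path: str | Path, source: str = "ground_truth") -> dict[str, MarkerSet]:
    """Read a marker CSV, returning one MarkerSet per rigid body present."""
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: marker table missing columns {missing}")
    out: dict[str, MarkerSet] = {}
    for body, group in frame.groupby("body", sort=True):
        out[str(body)] = MarkerSet(
            body=str(body),
            ids=tuple(str(i) for i in group["marker_id"]),
            coords=group[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            source=source,
        )
    return out


def marker_dict(sets: Iterable[MarkerSet]) -> Mapping[str, MarkerSet]:
    return {s.body: s for s in sets}
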