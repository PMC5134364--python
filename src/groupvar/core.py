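"""Core containers shared across the pipeline.

Everything operates on tissue-concentration grids: per-voxel fractions in
[0, 1] of gray matter (GM), white matter (WM) and cerebrospinal fluid (CSF)
on a common lattice.  Grids may be 2-D (the fast default used for analysis
at desk scale) or 3-D; all downstream code is dimension-agnostic.

Coordinate conventions: 0-based voxel indices, voxel-centred sampling,
displacements expressed in voxel units.  Physical spacing (mm per voxel
axis) is only consulted when converting a smoothing FWHM to voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

TISSUES = ("gm", "wm", "csf")

#: tolerance on the per-voxel tissue-sum constraint gm+wm+csf <= 1
TISSUE_SUM_EPS = 1e-6


class GroupvarError(Exception):
    """Base class for all pipeline errors."""


class ShapeError(GroupvarError):
    """Lattice/shape mismatch between grids."""


class DataError(GroupvarError):
    """Non-finite or out-of-contract values in inputs."""


class CardinalityError(GroupvarError):
    """Too few (or too many) elements for an operation."""


class ParameterError(GroupvarError):
    """Invalid configuration value."""


class DegenerateGeometryError(GroupvarError):
    """Phantom parameters produce an empty or inverted structure."""


class PairingError(GroupvarError):
    """No acceptable age-matched partner available."""


class Diagnosis(str, Enum):
    TDC = "TDC"
    ASD = "ASD"


@dataclass(frozen=True)
class TissueMapSet:
    """GM/WM/CSF concentration grids for one subject on a shared lattice.

    Invariants (checked by :meth:`validate`): every voxel value lies in
    [0, 1], the three grids share shape, and gm+wm+csf <= 1 + eps at every
    voxel.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape

    @property
    def ndim(self) -> int:
        return self.gm.ndim

    def tissue(self, name: str) -> np.ndarray:
        if name not in TISSUES:
            raise KeyError(name)
        return getattr(self, name)

    def validate(self) -> None:
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise ShapeError("tissue grids do not share a lattice")
        if len(self.spacing) != self.gm.ndim:
            raise ShapeError("spacing length does not match grid dimension")
        for name in TISSUES:
            arr = self.tissue(name)
            if not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite values in {name} map")
            if arr.min() < -TISSUE_SUM_EPS or arr.max() > 1 + TISSUE_SUM_EPS:
                raise DataError(f"{name} concentrations outside [0, 1]")
        total = self.gm + self.wm + self.csf
        if total.max() > 1 + TISSUE_SUM_EPS:
            raise DataError("gm+wm+csf exceeds 1 at some voxel")

    def with_maps(self, **maps: np.ndarray) -> "TissueMapSet":
        return replace(self, **maps)

    def stack(self, channels: tuple[str, ...] = TISSUES) -> np.ndarray:
        """Channel-first array view of the selected tissue maps."""
        return np.stack([self.tissue(c) for c in channels])


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: identity, covariates and tissue maps."""

    subject_id: str
    age: float
    diagnosis: Diagnosis
    seed: int
    maps: TissueMapSet


@dataclass
class GroupTemplate:
    """Per-tissue mean concentration grids from iterative template building.

    ``history`` records the mean absolute per-voxel template change at each
    outer iteration, the operational proxy for the template growing
    progressively crisper.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)
    iteration_index: int = 0
    history: list[float] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm.shape

    def tissue(self, name: str) -> np.ndarray:
        if name not in TISSUES:
            raise KeyError(name)
        return getattr(self, name)

    def as_map_set(self) -> TissueMapSet:
        return TissueMapSet(gm=self.gm, wm=self.wm, csf=self.csf, spacing=self.spacing)


def check_same_lattice(*shapes: tuple[int, ...]) -> None:
    first = shapes[0]
    for s in shapes[1:]:
        if s != first:
            raise ShapeError(f"lattice mismatch: {s} vs {first}")
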