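"""Core in-memory containers shared across the pipeline.

All image arrays follow the (z, y, x) axis convention with 0-based indexing;
z is the light-sheet scan axis. Physical voxel spacing is carried alongside
every grid so downstream volumetry can convert voxel counts to μm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Volume3D",
    "Mask3D",
    "ChamberMap",
    "CineSequence",
    "StackMeta",
    "LABEL_BACKGROUND",
    "LABEL_ATRIUM",
    "LABEL_VENTRICLE",
]

#: 8-bit label coding used on disk for chamber maps.
LABEL_BACKGROUND = 0
LABEL_ATRIUM = 100
LABEL_VENTRICLE = 200


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class Volume3D:
    """One 3D grayscale stack with physical voxel spacing.

    Parameters
    ----------
    data
        Intensity grid of shape (m, ny, nx) — m axial slices.
    spacing
        Voxel spacing (dz, dy, dx) in μm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data.astype(float, copy=False))):
            raise ValueError("volume contains non-finite values")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class Mask3D:
    """Binary intracardiac-lumen mask on the same grid as a :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class ChamberMap:
    """3-valued labeling of the lumen: 0 background, 1 atrium, 2 ventricle."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got shape {self.labels.shape}")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise ValueError(f"chamber labels must be in {{0, 1, 2}}, found {sorted(bad)}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def lumen(self) -> Mask3D:
        """Union of both chambers as a binary mask."""
        return Mask3D(self.labels > 0, self.spacing)

    def chamber(self, label: int) -> Mask3D:
        """Binary mask of one chamber (1 = atrium, 2 = ventricle)."""
        if label not in (1, 2):
            raise ValueError("chamber label must be 1 (atrium) or 2 (ventricle)")
        return Mask3D(self.labels == label, self.spacing)


@dataclass
class CineSequence:
    """Ordered phases of one cardiac cycle (images or masks).

    ``len(frames) * frame_interval == period`` and all frames share shape
    and spacing.
    """

    frames: list
    frame_interval: float  # ms
    period: float  # ms

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a cine needs at least 2 frames to represent a cycle")
        if self.frame_interval <= 0 or self.period <= 0:
            raise ValueError("frame_interval and period must be positive")
        if not np.isclose(len(self.frames) * self.frame_interval, self.period):
            raise ValueError(
                f"{len(self.frames)} frames × {self.frame_interval} ms ≠ period {self.period} ms"
            )
        shapes = {f.shape for f in self.frames}
        spacings = {tuple(f.spacing) for f in self.frames}
        if len(shapes) != 1 or len(spacings) != 1:
            raise ValueError("all cine frames must share shape and spacing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.frames[0].spacing


@dataclass
class StackMeta:
    """Physical metadata carried in JSON sidecars next to TIFF stacks."""

    voxel_spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    frame_interval: float | None = None  # ms
    period: float | None = None  # ms
    provenance: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxel_spacing = _check_spacing(self.voxel_spacing)
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
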