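"""Volumetry, cardiac-mechanics indices, and Dice validation.

Chamber volume is voxel count × voxel volume. Over one synchronized cycle
the extrema of the volume trace give the end-diastolic and end-systolic
volumes (EDV, ESV); stroke volume is SV = EDV − ESV and ejection fraction
EF = 100 · SV / EDV. Segmentation quality against a reference mask is the
Dice similarity 2|A∩B| / (|A| + |B|).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ChamberMap, CineSequence, Mask3D

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeTrace",
    "MechanicsReport",
    "mask_volume",
    "volume_trace",
    "edv_esv",
    "stroke_volume",
    "ejection_fraction",
    "chamber_mechanics",
    "dice",
    "dice_table",
]

CHAMBER_NAMES = {1: "atrium", 2: "ventricle"}


@dataclass
class VolumeTrace:
    """Volume per phase for one chamber (μm³)."""

    chamber: str
    volumes: np.ndarray
    frame_interval: float  # ms

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.ndim != 1 or self.volumes.size == 0:
            raise ValueError("volume trace must be a nonempty 1D sequence")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")


@dataclass
class MechanicsReport:
    """Per-chamber EDV/ESV (μm³), SV (μm³) and EF (%)."""

    chamber: str
    edv: float
    esv: float
    sv: float
    ef: float
    dpf: int | None = None

    def __post_init__(self) -> None:
        if self.esv > self.edv:
            raise ValueError("ESV cannot exceed EDV")
        if not np.isclose(self.sv, self.edv - self.esv):
            raise ValueError("SV must equal EDV − ESV")
        if not 0.0 <= self.ef <= 100.0:
            raise ValueError("EF must lie in [0, 100] percent")


def mask_volume(mask, label: int | None = None) -> float:
    """Foreground volume in μm³: voxel count × dz·dy·dx.

    ``mask`` is a binary :class:`Mask3D`, or a :class:`ChamberMap` with
    ``label`` selecting the chamber (1 atrium, 2 ventricle; None = lumen).
    Additive over disjoint masks by construction.
    """
    if isinstance(mask, ChamberMap):
        data = mask.labels > 0 if label is None else mask.labels == label
        return float(data.sum()) * mask.voxel_volume
    if isinstance(mask, Mask3D):
        if label is not None:
            raise ValueError("label selection requires a ChamberMap")
        return float(mask.data.sum()) * mask.voxel_volume
    raise TypeError(f"cannot measure volume of {type(mask).__name__}")


def volume_trace(maps: CineSequence, label: int) -> VolumeTrace:
    """Volume of one chamber across all phases of a cine."""
    vols = [mask_volume(cmap, label) for cmap in maps]
    return VolumeTrace(CHAMBER_NAMES.get(label, str(label)), vols, maps.frame_interval)


def edv_esv(trace: VolumeTrace) -> tuple[float, float, int, int]:
    """Extrema of the volume trace: (EDV, ESV, phase_of_EDV, phase_of_ESV).

    EDV is the most dilated point, ESV the most contracted; ties resolve to
    the earliest phase index (argmax/argmin convention).
    """
    v = trace.volumes
    i_max = int(np.argmax(v))
    i_min = int(np.argmin(v))
    return float(v[i_max]), float(v[i_min]), i_max, i_min


def stroke_volume(edv: float, esv: float) -> float:
    """SV = EDV − ESV (μm³)."""
    if edv < esv:
        raise ValueError(f"EDV {edv} < ESV {esv}")
    return edv - esv


def ejection_fraction(sv: float, edv: float) -> float:
    """EF = (SV / EDV) × 100, in percent."""
    if edv <= 0:
        raise ValueError("EDV must be positive to compute EF")
    return 100.0 * sv / edv


def chamber_mechanics(
    maps: CineSequence, label: int, dpf: int | None = None
) -> MechanicsReport:
    """EDV/ESV/SV/EF of one chamber from a cine of chamber maps."""
    trace = volume_trace(maps, label)
    edv, esv, _, _ = edv_esv(trace)
    sv = stroke_volume(edv, esv)
    return MechanicsReport(
        chamber=trace.chamber,
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ejection_fraction(sv, edv),
        dpf=dpf,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) of two same-shape binary masks.

    1 means identical segmentations, 0 disjoint ones. Two empty masks are
    defined as perfectly agreeing (the formula's 0/0 case), with a log note.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.info("dice of two empty masks: defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def dice_table(pred: CineSequence, truth: CineSequence) -> "pd.DataFrame":
    """Per-frame and per-slice Dice between predicted and reference cines.

    Returns a tidy DataFrame with columns frame, scope ('frame' or 'slice'),
    z (slice index or −1 for whole-frame rows) and dice. The per-frame value
    pools all voxels of the 3D frame; per-slice rows score each z plane.
    """
    import pandas as pd

    if len(pred) != len(truth):
        raise ValueError("cines have different frame counts")
    rows = []
    for k, (p, t) in enumerate(zip(pred, truth)):
        pm = p.data if isinstance(p, Mask3D) else p.labels > 0
        tm = t.data if isinstance(t, Mask3D) else t.labels > 0
        rows.append({"frame": k, "scope": "frame", "z": -1, "dice": dice(pm, tm)})
        for z in range(pm.shape[0]):
            rows.append(
                {"frame": k, "scope": "slice", "z": z, "dice": dice(pm[z], tm[z])}
            )
    return pd.DataFrame(rows)
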