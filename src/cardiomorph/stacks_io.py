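"""Reading and writing image stacks, masks, and mechanics reports.

Image data travel as multi-page TIFF (one page per z-slice, one file per
cardiac phase) with a JSON sidecar carrying the physical metadata the TIFF
itself does not: voxel spacing in μm, frame interval and cardiac period in
ms. Chamber maps are 8-bit TIFFs coded {0, 100, 200} = {background, atrium,
ventricle}; binary lumen masks are {0, 255}. Reports are plain CSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .containers import (
    LABEL_ATRIUM,
    LABEL_BACKGROUND,
    LABEL_VENTRICLE,
    ChamberMap,
    CineSequence,
    Mask3D,
    StackMeta,
    Volume3D,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_meta",
    "write_meta",
    "write_report",
    "read_report",
    "write_cine",
    "read_cine_masks",
]

#: axial pitch (μm) assumed when no sidecar is present, matching the 2 μm
#: slice thickness of the emulated light-sheet acquisitions
DEFAULT_SPACING = (2.0, 1.0, 1.0)

REPORT_COLUMNS = ["dpf", "chamber", "EDV_um3", "ESV_um3", "SV_um3", "EF_pct"]


def _read_pages(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected 2D pages, got array of shape {arr.shape}")
    return arr


def read_meta(meta_path: str | Path) -> StackMeta:
    d = json.loads(Path(meta_path).read_text())
    return StackMeta(
        voxel_spacing=tuple(d.get("voxel_spacing", DEFAULT_SPACING)),
        frame_interval=d.get("frame_interval"),
        period=d.get("period"),
        provenance=d.get("provenance", ""),
        extra={
            k: v
            for k, v in d.items()
            if k not in {"voxel_spacing", "frame_interval", "period", "provenance"}
        },
    )


def write_meta(meta: StackMeta, meta_path: str | Path) -> None:
    d = {
        "voxel_spacing": list(meta.voxel_spacing),
        "frame_interval": meta.frame_interval,
        "period": meta.period,
        "provenance": meta.provenance,
        **meta.extra,
    }
    Path(meta_path).write_text(json.dumps(d, indent=2, sort_keys=True))


def _sidecar_for(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path: str | Path, meta_path: str | Path | None = None) -> Volume3D:
    """Read a single- or multi-page TIFF as a :class:`Volume3D`.

    The sidecar JSON (``meta_path``, or ``<stem>.json`` next to the TIFF)
    supplies the voxel spacing; if absent the spacing defaults to
    (2, 1, 1) μm with a logged warning.
    """
    path = Path(path)
    arr = _read_pages(path)
    if meta_path is None and _sidecar_for(path).exists():
        meta_path = _sidecar_for(path)
    if meta_path is not None:
        spacing = read_meta(meta_path).voxel_spacing
    else:
        spacing = DEFAULT_SPACING
        logger.warning(
            "%s: no metadata sidecar; assuming voxel spacing %s μm", path, spacing
        )
    return Volume3D(arr, spacing)


def write_stack(
    volume: Volume3D, path: str | Path, meta: StackMeta | None = None
) -> None:
    """Write a volume as a multi-page TIFF (+ JSON sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.data
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(data, 0, 255).astype(np.uint8)
    tifffile.imwrite(str(path), data)
    if meta is None:
        meta = StackMeta(voxel_spacing=volume.spacing)
    write_meta(meta, _sidecar_for(path))


def read_mask(path: str | Path, meta_path: str | Path | None = None):
    """Read an 8-bit mask TIFF as :class:`Mask3D` or :class:`ChamberMap`.

    Value sets {0, 255} (or {0, v} for one nonzero v, with a warning) decode
    to a binary mask; {0, 100, 200} decodes to a chamber map. Any other
    coding is rejected.
    """
    path = Path(path)
    arr = _read_pages(path)
    if meta_path is None and _sidecar_for(path).exists():
        meta_path = _sidecar_for(path)
    spacing = read_meta(meta_path).voxel_spacing if meta_path else DEFAULT_SPACING
    values = set(np.unique(arr).tolist())
    if values <= {LABEL_BACKGROUND, LABEL_ATRIUM, LABEL_VENTRICLE} and (
        LABEL_ATRIUM in values or LABEL_VENTRICLE in values
    ):
        labels = np.zeros(arr.shape, dtype=np.uint8)
        labels[arr == LABEL_ATRIUM] = 1
        labels[arr == LABEL_VENTRICLE] = 2
        return ChamberMap(labels, spacing)
    if values <= {0, 255}:
        return Mask3D(arr > 0, spacing)
    nonzero = values - {0}
    if len(nonzero) == 1:
        warnings.warn(
            f"{path}: binary mask coded {{0, {nonzero.pop()}}}; treating nonzero as foreground"
        )
        return Mask3D(arr > 0, spacing)
    raise ValueError(f"{path}: unknown mask label coding {sorted(values)[:10]}")


def write_mask(mask, path: str | Path, meta: StackMeta | None = None) -> None:
    """Write a binary mask as {0, 255} or a chamber map as {0, 100, 200}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(mask, ChamberMap):
        coded = np.zeros(mask.shape, dtype=np.uint8)
        coded[mask.labels == 1] = LABEL_ATRIUM
        coded[mask.labels == 2] = LABEL_VENTRICLE
        spacing = mask.spacing
    elif isinstance(mask, Mask3D):
        coded = np.where(mask.data, 255, 0).astype(np.uint8)
        spacing = mask.spacing
    else:
        raise TypeError(f"cannot write mask of type {type(mask).__name__}")
    tifffile.imwrite(str(path), coded)
    if meta is None:
        meta = StackMeta(voxel_spacing=spacing)
    write_meta(meta, _sidecar_for(path))


def write_report(reports: Sequence, path: str | Path) -> None:
    """Write per-chamber mechanics rows to CSV.

    Columns: dpf, chamber, EDV_um3, ESV_um3, SV_um3, EF_pct — one row per
    chamber per dataset. An empty sequence yields a header-only file.
    """
    rows = [
        {
            "dpf": r.dpf,
            "chamber": r.chamber,
            "EDV_um3": r.edv,
            "ESV_um3": r.esv,
            "SV_um3": r.sv,
            "EF_pct": r.ef,
        }
        for r in reports
    ]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# cine directories


def _frame_name(kind: str, k: int) -> str:
    return f"{kind}_{k:03d}.tif"


def write_cine(
    images: CineSequence | None,
    truths: CineSequence | None,
    out_dir: str | Path,
    *,
    extra_meta: dict | None = None,
) -> None:
    """Write a cine as frame_###.tif / truth_###.tif plus one meta.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = images if images is not None else truths
    if ref is None:
        raise ValueError("nothing to write")
    meta = StackMeta(
        voxel_spacing=ref.spacing,
        frame_interval=ref.frame_interval,
        period=ref.period,
        provenance="cardiomorph phantom",
        extra=extra_meta or {},
    )
    write_meta(meta, out_dir / "meta.json")
    if images is not None:
        for k, vol in enumerate(images):
            tifffile.imwrite(str(out_dir / _frame_name("frame", k)), vol.data)
    if truths is not None:
        for k, cm in enumerate(truths):
            coded = np.zeros(cm.shape, dtype=np.uint8)
            coded[cm.labels == 1] = LABEL_ATRIUM
            coded[cm.labels == 2] = LABEL_VENTRICLE
            tifffile.imwrite(str(out_dir / _frame_name("truth", k)), coded)


def read_cine_masks(directory: str | Path, kind: str = "truth") -> CineSequence:
    """Read truth_###.tif (or mask_###.tif etc.) frames back as a cine."""
    directory = Path(directory)
    meta = read_meta(directory / "meta.json")
    paths = sorted(directory.glob(f"{kind}_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no {kind}_*.tif frames in {directory}")
    frames = []
    for p in paths:
        arr = _read_pages(p)
        values = set(np.unique(arr).tolist())
        if values <= {0, 255}:
            frames.append(Mask3D(arr > 0, meta.voxel_spacing))
        else:
            labels = np.zeros(arr.shape, dtype=np.uint8)
            labels[arr == LABEL_ATRIUM] = 1
            labels[arr == LABEL_VENTRICLE] = 2
            frames.append(ChamberMap(labels, meta.voxel_spacing))
    if meta.frame_interval is None or meta.period is None:
        raise ValueError(f"{directory}/meta.json lacks frame_interval/period")
    return CineSequence(frames, meta.frame_interval, meta.period)
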