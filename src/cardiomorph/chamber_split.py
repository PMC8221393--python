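"""Separation of the intracardiac lumen into atrium and ventricle.

The segmented lumen is a single connected volume: two chambers joined by
the narrow atrioventricular canal. The split follows the classic
morphological recipe — erode the master volume with a 3D structuring
element until it fractures into (at least) two components, dilate each
surviving seed by the same number of steps to recover the lost space, and
intersect the dilated seeds with the original volume. Voxels claimed by
both seeds or by neither are then assigned by geodesic distance *within*
the mask (a simultaneous ring-growing of both labels constrained to the
lumen), so every original foreground voxel ends with exactly one label and
labels can never jump across background.

Chamber identity (which blob is the ventricle) is decided separately by
:func:`assign_identity`; across the frames of a cine the identities are
kept consistent by matching centroids to the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .containers import ChamberMap, CineSequence, Mask3D

__all__ = [
    "SplitConfig",
    "UnsplittableMaskError",
    "split_chambers",
    "assign_identity",
    "split_cine",
    "area_trace",
]

#: 26-connectivity structuring element for component labeling
_CONN26 = np.ones((3, 3, 3), dtype=bool)


class UnsplittableMaskError(RuntimeError):
    """Erosion exhausted the mask (or the iteration cap) before it fractured."""


@dataclass
class SplitConfig:
    """Morphology knobs: ball SE of radius r (voxels), 26-connectivity."""

    se_radius: int = 1
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if self.se_radius < 1 or self.max_iterations < 1:
            raise ValueError("se_radius and max_iterations must be >= 1")

    @property
    def selem(self) -> np.ndarray:
        return ball(self.se_radius, dtype=bool)


def _n_components(mask: np.ndarray) -> tuple[np.ndarray, int]:
    return ndimage.label(mask, structure=_CONN26)


def _geodesic_assign(
    mask: np.ndarray, seed_a: np.ndarray, seed_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Grow both seeds simultaneously inside the mask until it is covered.

    Ring-by-ring 26-connected dilation constrained to the mask approximates
    geodesic distance; a voxel reached by both labels in the same ring goes
    to the larger seed (deterministic tie-break).
    """
    a = seed_a.copy()
    b = seed_b.copy()
    bigger_is_a = a.sum() >= b.sum()
    remaining = mask & ~a & ~b
    while remaining.any():
        grow_a = ndimage.binary_dilation(a, structure=_CONN26, mask=mask) & ~a & ~b
        grow_b = ndimage.binary_dilation(b, structure=_CONN26, mask=mask) & ~a & ~b
        contested = grow_a & grow_b
        if bigger_is_a:
            grow_b &= ~contested
        else:
            grow_a &= ~contested
        if not (grow_a.any() or grow_b.any()):
            # isolated crumbs unreachable from either seed (cannot happen for
            # a connected mask); hand them to the larger seed
            if bigger_is_a:
                a |= remaining
            else:
                b |= remaining
            break
        a |= grow_a
        b |= grow_b
        remaining &= ~a
        remaining &= ~b
    return a, b


def split_chambers(
    mask: Mask3D, cfg: SplitConfig | None = None
) -> tuple[ChamberMap, int]:
    """Split one lumen mask into two chambers; returns (map, iterations_used).

    The returned labels are positional only (1 and 2 in arbitrary order);
    apply :func:`assign_identity` to name them. Label support equals the
    input mask support exactly.

    Raises
    ------
    UnsplittableMaskError
        If the mask erodes to fewer than two components before fracturing
        (e.g. a solid sphere) or the iteration cap is reached.
    """
    cfg = cfg or SplitConfig()
    fg = mask.data.astype(bool)
    if not fg.any():
        raise ValueError("mask is empty")
    selem = cfg.selem

    eroded = fg
    iterations = 0
    _, n = _n_components(eroded)
    while n < 2:
        if iterations >= cfg.max_iterations:
            raise UnsplittableMaskError(
                f"no fracture after {iterations} erosions (cap reached)"
            )
        eroded = ndimage.binary_erosion(eroded, structure=selem)
        iterations += 1
        if not eroded.any():
            raise UnsplittableMaskError(
                f"mask vanished after {iterations} erosions without fracturing"
            )
        _, n = _n_components(eroded)

    labeled, n = _n_components(eroded)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1  # component ids, largest first
    seed_a = labeled == order[0]
    seed_b = labeled == order[1]

    # recover lost space: dilate each seed as many times as we eroded, then
    # clip to the original volume
    for _ in range(iterations):
        seed_a = ndimage.binary_dilation(seed_a, structure=selem)
        seed_b = ndimage.binary_dilation(seed_b, structure=selem)
    seed_a &= fg
    seed_b &= fg

    contested = seed_a & seed_b
    seed_a &= ~contested
    seed_b &= ~contested
    region_a, region_b = _geodesic_assign(fg, seed_a, seed_b)

    labels = np.zeros(fg.shape, dtype=np.uint8)
    labels[region_a] = 1
    labels[region_b] = 2
    out = ChamberMap(labels, mask.spacing)
    assert ((labels > 0) == fg).all(), "split changed the mask support"
    return out, iterations


def _volumes(cmap: ChamberMap) -> tuple[float, float]:
    vv = cmap.voxel_volume
    return float((cmap.labels == 1).sum() * vv), float((cmap.labels == 2).sum() * vv)


def _centroids(cmap: ChamberMap) -> dict[int, np.ndarray]:
    return {
        lab: np.array(ndimage.center_of_mass(cmap.labels == lab))
        for lab in (1, 2)
        if (cmap.labels == lab).any()
    }


def assign_identity(
    cmap: ChamberMap,
    rule: str = "larger-is-ventricle",
    ventricle_hint: tuple[float, float, float] | None = None,
) -> ChamberMap:
    """Decide which positional label is the ventricle.

    rule:
      * ``"larger-is-ventricle"`` (default) — the bigger blob becomes label 2
        (ventricle). On an exact volume tie falls back to the hint, or errors.
      * ``"position-hint"`` — the blob whose centroid is nearer
        ``ventricle_hint`` (voxel coordinates z, y, x) becomes the ventricle.
      * ``"keep"`` — labels returned unchanged.

    Idempotent: applying the same rule twice changes nothing.
    """
    if rule == "keep":
        return cmap
    v1, v2 = _volumes(cmap)
    if v1 == 0 or v2 == 0:
        raise ValueError("both chambers must be nonempty to assign identity")
    if rule == "larger-is-ventricle":
        if v1 == v2:
            if ventricle_hint is None:
                raise ValueError(
                    "volume tie under larger-is-ventricle and no ventricle_hint"
                )
            rule = "position-hint"
        else:
            if v1 > v2:  # label 1 is bigger → swap so the ventricle is 2
                return _swap(cmap)
            return cmap
    if rule == "position-hint":
        if ventricle_hint is None:
            raise ValueError("position-hint rule requires ventricle_hint")
        cents = _centroids(cmap)
        hint = np.asarray(ventricle_hint, dtype=float)
        d1 = np.linalg.norm(cents[1] - hint)
        d2 = np.linalg.norm(cents[2] - hint)
        if d1 < d2:  # label 1 is the ventricle → swap
            return _swap(cmap)
        return cmap
    raise ValueError(f"unknown identity rule {rule!r}")


def _swap(cmap: ChamberMap) -> ChamberMap:
    swapped = cmap.labels.copy()
    swapped[cmap.labels == 1] = 2
    swapped[cmap.labels == 2] = 1
    return ChamberMap(swapped, cmap.spacing)


def split_cine(
    masks: CineSequence,
    cfg: SplitConfig | None = None,
    rule: str = "larger-is-ventricle",
    ventricle_hint: tuple[float, float, float] | None = None,
) -> tuple[CineSequence, list[int]]:
    """Split every frame of a cine and keep chamber identities consistent.

    Positional labels are first made consistent across frames by nearest-
    centroid matching against frame 0. The identity ``rule`` is then applied
    at the cine level: under ``larger-is-ventricle`` the chamber with the
    larger *cycle-mean* volume becomes the ventricle — a single frame caught
    at peak atrial filling would fool a per-frame size comparison, the cycle
    mean cannot. ``position-hint`` compares frame-0 centroids against the
    hint; ``keep`` leaves the matched positional labels.
    """
    out_frames: list[ChamberMap] = []
    iters: list[int] = []
    ref_cents: dict[int, np.ndarray] | None = None
    for k, frame in enumerate(masks):
        fg = frame.data if isinstance(frame, Mask3D) else frame.labels > 0
        cmap, it = split_chambers(Mask3D(fg, frame.spacing), cfg)
        if k == 0:
            ref_cents = _centroids(cmap)
        else:
            cents = _centroids(cmap)
            # does label 1 sit nearer the reference label 1 or label 2?
            d_same = np.linalg.norm(cents[1] - ref_cents[1]) + np.linalg.norm(
                cents[2] - ref_cents[2]
            )
            d_swap = np.linalg.norm(cents[1] - ref_cents[2]) + np.linalg.norm(
                cents[2] - ref_cents[1]
            )
            if d_swap < d_same:
                cmap = _swap(cmap)
        out_frames.append(cmap)
        iters.append(it)

    swap = False
    if rule == "larger-is-ventricle":
        mean1 = float(np.mean([(m.labels == 1).sum() for m in out_frames]))
        mean2 = float(np.mean([(m.labels == 2).sum() for m in out_frames]))
        if mean1 == mean2:
            if ventricle_hint is None:
                raise ValueError(
                    "cycle-mean volume tie under larger-is-ventricle and no hint"
                )
            rule = "position-hint"
        else:
            swap = mean1 > mean2
    if rule == "position-hint":
        if ventricle_hint is None:
            raise ValueError("position-hint rule requires ventricle_hint")
        hint = np.asarray(ventricle_hint, dtype=float)
        swap = np.linalg.norm(ref_cents[1] - hint) < np.linalg.norm(
            ref_cents[2] - hint
        )
    elif rule not in ("larger-is-ventricle", "keep"):
        raise ValueError(f"unknown identity rule {rule!r}")
    if swap:
        out_frames = [_swap(m) for m in out_frames]
    return CineSequence(out_frames, masks.frame_interval, masks.period), iters


def area_trace(maps: CineSequence, z_index: int) -> np.ndarray:
    """Per-chamber cross-section area vs. phase at one z slice (μm²).

    Returns an (N, 2) array of (atrium, ventricle) areas.
    """
    first = maps[0]
    if not 0 <= z_index < first.shape[0]:
        raise IndexError(f"z_index {z_index} outside [0, {first.shape[0]})")
    _, dy, dx = first.spacing
    pix = dy * dx
    out = np.zeros((len(maps), 2), dtype=float)
    for k, cmap in enumerate(maps):
        sl = cmap.labels[z_index]
        out[k, 0] = (sl == 1).sum() * pix
        out[k, 1] = (sl == 2).sum() * pix
    return out
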