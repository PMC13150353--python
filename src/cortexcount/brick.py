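"""The unbiased 3D counting brick.

A rectangular sampling prism with three acceptance faces and three exclusion
faces (one of each per axis). A nucleus is counted iff its spatial support
intersects the brick and does not touch any exclusion face; at corners and
edges exclusion wins, which is what makes an exact tiling of adjacent bricks
count every object exactly once.

Two support representations are accepted: a physical axis-aligned box
``(lo_um, hi_um)`` (used by the Monte-Carlo unbiasedness oracle and as a
bbox fallback) and a :class:`~cortexcount.segment.SegmentedNucleus` carrying
its voxel mask, in which case face contact is decided at voxel resolution
with the half-open convention that a voxel owns its low edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segment import SegmentedNucleus

__all__ = ["CountingBrick", "classify_inclusion", "filter_counted", "count_boxes"]


@dataclass(frozen=True)
class CountingBrick:
    """Rectangular prism ROI with per-axis face roles.

    ``exclusion_low[a]`` is True when the low-coordinate face of axis ``a``
    is the exclusion face (the default on all three axes); the opposite face
    of the same axis is then the acceptance face.
    """

    origin_um: tuple[float, float, float]
    extent_um: tuple[float, float, float]
    exclusion_low: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self):
        if len(self.origin_um) != 3 or len(self.extent_um) != 3:
            raise ValueError("origin_um and extent_um must be 3-vectors")
        if any(e <= 0 for e in self.extent_um):
            raise ValueError("brick extents must be positive (degenerate brick)")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.origin_um, dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return self.lo + np.asarray(self.extent_um, dtype=float)

    @property
    def volume_um3(self) -> float:
        return float(np.prod(self.extent_um))

    @property
    def volume_mm3(self) -> float:
        return self.volume_um3 * 1e-9

    def exclusion_coords(self):
        """Per axis: the plane coordinate of the exclusion face."""
        return [self.lo[a] if self.exclusion_low[a] else self.hi[a]
                for a in range(3)]


def _box_support(nucleus, voxel_size_um):
    """Normalize a support argument to (lo, hi) physical box + optional
    voxel-level detail (mask, index origin, voxel size)."""
    if isinstance(nucleus, SegmentedNucleus):
        if nucleus.mask is not None and nucleus.bbox_voxels is not None:
            if voxel_size_um is None:
                raise ValueError("voxel_size_um required for mask-based support")
            vox = np.asarray(voxel_size_um, dtype=float)
            idx0 = np.asarray(nucleus.bbox_voxels[0])
            lo = idx0 * vox
            hi = np.asarray(nucleus.bbox_voxels[1]) * vox
            return lo, hi, (nucleus.mask, idx0, vox)
        lo = np.asarray(nucleus.bbox_um[0], dtype=float)
        hi = np.asarray(nucleus.bbox_um[1], dtype=float)
        return lo, hi, None
    lo, hi = nucleus
    return np.asarray(lo, dtype=float), np.asarray(hi, dtype=float), None


def classify_inclusion(nucleus, brick: CountingBrick, voxel_size_um=None):
    """Decide whether one nucleus is counted by the brick.

    Returns ``(decision, reason)`` with ``decision`` in {"counted",
    "rejected"} and ``reason`` in {None, "outside", "exclusion_plane"}.

    The rule: counted iff the support intersects the brick AND touches no
    exclusion face; "intersecting a plane" is evaluated on the bounded face
    rectangle, so a nucleus beyond the brick crossing only the plane's
    extension is "outside", not excluded.
    """
    lo, hi, voxel_detail = _box_support(nucleus, voxel_size_um)

    # overlap with the brick box (closed intervals on the physical boxes)
    if np.any(hi < brick.lo) or np.any(lo > brick.hi):
        return "rejected", "outside"

    if voxel_detail is None:
        for a in range(3):
            f = brick.lo[a] if brick.exclusion_low[a] else brick.hi[a]
            if lo[a] <= f <= hi[a] and _face_rect_overlap(lo, hi, brick, a):
                return "rejected", "exclusion_plane"
        return "counted", None

    mask, idx0, vox = voxel_detail
    if not _mask_overlaps_brick(mask, idx0, vox, brick):
        return "rejected", "outside"
    for a in range(3):
        f = brick.lo[a] if brick.exclusion_low[a] else brick.hi[a]
        if _mask_touches_face(mask, idx0, vox, brick, a, f):
            return "rejected", "exclusion_plane"
    return "counted", None


def _face_rect_overlap(lo, hi, brick, axis):
    """Does the support's projection overlap the bounded face rectangle?"""
    for b in range(3):
        if b == axis:
            continue
        if hi[b] < brick.lo[b] or lo[b] > brick.hi[b]:
            return False
    return True


def _mask_overlaps_brick(mask, idx0, vox, brick):
    """Any True voxel whose half-open physical box meets the brick box."""
    sub = _mask_window(mask, idx0, vox, brick.lo, brick.hi)
    return sub is not None and bool(sub.any())


def _mask_window(mask, idx0, vox, lo_um, hi_um):
    """Boolean sub-mask of voxels whose boxes intersect [lo_um, hi_um]."""
    sl = []
    for a in range(3):
        # voxel j spans [j*v, (j+1)*v); it meets the closed interval
        # [lo, hi] iff j in [floor(lo/v), floor(hi/v)]
        j0 = int(np.floor(lo_um[a] / vox[a]))
        j1 = int(np.floor(hi_um[a] / vox[a]))
        a0 = max(j0 - int(idx0[a]), 0)
        a1 = min(j1 - int(idx0[a]) + 1, mask.shape[a])
        if a0 >= a1:
            return None
        sl.append(slice(a0, a1))
    return mask[tuple(sl)]


def _mask_touches_face(mask, idx0, vox, brick, axis, plane):
    """Does any voxel of the mask contain the plane coordinate on ``axis``
    while overlapping the bounded face rectangle on the other axes?

    A voxel [j*v, (j+1)*v) contains the plane iff j*v <= plane < (j+1)*v
    (the voxel owns its low edge).
    """
    j = int(np.floor(plane / vox[axis]))
    j_local = j - int(idx0[axis])
    if j_local < 0 or j_local >= mask.shape[axis]:
        return False
    layer = np.take(mask, j_local, axis=axis)
    if not layer.any():
        return False
    # restrict to the face rectangle on the remaining axes
    other = [a for a in range(3) if a != axis]
    sl = []
    for k, a in enumerate(other):
        j0 = int(np.floor(brick.lo[a] / vox[a]))
        j1 = int(np.floor(brick.hi[a] / vox[a]))
        a0 = max(j0 - int(idx0[a]), 0)
        a1 = min(j1 - int(idx0[a]) + 1, layer.shape[k])
        if a0 >= a1:
            return False
        sl.append(slice(a0, a1))
    return bool(layer[tuple(sl)].any())


def filter_counted(nuclei, brick: CountingBrick, voxel_size_um=None):
    """Apply the brick rule to every nucleus.

    Returns ``(counted, audit)`` where ``audit`` has one record per input
    nucleus with its decision and reason; ``len(counted) + rejections ==
    len(nuclei)`` always.
    """
    counted = []
    audit = []
    for i, nuc in enumerate(nuclei):
        decision, reason = classify_inclusion(nuc, brick, voxel_size_um)
        nid = getattr(nuc, "id", i)
        audit.append({"id": nid, "decision": decision, "reason": reason})
        if decision == "counted":
            counted.append(nuc)
    return counted, audit


def count_boxes(lo: np.ndarray, hi: np.ndarray, brick: CountingBrick) -> np.ndarray:
    """Vectorized brick decision for ``n`` axis-aligned box supports.

    ``lo`` and ``hi`` are ``(n, 3)`` physical corners. Returns a boolean
    "counted" array. Used by the Monte-Carlo unbiasedness oracle where
    per-object voxel masks would be needlessly slow.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    overlap = np.all(hi >= brick.lo, axis=1) & np.all(lo <= brick.hi, axis=1)
    excluded = np.zeros(len(lo), dtype=bool)
    for a in range(3):
        f = brick.lo[a] if brick.exclusion_low[a] else brick.hi[a]
        touches = (lo[:, a] <= f) & (hi[:, a] >= f)
        # bounded face rectangle on the other axes
        for b in range(3):
            if b == a:
                continue
            touches &= (hi[:, b] >= brick.lo[b]) & (lo[:, b] <= brick.hi[b])
        excluded |= touches
    return overlap & ~excluded
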