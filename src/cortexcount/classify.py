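"""Cell-type assignment for counted nuclei.

Every counted nucleus ends up in exactly one of {neuron, glia, vascular}:

* **neuron** — the nucleus is immunopositive in the neuron-marker channel
  (NeuN-like): its mean intensity sits a configurable number of robust
  spreads above the channel background;
* **vascular** — either the nucleus colocalizes with the thresholded
  vessel-marker tube mask (marker mode, RECA-1-like), or, when no vessel
  channel was acquired (the human-like protocol), it is picked up
  geometrically: chains of mutually aligned, elongated (filiform)
  non-neuronal nuclei tracing a vessel's cylindrical cell arrangement;
* **glia** — the non-neuronal, non-vascular remainder.

Precedence is neuron > vascular > glia: a marker-positive nucleus next to a
vessel is still a neuron, because vascular identification only ever applied
within the non-neuronal population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .segment import SegmentedNucleus
from .stack import NEURON_MARKER, VESSEL_MARKER, ImageStack

__all__ = [
    "GeometryParams",
    "ClassifiedCell",
    "is_neuron",
    "vessel_mask_from_stack",
    "is_vascular_by_marker",
    "is_vascular_by_geometry",
    "classify_all",
]

EVIDENCE = ("neuron_marker", "vessel_marker", "geometry", "default_glia")


@dataclass(frozen=True)
class GeometryParams:
    """Free parameters of the geometric (no-vessel-channel) vascular
    detector; none are quantified by the visual criterion they
    operationalize, so all are exposed and documented."""

    max_link_dist_um: float = 18.0
    min_chain_len: int = 2
    min_aspect_ratio: float = 1.8
    collinearity_tol_deg: float = 30.0
    #: cylinder tolerance: a pair whose link is not collinear with the axes
    #: still links if its perpendicular offset from the shared axis is
    #: within this radius (nuclei on opposite walls of the same vessel)
    max_perp_offset_um: float = 8.0


@dataclass
class ClassifiedCell:
    """A counted nucleus with its class and the evidence that produced it."""

    nucleus: SegmentedNucleus
    cell_class: str
    evidence: str
    score: float = 0.0

    def __post_init__(self):
        if self.evidence not in EVIDENCE:
            raise ValueError(f"unknown evidence {self.evidence!r}")
        consistent = {
            "neuron": ("neuron_marker",),
            "vascular": ("vessel_marker", "geometry"),
            "glia": ("default_glia",),
        }
        if self.evidence not in consistent[self.cell_class]:
            raise ValueError(
                f"evidence {self.evidence!r} inconsistent with class "
                f"{self.cell_class!r}")


def is_neuron(nucleus: SegmentedNucleus, k: float = 4.0,
              channel: str = NEURON_MARKER):
    """Marker-positivity test: contrast (mean - background) / spread >= k.

    Returns ``(positive, score)``. Raises if the marker channel was never
    measured on the nucleus — the pipeline requires a neuron marker, as did
    both species' staining protocols.
    """
    if channel not in nucleus.channel_means:
        raise ValueError(
            f"nucleus {nucleus.id} has no {channel!r} measurement; the "
            "neuron marker channel is required")
    level, spread = nucleus.channel_background.get(channel, (0.0, 0.0))
    if spread <= 0:
        spread = 1.0
    score = (nucleus.channel_means[channel] - level) / spread
    return bool(score >= k), float(score)


def vessel_mask_from_stack(stack: ImageStack) -> np.ndarray:
    """Threshold the vessel-marker channel into a boolean tube mask (Otsu)."""
    img = np.asarray(stack.channel(VESSEL_MARKER), dtype=np.float32)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)


def vessel_distance_map(vessel_mask: np.ndarray, voxel_size_um) -> np.ndarray:
    """Physical-unit distance of every voxel to the vessel mask."""
    if not vessel_mask.any():
        return np.full(vessel_mask.shape, np.inf, dtype=np.float32)
    return ndimage.distance_transform_edt(~vessel_mask, sampling=voxel_size_um)


def is_vascular_by_marker(nucleus: SegmentedNucleus, vessel_mask: np.ndarray,
                          max_dist_um: float = 2.0, voxel_size_um=None,
                          _dist_map: np.ndarray | None = None) -> bool:
    """Colocalization test: nucleus support within ``max_dist_um`` of the
    vessel tube mask. Pass ``_dist_map`` (from :func:`vessel_distance_map`)
    to amortize the distance transform over many nuclei."""
    if _dist_map is None:
        if voxel_size_um is None:
            raise ValueError("voxel_size_um required to build the distance map")
        _dist_map = vessel_distance_map(vessel_mask, voxel_size_um)
    if not np.isfinite(_dist_map).any():
        return False
    (z0, y0, x0), (z1, y1, x1) = nucleus.bbox_voxels
    sub = _dist_map[z0:z1, y0:y1, x0:x1]
    vals = sub[nucleus.mask]
    return bool(vals.size and vals.min() <= max_dist_um)


def is_vascular_by_geometry(nuclei: list[SegmentedNucleus],
                            params: GeometryParams | None = None) -> np.ndarray:
    """Geometric vascular detection on the non-neuronal counted set.

    Builds a graph over elongated nuclei (aspect ratio >= threshold,
    degenerate shapes never participate) linking pairs whose centroids are
    close and whose long axes are mutually aligned and aligned with the
    link direction; connected chains of at least ``min_chain_len`` members
    are labeled vascular. Returns one boolean per input nucleus.
    """
    params = params or GeometryParams()
    n = len(nuclei)
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags

    eligible = [
        i for i, nuc in enumerate(nuclei)
        if (not nuc.degenerate and nuc.long_axis is not None
            and nuc.aspect_ratio >= params.min_aspect_ratio)
    ]
    if len(eligible) < params.min_chain_len:
        return flags

    pts = np.array([nuclei[i].centroid_um for i in eligible])
    axes = np.array([nuclei[i].long_axis for i in eligible])
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    cos_tol = np.cos(np.deg2rad(params.collinearity_tol_deg))

    parent = list(range(len(eligible)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    close = d2 <= params.max_link_dist_um ** 2
    for i in range(len(eligible)):
        for j in range(i + 1, len(eligible)):
            if not close[i, j]:
                continue
            link = pts[j] - pts[i]
            dist = np.sqrt(d2[i, j])
            if dist < 1e-9:
                union(i, j)
                continue
            link = link / dist
            if abs(axes[i] @ axes[j]) < cos_tol:
                continue
            collinear = (abs(axes[i] @ link) >= cos_tol
                         and abs(axes[j] @ link) >= cos_tol)
            # cylinder criterion: perpendicular offset from the shared axis
            mean_axis = axes[i] + np.sign(axes[i] @ axes[j]) * axes[j]
            mean_axis /= np.linalg.norm(mean_axis)
            perp = dist * np.sqrt(max(1.0 - float(link @ mean_axis) ** 2, 0.0))
            if collinear or perp <= params.max_perp_offset_um:
                union(i, j)

    from collections import Counter

    comp = [find(i) for i in range(len(eligible))]
    sizes = Counter(comp)
    for local, root in enumerate(comp):
        if sizes[root] >= params.min_chain_len:
            flags[eligible[local]] = True
    return flags


def classify_all(nuclei: list[SegmentedNucleus], stack: ImageStack,
                 mode: str = "marker", neuron_k: float = 4.0,
                 vascular_max_dist_um: float = 2.0,
                 geometry_params: GeometryParams | None = None
                 ) -> list[ClassifiedCell]:
    """Assign every counted nucleus exactly one class.

    ``mode="marker"`` uses vessel-channel colocalization for vascular cells
    (the immersion-fixed mouse protocol); ``mode="geometry"`` uses the
    chain detector (the human protocol, recorded without a vessel channel).
    Precedence: neuron > vascular > glia; counts are conserved.
    """
    if mode not in ("marker", "geometry"):
        raise ValueError(f"mode must be 'marker' or 'geometry', got {mode!r}")
    if mode == "marker" and not stack.has_channel(VESSEL_MARKER):
        raise ValueError(
            "marker mode needs a vessel_marker channel; this stack has "
            f"{stack.channels} — use mode='geometry' instead")

    neuron_flags = []
    neuron_scores = []
    for nuc in nuclei:
        pos, score = is_neuron(nuc, k=neuron_k)
        neuron_flags.append(pos)
        neuron_scores.append(score)

    non_neuron_idx = [i for i, f in enumerate(neuron_flags) if not f]
    vascular = {}
    if mode == "marker":
        vmask = vessel_mask_from_stack(stack)
        dist_map = vessel_distance_map(vmask, stack.voxel_size_um)
        for i in non_neuron_idx:
            if is_vascular_by_marker(nuclei[i], vmask,
                                     max_dist_um=vascular_max_dist_um,
                                     _dist_map=dist_map):
                vascular[i] = "vessel_marker"
    else:
        subset = [nuclei[i] for i in non_neuron_idx]
        flags = is_vascular_by_geometry(subset, geometry_params)
        for i, f in zip(non_neuron_idx, flags):
            if f:
                vascular[i] = "geometry"

    out = []
    for i, nuc in enumerate(nuclei):
        if neuron_flags[i]:
            out.append(ClassifiedCell(nuc, "neuron", "neuron_marker",
                                      neuron_scores[i]))
        elif i in vascular:
            score = nuc.aspect_ratio if vascular[i] == "geometry" else 0.0
            out.append(ClassifiedCell(nuc, "vascular", vascular[i], score))
        else:
            out.append(ClassifiedCell(nuc, "glia", "default_glia",
                                      neuron_scores[i]))
    return out
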