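"""Synthetic cortical-column stacks with known cellular composition.

Generates ground-truthed multichannel 3D stacks that emulate confocal imaging
of DAPI-counterstained cortex with an optional neuronal nuclear marker
(NeuN-like) and an optional endothelial vessel marker (RECA-1-like):

* nuclei are ellipsoids placed layer by layer by a hard-core point process at
  a configurable density, with the cell class (neuron / glia / vascular)
  drawn per cell from the layer's composition;
* vascular nuclei are not scattered uniformly — they sit on the walls of
  simulated penetrating vessels, elongated (filiform) along the local vessel
  direction, reproducing the characteristic cylindrical clustering that a
  geometric vascular detector must exploit when no vessel channel exists;
* channels are rendered as additive intensity kernels, blurred by a Gaussian
  PSF and degraded by Poisson-Gaussian noise parameterized by a single SNR.

Coordinates are physical (um), ordered (z, y, x) to match
:mod:`cortexcount.stack`: z is the optical axis (section thickness), y the
cortical depth from the pia, x the tangential width.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stack import NUCLEAR, NEURON_MARKER, VESSEL_MARKER, ImageStack

__all__ = [
    "LayerSpec",
    "GroundTruthCell",
    "VesselPath",
    "SimulationConfig",
    "PackingError",
    "place_cells",
    "render_stack",
    "ground_truth_labels",
    "write_ground_truth",
    "read_ground_truth",
    "simulate_column",
    "mouse_s1hl",
    "human_ba21",
    "PRESETS",
]

CELL_CLASSES = ("neuron", "glia", "vascular")

# output intensity scale: foreground amplitude maps to this many grey levels,
# background sits at BACKGROUND_FRACTION of it (16-bit-equivalent range)
FOREGROUND_LEVEL = 10_000.0
BACKGROUND_FRACTION = 0.1


class PackingError(RuntimeError):
    """Raised when the hard-core process cannot place a cell within budget."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """One cortical layer: thickness, total cell density and composition.

    ``composition`` is ``(p_neuron, p_glia, p_vascular)`` and must sum to 1.
    """

    label: str
    thickness_um: float
    density_per_mm3: float
    composition: tuple[float, float, float]

    def __post_init__(self):
        p = self.composition
        if len(p) != 3 or any(q < 0 or q > 1 for q in p):
            raise ValueError("composition must be 3 probabilities in [0, 1]")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {sum(p)}")
        if self.thickness_um <= 0:
            raise ValueError("thickness_um must be positive")
        if self.density_per_mm3 < 0:
            raise ValueError("density_per_mm3 must be non-negative")


@dataclass
class GroundTruthCell:
    """A cell as placed by the simulator (the recovery target)."""

    id: int
    center_um: np.ndarray  # (z, y, x)
    radii_um: np.ndarray  # 3 semi-axes, long axis first
    orientation: np.ndarray  # unit vector of the long axis (z, y, x)
    cell_class: str
    layer: str
    vessel_id: int | None = None

    def __post_init__(self):
        self.center_um = np.asarray(self.center_um, dtype=float)
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if np.any(self.radii_um <= 0):
            raise ValueError("radii_um must be positive")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if self.cell_class == "vascular" and self.vessel_id is None:
            raise ValueError("vascular cells must carry a vessel_id")


@dataclass
class VesselPath:
    """A blood-vessel centerline as an ordered polyline with a tube radius."""

    id: int
    polyline_um: np.ndarray  # (n, 3) points, (z, y, x)
    radius_um: float

    def __post_init__(self):
        self.polyline_um = np.asarray(self.polyline_um, dtype=float)
        if self.polyline_um.shape[0] < 2:
            raise ValueError("vessel polyline needs at least 2 points")
        if self.radius_um <= 0:
            raise ValueError("vessel radius must be positive")


@dataclass
class SimulationConfig:
    """Everything needed to generate one cortical column deterministically.

    The section geometry follows the acquisition the package emulates:
    ~50-um-thick sections sampled with a ~1 um z-step; the cortical-depth
    extent is the sum of layer thicknesses; the tangential width is free.
    """

    layers: list[LayerSpec]
    width_um: float = 350.0
    section_thickness_um: float = 50.0
    voxel_size_um: tuple[float, float, float] = (1.0, 0.69, 0.69)
    channels: tuple[str, ...] = (NUCLEAR, NEURON_MARKER)
    snr: float = 10.0
    psf_sigma_um: tuple[float, float, float] = (0.75, 0.5, 0.5)
    min_separation_um: float = 4.0
    overlap_factor: float = 0.95
    touching_fraction: float = 0.0
    neuron_radius_um: float = 5.0
    glia_radius_um: float = 3.0
    vascular_radii_um: tuple[float, float] = (5.0, 2.0)  # long, short semi-axes
    min_vascular_aspect: float = 2.5
    vessel_radius_um: float = 3.5
    vascular_per_vessel: float = 25.0
    vessel_clearance_um: float = 3.0
    seed: int = 0
    max_voxels: int = 2**28

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        unknown = set(self.channels) - {NUCLEAR, NEURON_MARKER, VESSEL_MARKER}
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")

    @property
    def depth_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical stack extent (z, y, x) in um."""
        return (self.section_thickness_um, self.depth_um, self.width_um)

    @property
    def layer_boundaries_um(self) -> np.ndarray:
        """Depth breakpoints from the pia (0) to the deep boundary."""
        t = np.array([l.thickness_um for l in self.layers])
        return np.concatenate([[0.0], np.cumsum(t)])

    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(e / v)) for e, v in zip(self.extent_um, self.voxel_size_um)
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=list)


# ---------------------------------------------------------------------------
# presets — compositions from the two published composition tables
# ---------------------------------------------------------------------------

#: Human BA21 (temporal cortex) per-layer (p_neuron, p_glia, p_vascular).
HUMAN_BA21_COMPOSITION = {
    "I": (0.11, 0.56, 0.33),
    "II": (0.55, 0.28, 0.17),
    "IIIa": (0.39, 0.35, 0.26),
    "IIIb": (0.28, 0.38, 0.34),
    "IV": (0.40, 0.48, 0.12),
    "V": (0.27, 0.48, 0.25),
    "VI": (0.16, 0.59, 0.25),
}

#: Mouse S1HL (immersion-fixed) neuron proportion per layer, with the
#: non-neuronal remainder split between glia and vascular using the published
#: per-layer glia-to-neuron vs non-neuron-to-neuron ratios.
MOUSE_S1HL_COMPOSITION = {
    "I": (0.14, 0.550, 0.310),
    "II": (0.69, 0.186, 0.124),
    "III": (0.69, 0.186, 0.124),
    "IV": (0.71, 0.145, 0.145),
    "V": (0.53, 0.261, 0.209),
    "VI": (0.66, 0.204, 0.136),
}

# layer thickness fractions of the simulated column depth (placeholders: the
# source tables report proportions, not absolute laminar geometry)
_HUMAN_THICKNESS_FRACTION = {
    "I": 0.10, "II": 0.10, "IIIa": 0.15, "IIIb": 0.15,
    "IV": 0.10, "V": 0.20, "VI": 0.20,
}
_MOUSE_THICKNESS_FRACTION = {
    "I": 0.10, "II": 0.12, "III": 0.18, "IV": 0.15, "V": 0.25, "VI": 0.20,
}

#: total cell density placeholders (cells per mm^3); the mouse value is the
#: study-wide average (25,003 cells in ~0.075 mm^3), the human value is set in
#: the same range so that single-column stacks carry enough cells to estimate
#: per-layer proportions
MOUSE_DENSITY_PER_MM3 = 3.3e5
HUMAN_DENSITY_PER_MM3 = 3.0e5


def _normalize(comp):
    p = np.asarray(comp, dtype=float)
    p = p / p.sum()
    return tuple(float(q) for q in p)


def human_ba21(seed: int = 0, width_um: float = 350.0,
               depth_um: float | None = None,
               density_per_mm3: float = HUMAN_DENSITY_PER_MM3,
               **kwargs) -> SimulationConfig:
    """Human temporal-cortex preset: 7 layers, nuclear + neuron-marker
    channels only (no vessel channel — vascular cells must be found
    geometrically), 0.69 um/px in-plane, 1 um z-step."""
    depth = depth_um if depth_um is not None else 512 * 0.69
    layers = [
        LayerSpec(lab, _HUMAN_THICKNESS_FRACTION[lab] * depth, density_per_mm3,
                  _normalize(HUMAN_BA21_COMPOSITION[lab]))
        for lab in HUMAN_BA21_COMPOSITION
    ]
    kwargs.setdefault("voxel_size_um", (1.0, 0.69, 0.69))
    kwargs.setdefault("channels", (NUCLEAR, NEURON_MARKER))
    return SimulationConfig(layers=layers, width_um=width_um, seed=seed, **kwargs)


def mouse_s1hl(seed: int = 0, width_um: float = 350.0,
               depth_um: float | None = None,
               density_per_mm3: float = MOUSE_DENSITY_PER_MM3,
               **kwargs) -> SimulationConfig:
    """Mouse S1HL preset: 6 layers, all three channels (immersion-fixed
    protocol with a vessel marker), 0.83 um/px in-plane, 1 um z-step."""
    depth = depth_um if depth_um is not None else 512 * 0.83
    layers = [
        LayerSpec(lab, _MOUSE_THICKNESS_FRACTION[lab] * depth, density_per_mm3,
                  _normalize(MOUSE_S1HL_COMPOSITION[lab]))
        for lab in MOUSE_S1HL_COMPOSITION
    ]
    kwargs.setdefault("voxel_size_um", (1.0, 0.83, 0.83))
    kwargs.setdefault("channels", (NUCLEAR, NEURON_MARKER, VESSEL_MARKER))
    return SimulationConfig(layers=layers, width_um=width_um, seed=seed, **kwargs)


PRESETS = {"human-ba21": human_ba21, "mouse-s1hl": mouse_s1hl}


# ---------------------------------------------------------------------------
# cell placement
# ---------------------------------------------------------------------------


class _SpatialGrid:
    """Uniform grid for hard-core neighbour queries during placement."""

    def __init__(self, cell_size: float):
        self.h = float(cell_size)
        self.cells: dict[tuple[int, int, int], list[tuple[np.ndarray, float]]] = {}

    def _key(self, p):
        return (int(p[0] // self.h), int(p[1] // self.h), int(p[2] // self.h))

    def neighbours(self, p):
        kz, ky, kx = self._key(p)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yield from self.cells.get((kz + dz, ky + dy, kx + dx), ())

    def admissible(self, p, r, min_sep, overlap_factor):
        for q, rq in self.neighbours(p):
            lim = max(min_sep, overlap_factor * (r + rq))
            d = p - q
            if d @ d < lim * lim:
                return False
        return True

    def add(self, p, r):
        self.cells.setdefault(self._key(p), []).append((np.asarray(p, float), float(r)))


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_radii(rng, cell_class, cfg: SimulationConfig):
    """Semi-axes (long first) and long-axis orientation for one nucleus."""
    if cell_class == "neuron":
        r = max(2.0, rng.normal(cfg.neuron_radius_um, 0.4))
        ratios = rng.uniform(0.85, 1.0, size=2)
        radii = np.array([r, r * ratios[0], r * ratios[1]])
        orient = _random_unit(rng)
    elif cell_class == "glia":
        r = max(1.5, rng.normal(cfg.glia_radius_um, 0.3))
        ratios = rng.uniform(0.85, 1.0, size=2)
        radii = np.array([r, r * ratios[0], r * ratios[1]])
        orient = _random_unit(rng)
    else:  # vascular: filiform, elongated along the vessel
        long_r, short_r = cfg.vascular_radii_um
        a = max(3.0, rng.normal(long_r, 0.4))
        b = max(a / 4.0, rng.normal(short_r, 0.15))
        b = min(b, a / cfg.min_vascular_aspect)
        radii = np.array([a, b, b])
        orient = None  # set from the vessel tangent by the caller
    return radii, orient


def _make_vessels(rng, cfg: SimulationConfig, n_vessels: int) -> list[VesselPath]:
    """Penetrating vessels running roughly along the cortical depth axis
    with a gentle lateral random walk."""
    zmax, ymax, xmax = cfg.extent_um
    vessels = []
    n_pts = 9
    ys = np.linspace(0.0, ymax, n_pts)
    for vid in range(n_vessels):
        # uniform over a slightly padded volume so vascular density carries
        # no interior bias relative to the uniformly placed other classes
        z0 = rng.uniform(-3.0, zmax + 3.0)
        x0 = rng.uniform(-3.0, xmax + 3.0)
        step = ymax / (n_pts - 1)
        jitter = 0.06 * step  # lateral drift per segment
        dz = np.concatenate([[0], rng.normal(0, jitter, n_pts - 1)]).cumsum()
        dx = np.concatenate([[0], rng.normal(0, jitter, n_pts - 1)]).cumsum()
        pts = np.stack([z0 + dz, ys, x0 + dx], axis=1)
        vessels.append(VesselPath(id=vid, polyline_um=pts, radius_um=cfg.vessel_radius_um))
    return vessels


def _vessel_samples(vessel: VesselPath, spacing_um: float = 1.0):
    """Densely resampled (point, unit tangent) pairs along the centerline."""
    pts = vessel.polyline_um
    segs = np.diff(pts, axis=0)
    lens = np.linalg.norm(segs, axis=1)
    out_p, out_t = [], []
    for p0, s, L in zip(pts[:-1], segs, lens):
        n = max(int(L / spacing_um), 1)
        t = s / L
        for k in range(n):
            out_p.append(p0 + s * (k / n))
            out_t.append(t)
    return np.asarray(out_p), np.asarray(out_t)


def place_cells(config: SimulationConfig):
    """Place ground-truth cells and vessel paths for one column.

    Neurons and glia follow a hard-core point process within each layer slab
    at the layer's density; each cell's class is drawn from the layer
    composition. Vascular cells are placed along sampled vessel centerlines
    (Poisson number per layer), sitting on the tube wall and elongated along
    the local tangent. Deterministic for a fixed ``config.seed``.

    Returns
    -------
    (cells, vessels) : (list[GroundTruthCell], list[VesselPath])
    """
    rng = np.random.default_rng(config.seed)
    zmax, ymax, xmax = config.extent_um
    bounds = config.layer_boundaries_um

    # per-layer Poisson cell totals and multinomial class splits
    layer_counts = []
    for spec in config.layers:
        vol_mm3 = (zmax * spec.thickness_um * xmax) * 1e-9
        expected = spec.density_per_mm3 * vol_mm3
        n = int(rng.poisson(expected)) if expected > 0 else 0
        classes = rng.choice(3, size=n, p=np.asarray(spec.composition))
        layer_counts.append(np.bincount(classes, minlength=3))

    total_vascular = int(sum(c[2] for c in layer_counts))
    # enough vessels that the densest layer's quota fits on the walls at
    # the end-to-end packing spacing (~8 um), with headroom
    demand = max(
        (int(np.ceil(2.0 * c[2] * 8.0 / spec.thickness_um))
         for spec, c in zip(config.layers, layer_counts)),
        default=0,
    )
    n_vessels = max(3, int(np.ceil(total_vascular / config.vascular_per_vessel)),
                    demand)
    vessels = _make_vessels(rng, config, n_vessels) if total_vascular else []
    #: target axial spacing of nuclei along an occupied vessel segment (um);
    #: sets how strongly vascular nuclei agglomerate per vessel
    occupancy_spacing = 9.5
    # one shared occupancy order: the first vessels of this permutation are
    # lined with nuclei in every layer, so chains run continuously across
    # layer boundaries as they do along real penetrating vessels
    vessel_order = list(rng.permutation(len(vessels))) if vessels else []

    # pre-sample vessel walls, bucketed by layer for fast per-layer draws
    wall_pts, wall_tan, wall_vid = [], [], []
    for v in vessels:
        p, t = _vessel_samples(v)
        wall_pts.append(p)
        wall_tan.append(t)
        wall_vid.append(np.full(len(p), v.id))
    if vessels:
        wall_pts = np.concatenate(wall_pts)
        wall_tan = np.concatenate(wall_tan)
        wall_vid = np.concatenate(wall_vid)

    max_r = max(config.neuron_radius_um + 1.5, config.vascular_radii_um[0] + 1.5)
    grid = _SpatialGrid(cell_size=2.0 * max_r * config.overlap_factor + 0.5)
    cells: list[GroundTruthCell] = []
    next_id = 0
    max_attempts = 200

    # the vessel tube displaces tissue: non-vascular nuclei keep clear of
    # the lumen (vascular nuclei sit on the wall by construction)
    centerline_tree = None
    if vessels:
        from scipy.spatial import cKDTree

        centerline_tree = cKDTree(wall_pts)

    def clear_of_lumen(p, r):
        if centerline_tree is None:
            return True
        d, _ = centerline_tree.query(p)
        return d >= config.vessel_radius_um + 0.9 * r + config.vessel_clearance_um

    def try_place(center_fn, radii, layer_label, cell_class, vessel_id, orient_fn,
                  hard_radius=None, check_lumen=False):
        nonlocal next_id
        r_eff = float(radii[0]) if hard_radius is None else float(hard_radius)
        for _ in range(max_attempts):
            p = center_fn()
            if p is None:
                continue
            if check_lumen and not clear_of_lumen(p, float(radii[0])):
                continue
            if not grid.admissible(p, r_eff, config.min_separation_um,
                                   config.overlap_factor):
                continue
            orient = orient_fn(p)
            grid.add(p, r_eff)
            cells.append(GroundTruthCell(
                id=next_id, center_um=p, radii_um=radii, orientation=orient,
                cell_class=cell_class, layer=layer_label, vessel_id=vessel_id))
            next_id += 1
            return True
        return False

    for spec, counts, (y0, y1) in zip(config.layers, layer_counts,
                                      zip(bounds[:-1], bounds[1:])):
        n_neu, n_gli, n_vas = (int(c) for c in counts)

        # vascular first: they are the most constrained (must sit on a wall)
        if n_vas:
            in_layer = (wall_pts[:, 1] >= y0) & (wall_pts[:, 1] < y1)
            layer_idx = np.flatnonzero(in_layer)
            if layer_idx.size == 0:
                raise PackingError(
                    f"no vessel passes through layer {spec.label}; cannot place "
                    f"{n_vas} vascular cells")
            # concentrate the quota on few vessels so the nuclei form the
            # dense per-vessel agglomerations the geometric detector keys on
            by_vessel = {}
            for k in layer_idx:
                by_vessel.setdefault(int(wall_vid[k]), []).append(k)
            vids = [v for v in vessel_order if v in by_vessel]
            n_use = min(len(vids),
                        max(1, int(np.ceil(n_vas * occupancy_spacing
                                           / spec.thickness_um))))
            active = list(range(n_use))
            idx_pool = np.concatenate([by_vessel[vids[i]] for i in active])
            for _ in range(n_vas):
                radii, _ = _sample_radii(rng, "vascular", config)
                state = {}

                def center_fn():
                    # resample until the nucleus center lies inside the
                    # stack and its own layer slab: vessels extend into a
                    # padded volume, so conditioning on "inside" keeps the
                    # accepted centers spatially uniform with no border
                    # deficit relative to the other classes
                    for _ in range(50):
                        i = int(rng.choice(idx_pool))
                        tangent = wall_tan[i]
                        # radial offset onto the tube wall
                        perp = _random_unit(rng)
                        perp = perp - (perp @ tangent) * tangent
                        nrm = np.linalg.norm(perp)
                        perp = perp / nrm if nrm > 1e-9 else np.array([1.0, 0, 0])
                        dist = config.vessel_radius_um * rng.uniform(0.7, 1.0)
                        p = wall_pts[i] + dist * perp
                        if (0 <= p[0] < zmax and 0 <= p[2] < xmax
                                and y0 <= p[1] < y1):
                            state["i"] = i
                            return p
                    return None

                def orient_fn(p):
                    return wall_tan[state["i"]].copy()

                # filiform nuclei pack end-to-end along the wall: use a
                # softer hard core than their long semi-axis would imply
                while not try_place(center_fn, radii, spec.label, "vascular",
                                    0, orient_fn, hard_radius=0.8 * radii[0]):
                    if len(active) >= len(vids):
                        raise PackingError(
                            f"could not place vascular cell in layer "
                            f"{spec.label} after {max_attempts} attempts")
                    # occupied vessels are full here: open another one
                    active.append(len(active))
                    idx_pool = np.concatenate(
                        [by_vessel[vids[i]] for i in active])
                # record the actual vessel used
                cells[-1].vessel_id = int(wall_vid[state["i"]])

        for cell_class, n in (("neuron", n_neu), ("glia", n_gli)):
            for _ in range(n):
                radii, orient = _sample_radii(rng, cell_class, config)

                def center_fn():
                    return np.array([
                        rng.uniform(0, zmax),
                        rng.uniform(y0, y1),
                        rng.uniform(0, xmax),
                    ])

                if not try_place(center_fn, radii, spec.label, cell_class, None,
                                 lambda p, o=orient: o, check_lumen=True):
                    raise PackingError(
                        f"could not place {cell_class} in layer {spec.label} after "
                        f"{max_attempts} attempts (density vs. min separation)")

    # optional touching-pair injection for segmentation stress tests
    if config.touching_fraction > 0:
        base = [c for c in cells if c.cell_class != "vascular"]
        n_extra = int(round(config.touching_fraction * len(base)))
        picks = rng.choice(len(base), size=min(n_extra, len(base)), replace=False)
        for k in picks:
            host = base[int(k)]
            radii, orient = _sample_radii(rng, host.cell_class, config)
            direction = _random_unit(rng)
            p = host.center_um + direction * 0.85 * (host.radii_um[0] + radii[0])
            lo = np.zeros(3)
            hi = np.array(config.extent_um)
            if np.any(p < lo) or np.any(p >= hi):
                continue
            layer_idx = min(np.searchsorted(bounds, p[1], side="right") - 1,
                            len(config.layers) - 1)
            cells.append(GroundTruthCell(
                id=next_id, center_um=p, radii_um=radii, orientation=orient,
                cell_class=host.cell_class,
                layer=config.layers[max(layer_idx, 0)].label))
            next_id += 1

    return cells, vessels


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _cell_patch(cell: GroundTruthCell, voxel, shape, margin_um=2.0):
    """Voxel slice around one cell and the ellipsoidal coordinate ``m`` on it
    (m = 1 at the nucleus surface)."""
    vox = np.asarray(voxel)
    r_max = float(cell.radii_um.max()) + margin_um
    lo = np.maximum(((cell.center_um - r_max) / vox).astype(int), 0)
    hi = np.minimum(((cell.center_um + r_max) / vox).astype(int) + 2,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return None, None
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[(np.arange(a, b) + 0.5) * v
                          for a, b, v in zip(lo, hi, vox)], indexing="ij")
    d = np.stack(grids, axis=-1) - cell.center_um

    # orthonormal frame: long axis + any perpendicular complement
    u = cell.orientation / np.linalg.norm(cell.orientation)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v1 = np.cross(u, helper)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    R = np.stack([u, v1, v2])  # rows = ellipsoid axes
    local = d @ R.T
    m2 = (local / cell.radii_um) ** 2
    m = np.sqrt(m2.sum(axis=-1))
    return sl, m


def _kernel_profile(m, radii, falloff_um=0.5):
    """Flat top inside the surface, Gaussian falloff (in physical um) outside."""
    r_eff = float(np.cbrt(np.prod(radii)))
    d_out = np.clip(m - 1.0, 0.0, None) * r_eff
    return np.where(m <= 1.0, 1.0, np.exp(-0.5 * (d_out / falloff_um) ** 2))


def render_stack(cells, vessels, config: SimulationConfig) -> ImageStack:
    """Render the forward model: ellipsoidal intensity kernels per channel,
    vessel tubes, PSF blur and Poisson-Gaussian noise at the configured SNR.

    The nuclear channel sums kernels of all cells; the neuron-marker channel
    only of neurons; the vessel-marker channel renders the vessel tubes.
    Output intensities live in a fixed unsigned-16-bit-equivalent range.
    """
    shape = config.grid_shape()
    n_vox = int(np.prod(shape)) * len(config.channels)
    if n_vox > config.max_voxels:
        raise ValueError(
            f"stack of {n_vox} voxels exceeds the configured budget "
            f"({config.max_voxels}); shrink the stack or raise max_voxels")

    vox = np.asarray(config.voxel_size_um)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    amp = {c.id: rng.uniform(0.85, 1.15) for c in cells}

    planes = {}
    for name in config.channels:
        planes[name] = np.zeros(shape, dtype=np.float32)

    for cell in cells:
        sl, m = _cell_patch(cell, vox, shape)
        if sl is None:
            continue
        prof = (_kernel_profile(m, cell.radii_um) * amp[cell.id]).astype(np.float32)
        if NUCLEAR in planes:
            np.maximum(planes[NUCLEAR][sl], prof, out=planes[NUCLEAR][sl])
        if NEURON_MARKER in planes and cell.cell_class == "neuron":
            np.maximum(planes[NEURON_MARKER][sl], prof,
                       out=planes[NEURON_MARKER][sl])

    if VESSEL_MARKER in planes:
        tube = planes[VESSEL_MARKER]
        for vessel in vessels:
            pts = vessel.polyline_um
            for p0, p1 in zip(pts[:-1], pts[1:]):
                _render_tube_segment(tube, p0, p1, vessel.radius_um, vox)

    out = np.empty((len(config.channels),) + shape, dtype=np.uint16)
    sigma_vox = np.asarray(config.psf_sigma_um) / vox
    bg_counts = BACKGROUND_FRACTION * config.snr**2
    fg_counts = config.snr**2
    for i, name in enumerate(config.channels):
        img = gaussian_filter(planes[name], sigma=sigma_vox)
        counts = rng.poisson(bg_counts + img * fg_counts).astype(np.float32)
        counts += rng.normal(0.0, np.sqrt(bg_counts) * 0.25, size=shape)
        scaled = counts * (FOREGROUND_LEVEL / fg_counts)
        out[i] = np.clip(scaled, 0, 65535).astype(np.uint16)

    return ImageStack(data=out, channels=list(config.channels),
                      voxel_size_um=config.voxel_size_um,
                      meta={"seed": config.seed, "snr": config.snr})


def _render_tube_segment(vol, p0, p1, radius, vox):
    """Add a soft-edged cylinder between two points into ``vol`` (in place)."""
    pad = radius + 1.5
    lo = np.maximum(((np.minimum(p0, p1) - pad) / vox).astype(int), 0)
    hi = np.minimum(((np.maximum(p0, p1) + pad) / vox).astype(int) + 2,
                    np.asarray(vol.shape))
    if np.any(lo >= hi):
        return
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[(np.arange(a, b) + 0.5) * v
                          for a, b, v in zip(lo, hi, vox)], indexing="ij")
    p = np.stack(grids, axis=-1)
    seg = p1 - p0
    L2 = seg @ seg
    t = np.clip(((p - p0) @ seg) / L2, 0.0, 1.0)
    closest = p0 + t[..., None] * seg
    dist = np.linalg.norm(p - closest, axis=-1)
    prof = np.where(dist <= radius, 1.0,
                    np.exp(-0.5 * ((dist - radius) / 0.5) ** 2)).astype(np.float32)
    np.maximum(vol[sl], prof, out=vol[sl])


def cell_bbox_um(cell: GroundTruthCell):
    """Tight axis-aligned physical bounding box of a cell's ellipsoid."""
    u = cell.orientation / np.linalg.norm(cell.orientation)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v1 = np.cross(u, helper)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    R = np.stack([u, v1, v2])  # rows = ellipsoid axes
    # support of the ellipsoid along world axis a: ||diag(r) R e_a||
    half = np.sqrt(((cell.radii_um[:, None] * R) ** 2).sum(axis=0))
    return cell.center_um - half, cell.center_um + half


def ground_truth_labels(cells, config: SimulationConfig,
                        core: float = 0.9) -> np.ndarray:
    """Voxel-level ground-truth labeling: voxel centers with ellipsoidal
    coordinate m <= ``core`` get the cell's id + 1 (later cells win ties)."""
    shape = config.grid_shape()
    labels = np.zeros(shape, dtype=np.int32)
    vox = np.asarray(config.voxel_size_um)
    for cell in cells:
        sl, m = _cell_patch(cell, vox, shape, margin_um=0.5)
        if sl is None:
            continue
        labels[sl][m <= core] = cell.id + 1
    return labels


# ---------------------------------------------------------------------------
# ground-truth persistence
# ---------------------------------------------------------------------------

_GT_COLUMNS = ["id", "z_um", "y_um", "x_um", "r1_um", "r2_um", "r3_um",
               "oz", "oy", "ox", "cell_class", "layer", "vessel_id"]


def cells_to_frame(cells) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append({
            "id": c.id,
            "z_um": c.center_um[0], "y_um": c.center_um[1], "x_um": c.center_um[2],
            "r1_um": c.radii_um[0], "r2_um": c.radii_um[1], "r3_um": c.radii_um[2],
            "oz": c.orientation[0], "oy": c.orientation[1], "ox": c.orientation[2],
            "cell_class": c.cell_class, "layer": c.layer,
            "vessel_id": -1 if c.vessel_id is None else c.vessel_id,
        })
    return pd.DataFrame(rows, columns=_GT_COLUMNS)


def write_ground_truth(cells, path) -> None:
    """Write one CSV row per placed cell; round-trips losslessly through
    :func:`read_ground_truth` (full float precision)."""
    cells_to_frame(cells).to_csv(path, index=False, float_format="%.17g")


def read_ground_truth(path) -> list[GroundTruthCell]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        vid = int(r["vessel_id"])
        out.append(GroundTruthCell(
            id=int(r["id"]),
            center_um=np.array([r["z_um"], r["y_um"], r["x_um"]]),
            radii_um=np.array([r["r1_um"], r["r2_um"], r["r3_um"]]),
            orientation=np.array([r["oz"], r["oy"], r["ox"]]),
            cell_class=str(r["cell_class"]), layer=str(r["layer"]),
            vessel_id=None if vid < 0 else vid))
    return out


def simulate_column(config: SimulationConfig):
    """Convenience wrapper: place cells and render in one call.

    Returns ``(stack, cells, vessels)``.
    """
    cells, vessels = place_cells(config)
    stack = render_stack(cells, vessels, config)
    return stack, cells, vessels
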