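"""Multichannel 3D image container and OME-TIFF I/O.

Axis convention used throughout the package: arrays are ordered
``(channel, z, y, x)`` where ``z`` is the optical axis (the ~50 um section
thickness sampled at ~1 um steps), ``y`` is the cortical-depth axis running
from the pia (y = 0) toward the white matter, and ``x`` is the tangential
width. Physical voxel sizes are carried as ``(z, y, x)`` spacings in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack"]

#: canonical channel names understood by the pipeline
NUCLEAR = "nuclear"
NEURON_MARKER = "neuron_marker"
VESSEL_MARKER = "vessel_marker"
KNOWN_CHANNELS = (NUCLEAR, NEURON_MARKER, VESSEL_MARKER)


@dataclass
class ImageStack:
    """A multichannel 3D voxel grid with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, nz, ny, nx)``.
    channels
        Channel names, one per leading-axis slice (e.g. ``["nuclear",
        "neuron_marker"]``).
    voxel_size_um
        Spacings ``(dz, dy, dx)`` in micrometres.
    """

    data: np.ndarray
    channels: list[str]
    voxel_size_um: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be 3 positive spacings (dz, dy, dx)")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) of the voxel grid in um."""
        return tuple(n * v for n, v in zip(self.shape_zyx, self.voxel_size_um))

    def channel(self, name: str) -> np.ndarray:
        """Return the 3D array for a named channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (has {self.channels})"
            ) from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a single OME-TIFF (CZYX order).

    Physical voxel sizes and channel names go into the OME metadata so the
    file round-trips through :func:`read_stack` without sidecar files.
    """
    dz, dy, dx = stack.voxel_size_um
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channels)},
        },
    )


def read_stack(path, voxel_size_um=None, channels=None) -> ImageStack:
    """Read a multipage/OME TIFF into an :class:`ImageStack`.

    Voxel sizes and channel names are taken from OME metadata when present;
    ``voxel_size_um`` / ``channels`` act as overrides for plain TIFFs.

    Raises
    ------
    ValueError
        If no physical calibration is available from either source.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta_vox = None
        meta_channels = None
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                try:
                    meta_vox = (
                        float(px.attrib["PhysicalSizeZ"]),
                        float(px.attrib["PhysicalSizeY"]),
                        float(px.attrib["PhysicalSizeX"]),
                    )
                except KeyError:
                    meta_vox = None
                names = [
                    ch.attrib.get("Name")
                    for ch in px.findall("ome:Channel", ns)
                ]
                if names and all(n is not None for n in names):
                    meta_channels = names

    # normalize to (C, Z, Y, X)
    if data.ndim == 3:
        if axes.upper().startswith("C"):
            data = data[:, None]  # (C, Y, X) -> single plane
        else:
            data = data[None]  # (Z, Y, X) single channel
    elif data.ndim == 4:
        if axes.upper() in ("ZCYX",):
            data = np.moveaxis(data, 1, 0)
    elif data.ndim != 4:
        raise ValueError(f"cannot interpret TIFF with axes {axes!r}")

    vox = voxel_size_um or meta_vox
    if vox is None:
        raise ValueError(
            "no physical voxel calibration in TIFF metadata and no override given"
        )
    names = channels or meta_channels or [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data=data, channels=list(names), voxel_size_um=tuple(vox))
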