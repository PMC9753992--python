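"""In-memory containers for multichannel 3D organoid stacks and label images.

An :class:`OrganoidVolume` is an anisotropic confocal z-stack: one intensity
array per named fluorescence channel (DAPI plus cytoplasmic markers such as
alpha-SMA, CK-19 and annexin A5), with physical voxel dimensions in
micrometres. A :class:`LabelVolume` is an integer object map produced by
segmentation (``kind="nuclei"`` or ``kind="cells"``).

Volumes round-trip through OME-TIFF with ZCYX axis order and channel names in
the metadata; label volumes are written as 16-bit TIFF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "OrganoidVolume",
    "LabelVolume",
    "VolumeFormatError",
    "load_volume",
    "save_volume",
    "save_labels",
    "load_labels",
]

#: Channel names used throughout the package.
DAPI = "DAPI"
ASMA = "aSMA"
CK19 = "CK19"
ANNEXIN = "AnnexinA5"
KI67 = "Ki67"

CYTOPLASMIC_CHANNELS = (ASMA, CK19, ANNEXIN)


class VolumeFormatError(ValueError):
    """Raised when a TIFF cannot be interpreted as an organoid volume."""


@dataclass
class OrganoidVolume:
    """A multichannel 3D intensity stack.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_z, n_y, n_x)``, nonnegative.
    channels
        Channel names, one per leading-axis slice. Must contain ``"DAPI"``.
    voxel_size_um
        Physical voxel size ``(x, y, z)`` in micrometres, all positive.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 5.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channels = tuple(self.channels)
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) data, got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("number of channel names must match data.shape[0]")
        if DAPI not in self.channels:
            raise ValueError("a DAPI channel is required")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be nonnegative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def depth_um(self) -> float:
        """Physical z-extent of the stack (n_z x z-step)."""
        return self.data.shape[1] * self.voxel_size_um[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) intensity array for one channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None
        return self.data[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Voxel spacing reordered to (z, y, x), for anisotropy-aware transforms."""
        x, y, z = self.voxel_size_um
        return (z, y, x)


@dataclass
class LabelVolume:
    """An integer object map over a volume.

    Labels are contiguous ``1..K`` with 0 as background; ``kind`` records
    whether objects are nuclei or whole cells.
    """

    labels: np.ndarray
    kind: str
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 5.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected (Z, Y, X) labels, got shape {self.labels.shape}")
        if self.kind not in ("nuclei", "cells"):
            raise ValueError("kind must be 'nuclei' or 'cells'")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def voxel_volume_um3(self) -> float:
        x, y, z = self.voxel_size_um
        return x * y * z

    def object_table(self):
        """Per-object centroid (μm, zyx) and volume (μm³) as a DataFrame."""
        import pandas as pd
        from scipy import ndimage

        k = self.n_objects
        if k == 0:
            return pd.DataFrame(
                columns=["label", "z_um", "y_um", "x_um", "volume_um3"]
            )
        idx = np.arange(1, k + 1)
        centroids = ndimage.center_of_mass(
            np.ones_like(self.labels, dtype=np.uint8), self.labels, idx
        )
        counts = ndimage.sum_labels(
            np.ones_like(self.labels, dtype=np.uint8), self.labels, idx
        )
        sz, sy, sx = (self.voxel_size_um[2], self.voxel_size_um[1], self.voxel_size_um[0])
        return pd.DataFrame(
            {
                "label": idx,
                "z_um": [c[0] * sz for c in centroids],
                "y_um": [c[1] * sy for c in centroids],
                "x_um": [c[2] * sx for c in centroids],
                "volume_um3": counts * self.voxel_volume_um3,
            }
        )


def save_volume(volume: OrganoidVolume, path: str | Path) -> Path:
    """Write a volume as OME-TIFF (ZCYX) with channel names and voxel sizes."""
    path = Path(path)
    x, y, z = volume.voxel_size_um
    # tifffile expects TZCYX-style axes; write ZCYX explicitly.
    data = np.moveaxis(volume.data, 0, 1)  # (Z, C, Y, X)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "Channel": {"Name": list(volume.channels)},
            "PhysicalSizeX": x,
            "PhysicalSizeY": y,
            "PhysicalSizeZ": z,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )
    return path


def load_volume(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channels: tuple[str, ...] | None = None,
) -> OrganoidVolume:
    """Read a TIFF/OME-TIFF stack as an :class:`OrganoidVolume`.

    Axis order is normalized to ``(channel, z, y, x)``. Voxel sizes and channel
    names come from OME metadata when present; explicit arguments override the
    metadata. A plain 2D image is promoted to a single z-plane with a warning.

    Raises
    ------
    VolumeFormatError
        If the file is unreadable, or voxel metadata is absent and no
        ``voxel_size_um`` override is given.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            axes = None
            meta_channels = None
            meta_voxel = None
            if tif.ome_metadata:
                series = tif.series[0]
                axes = series.axes
                meta_channels, meta_voxel = _parse_ome(tif.ome_metadata)
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise VolumeFormatError(f"cannot read {path}: {exc}") from exc

    if data.ndim == 2:
        warnings.warn("2D single-plane TIFF promoted to a z=1 stack", stacklevel=2)
        data = data[None, None]  # (C=1, Z=1, Y, X)
    elif data.ndim == 3:
        # ambiguous: treat leading axis as channel only when OME says so
        if axes and axes.replace("S", "").startswith("C"):
            data = data[:, None]
        else:
            data = data[None]  # single channel z-stack
    elif data.ndim == 4:
        if axes and axes[:2] == "ZC":
            data = np.moveaxis(data, 1, 0)
        # else assume already (C, Z, Y, X)
    else:
        raise VolumeFormatError(f"unsupported TIFF dimensionality {data.ndim}")

    if channels is None:
        channels = tuple(meta_channels) if meta_channels else None
    if channels is None:
        channels = tuple(
            [DAPI] + [f"ch{i}" for i in range(1, data.shape[0])]
        )
    voxel = voxel_size_um or meta_voxel
    if voxel is None:
        raise VolumeFormatError(
            f"{path} carries no voxel-size metadata; pass voxel_size_um explicitly"
        )
    return OrganoidVolume(data=data, channels=channels, voxel_size_um=tuple(voxel))


def _parse_ome(ome_xml: str):
    """Extract channel names and (x, y, z) voxel sizes from OME-XML."""
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return None, None
    names = [
        c.get("Name") or f"ch{i}"
        for i, c in enumerate(pixels.findall("ome:Channel", ns))
    ]
    try:
        voxel = (
            float(pixels.get("PhysicalSizeX")),
            float(pixels.get("PhysicalSizeY")),
            float(pixels.get("PhysicalSizeZ")),
        )
    except (TypeError, ValueError):
        voxel = None
    return (names or None), voxel


def save_labels(labels: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as 16-bit TIFF."""
    path = Path(path)
    if labels.n_objects > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 objects cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, labels.labels.astype(np.uint16))
    return path


def load_labels(
    path: str | Path,
    kind: str,
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 5.0),
) -> LabelVolume:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelVolume(labels=arr.astype(np.int32), kind=kind, voxel_size_um=voxel_size_um)
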