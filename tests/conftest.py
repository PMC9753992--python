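"""Shared phantoms and matching helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from obp.synthetic import VolumeParams, generate_volume
from obp.volume import OrganoidVolume

#: spacing used by every constructed phantom (x, y, z) μm
VOX = (0.5, 0.5, 5.0)


def sphere_mask(shape_zyx, center_um, radius_um, voxel=VOX):
    """Boolean ball in physical coordinates on a (z, y, x) grid."""
    sx, sy, sz = voxel
    zc = (np.arange(shape_zyx[0]) + 0.5) * sz
    yc = (np.arange(shape_zyx[1]) + 0.5) * sy
    xc = (np.arange(shape_zyx[2]) + 0.5) * sx
    dz = zc[:, None, None] - center_um[0]
    dy = yc[None, :, None] - center_um[1]
    dx = xc[None, None, :] - center_um[2]
    return dz**2 + dy**2 + dx**2 <= radius_um**2


def make_volume(channel_arrays: dict[str, np.ndarray], voxel=VOX) -> OrganoidVolume:
    names = tuple(channel_arrays)
    data = np.stack([channel_arrays[n] for n in names]).astype(np.uint16)
    return OrganoidVolume(data=data, channels=names, voxel_size_um=voxel)


def well_separated_params(n_cells: int, seed: int = 3) -> VolumeParams:
    """Phantom parameters with centers at least two cytoplasm radii apart."""
    shell = {1: 18.0, 12: 30.0, 50: 55.0}.get(n_cells, 30.0 + 3.5 * np.sqrt(n_cells))
    return VolumeParams(
        n_cells=n_cells,
        seed=seed,
        shell_radius_um=shell,
        min_center_distance_um=16.0,
        # uniform radius: cytoplasm coronas (1.8 x 4 μm) then never overlap
        # at 16 μm spacing, so per-cell maxima are exactly attributable
        nucleus_radius_dispersion=0.0,
    )


@pytest.fixture(scope="session")
def phantom12():
    """A 12-cell noiseless phantom with ground truth (session-cached)."""
    return generate_volume(well_separated_params(12))


def centers_to_labels(truth, labels):
    """Map each ground-truth cell to the segmentation label at its center voxel."""
    sx, sy, sz = VOX
    out = []
    for z, y, x in truth.nucleus_centers_um:
        out.append(int(labels[int(z / sz), int(y / sy), int(x / sx)]))
    return out
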