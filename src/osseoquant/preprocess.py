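"""Grey-volume preprocessing: box-filter downsampling, unsharp masking, cropping.

These mirror the standard workstation workflow for large reconstructed
volumes: a 2x2x2 box-filter resample (factor 8 reduction of the data volume,
factor 2 of the resolution), slice-wise unsharp masking to steepen the
bone/background transition before thresholding, and cropping to the volume
of interest.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import GreyVolume


def resample_box2(vol: GreyVolume) -> GreyVolume:
    """Downsample by 2 along each axis with a 2x2x2 box (mean) filter.

    Each output voxel is the mean of a disjoint 2x2x2 input block; trailing
    odd rows/columns/slabs are dropped. Output spacing doubles; the origin
    shifts by half an input voxel so voxel-centre coordinates stay
    consistent.
    """
    if min(vol.shape) < 2:
        raise ValueError("all dimensions must be >= 2 to resample")
    nz, ny, nx = (d // 2 for d in vol.shape)
    d = vol.data[: 2 * nz, : 2 * ny, : 2 * nx].astype(np.float64)
    out = d.reshape(nz, 2, ny, 2, nx, 2).mean(axis=(1, 3, 5))
    origin = tuple(o + vol.spacing / 2 for o in vol.origin)
    return GreyVolume(out, spacing=2 * vol.spacing, origin=origin)


def unsharp_mask(
    vol: GreyVolume,
    kernel_size: int = 5,
    sharpness: float = 0.6,
    plain_gain: bool = False,
) -> GreyVolume:
    """Slice-wise (x-y plane) unsharp masking.

    ``out = in + g * (in - lowpass(in))`` where the lowpass is a
    ``kernel_size`` x ``kernel_size`` uniform mean with edge replication and
    the gain is ``g = sharpness / (1 - sharpness)`` (a convention: sharpness
    0.6 gives gain 1.5; ``plain_gain=True`` uses ``g = sharpness`` instead).
    The output is clipped to the input value range so edge overshoot cannot
    leave the original grey scale.
    """
    if kernel_size % 2 == 0 or kernel_size < 3:
        raise ValueError(f"kernel_size must be odd and >= 3, got {kernel_size}")
    if not 0.0 <= sharpness < 1.0:
        raise ValueError(f"sharpness must be in [0, 1), got {sharpness}")
    gain = sharpness if plain_gain else sharpness / (1.0 - sharpness)
    data = vol.data.astype(np.float64)
    low = ndimage.uniform_filter(data, size=(1, kernel_size, kernel_size), mode="nearest")
    out = data + gain * (data - low)
    out = np.clip(out, data.min(), data.max())
    return GreyVolume(out, spacing=vol.spacing, origin=vol.origin)


def crop_roi(
    vol: GreyVolume, box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
) -> GreyVolume:
    """Crop to a half-open voxel-index box ``((z0,z1),(y0,y1),(x0,x1))``."""
    (z0, z1), (y0, y1), (x0, x1) = box
    shape = vol.shape
    for (a, b), n in zip(((z0, z1), (y0, y1), (x0, x1)), shape):
        if not (0 <= a < b <= n):
            raise ValueError(f"box range ({a},{b}) invalid for axis of size {n}")
    out = vol.data[z0:z1, y0:y1, x0:x1].copy()
    origin = (
        vol.origin[0] + z0 * vol.spacing,
        vol.origin[1] + y0 * vol.spacing,
        vol.origin[2] + x0 * vol.spacing,
    )
    return GreyVolume(out, spacing=vol.spacing, origin=origin)
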