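"""From raw FOV hyperstacks to per-channel 2.5D network inputs.

Three steps: (1) clip the FOV into 8 channel crops, one pitch (150 um) wide,
centered on channel centerlines predicted from the fiduciary marker; (2) find
the best focal plane of a crop as the z-slice with the largest variance of
its discrete Laplacian response; (3) stack the N slices on either side of the
best focal plane into a (2N+1, H, W) tensor, min-max normalized and padded
symmetrically to a fixed network width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic_data import ChannelStack, FOVHyperstack

__all__ = [
    "InputTensor", "crop_fov", "best_focal_plane", "assemble_input",
    "NETWORK_WIDTH",
]

NETWORK_WIDTH = 384  # fixed padded width of full-resolution network inputs


def default_pad_width(width_px: int, multiple: int = 16) -> int:
    """Padded width for a crop: 384 for full-resolution crops (340-360 px),
    otherwise the next multiple of the network's downsampling factor."""
    if width_px >= 320:
        return NETWORK_WIDTH
    return -(-width_px // multiple) * multiple


@dataclass
class InputTensor:
    """The (2N+1, H, W) normalized, width-padded network input."""

    planes: np.ndarray
    focus_index: int
    pad_left: int
    pad_right: int
    source: ChannelStack | None = None

    @property
    def shape(self):
        return self.planes.shape

    def unpad(self) -> np.ndarray:
        """Remove the width padding, recovering the original crop width."""
        w = self.planes.shape[-1]
        return self.planes[..., self.pad_left : w - self.pad_right]


def crop_fov(
    fov: FOVHyperstack,
    fiduciary_position: tuple[int, int] | None = None,
) -> list[ChannelStack]:
    """Clip a FOV hyperstack into 8 channel crops, one pitch wide each.

    Channel centerlines are predicted as ``fiduciary_x + offset + k * pitch``
    for k = 0..7, with sub-pixel centers rounded to the nearest integer;
    crops are non-overlapping and ordered left to right.
    """
    scene = fov.scene
    if fiduciary_position is None:
        fiduciary_position = fov.fiduciary_xy_px
    fx = fiduciary_position[0]
    pitch_px = scene.channel_pitch_um / scene.pixel_size_um
    cw = scene.channel_width_px
    w_fov = fov.volume.shape[-1]
    if w_fov < scene.n_channels_per_fov * cw:
        raise ValueError(
            f"FOV width {w_fov} px is narrower than "
            f"{scene.n_channels_per_fov} pitches of {cw} px"
        )
    # offset from the fiduciary x to the first channel centerline
    first_center = fov.channel_centers_px[0] if fov.channel_centers_px else (
        (w_fov - scene.n_channels_per_fov * cw) // 2 + cw // 2
    )
    offset = first_center - fx
    crops = []
    for k in range(scene.n_channels_per_fov):
        center = int(round(fx + offset + k * pitch_px))
        x0 = center - cw // 2
        x0 = min(max(x0, 0), w_fov - cw)
        crops.append(
            ChannelStack(
                volume=fov.volume[:, :, :, x0 : x0 + cw].copy(),
                well_id=fov.well_id,
                fov_index=fov.fov_index,
                channel_index=k,
                pixel_size_um=scene.pixel_size_um,
                z_step_um=scene.z_step_um,
                centerline_x_px=center,
                fiduciary_offset_px=(center - fx, -fiduciary_position[1]),
            )
        )
    return crops


def best_focal_plane(stack: ChannelStack, t: int = 0) -> int:
    """Index of the sharpest z-slice at time point ``t``.

    Sharpness is the variance of the 4-neighbour discrete Laplacian of the
    slice ("highest frequency components").  Ties break to the lowest index.
    """
    vol = stack.volume
    if t >= vol.shape[0]:
        raise IndexError(f"time point {t} outside stack with T={vol.shape[0]}")
    energies = [
        float(ndimage.laplace(vol[t, z].astype(np.float64)).var())
        for z in range(vol.shape[1])
    ]
    return int(np.argmax(energies))  # argmax returns the first maximum


def assemble_input(
    stack: ChannelStack,
    t: int = 0,
    n_planes: int = 1,
    pad_to: int = NETWORK_WIDTH,
    normalize: bool = True,
) -> InputTensor:
    """Build the (2N+1, H, W) network input around the best focal plane.

    Slices z*-N .. z*+N are gathered (indices beyond the stack are clamped
    by edge replication); the width is padded symmetrically to ``pad_to``
    with edge replication, an odd remainder adding the extra column on the
    right.  Intensities are min-max normalized to [0, 1] per crop.
    """
    vol = stack.volume
    n_z = vol.shape[1]
    if 2 * n_planes + 1 > n_z:
        raise ValueError(
            f"2N+1 = {2 * n_planes + 1} planes requested but stack has Z={n_z}"
        )
    z_star = best_focal_plane(stack, t)
    z_idx = np.clip(
        np.arange(z_star - n_planes, z_star + n_planes + 1), 0, n_z - 1
    )
    planes = vol[t, z_idx].astype(np.float64)
    if normalize:
        lo, hi = planes.min(), planes.max()
        planes = (planes - lo) / (hi - lo) if hi > lo else np.zeros_like(planes)
    w = planes.shape[-1]
    if pad_to < w:
        raise ValueError(f"crop width {w} exceeds network width {pad_to}")
    pad_left = (pad_to - w) // 2
    pad_right = pad_to - w - pad_left
    planes = np.pad(planes, ((0, 0), (0, 0), (pad_left, pad_right)),
                    mode="edge")
    return InputTensor(
        planes=planes,
        focus_index=int(z_star),
        pad_left=pad_left,
        pad_right=pad_right,
        source=stack,
    )
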