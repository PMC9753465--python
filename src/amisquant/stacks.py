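"""Calibrated image volumes and the projection conventions used throughout.

Two projections are supported: a maximum-value projection over the whole
z stack (used for whole-cluster views and counting) and a maximum-value
projection over exactly the three central slices (used for all line-scan
and region-of-interest measurements, where out-of-plane membrane signal
would contaminate the interface profile).

Coordinate contract
-------------------
All geometry is specified in μm and converted to pixel indices at use
time.  Indices are 0-based; the physical coordinate of voxel centre
``(iz, iy, ix)`` is ``(iz * z_step_um, iy * pixel_size_um,
ix * pixel_size_um)``; points are passed around as ``(x, y[, z])``
tuples with x fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalibratedStack:
    """Multi-channel image volume with physical calibration.

    Parameters
    ----------
    voxels
        Intensity array.  Axis order follows ``axes``: ``"CZYX"`` for a
        z-stack (the default), ``"CTYX"`` for a single-plane time-lapse,
        ``"CTZYX"`` for a time-lapse of z-stacks.
    pixel_size_um
        In-plane pixel size (μm/pixel), identical in x and y.
    z_step_um
        Axial spacing between slices (μm); ``None`` for purely 2D data.
    channel_names
        One label per channel, e.g. ``("actin", "cadherin", "par3")``.
    frame_interval_s
        Time between frames for time-lapse stacks; ``None`` otherwise.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_step_um: float | None = None
    channel_names: tuple[str, ...] = ()
    axes: str = "CZYX"
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.axes not in ("CZYX", "CTYX", "CTZYX"):
            raise ValueError(f"unsupported axes {self.axes!r}")
        if self.voxels.ndim != len(self.axes):
            raise ValueError(
                f"voxels ndim {self.voxels.ndim} does not match axes {self.axes!r}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.z_step_um is not None and self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.voxels.shape[0]))
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError("channel_names length must match channel axis")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be >= 0")

    # -- access -----------------------------------------------------------

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.voxels.shape[0]:
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    @property
    def n_z(self) -> int:
        if "Z" not in self.axes:
            return 1
        return self.voxels.shape[self.axes.index("Z")]

    @property
    def n_frames(self) -> int:
        if "T" not in self.axes:
            return 1
        return self.voxels.shape[self.axes.index("T")]

    def channel_volume(self, channel: int | str) -> np.ndarray:
        """The (Z, Y, X) volume of one channel (z-stack axes only)."""
        if self.axes != "CZYX":
            raise ValueError("channel_volume requires CZYX axes")
        return self.voxels[self.channel_index(channel)]

    def frame_image(self, channel: int | str, frame: int) -> np.ndarray:
        """The (Y, X) image of one channel at one time frame (CTYX axes)."""
        if self.axes != "CTYX":
            raise ValueError("frame_image requires CTYX axes")
        return self.voxels[self.channel_index(channel), frame]


@dataclass
class ProjectedImage:
    """A 2D projection of one channel, with provenance and calibration."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = "ch0"
    provenance: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ProjectedImage.pixels must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")


def max_project_full(stack: CalibratedStack, channel: int | str) -> ProjectedImage:
    """Maximum-value projection over the whole z stack of one channel.

    Used to produce whole-cluster views; each output pixel is the
    maximum over all slices of that pixel.  Input bit depth is retained.
    """
    vol = stack.channel_volume(channel)
    idx = stack.channel_index(channel)
    return ProjectedImage(
        pixels=vol.max(axis=0),
        pixel_size_um=stack.pixel_size_um,
        channel=stack.channel_names[idx],
        provenance=tuple(range(vol.shape[0])),
    )


def central_section_project(
    stack: CalibratedStack, channel: int | str
) -> ProjectedImage:
    """Maximum-value projection over exactly the three central slices.

    Central-section images are the substrate of all line-scan and
    region-of-interest measurements.  For a stack of ``n`` slices the
    central three are ``{n//2 - 1, n//2, n//2 + 1}`` (0-based), which
    for odd ``n`` is the middle slice and its neighbours; the slice
    indices used are recorded in ``provenance``.
    """
    vol = stack.channel_volume(channel)
    n = vol.shape[0]
    if n < 3:
        raise ValueError(f"central_section_project needs >= 3 slices, got {n}")
    centre = n // 2
    indices = (centre - 1, centre, centre + 1)
    idx = stack.channel_index(channel)
    return ProjectedImage(
        pixels=vol[list(indices)].max(axis=0),
        pixel_size_um=stack.pixel_size_um,
        channel=stack.channel_names[idx],
        provenance=indices,
    )
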