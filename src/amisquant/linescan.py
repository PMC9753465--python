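"""Width-averaged line-scans along cell–cell interfaces.

The measurement recipe: a polyline path (default band width 0.8 μm) is
drawn along the interface on a central-section image, intensity is
sampled along the path with perpendicular width-averaging, the two
F-actin peaks at the path ends delimit the interface ("1× cell–cell
interface"), and the delimited span is sectioned into 20 bins of 5%
arc length whose means form the normalized profile.  Profiles from many
doublets are then averaged bin-wise.

Paths are supplied (from annotation files or synthetic-scene truth),
never auto-traced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates

from ._util import partition_indices, perpendicular_offsets
from .errors import DetectionError, GeometryError
from .stacks import CalibratedStack, ProjectedImage

DEFAULT_LINE_WIDTH_UM = 0.8
N_INTERFACE_BINS = 20


@dataclass
class PolyLinePath:
    """An ordered polyline in physical (x, y) μm coordinates with a
    perpendicular averaging band width."""

    vertices: np.ndarray  # (N, 2) of (x, y) in μm
    width_um: float = DEFAULT_LINE_WIDTH_UM

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y) μm")
        if len(self.vertices) < 2:
            raise ValueError("a path needs at least 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive vertices must be distinct")
        if self.width_um <= 0:
            raise ValueError("width_um must be > 0")

    @property
    def length_um(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def sample_points(self, spacing_um: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Equally spaced arc-length samples along the polyline.

        Returns ``(arc_positions, points, normals)`` where ``points`` is
        (n, 2) μm and ``normals`` the unit perpendicular of the local
        segment at each sample.
        """
        if spacing_um <= 0:
            raise ValueError("spacing_um must be > 0")
        seg = np.diff(self.vertices, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        n = int(np.floor(total / spacing_um + 1e-9)) + 1
        arc = np.arange(n) * spacing_um
        # locate each arc position on its segment
        seg_idx = np.clip(np.searchsorted(cum, arc, side="right") - 1, 0, len(seg) - 1)
        frac = (arc - cum[seg_idx]) / seg_len[seg_idx]
        points = self.vertices[seg_idx] + frac[:, None] * seg[seg_idx]
        tangents = seg[seg_idx] / seg_len[seg_idx, None]
        normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
        return arc, points, normals

    # -- annotation serialisation ----------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"vertices_um": self.vertices.tolist(), "width_um": self.width_um},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PolyLinePath":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["vertices_um"], float), float(d["width_um"]))


@dataclass
class InterfaceProfile:
    """Width-averaged intensity samples along an interface path."""

    arc_positions_um: np.ndarray
    values: dict[str, np.ndarray]  # channel -> per-sample intensity
    pixel_size_um: float
    interface_start_idx: int | None = None
    interface_end_idx: int | None = None

    def __post_init__(self) -> None:
        self.arc_positions_um = np.asarray(self.arc_positions_um, float)
        if np.any(np.diff(self.arc_positions_um) <= 0):
            raise ValueError("arc positions must be strictly increasing")
        for ch, v in self.values.items():
            if len(v) != len(self.arc_positions_um):
                raise ValueError(f"channel {ch!r} has wrong sample count")
        if self.interface_start_idx is not None and self.interface_end_idx is not None:
            if not self.interface_start_idx < self.interface_end_idx:
                raise ValueError("interface_start_idx must precede interface_end_idx")

    @property
    def n_samples(self) -> int:
        return len(self.arc_positions_um)


@dataclass
class BinnedProfile:
    """The 20-bin (5% arc length each) normalized interface profile."""

    bin_means: np.ndarray
    channel: str
    n_bins: int = N_INTERFACE_BINS
    n_profiles: int = 1

    def __post_init__(self) -> None:
        self.bin_means = np.asarray(self.bin_means, float)
        if len(self.bin_means) != self.n_bins:
            raise ValueError(f"expected {self.n_bins} bins, got {len(self.bin_means)}")

    @property
    def arc_fractions(self) -> np.ndarray:
        """Bin-centre positions as fractions of interface length."""
        return (np.arange(self.n_bins) + 0.5) / self.n_bins


def _image_and_calibration(
    image: ProjectedImage | CalibratedStack,
    channels: list[str] | None,
    z: int | None,
) -> tuple[dict[str, np.ndarray], float]:
    if isinstance(image, ProjectedImage):
        return {image.channel: image.pixels}, image.pixel_size_um
    if isinstance(image, CalibratedStack):
        if image.axes != "CZYX":
            raise ValueError("line-scans on stacks require CZYX axes")
        z_idx = image.n_z // 2 if z is None else z
        names = channels if channels is not None else list(image.channel_names)
        planes = {
            name: image.channel_volume(name)[z_idx] for name in names
        }
        return planes, image.pixel_size_um
    raise TypeError("image must be a ProjectedImage or CalibratedStack")


def sample_path_intensity(
    image: ProjectedImage | CalibratedStack,
    path: PolyLinePath,
    channels: list[str] | None = None,
    z: int | None = None,
) -> InterfaceProfile:
    """Sample width-averaged intensity along ``path``.

    One sample per pixel-size of arc length.  At each sample the value is
    the mean of bilinearly interpolated sub-samples taken along the
    perpendicular segment of length ``path.width_um`` centred on the
    path; the sub-sample count is ``ceil(width/pixel)`` forced odd, with
    pixel-size spacing.

    Raises
    ------
    GeometryError
        If any sub-sample falls outside the image after dilating the
        path by half its width.
    """
    planes, pixel_size = _image_and_calibration(image, channels, z)
    arc, points, normals = path.sample_points(pixel_size)
    offsets = perpendicular_offsets(path.width_um, pixel_size)
    # sub-sample coordinates, shape (n_samples, n_sub, 2)
    coords = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    cols = coords[..., 0] / pixel_size  # x -> column index
    rows = coords[..., 1] / pixel_size  # y -> row index
    shape = next(iter(planes.values())).shape
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() > shape[0] - 1
        or cols.max() > shape[1] - 1
    ):
        raise GeometryError("path (dilated by its width) exits the image bounds")
    values = {}
    for name, plane in planes.items():
        sub = map_coordinates(
            np.asarray(plane, float), [rows.ravel(), cols.ravel()], order=1
        ).reshape(rows.shape)
        values[name] = sub.mean(axis=1)
    return InterfaceProfile(arc, values, pixel_size)


def detect_interface_ends(
    profile: InterfaceProfile,
    actin_channel: str = "actin",
    prominence_frac: float = 0.05,
) -> tuple[int, int]:
    """Delimit the interface from the two F-actin end peaks.

    The start index is the actin argmax over the first half of the path
    and the end index the argmax over the second half (halves split at
    the sample midpoint).  Each peak must rise above its half's minimum
    by at least ``prominence_frac`` of the full profile's dynamic range,
    rejecting flat halves.  The detected indices are stored on the
    profile and returned; the span between them is the "1× interface".
    """
    if profile.n_samples < 5:
        raise ValueError("need at least 5 samples to detect interface ends")
    try:
        actin = profile.values[actin_channel]
    except KeyError:
        raise KeyError(f"profile has no channel {actin_channel!r}") from None
    dyn = float(actin.max() - actin.min())
    mid = profile.n_samples // 2
    first, second = actin[:mid], actin[mid:]
    if dyn == 0:
        raise DetectionError("actin profile is constant; no end peaks")
    start = int(np.argmax(first))
    # symmetric tie-break: last argmax in the second half
    end = mid + (len(second) - 1 - int(np.argmax(second[::-1])))
    min_prom = prominence_frac * dyn
    if actin[start] - first.min() < min_prom:
        raise DetectionError("no distinguishable actin peak in first half")
    if actin[end] - second.min() < min_prom:
        raise DetectionError("no distinguishable actin peak in second half")
    profile.interface_start_idx = start
    profile.interface_end_idx = end
    return start, end


def bin_profile(
    profile: InterfaceProfile,
    channel: str,
    n_bins: int = N_INTERFACE_BINS,
) -> BinnedProfile:
    """Section the delimited interface span into ``n_bins`` equal-share
    bins (default 20, i.e. 5% of interface length each) and average.

    The sample span ``[start_idx, end_idx]`` (inclusive) is partitioned
    into contiguous near-equal index ranges, remainder samples going to
    the earliest bins; each bin's value is the mean of its samples.
    """
    if profile.interface_start_idx is None or profile.interface_end_idx is None:
        raise ValueError("interface endpoints are unset; run detect_interface_ends")
    s, e = profile.interface_start_idx, profile.interface_end_idx
    span = profile.values[channel][s : e + 1]
    if len(span) < n_bins:
        raise ValueError(
            f"interface span of {len(span)} samples is shorter than {n_bins} bins"
        )
    means = np.array([span[sl].mean() for sl in partition_indices(len(span), n_bins)])
    return BinnedProfile(means, channel=channel, n_bins=n_bins)


def average_binned_profiles(
    profiles: list[BinnedProfile], dispersion: str = "sem"
) -> tuple[BinnedProfile, np.ndarray]:
    """Bin-wise mean of many normalized profiles, with per-bin dispersion.

    ``dispersion`` is ``"sem"`` (default, matching mean ± SEM plots) or
    ``"sd"``; for a single profile the dispersion is zero.
    """
    if not profiles:
        raise ValueError("need at least one profile to average")
    n_bins = profiles[0].n_bins
    if any(p.n_bins != n_bins for p in profiles):
        raise ValueError("all profiles must have the same bin count")
    stack = np.stack([p.bin_means for p in profiles])
    mean = stack.mean(axis=0)
    if dispersion == "sd":
        disp = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros(n_bins)
    elif dispersion == "sem":
        disp = (
            stack.std(axis=0, ddof=1) / np.sqrt(len(profiles))
            if len(profiles) > 1
            else np.zeros(n_bins)
        )
    else:
        raise ValueError("dispersion must be 'sem' or 'sd'")
    out = BinnedProfile(
        mean, channel=profiles[0].channel, n_bins=n_bins, n_profiles=len(profiles)
    )
    return out, disp


@dataclass
class CentreSideScans:
    """Perpendicular scans across the interface centre and sides, with
    the area under each curve for comparison."""

    centre: InterfaceProfile
    side: InterfaceProfile  # average of the two side scans
    auc_centre: float
    auc_side: float
    channel: str
    scan_width_um: float = 3.0

    @property
    def auc_ratio(self) -> float:
        return self.auc_centre / self.auc_side


def centre_side_linescans(
    image: ProjectedImage | CalibratedStack,
    interface_endpoints_um: np.ndarray,
    channel: str,
    scan_width_um: float = 3.0,
    scan_length_um: float = 3.0,
    z: int | None = None,
) -> CentreSideScans:
    """Centre-most versus side scans taken perpendicular across the
    interface.

    Three width-averaged scans (band width ``scan_width_um``, default
    3 μm, running parallel to the interface) cross the interface
    perpendicular to its chord: one at the interface midpoint and one on
    each side, centred one band-width away so the three regions tile
    without overlap and sit symmetrically about the midpoint.  The two
    side scans are averaged into one, and the area under each curve is
    returned for centre-vs-side comparison.
    """
    pts = np.asarray(interface_endpoints_um, float)
    if pts.shape != (2, 2):
        raise ValueError("interface_endpoints_um must be two (x, y) points")
    chord = pts[1] - pts[0]
    length = float(np.hypot(*chord))
    if length < 3 * scan_width_um:
        raise GeometryError(
            f"interface of {length:.2f} μm cannot host three non-overlapping "
            f"{scan_width_um} μm regions"
        )
    u = chord / length
    nvec = np.array([-u[1], u[0]])
    mid = pts.mean(axis=0)
    half = scan_length_um / 2.0

    def scan_at(centre_pt: np.ndarray) -> InterfaceProfile:
        path = PolyLinePath(
            np.stack([centre_pt - half * nvec, centre_pt + half * nvec]),
            width_um=scan_width_um,
        )
        return sample_path_intensity(image, path, channels=[channel], z=z)

    centre_scan = scan_at(mid)
    side_a = scan_at(mid - scan_width_um * u)
    side_b = scan_at(mid + scan_width_um * u)
    side_vals = (side_a.values[channel] + side_b.values[channel]) / 2.0
    side_scan = InterfaceProfile(
        side_a.arc_positions_um, {channel: side_vals}, side_a.pixel_size_um
    )
    auc_c = float(np.trapezoid(centre_scan.values[channel], centre_scan.arc_positions_um))
    auc_s = float(np.trapezoid(side_vals, side_scan.arc_positions_um))
    return CentreSideScans(
        centre=centre_scan,
        side=side_scan,
        auc_centre=auc_c,
        auc_side=auc_s,
        channel=channel,
        scan_width_um=scan_width_um,
    )
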