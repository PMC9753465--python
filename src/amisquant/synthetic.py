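"""Synthetic fluorescence scenes with known ground truth.

The generator renders the kinds of specimens the measurement pipeline is
designed for — two-cell doublets and small clusters of mouse embryonic
stem cells in 3D culture — as calibrated multi-channel z-stacks with a
machine-readable truth record, so every downstream statistic can be
asserted against known geometry and enrichment.

Scene model
-----------
Cell bodies are spheres with a soft-edged membrane shell of Gaussian
cross-section.  In a doublet the two spheres overlap and each is clipped
at the mid-plane, producing a flat shared interface whose membrane
signal receives one contribution per cell (hence roughly twice the
free-membrane level, as at a real junction).  Three channels are
rendered:

* ``actin`` and ``cadherin`` — membrane-localized: the clipped shells
  plus the interface disc.  A line-scan along the interface chord shows
  the two end peaks the interface detector requires.
* ``par3`` — a uniform cell-body baseline (the unpolarized, largely
  cytosolic pool) plus a Gaussian focus at the interface midpoint whose
  peak total equals ``par3_enrichment`` × baseline, plus optional
  peripheral puncta.  ``par3_enrichment = 1`` is the unpolarized null:
  the channel is flat across the cell bodies and every enrichment
  statistic equals 1.

Clusters (n ≥ 3 cells) place the cell centres symmetrically around a
common junction; the focus sits at the junction.  Noise follows the
standard fluorescence-camera model: optional Gaussian blur, then Poisson
noise on the scaled signal, then additive Gaussian read noise (clipped
at zero).  All geometry is specified in μm and converted to pixels at
render time (voxel-centre convention, 0-based indices, x fastest).
Identical parameters and seed give bit-identical output.

FRAP traces and moving-focus time-lapse stacks (for kymograph testing)
are generated from closed-form kinematics with the truth recorded
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError
from .frap import FRAPTrace
from .linescan import PolyLinePath
from .regions import RegionMask
from .stacks import CalibratedStack

SCENE_CHANNELS = ("actin", "cadherin", "par3")


@dataclass
class SceneParams:
    """Parameters of a synthetic doublet/cluster scene.

    Defaults render a 30 × 30 μm field at 0.2 μm pixels with 6 z-slices
    at a 2 μm step (the live-imaging axial sampling), two 6-μm-radius
    cells, a 0.8-μm-wide interface focus, and no noise.
    """

    n_cells: int = 2
    cell_radius_um: float = 6.0
    centre_spacing_um: float | None = None  # doublet centre-to-centre; default 1.2 r
    pixel_size_um: float = 0.2
    fov_um: tuple[float, float] = (30.0, 30.0)  # (y, x)
    z_slices: int = 7  # odd: the central slice passes through the cell equator
    z_step_um: float = 2.0
    membrane_width_um: float = 0.4
    membrane_amplitude: float = 100.0
    par3_enrichment: float = 1.0  # E: peak focus level relative to baseline
    par3_spot_sigma_um: float = 1.2  # FWHM ~2.8 μm: a junction-filling focus
    puncta_density: int = 0  # peripheral puncta per cell
    puncta_amplitude: float = 50.0
    noise_gaussian_sigma: float = 0.0
    noise_poisson_scale: float = 0.0  # 0 disables shot noise
    blur_sigma_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_radius_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("cell_radius_um and pixel_size_um must be > 0")
        if self.z_slices < 1 or self.z_step_um <= 0:
            raise ValueError("need z_slices >= 1 and z_step_um > 0")
        for name in (
            "membrane_width_um",
            "par3_spot_sigma_um",
            "noise_gaussian_sigma",
            "blur_sigma_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.par3_enrichment < 0:
            raise ValueError("par3_enrichment must be >= 0")

    @property
    def spacing_um(self) -> float:
        return (
            1.2 * self.cell_radius_um
            if self.centre_spacing_um is None
            else self.centre_spacing_um
        )


@dataclass
class SyntheticSceneTruth:
    """Ground truth of a rendered scene, in physical μm coordinates."""

    cell_centres: np.ndarray  # (n, 3) of (x, y, z)
    interface_chord_endpoints: np.ndarray  # (2, 3)
    interface_midpoint: np.ndarray  # (3,)
    long_axis_endpoints: np.ndarray  # (2, 3)
    centrosome_positions: np.ndarray  # (n, 3)
    enrichment_factor: float
    cell_radius_um: float
    pixel_size_um: float
    reference: np.ndarray | None = None  # noiseless (C, Z, Y, X) volume
    channel_names: tuple[str, ...] = SCENE_CHANNELS

    # -- convenience geometry --------------------------------------------

    @property
    def interface_midpoint_xy(self) -> tuple[float, float]:
        return float(self.interface_midpoint[0]), float(self.interface_midpoint[1])

    def interface_path(self, width_um: float = 0.8, margin_um: float = 1.0) -> PolyLinePath:
        """A straight annotation path along the interface chord, extended
        past both chord ends by ``margin_um`` so the actin end peaks fall
        strictly inside the path."""
        a, b = self.interface_chord_endpoints[:, :2]
        u = b - a
        length = float(np.hypot(*u))
        if length == 0:
            raise GeometryError("degenerate interface chord")
        u = u / length
        return PolyLinePath(
            np.stack([a - margin_um * u, b + margin_um * u]), width_um=width_um
        )

    def cluster_mask(self, shape: tuple[int, int]) -> RegionMask:
        """Union of the cell-body discs on the central section."""
        yy = np.arange(shape[0])[:, None] * self.pixel_size_um
        xx = np.arange(shape[1])[None, :] * self.pixel_size_um
        mask = np.zeros(shape, bool)
        for c in self.cell_centres:
            mask |= (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= self.cell_radius_um**2
        return RegionMask(mask, self.pixel_size_um, role="cluster boundary")

    def to_json(self, path: str | Path) -> None:
        """Serialize the geometric truth (without the reference volume)
        as a JSON sidecar."""
        d = {
            "cell_centres_um": self.cell_centres.tolist(),
            "interface_chord_endpoints_um": self.interface_chord_endpoints.tolist(),
            "interface_midpoint_um": self.interface_midpoint.tolist(),
            "long_axis_endpoints_um": self.long_axis_endpoints.tolist(),
            "centrosome_positions_um": self.centrosome_positions.tolist(),
            "enrichment_factor": self.enrichment_factor,
            "cell_radius_um": self.cell_radius_um,
            "pixel_size_um": self.pixel_size_um,
            "channel_names": list(self.channel_names),
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSceneTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cell_centres=np.asarray(d["cell_centres_um"], float),
            interface_chord_endpoints=np.asarray(
                d["interface_chord_endpoints_um"], float
            ),
            interface_midpoint=np.asarray(d["interface_midpoint_um"], float),
            long_axis_endpoints=np.asarray(d["long_axis_endpoints_um"], float),
            centrosome_positions=np.asarray(d["centrosome_positions_um"], float),
            enrichment_factor=float(d["enrichment_factor"]),
            cell_radius_um=float(d["cell_radius_um"]),
            pixel_size_um=float(d["pixel_size_um"]),
            channel_names=tuple(d["channel_names"]),
        )


@dataclass
class FRAPSimParams:
    """Parameters of a simulated FRAP recovery trace.

    Defaults follow the acquisition protocol of the experiments the
    model targets: 3 pre-bleach and 30 post-bleach frames at a 10 s
    interval.
    """

    mobile_fraction: float = 0.6
    rate_k: float = 0.02  # 1/s
    bleach_depth: float = 0.85
    pre_frames: int = 3
    post_frames: int = 30
    frame_interval_s: float = 10.0
    baseline: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.rate_k < 0:
            raise ValueError("rate_k must be >= 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.pre_frames < 1 or self.post_frames < 2:
            raise ValueError("need >= 1 pre-bleach and >= 2 post-bleach frames")


# ---------------------------------------------------------------------------
# scene rendering


def _grids(params: SceneParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ny = int(round(params.fov_um[0] / params.pixel_size_um))
    nx = int(round(params.fov_um[1] / params.pixel_size_um))
    zz = (np.arange(params.z_slices) * params.z_step_um)[:, None, None]
    yy = (np.arange(ny) * params.pixel_size_um)[None, :, None]
    xx = (np.arange(nx) * params.pixel_size_um)[None, None, :]
    return zz, yy, xx


def _volume_centre(params: SceneParams) -> np.ndarray:
    zz, yy, xx = _grids(params)
    return np.array(
        [float(xx.max()) / 2.0, float(yy.max()) / 2.0, float(zz.max()) / 2.0]
    )


def _shell(
    dist_to_centre: np.ndarray, radius: float, sigma: float, amplitude: float
) -> np.ndarray:
    return amplitude * np.exp(-((dist_to_centre - radius) ** 2) / (2.0 * sigma**2))


def _apply_noise(volume: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    out = volume
    if params.blur_sigma_um > 0:
        sig_xy = params.blur_sigma_um / params.pixel_size_um
        sig_z = params.blur_sigma_um / params.z_step_um
        out = np.stack([gaussian_filter(c, sigma=(sig_z, sig_xy, sig_xy)) for c in out])
    if params.noise_poisson_scale > 0:
        s = params.noise_poisson_scale
        out = rng.poisson(np.clip(out, 0, None) * s).astype(float) / s
    if params.noise_gaussian_sigma > 0:
        out = out + rng.normal(0.0, params.noise_gaussian_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


def _render_puncta(
    params: SceneParams,
    centres: np.ndarray,
    zz: np.ndarray,
    yy: np.ndarray,
    xx: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scattered peripheral puncta: points drawn on each cell's membrane
    sphere, rendered as Gaussian blobs of the membrane cross-section."""
    vol = np.zeros(np.broadcast_shapes(zz.shape, yy.shape, xx.shape))
    sigma = max(params.membrane_width_um, params.pixel_size_um)
    for c in centres:
        for _ in range(params.puncta_density):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = c + params.cell_radius_um * v  # (x, y, z)
            d2 = (xx - p[0]) ** 2 + (yy - p[1]) ** 2 + (zz - p[2]) ** 2
            vol += params.puncta_amplitude * np.exp(-d2 / (2.0 * sigma**2))
    return vol


def generate_doublet_scene(
    params: SceneParams,
) -> tuple[CalibratedStack, SyntheticSceneTruth]:
    """Render a two-cell doublet with a shared flat interface.

    Returns the noisy calibrated stack and the truth record (which keeps
    the noiseless per-channel reference volume).

    Raises
    ------
    GeometryError
        If the centre spacing does not place the two spheres in overlap
        (0 < spacing < 2 × radius is required).
    """
    if params.n_cells != 2:
        raise ValueError("generate_doublet_scene requires n_cells == 2")
    r = params.cell_radius_um
    s = params.spacing_um
    if not 0 < s < 2 * r:
        raise GeometryError(
            f"centre spacing {s} μm does not overlap two radius-{r} μm cells"
        )
    zz, yy, xx = _grids(params)
    centre = _volume_centre(params)
    cx, cy, cz = centre
    c1 = np.array([cx - s / 2.0, cy, cz])
    c2 = np.array([cx + s / 2.0, cy, cz])
    chord_radius = float(np.sqrt(r**2 - (s / 2.0) ** 2))

    sigma_m = max(params.membrane_width_um / 2.0, params.pixel_size_um / 2.0)
    amp = params.membrane_amplitude

    d1 = np.sqrt((xx - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (zz - c1[2]) ** 2)
    d2 = np.sqrt((xx - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (zz - c2[2]) ** 2)
    side1 = xx <= cx  # cell 1's half-space
    side2 = xx >= cx
    in_plane_r = np.sqrt((yy - cy) ** 2 + (zz - cz) ** 2)
    on_disc = in_plane_r <= chord_radius
    disc_term = amp * np.exp(-((xx - cx) ** 2) / (2.0 * sigma_m**2)) * on_disc

    # membrane channels: clipped shells + one interface-disc term per cell
    membrane = (
        _shell(d1, r, sigma_m, amp) * side1
        + _shell(d2, r, sigma_m, amp) * side2
        + 2.0 * disc_term
    )

    # PAR-3: uniform cell-body baseline (unpolarized, largely cytosolic
    # pool over the unclipped sphere union, so the body matches the
    # truth's disc-union cluster mask) + central focus (+ puncta)
    baseline = amp
    body = (d1 <= r) | (d2 <= r)
    par3 = baseline * body.astype(float)
    if params.par3_enrichment != 1.0:
        d_mid2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        focus = (
            (params.par3_enrichment - 1.0)
            * baseline
            * np.exp(-d_mid2 / (2.0 * params.par3_spot_sigma_um**2))
        )
        par3 = par3 + focus

    rng = np.random.default_rng(params.seed)
    if params.puncta_density > 0:
        par3 = par3 + _render_puncta(params, np.stack([c1, c2]), zz, yy, xx, rng)

    reference = np.stack([membrane, membrane.copy(), par3])
    voxels = _apply_noise(reference.copy(), params, rng)
    stack = CalibratedStack(
        voxels,
        pixel_size_um=params.pixel_size_um,
        z_step_um=params.z_step_um,
        channel_names=SCENE_CHANNELS,
    )
    chord = np.array(
        [[cx, cy - chord_radius, cz], [cx, cy + chord_radius, cz]]
    )
    truth = SyntheticSceneTruth(
        cell_centres=np.stack([c1, c2]),
        interface_chord_endpoints=chord,
        interface_midpoint=np.array([cx, cy, cz]),
        long_axis_endpoints=np.array([[c1[0] - r, cy, cz], [c2[0] + r, cy, cz]]),
        centrosome_positions=np.array(
            [[cx - 1.0, cy, cz], [cx + 1.0, cy, cz]]
        ),
        enrichment_factor=params.par3_enrichment,
        cell_radius_um=r,
        pixel_size_um=params.pixel_size_um,
        reference=reference,
    )
    return stack, truth


def generate_cluster_scene(
    params: SceneParams,
) -> tuple[CalibratedStack, SyntheticSceneTruth]:
    """Render a small cluster (n ≥ 3) of cells meeting at a common
    junction, with the polarity focus at the junction.

    Cell centres sit on a circle around the junction at a distance that
    keeps the junction inside every cell; for ``n_cells == 2`` this
    delegates to :func:`generate_doublet_scene`.
    """
    if params.n_cells == 2:
        return generate_doublet_scene(params)
    if params.n_cells < 3:
        raise ValueError("generate_cluster_scene requires n_cells >= 2")
    r = params.cell_radius_um
    d = (
        params.centre_spacing_um / 2.0
        if params.centre_spacing_um is not None
        else 0.7 * r
    )
    if not 0 < d < r:
        raise GeometryError(
            f"junction offset {d} μm must be within the cell radius {r} μm"
        )
    zz, yy, xx = _grids(params)
    junction = _volume_centre(params)
    angles = 2.0 * np.pi * np.arange(params.n_cells) / params.n_cells
    centres = np.stack(
        [
            junction + d * np.array([np.cos(a), np.sin(a), 0.0])
            for a in angles
        ]
    )
    sigma_m = max(params.membrane_width_um / 2.0, params.pixel_size_um / 2.0)
    amp = params.membrane_amplitude
    membrane = np.zeros(np.broadcast_shapes(zz.shape, yy.shape, xx.shape))
    body = np.zeros_like(membrane, dtype=bool)
    for c in centres:
        dist = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
        membrane += _shell(dist, r, sigma_m, amp)
        body |= dist <= r
    baseline = amp
    par3 = baseline * body.astype(float)
    if params.par3_enrichment != 1.0:
        d_j2 = (
            (xx - junction[0]) ** 2 + (yy - junction[1]) ** 2 + (zz - junction[2]) ** 2
        )
        par3 = par3 + (params.par3_enrichment - 1.0) * baseline * np.exp(
            -d_j2 / (2.0 * params.par3_spot_sigma_um**2)
        )
    rng = np.random.default_rng(params.seed)
    if params.puncta_density > 0:
        par3 = par3 + _render_puncta(params, centres, zz, yy, xx, rng)

    reference = np.stack([membrane, membrane.copy(), par3])
    voxels = _apply_noise(reference.copy(), params, rng)
    stack = CalibratedStack(
        voxels,
        pixel_size_um=params.pixel_size_um,
        z_step_um=params.z_step_um,
        channel_names=SCENE_CHANNELS,
    )
    # pairwise interface of the first two cells provides a nominal chord
    a = float(np.sqrt(max(r**2 - (d * np.sin(np.pi / params.n_cells)) ** 2, 0.0)))
    chord = np.array(
        [
            junction + np.array([0.0, -a, 0.0]),
            junction + np.array([0.0, a, 0.0]),
        ]
    )
    truth = SyntheticSceneTruth(
        cell_centres=centres,
        interface_chord_endpoints=chord,
        interface_midpoint=junction.copy(),
        long_axis_endpoints=np.stack(
            [centres[0] + r * _unit(centres[0] - junction), junction]
        ),
        centrosome_positions=np.stack(
            [c + 1.0 * _unit(junction - c) for c in centres]
        ),
        enrichment_factor=params.par3_enrichment,
        cell_radius_um=r,
        pixel_size_um=params.pixel_size_um,
        reference=reference,
    )
    return stack, truth


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise GeometryError("zero-length direction")
    return v / n


# ---------------------------------------------------------------------------
# FRAP simulation


def simulate_frap_trace(params: FRAPSimParams) -> FRAPTrace:
    """Simulate a raw FRAP intensity trace from the one-phase model.

    Pre-bleach frames sit at the baseline; the first post-bleach frame
    drops to baseline × (1 − bleach_depth); subsequent frames follow
    F(t) = F(0) + (F(i) − F(0)) × mobile_fraction × (1 − exp(−k t)) with
    t measured from the first post-bleach frame.  Gaussian noise of
    ``noise_sigma`` is added to every frame.
    """
    dt = params.frame_interval_s
    f_pre = params.baseline
    f0 = params.baseline * (1.0 - params.bleach_depth)
    t_post = np.arange(params.post_frames) * dt
    recovery = f0 + (f_pre - f0) * params.mobile_fraction * -np.expm1(
        -params.rate_k * t_post
    )
    times = np.concatenate(
        [-(np.arange(params.pre_frames)[::-1] + 1) * dt, t_post]
    )
    intensities = np.concatenate([np.full(params.pre_frames, f_pre), recovery])
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        intensities = intensities + rng.normal(0.0, params.noise_sigma, len(intensities))
    return FRAPTrace(times, intensities, n_pre=params.pre_frames)


# ---------------------------------------------------------------------------
# moving-focus time-lapse (kymograph substrate)


@dataclass
class KymographTruth:
    """Per-frame position of the simulated moving focus."""

    positions_um: np.ndarray  # (n_frames, 2) of (x, y)
    arc_positions_um: np.ndarray  # (n_frames,) distance along the path
    path: PolyLinePath = field(repr=False, default=None)


def generate_kymograph_stack(
    path_length_um: float,
    speed_um_per_frame: float,
    n_frames: int,
    params: SceneParams | None = None,
) -> tuple[CalibratedStack, KymographTruth]:
    """Time-lapse of a bright focus translating along a straight path.

    The path is horizontal through the field centre; the focus (a 2D
    Gaussian of ``par3_spot_sigma_um``) starts at the path origin and
    advances ``speed_um_per_frame`` per frame.  The truth records the
    focus position for every frame.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if path_length_um <= 0:
        raise ValueError("path_length_um must be > 0")
    p = params if params is not None else SceneParams()
    ny = int(round(p.fov_um[0] / p.pixel_size_um))
    nx = int(round(p.fov_um[1] / p.pixel_size_um))
    yy = (np.arange(ny) * p.pixel_size_um)[:, None]
    xx = (np.arange(nx) * p.pixel_size_um)[None, :]
    cy = float(yy.max()) / 2.0
    x0 = (float(xx.max()) - path_length_um) / 2.0
    if x0 < 0:
        raise GeometryError("path longer than the field of view")
    sigma = p.par3_spot_sigma_um
    rng = np.random.default_rng(p.seed)
    frames = []
    positions = []
    arcs = []
    for f in range(n_frames):
        arc = speed_um_per_frame * f
        px, py = x0 + arc, cy
        img = p.membrane_amplitude * np.exp(
            -(((xx - px) ** 2) + (yy - py) ** 2) / (2.0 * sigma**2)
        )
        if p.noise_gaussian_sigma > 0:
            img = img + rng.normal(0.0, p.noise_gaussian_sigma, img.shape)
        frames.append(np.clip(img, 0.0, None))
        positions.append((px, py))
        arcs.append(arc)
    stack = CalibratedStack(
        np.stack(frames)[None, ...],
        pixel_size_um=p.pixel_size_um,
        z_step_um=None,
        channel_names=("focus",),
        axes="CTYX",
        frame_interval_s=30.0 * 60.0,  # slow time-lapse; informational only
    )
    path = PolyLinePath(
        np.array([[x0, cy], [x0 + path_length_um, cy]]), width_um=p.membrane_width_um
    )
    truth = KymographTruth(
        positions_um=np.asarray(positions, float),
        arc_positions_um=np.asarray(arcs, float),
        path=path,
    )
    return stack, truth


def vary(params: SceneParams, **changes) -> SceneParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **changes)
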