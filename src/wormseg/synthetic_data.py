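"""Seeded generator of channel-device-like *C. elegans* image data.

The real assay images worms immobilized in 24 wells x 40 parallel tapering
microfluidic channels (960 channels per device), 5 fields of view (FOV) of 8
channels each per well, with 10 brightfield z-slices at 6 um steps plus a
single fluorescence z-stack.  No public image data exists for such devices,
so this module emulates the acquisition: elongated sinuous worm bodies of
varying size and contrast inside vertical channels, full/partial/empty
channel occupancy at a roughly 81/14/5 mix, depth-dependent defocus across
z, intestinal autofluorescence granules, and dose-dependent body-size
shrinkage following a Hill curve.

Every generator is a pure function of (configuration, seed): identical
inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "SceneConfig", "WormSpec", "DosePlan", "ChannelStack", "FOVHyperstack",
    "DeviceDataset", "ChannelRecord", "CLASS_LABELS", "hill",
    "make_worm", "rasterize_worm", "render_channel_stack", "make_fov",
    "render_fluorescence_stack", "make_device_dataset",
    "sample_class_labels", "simulate_dose_response",
    "make_labeled_channels", "classify_mask",
]

CLASS_LABELS = ("full", "partial", "empty")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Geometry and imaging parameters of one simulated device/FOV.

    Defaults mirror the real acquisition (5,056-px-tall channel crops, 8
    channels per FOV at 150 um pitch, 10 z-slices at 6 um steps, 5 time
    points).  ``tiny()`` provides a small preset used throughout the test
    suite; it keeps every geometric relation but shrinks the pixel grid.
    """

    fov_width_px: int = 2960
    fov_height_px: int = 5056
    n_channels_per_fov: int = 8
    channel_pitch_um: float = 150.0
    n_z: int = 10
    z_step_um: float = 6.0
    n_timepoints: int = 5
    # 4.25 um camera pixels behind a 10x objective; one 150 um channel pitch
    # then spans ~353 px, matching the published 340-360 px crop widths
    pixel_size_um: float = 0.425
    class_mix: tuple[float, float, float] = (0.81, 0.14, 0.05)
    contrast_range: tuple[float, float] = (0.35, 0.65)
    noise_sd: float = 0.01          # additive noise, fraction of full scale
    defocus_um_per_um: float = 0.2  # lateral blur per um of defocus (0.4 NA)
    debris_rate: float = 0.3        # expected debris specks per channel
    debris_max_px: int = 60         # area cap so debris stays below any worm
    fovs_per_well: int = 5
    n_wells: int = 24
    rng_seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def channel_width_px(self) -> int:
        return int(round(self.channel_pitch_um / self.pixel_size_um))

    @property
    def channel_shape(self) -> tuple[int, int]:
        return (self.fov_height_px, self.channel_width_px)

    @classmethod
    def tiny(cls, **overrides) -> "SceneConfig":
        """Coarse preset for CPU-scale tests: 288 x 32 px channels at
        5 um/px, tall enough (1.44 mm) to hold a day-1 adult worm."""
        kw = dict(
            fov_width_px=280, fov_height_px=288, channel_pitch_um=160.0,
            n_z=5, n_timepoints=1, pixel_size_um=5.0,
            # keep defocus blur comparable *per pixel* at the coarse grid
            defocus_um_per_um=0.8,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class WormSpec:
    """Geometric description of one simulated worm inside a channel crop.

    ``centerline`` is an (M, 2) polyline of (x, y) points in um, in the
    channel-crop coordinate frame (y axial, increasing toward the channel
    exit).  The arc length of the polyline equals ``body_length_um`` by
    construction.  ``taper`` in (0, 1] controls how much of each body end is
    tapered; ``taper == 0`` gives a constant-width tube.
    """

    body_length_um: float
    max_width_um: float
    centerline: np.ndarray
    granule_density: float = 0.02   # granules per um^2 of gut area
    contrast: float = 0.5
    truncated: bool = False
    taper: float = 0.5

    @property
    def arc_length_um(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1))
        )

    def width_profile(self, s_frac: np.ndarray) -> np.ndarray:
        """Body width (um) at fractional arc position ``s_frac`` in [0, 1]."""
        w = np.full_like(s_frac, self.max_width_um, dtype=float)
        if self.taper > 0:
            t = self.taper / 2.0
            head = s_frac < t
            tail = s_frac > 1.0 - t
            # sine-tapered ends: width -> ~0 at the tips
            w[head] = self.max_width_um * np.sin(
                0.5 * np.pi * s_frac[head] / t
            )
            w[tail] = self.max_width_um * np.sin(
                0.5 * np.pi * (1.0 - s_frac[tail]) / t
            )
        return w


def hill(x, bottom: float, top: float, ec50: float, slope: float):
    """4-parameter Hill curve ``Y = bottom + (top-bottom)/(1+(x/ec50)^slope)``.

    With ``slope > 0`` the curve decreases from ``top`` (response at zero
    dose) to ``bottom`` (response at saturating dose).
    """
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    zero = x == 0
    out[zero] = top if slope > 0 else bottom
    xs = x[~zero]
    out[~zero] = bottom + (top - bottom) / (1.0 + (xs / ec50) ** slope)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class DosePlan:
    """Dose layout and population dose-response structure for one device.

    Default emulates a reference-toxicant design: 11 methylmercury doses
    spanning 0.5-9.0 uM plus a solvent (DMSO) control, two wells per dose
    (24 wells), body size shrinking along a Hill curve and gut-granule
    autofluorescence rising along another.
    """

    doses_um: tuple[float, ...] = field(
        default_factory=lambda: tuple(
            [0.0] + [round(d, 3) for d in np.geomspace(0.5, 9.0, 11)]
        )
    )
    wells_per_dose: int = 2
    hill_top: float = 1100.0     # control body length, um (D1 adult)
    hill_bottom: float = 650.0   # saturating-dose body length, um (young L4)
    hill_ec50: float = 1.5       # uM
    hill_slope: float = 2.5
    af_hill: tuple[float, float, float, float] = (1.0, 2.5, 2.5, 3.0)
    # (baseline level, saturating level, ec50 uM, slope) for autofluorescence
    # two-level size variation: a shared per-well (batch) effect with CV
    # `biological_cv` plus independent worm-to-worm scatter `worm_cv`, so
    # control-well means reproduce at the assay's observed 4-8% CV
    biological_cv: float = 0.04
    worm_cv: float = 0.08

    def __post_init__(self):
        if any(d < 0 for d in self.doses_um):
            raise ValueError("doses must be non-negative")
        if 0.0 not in self.doses_um:
            raise ValueError("a control dose (0) must be present")
        if self.biological_cv <= 0:
            raise ValueError("biological_cv must be > 0")

    def mean_length_um(self, dose_um: float) -> float:
        return float(hill(dose_um, self.hill_bottom, self.hill_top,
                          self.hill_ec50, self.hill_slope))

    def af_level(self, dose_um: float) -> float:
        base, sat, ec50, slope = self.af_hill
        # rising curve: parameterize as a falling Hill on (sat -> base)
        return float(hill(dose_um, sat, base, ec50, slope))

    @property
    def n_wells(self) -> int:
        return len(self.doses_um) * self.wells_per_dose


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------

@dataclass
class ChannelStack:
    """One cropped channel's (T, Z, Y, X) brightfield volume plus provenance."""

    volume: np.ndarray
    well_id: str = "A1"
    fov_index: int = 0
    channel_index: int = 0
    pixel_size_um: float = 0.85
    z_step_um: float = 6.0
    centerline_x_px: int = 0
    fiduciary_offset_px: tuple[int, int] = (0, 0)
    axial_origin_um: float = 0.0   # channel entrance relative to fiduciary
    focus_z_true: int | None = None  # generator ground truth, if synthetic

    @property
    def shape(self):
        return self.volume.shape


@dataclass
class FOVHyperstack:
    """A full field of view: (T, Z, H, W) volume + fiduciary marker position."""

    volume: np.ndarray
    fiduciary_xy_px: tuple[int, int]
    channel_centers_px: tuple[int, ...]
    scene: SceneConfig
    well_id: str = "A1"
    fov_index: int = 0


@dataclass
class ChannelRecord:
    """Ground-truthed synthetic channel: images + sidecar annotations."""

    stack: ChannelStack
    fluorescence: np.ndarray | None   # (Z, Y, X) or None
    mask: np.ndarray                  # (Y, X) bool, empty for empty channels
    class_label: str
    dose_um: float = 0.0
    worm: WormSpec | None = None


@dataclass
class DeviceDataset:
    """All channels of one simulated 24-well device plus the dose layout."""

    records: list[ChannelRecord]
    layout: pd.DataFrame               # well, fov, channel, class, dose_um, seed
    plan: DosePlan
    scene: SceneConfig
    seed: int


# ---------------------------------------------------------------------------
# worm geometry
# ---------------------------------------------------------------------------

def make_worm(
    rng: np.random.Generator,
    length_um: float,
    width_um: float,
    sinuosity: float = 0.15,
    scene: SceneConfig | None = None,
    contrast: float | None = None,
    granule_density: float = 0.02,
    truncated: bool = False,
    taper: float = 0.5,
    n_points: int = 200,
) -> WormSpec:
    """Generate a sinuous worm centerline of exact arc length ``length_um``.

    The centerline is integrated from a smoothly varying heading angle
    (vertical plus a low-frequency sinusoidal deviation of amplitude
    ``sinuosity`` radians), so its arc length equals the requested length by
    construction.  If the lateral excursion would not fit the channel, the
    sinuosity is reduced geometrically until it does.

    Raises ``ValueError`` if the worm is wider than the channel.
    """
    if length_um <= 0 or width_um <= 0 or sinuosity < 0:
        raise ValueError("length, width and sinuosity must be non-negative "
                         "(length/width strictly positive)")
    scene = scene or SceneConfig()
    channel_w_um = scene.channel_width_px * scene.pixel_size_um
    if width_um >= channel_w_um:
        raise ValueError(
            f"worm width {width_um} um does not fit the "
            f"{channel_w_um:.0f} um wide channel"
        )

    ds = length_um / (n_points - 1)
    s = np.linspace(0.0, 1.0, n_points - 1)
    # heading deviation from vertical: 2-3 random low-frequency modes
    n_modes = 3
    freqs = rng.uniform(1.0, 3.0, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    amps = rng.dirichlet(np.ones(n_modes))
    amp = sinuosity
    for _ in range(30):
        theta = amp * np.sum(
            [a * np.sin(2 * np.pi * f * s + p)
             for a, f, p in zip(amps, freqs, phases)],
            axis=0,
        )
        dx = np.sin(theta) * ds
        dy = np.cos(theta) * ds
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        lateral_extent = x.max() - x.min()
        if lateral_extent + width_um <= 0.9 * channel_w_um:
            break
        amp *= 0.7
    else:
        raise ValueError("could not fit worm laterally inside the channel")

    # center laterally; place axially
    x = x - (x.max() + x.min()) / 2.0 + channel_w_um / 2.0
    body_span = y.max() - y.min()
    channel_h_um = scene.fov_height_px * scene.pixel_size_um
    if truncated:
        # translate so the worm crosses the channel entrance (y=0)
        y = y - y.min() - rng.uniform(0.35, 0.6) * body_span
    else:
        lo = 0.05 * channel_h_um
        hi = max(lo + 1e-6, channel_h_um - body_span - lo)
        y = y - y.min() + rng.uniform(lo, min(hi, 0.3 * channel_h_um))
        if y.max() + width_um / 2 > channel_h_um:
            y = y - (y.max() + width_um / 2 - channel_h_um) - 1.0
    centerline = np.column_stack([x, y])
    if contrast is None:
        contrast = float(rng.uniform(*scene.contrast_range))
    return WormSpec(
        body_length_um=float(length_um),
        max_width_um=float(width_um),
        centerline=centerline,
        granule_density=granule_density,
        contrast=contrast,
        truncated=truncated,
        taper=taper,
    )


def _dense_centerline(spec: WormSpec, step_um: float):
    """Resample the centerline at ~step_um spacing; returns points, s_frac."""
    pts = spec.centerline
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    n = max(int(total / step_um) + 1, 2)
    s = np.linspace(0.0, total, n)
    xs = np.interp(s, cum, pts[:, 0])
    ys = np.interp(s, cum, pts[:, 1])
    return np.column_stack([xs, ys]), s / total


def rasterize_worm(spec: WormSpec | None, scene: SceneConfig) -> np.ndarray:
    """Rasterize a worm to a (H, W) boolean mask in the channel crop frame.

    A pixel is foreground when it lies within half the local body width of
    the (densely resampled) centerline.  ``None`` yields an all-zero mask
    (empty channel).
    """
    h, w = scene.channel_shape
    mask = np.zeros((h, w), dtype=bool)
    if spec is None:
        return mask
    px = scene.pixel_size_um
    pts, s_frac = _dense_centerline(spec, step_um=0.5 * px)
    radius = spec.width_profile(s_frac) / 2.0
    tree = cKDTree(pts)
    rmax = radius.max()
    # candidate pixels: bounding box of the tube
    x0 = max(int((pts[:, 0].min() - rmax) / px) - 1, 0)
    x1 = min(int((pts[:, 0].max() + rmax) / px) + 2, w)
    y0 = max(int((pts[:, 1].min() - rmax) / px) - 1, 0)
    y1 = min(int((pts[:, 1].max() + rmax) / px) + 2, h)
    if x1 <= x0 or y1 <= y0:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    q = np.column_stack([(xx.ravel() + 0.5) * px, (yy.ravel() + 0.5) * px])
    dist, idx = tree.query(q)
    inside = dist <= radius[idx]
    mask[yy.ravel()[inside], xx.ravel()[inside]] = True
    return mask


# ---------------------------------------------------------------------------
# brightfield rendering
# ---------------------------------------------------------------------------

_BG = 0.60          # background level, fraction of full scale
_WALL = 0.30        # channel wall level
_FULL_SCALE = 50000.0  # 16-bit, arbitrary units


def _base_image(mask: np.ndarray, spec: WormSpec | None,
                scene: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """In-focus brightfield image in [0, 1] floats."""
    h, w = mask.shape
    img = np.full((h, w), _BG)
    # channel side walls: dark 1-2 px lines at the crop borders
    wall = max(1, w // 24)
    img[:, :wall] = _WALL
    img[:, -wall:] = _WALL
    if spec is not None and mask.any():
        c = spec.contrast
        interior = ndimage.binary_erosion(mask, iterations=1)
        edge = mask & ~interior
        img[interior] = _BG - 0.35 * c
        img[edge] = _BG - 0.8 * c
        # internal texture (gut granules etc.), fixed per worm
        tex = rng.normal(0.0, 0.08 * c, size=(h, w))
        tex = ndimage.gaussian_filter(tex, 1.0)
        img[interior] += tex[interior]
    # debris specks outside the worm, small by construction
    n_debris = rng.poisson(scene.debris_rate)
    for _ in range(n_debris):
        r_px = rng.uniform(1.0, np.sqrt(scene.debris_max_px / np.pi))
        cy = rng.uniform(r_px, h - r_px)
        cx = rng.uniform(r_px, w - r_px)
        yy, xx = np.ogrid[:h, :w]
        speck = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        speck &= ~mask
        img[speck] = _BG - 0.5 * rng.uniform(0.3, 0.9)
    return np.clip(img, 0.0, 1.0)


def render_channel_stack(
    mask: np.ndarray,
    spec: WormSpec | None,
    scene: SceneConfig,
    rng: np.random.Generator,
    z_focus: int | None = None,
    **provenance,
) -> ChannelStack:
    """Render a (T, Z, Y, X) brightfield volume of one channel.

    The slice at ``z_focus`` (default: middle slice, possibly jittered by
    the caller) is sharp; other slices are Gaussian-blurred with sigma
    proportional to their defocus distance, so a Laplacian-energy focus
    finder recovers ``z_focus``.  Additive Gaussian noise with
    ``scene.noise_sd`` is drawn independently per slice; time points are
    identical replicas (worms are immobilized).
    """
    if z_focus is None:
        z_focus = scene.n_z // 2
    if not 0 <= z_focus < scene.n_z:
        raise ValueError("z_focus outside the stack")
    base = _base_image(mask, spec, scene, rng)
    slices = []
    for z in range(scene.n_z):
        dz_um = abs(z - z_focus) * scene.z_step_um
        sigma_px = scene.defocus_um_per_um * dz_um / scene.pixel_size_um
        img = ndimage.gaussian_filter(base, sigma_px) if sigma_px > 0 else base
        if scene.noise_sd > 0:
            img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
        slices.append(np.clip(img, 0.0, 1.0))
    zstack = np.stack(slices)
    vol = np.broadcast_to(
        zstack, (scene.n_timepoints,) + zstack.shape
    ).copy()
    vol16 = (vol * _FULL_SCALE).astype(np.uint16)
    return ChannelStack(
        volume=vol16,
        pixel_size_um=scene.pixel_size_um,
        z_step_um=scene.z_step_um,
        focus_z_true=int(z_focus),
        **provenance,
    )


def sample_class_labels(n: int, mix, rng: np.random.Generator) -> list[str]:
    """Draw channel occupancy labels from the (full, partial, empty) mix."""
    return [CLASS_LABELS[i] for i in rng.choice(3, size=n, p=list(mix))]


def _sample_worm_for_class(label: str, scene: SceneConfig,
                           rng: np.random.Generator,
                           length_um: float | None = None,
                           plan: DosePlan | None = None,
                           dose_um: float = 0.0,
                           well_mean_um: float | None = None) -> WormSpec | None:
    if label == "empty":
        return None
    if length_um is None:
        if well_mean_um is not None:
            mu, cv = well_mean_um, (plan.worm_cv if plan else 0.08)
        elif plan is not None:
            mu, cv = plan.mean_length_um(dose_um), plan.worm_cv
        else:
            mu, cv = 1000.0, 0.08
        length_um = max(float(rng.normal(mu, cv * mu)), 0.2 * mu)
    # allometric width, ~6% of body length
    width_um = 0.06 * length_um * rng.uniform(0.9, 1.1)
    channel_h_um = scene.fov_height_px * scene.pixel_size_um
    length_um = min(length_um, 0.85 * channel_h_um)  # keep full worms inside
    return make_worm(
        rng, length_um, width_um,
        sinuosity=float(rng.uniform(0.05, 0.35)),
        scene=scene,
        truncated=(label == "partial"),
    )


def make_fov(
    worm_specs: list[WormSpec | None],
    scene: SceneConfig,
    rng: np.random.Generator,
    well_id: str = "A1",
    fov_index: int = 0,
) -> tuple[FOVHyperstack, list[tuple[np.ndarray, str]]]:
    """Composite one FOV from exactly ``n_channels_per_fov`` worm specs.

    Returns the FOV hyperstack (with a fiduciary cross marker at a known
    position) and per-channel ground truth ``(mask, class_label)`` pairs.
    Channel class labels are derived from the geometry of each mask: empty
    channels have no foreground, partial worms touch a channel end.
    """
    if len(worm_specs) != scene.n_channels_per_fov:
        raise ValueError(
            f"expected {scene.n_channels_per_fov} worm specs, got {len(worm_specs)}"
        )
    h = scene.fov_height_px
    w_fov = scene.fov_width_px
    cw = scene.channel_width_px
    pitch_px = cw
    margin = (w_fov - scene.n_channels_per_fov * pitch_px) // 2
    if margin < 0:
        raise ValueError("FOV narrower than 8 channel pitches")
    t, z = scene.n_timepoints, scene.n_z
    fov = np.full((t, z, h, w_fov), int(_BG * _FULL_SCALE), dtype=np.uint16)
    centers = []
    truth = []
    z_focus = int(rng.integers(max(0, z // 2 - 1), min(z, z // 2 + 2)))
    for k, spec in enumerate(worm_specs):
        mask = rasterize_worm(spec, scene)
        stack = render_channel_stack(mask, spec, scene, rng, z_focus=z_focus)
        x0 = margin + k * pitch_px
        fov[:, :, :, x0 : x0 + cw] = stack.volume
        centers.append(x0 + cw // 2)
        truth.append((mask, classify_mask(mask)))
    # fiduciary cross marker near the top-left corner of the channel array
    fx, fy = margin // 2 if margin >= 8 else 4, 12
    _draw_cross(fov, fx, fy)
    return (
        FOVHyperstack(
            volume=fov,
            fiduciary_xy_px=(fx, fy),
            channel_centers_px=tuple(centers),
            scene=scene,
            well_id=well_id,
            fov_index=fov_index,
        ),
        truth,
    )


def _draw_cross(fov: np.ndarray, x: int, y: int, arm: int = 4):
    lo = int(0.1 * _FULL_SCALE)
    fov[:, :, max(y - arm, 0) : y + arm + 1, x] = lo
    fov[:, :, y, max(x - arm, 0) : x + arm + 1] = lo


def classify_mask(mask: np.ndarray) -> str:
    """Occupancy class implied by a ground-truth mask's geometry."""
    if not mask.any():
        return "empty"
    if mask[0, :].any() or mask[-1, :].any():
        return "partial"
    return "full"


# ---------------------------------------------------------------------------
# fluorescence rendering
# ---------------------------------------------------------------------------

def render_fluorescence_stack(
    mask: np.ndarray,
    spec: WormSpec | None,
    dose_um: float,
    plan: DosePlan,
    scene: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a (Z, Y, X) uint16 autofluorescence z-stack.

    Bright punctate gut granules are placed only inside the gut region of
    the worm (central 60% of the centerline, inner 50% of the body width);
    their mean intensity follows the plan's autofluorescence Hill curve, so
    in-mask intensity increases monotonically with dose.  Background is low
    and uniform.
    """
    h, w = mask.shape
    bg = 0.02
    stack = np.full((scene.n_z, h, w), bg)
    if spec is not None and mask.any() and spec.granule_density > 0:
        px = scene.pixel_size_um
        pts, s_frac = _dense_centerline(spec, step_um=px)
        gut = (s_frac > 0.2) & (s_frac < 0.8)
        gut_pts = pts[gut]
        gut_half_w = spec.width_profile(s_frac[gut]) * 0.25  # inner 50%
        gut_area_um2 = float(np.sum(2 * gut_half_w) * px)  # ~ strip area
        n_gran = rng.poisson(spec.granule_density * gut_area_um2)
        level = plan.af_level(dose_um)
        if n_gran > 0:
            idx = rng.integers(0, len(gut_pts), n_gran)
            off = rng.uniform(-1, 1, n_gran) * gut_half_w[idx]
            gx = (gut_pts[idx, 0] + off) / px
            gy = gut_pts[idx, 1] / px
            gz = rng.uniform(0, scene.n_z - 1, n_gran)
            amp = level * 0.1 * rng.lognormal(0.0, 0.35, n_gran)
            sigma_px = max(1.0, 1.5 / px)
            yy, xx = np.mgrid[0:h, 0:w]
            for j in range(n_gran):
                if not (0 <= gy[j] < h and 0 <= gx[j] < w):
                    continue
                zc = gz[j]
                r2 = (yy - gy[j]) ** 2 + (xx - gx[j]) ** 2
                blob = amp[j] * np.exp(-r2 / (2 * sigma_px**2))
                for z in range(scene.n_z):
                    zfac = np.exp(-((z - zc) ** 2) / (2 * 1.2**2))
                    stack[z] += blob * zfac
    stack += rng.normal(0.0, 0.003, size=stack.shape)
    return (np.clip(stack, 0.0, 1.0) * _FULL_SCALE).astype(np.uint16)


# ---------------------------------------------------------------------------
# device-scale generation
# ---------------------------------------------------------------------------

def _well_ids(n: int) -> list[str]:
    rows = "ABCD"
    return [f"{rows[i // 6]}{i % 6 + 1}" for i in range(n)]


def make_device_dataset(
    plan: DosePlan,
    scene: SceneConfig,
    rng: np.random.Generator,
    with_fluorescence: bool = True,
    render_images: bool = True,
) -> DeviceDataset:
    """Simulate a full device: wells x FOVs x channels with ground truth.

    With the default scene (24 wells x 5 FOVs x 8 channels) this emits
    exactly 960 channel records.  Per-well worm lengths are drawn as
    ``Normal(mu(dose), cv * mu(dose))`` with ``mu`` the plan's Hill curve.
    ``render_images=False`` skips brightfield/fluorescence rendering and
    produces geometry-plus-mask records only (fast path for statistics).
    """
    seed = int(rng.integers(0, 2**31 - 1))
    sub = np.random.default_rng(seed)
    doses = []
    for d in plan.doses_um:
        doses.extend([d] * plan.wells_per_dose)
    if len(doses) < scene.n_wells:
        doses = (doses * (scene.n_wells // len(doses) + 1))[: scene.n_wells]
    doses = doses[: scene.n_wells]
    wells = _well_ids(scene.n_wells)
    records: list[ChannelRecord] = []
    rows = []
    for well_id, dose in zip(wells, doses):
        well_mean = plan.mean_length_um(dose) * (
            1.0 + plan.biological_cv * sub.standard_normal()
        )
        for fov_i in range(scene.fovs_per_well):
            labels = sample_class_labels(
                scene.n_channels_per_fov, scene.class_mix, sub
            )
            for ch_i, label in enumerate(labels):
                spec = _sample_worm_for_class(
                    label, scene, sub, plan=plan, dose_um=dose,
                    well_mean_um=well_mean,
                )
                mask = rasterize_worm(spec, scene)
                label = classify_mask(mask)
                if render_images:
                    stack = render_channel_stack(
                        mask, spec, scene, sub,
                        well_id=well_id, fov_index=fov_i, channel_index=ch_i,
                    )
                else:
                    stack = ChannelStack(
                        volume=np.zeros((1, 1, 1, 1), dtype=np.uint16),
                        well_id=well_id, fov_index=fov_i, channel_index=ch_i,
                        pixel_size_um=scene.pixel_size_um,
                        z_step_um=scene.z_step_um,
                    )
                fluor = None
                if with_fluorescence:
                    fluor = render_fluorescence_stack(
                        mask, spec, dose, plan, scene, sub
                    )
                records.append(
                    ChannelRecord(
                        stack=stack, fluorescence=fluor, mask=mask,
                        class_label=label, dose_um=dose, worm=spec,
                    )
                )
                rows.append(
                    dict(well=well_id, fov=fov_i, channel=ch_i,
                         **{"class": label}, dose_um=dose, seed=seed)
                )
    layout = pd.DataFrame(rows)
    return DeviceDataset(records=records, layout=layout, plan=plan,
                         scene=scene, seed=seed)


def make_labeled_channels(
    scene: SceneConfig,
    rng: np.random.Generator,
    labels: list[str],
    length_range: tuple[float, float] = (600.0, 900.0),
    contrast_range: tuple[float, float] = (0.40, 0.65),
    with_fluorescence: bool = False,
    doses: list[float] | None = None,
    plan: DosePlan | None = None,
) -> list[ChannelRecord]:
    """Render ground-truthed channel records for explicit class labels.

    A convenience wrapper for building small labeled corpora (training
    fixtures, transfer-learning domains) with controlled worm size and
    contrast; class labels are re-derived from the rasterized geometry.
    """
    plan = plan or DosePlan()
    records = []
    for i, label in enumerate(labels):
        dose = 0.0 if doses is None else doses[i]
        spec = None
        if label != "empty":
            length = rng.uniform(*length_range)
            spec = make_worm(
                rng, length, 0.06 * length, scene=scene,
                contrast=rng.uniform(*contrast_range),
                truncated=(label == "partial"),
            )
        mask = rasterize_worm(spec, scene)
        stack = render_channel_stack(
            mask, spec, scene, rng,
            well_id=f"W{i // 8 + 1}", fov_index=0, channel_index=i % 8,
        )
        fluor = None
        if with_fluorescence:
            fluor = render_fluorescence_stack(mask, spec, dose, plan, scene,
                                              rng)
        records.append(ChannelRecord(
            stack=stack, fluorescence=fluor, mask=mask,
            class_label=classify_mask(mask), dose_um=dose,
        ))
    return records


def simulate_dose_response(
    plan: DosePlan,
    rng: np.random.Generator,
    n_replicates: int = 5,
    n_worms_per_well: int = 25,
) -> pd.DataFrame:
    """Draw per-worm endpoint values for a dose-response study, no imaging.

    Mean lengths follow the plan's Hill curve; each well carries a shared
    batch effect with CV ``plan.biological_cv`` on top of worm-to-worm
    scatter ``plan.worm_cv``.  Area and volume scale allometrically
    (~L^2 and ~L^3, width proportional to length), so they decline more
    steeply with dose than length does.  Autofluorescence per unit length
    follows ``plan.af_hill``.  Returns a tidy frame: dose_um, replicate,
    well, worm, length_um, area_um2, volume_um3, af_per_length.
    """
    rows = []
    for rep in range(n_replicates):
        for di, dose in enumerate(plan.doses_um):
            mu = plan.mean_length_um(dose) * \
                (1.0 + plan.biological_cv * rng.standard_normal())
            af_mu = plan.af_level(dose) * \
                (1.0 + plan.biological_cv * rng.standard_normal())
            for wi in range(n_worms_per_well):
                L = rng.normal(mu, plan.worm_cv * mu)
                width = 0.06 * L * rng.normal(1.0, 0.02)
                rows.append(
                    dict(
                        dose_um=dose, replicate=rep, well=f"r{rep}d{di}",
                        worm=wi, length_um=L,
                        area_um2=0.85 * L * width,
                        volume_um3=0.7 * L * width**2,
                        af_per_length=af_mu * rng.normal(1.0, 0.05),
                    )
                )
    return pd.DataFrame(rows)
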