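"""Synthetic fluorescence-microscopy generator with exact ground truth.

No raw recordings accompany the original study, so every analysis stage in
this package is validated by parameter recovery on simulated data that
emulates the study's acquisition designs:

* two-channel snapshots (green cargo / red Golgi marker) at 0, 3, 7, 15 and
  30 min after solubilizer addition, with a planted fraction of cargo
  relocated from the ER into a Golgi blob;
* 600-frame single-channel vesicle movies at 200 ms intervals with planted
  tracks, exponential photobleaching and shot noise;
* cargo puncta that disaggregate (elongated aggregates relaxing into round
  spots) for the form-factor readout;
* filament images (bright curvilinear microtubules over a dim cytosol);
* ratiometric biosensor traces with a basal plateau and a planted decline.

All geometry is synthetic convention — the study never quantifies cell or
Golgi shapes — but every intensity is conserved and every planted quantity
is recorded in a :class:`GroundTruth` so recovery is checkable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import line

from .errors import ParameterError
from .stack import ImageStack
from .traces import RatioTrace

# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class SceneParams:
    """Static scene geometry and noise settings shared by the generators."""

    image_shape: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.1
    cell_count: int = 1
    golgi_radius_px: float = 20.0
    puncta_count: int = 30
    background_level: float = 5.0
    noise_model: str = "none"  # none | poisson | poisson+gaussian
    gaussian_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cell_count < 1:
            raise ParameterError("cell_count must be >= 1")
        if self.puncta_count < 0:
            raise ParameterError("puncta_count must be >= 0")
        if self.background_level < 0:
            raise ParameterError("background_level must be >= 0")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if self.noise_model not in ("none", "poisson", "poisson+gaussian"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")


@dataclass
class TransportKinetics:
    """Planted ER-to-Golgi transport kinetics.

    ``golgi_fraction[t]`` is the fraction of total cargo residing in the
    Golgi footprint at each acquisition timepoint; the remainder sits in ER
    puncta and a diffuse ER pool. ``puncta_fraction`` and ``puncta_aspect``
    shape the ER pool over time so that aggregate disaggregation (puncta
    dissolving and rounding up) is a planted, recoverable signal.
    """

    timepoints_min: tuple[float, ...] = (0.0, 3.0, 7.0, 15.0, 30.0)
    golgi_fraction: tuple[float, ...] = (0.02, 0.02, 0.02, 0.02, 0.02)
    cargo_total_intensity: float = 2.0e5
    puncta_fraction: tuple[float, ...] | None = None
    puncta_aspect: tuple[float, ...] | None = None

    def __post_init__(self):
        tp = np.asarray(self.timepoints_min, dtype=float)
        if tp[0] != 0:
            raise ParameterError("timepoints must start at 0 (initiation)")
        if np.any(np.diff(tp) <= 0):
            raise ParameterError("timepoints must be strictly increasing")
        gf = np.asarray(self.golgi_fraction, dtype=float)
        if gf.shape != tp.shape:
            raise ParameterError("golgi_fraction must match timepoints")
        if np.any(gf < 0) or np.any(gf > 1):
            raise ParameterError("golgi_fraction must lie in [0, 1]")
        if self.puncta_fraction is None:
            # aggregates dissolve after solubilizer addition
            self.puncta_fraction = tuple(
                float(v) for v in np.interp(tp, [0, tp[-1]], [0.6, 0.05])
            )
        if self.puncta_aspect is None:
            # aggregates start elongated/irregular and round up
            self.puncta_aspect = tuple(
                float(v) for v in np.interp(tp, [0, tp[-1]], [3.0, 1.0])
            )
        if len(self.puncta_fraction) != tp.size or len(self.puncta_aspect) != tp.size:
            raise ParameterError("puncta_fraction/aspect must match timepoints")

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints_min)


@dataclass
class VesicleMovieParams:
    """Settings for a single-channel vesicle movie."""

    image_shape: tuple[int, int] = (128, 128)
    n_frames: int = 600
    frame_interval_s: float = 0.2
    n_vesicles: int = 20
    speed_px_per_frame: float | tuple[float, ...] = 1.0
    motion: str = "directed"  # directed | brownian | stationary
    vesicle_area_px: int = 12
    vesicle_amplitude: float = 200.0
    background_level: float = 5.0
    bleach_rate_per_frame: float = 0.0
    noise_model: str = "none"
    gaussian_sigma: float = 0.0
    pixel_size_um: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.vesicle_area_px <= 0:
            raise ParameterError("vesicle_area_px must be > 0")
        if self.motion not in ("directed", "brownian", "stationary"):
            raise ParameterError(f"unknown motion model {self.motion!r}")
        if self.bleach_rate_per_frame < 0:
            raise ParameterError("bleach_rate_per_frame must be >= 0")
        speeds = np.broadcast_to(
            np.asarray(self.speed_px_per_frame, dtype=float), (self.n_vesicles,)
        )
        if not np.all(np.isfinite(speeds)) or np.any(speeds < 0):
            raise ParameterError("speeds must be finite and >= 0")

    @classmethod
    def from_duration(
        cls, duration_s: float, frame_interval_s: float = 0.2, **kwargs
    ) -> "VesicleMovieParams":
        """Frame count from acquisition duration: round(duration/interval).

        The study's protocol (one frame every 200 ms for 2 min) gives 600.
        """
        n = int(round(duration_s / frame_interval_s))
        return cls(n_frames=n, frame_interval_s=frame_interval_s, **kwargs)

    @property
    def speeds(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.speed_px_per_frame, dtype=float), (self.n_vesicles,)
        ).copy()


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    seed: int | None = None
    golgi_mask_true: np.ndarray | None = None  # label image, one label/cell
    cell_masks_true: np.ndarray | None = None  # label image
    golgi_fraction_true: tuple[float, ...] | None = None
    puncta_fraction_true: tuple[float, ...] | None = None
    puncta_aspect_true: tuple[float, ...] | None = None
    tracks_true: np.ndarray | None = None  # (n_vesicles, n_frames, 2) as (x, y)
    speed_true: np.ndarray | None = None  # px/frame per vesicle
    bleach_rate_true: float | None = None
    filament_mask_true: np.ndarray | None = None
    filament_contrast_true: float | None = None
    basal_true: float | None = None
    end_true: float | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Closed-form transport-index predictor

def transport_index_closed_form(
    golgi_fraction: np.ndarray | float, golgi_fraction_t0: float
) -> np.ndarray | float:
    """Predicted transport index for a planted Golgi cargo fraction.

    With fraction f of total cargo in the Golgi and 1-f outside, the
    Golgi/non-Golgi intensity ratio is f/(1-f); normalizing to the
    initiation timepoint gives TI = f(1-f0) / (f0(1-f)). Exact whenever the
    Golgi mask captures the planted footprint and no ER cargo leaks in.
    """
    f = np.asarray(golgi_fraction, dtype=float)
    f0 = float(golgi_fraction_t0)
    return (f * (1 - f0)) / (f0 * (1 - f))


def golgi_fraction_for_ti(ti: np.ndarray | float, golgi_fraction_t0: float) -> np.ndarray | float:
    """Inverse of :func:`transport_index_closed_form`: fraction giving a TI."""
    ti = np.asarray(ti, dtype=float)
    f0 = float(golgi_fraction_t0)
    x = ti * f0 / (1 - f0)
    return x / (1 + x)


# ---------------------------------------------------------------------------
# Scene geometry helpers

def _cell_layout(scene: SceneParams) -> list[dict]:
    """Place cells on a grid; each gets a disc footprint and a Golgi disc."""
    ny, nx = scene.image_shape
    n = scene.cell_count
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    tile_y, tile_x = ny / rows, nx / cols
    r_cell = 0.42 * min(tile_y, tile_x)
    if scene.golgi_radius_px + 4 >= r_cell:
        raise ParameterError(
            f"golgi_radius_px={scene.golgi_radius_px} does not fit inside the "
            f"cell footprint (radius {r_cell:.1f} px)"
        )
    rng = np.random.default_rng(scene.seed)
    cells = []
    for i in range(n):
        r, c = divmod(i, cols)
        cy = (r + 0.5) * tile_y
        cx = (c + 0.5) * tile_x
        # Golgi sits off-center, direction randomized per cell
        theta = rng.uniform(0, 2 * np.pi)
        d = 0.45 * (r_cell - scene.golgi_radius_px - 4)
        gy, gx = cy + d * np.sin(theta), cx + d * np.cos(theta)
        cells.append(
            dict(label=i + 1, cy=cy, cx=cx, r_cell=r_cell, gy=gy, gx=gx)
        )
    return cells, rng


def _disc(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _apply_noise(
    image: np.ndarray, noise_model: str, gaussian_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    if noise_model == "none":
        return image
    noisy = rng.poisson(np.clip(image, 0, None)).astype(float)
    if noise_model == "poisson+gaussian":
        noisy = noisy + rng.normal(0.0, gaussian_sigma, size=image.shape)
    return np.clip(noisy, 0, None)


def _normalized(weights: np.ndarray, total: float) -> np.ndarray:
    s = weights.sum()
    if s <= 0:
        return np.zeros_like(weights)
    return weights * (total / s)


# ---------------------------------------------------------------------------
# Transport series

#: Marker staining extends this many pixels beyond the cargo's Golgi
#: footprint, so the Otsu + double-erosion mask still covers the footprint.
MARKER_HALO_PX = 2
#: ER cargo is kept this far outside the Golgi footprint.
ER_CLEARANCE_PX = 4
MARKER_LEVEL = 1000.0


def generate_transport_series(
    scene: SceneParams, kinetics: TransportKinetics
) -> tuple[ImageStack, GroundTruth]:
    """Render a two-channel (cargo, golgi_marker) snapshot series.

    At timepoint t, golgi_fraction[t] of each cell's total cargo intensity
    is placed inside its Golgi footprint (a disc); the remainder is split
    between ER puncta (aggregates) and a diffuse ER pool strictly outside
    the footprint. Before noise, the summed cargo intensity per frame per
    cell equals ``cargo_total_intensity`` to machine precision.
    """
    cells, rng = _cell_layout(scene)
    ny, nx = scene.image_shape
    n_t = kinetics.n_timepoints

    cell_labels = np.zeros((ny, nx), dtype=np.uint16)
    golgi_labels = np.zeros((ny, nx), dtype=np.uint16)
    marker = np.zeros((ny, nx), dtype=float)

    per_cell = []
    for cell in cells:
        cmask = _disc((ny, nx), cell["cy"], cell["cx"], cell["r_cell"])
        gmask = _disc((ny, nx), cell["gy"], cell["gx"], scene.golgi_radius_px)
        cell_labels[cmask] = cell["label"]
        golgi_labels[gmask] = cell["label"]
        marker_support = _disc(
            (ny, nx), cell["gy"], cell["gx"], scene.golgi_radius_px + MARKER_HALO_PX
        )
        marker[marker_support] = MARKER_LEVEL

        # Golgi cargo: Gaussian-weighted over the footprint (brightest core)
        yy, xx = np.nonzero(gmask)
        sigma_g = max(scene.golgi_radius_px / 3.0, 1.0)
        golgi_w = np.exp(
            -((yy - cell["gy"]) ** 2 + (xx - cell["gx"]) ** 2) / (2 * sigma_g**2)
        )
        # ER region: inside the cell, clear of the marker halo
        er_region = cmask & ~_disc(
            (ny, nx),
            cell["gy"],
            cell["gx"],
            scene.golgi_radius_px + MARKER_HALO_PX + ER_CLEARANCE_PX,
        )
        er_idx = np.nonzero(er_region)
        # fixed puncta positions (per cell, per seed), re-rendered per timepoint
        if er_idx[0].size and scene.puncta_count:
            pick = rng.choice(er_idx[0].size, size=scene.puncta_count, replace=True)
            pyx = np.stack([er_idx[0][pick], er_idx[1][pick]], axis=1).astype(float)
            angles = rng.uniform(0, np.pi, size=scene.puncta_count)
        else:
            pyx = np.zeros((0, 2))
            angles = np.zeros(0)
        per_cell.append(
            dict(
                cell=cell,
                gmask=gmask,
                golgi_idx=(yy, xx),
                golgi_w=golgi_w,
                er_region=er_region,
                puncta_yx=pyx,
                puncta_angles=angles,
            )
        )

    frames = np.zeros((n_t, 2, ny, nx), dtype=float)
    noise_rng = np.random.default_rng(np.random.default_rng(scene.seed).integers(2**31))
    for ti_idx in range(n_t):
        f = kinetics.golgi_fraction[ti_idx]
        p_frac = kinetics.puncta_fraction[ti_idx]
        aspect = kinetics.puncta_aspect[ti_idx]
        cargo = np.zeros((ny, nx), dtype=float)
        for info in per_cell:
            total = kinetics.cargo_total_intensity
            # Golgi pool
            g_img = np.zeros((ny, nx))
            g_img[info["golgi_idx"]] = _normalized(info["golgi_w"], f * total)
            # ER pool: puncta + diffuse, both strictly outside the halo
            er_total = (1 - f) * total
            p_img = _render_puncta(
                (ny, nx),
                info["puncta_yx"],
                info["puncta_angles"],
                aspect,
                info["er_region"],
            )
            p_img = _normalized(p_img, p_frac * er_total)
            d_img = np.zeros((ny, nx))
            d_img[info["er_region"]] = 1.0
            d_img = _normalized(d_img, (1 - p_frac) * er_total)
            cargo += g_img + p_img + d_img
        cargo_frame = cargo + scene.background_level
        marker_frame = marker + scene.background_level
        frames[ti_idx, 0] = _apply_noise(
            cargo_frame, scene.noise_model, scene.gaussian_sigma, noise_rng
        )
        frames[ti_idx, 1] = _apply_noise(
            marker_frame, scene.noise_model, scene.gaussian_sigma, noise_rng
        )

    stack = ImageStack(
        data=frames,
        pixel_size_um=scene.pixel_size_um,
        timepoints_min=kinetics.timepoints_min,
        channel_names=("cargo", "golgi_marker"),
    )
    truth = GroundTruth(
        seed=scene.seed,
        golgi_mask_true=golgi_labels,
        cell_masks_true=cell_labels,
        golgi_fraction_true=tuple(kinetics.golgi_fraction),
        puncta_fraction_true=tuple(kinetics.puncta_fraction),
        puncta_aspect_true=tuple(kinetics.puncta_aspect),
        extras={"cargo_total_intensity": kinetics.cargo_total_intensity},
    )
    return stack, truth


def _render_puncta(
    shape: tuple[int, int],
    centers_yx: np.ndarray,
    angles: np.ndarray,
    aspect: float,
    allowed: np.ndarray,
) -> np.ndarray:
    """Render anisotropic Gaussian puncta (aspect = major/minor axis ratio),
    clipped to the allowed (ER) region so no aggregate bleeds into the Golgi."""
    img = np.zeros(shape)
    if centers_yx.shape[0] == 0:
        return img
    sigma_minor = 1.3
    sigma_major = sigma_minor * max(aspect, 1.0)
    half = int(np.ceil(3 * sigma_major))
    for (cy, cx), ang in zip(centers_yx, angles):
        y0, y1 = int(cy) - half, int(cy) + half + 1
        x0, x1 = int(cx) - half, int(cx) + half + 1
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        dy, dx = yy - cy, xx - cx
        u = dy * np.sin(ang) + dx * np.cos(ang)  # along major axis
        v = dy * np.cos(ang) - dx * np.sin(ang)
        img[y0c:y1c, x0c:x1c] += np.exp(
            -(u**2 / (2 * sigma_major**2) + v**2 / (2 * sigma_minor**2))
        )
    img[~allowed] = 0.0
    return img


# ---------------------------------------------------------------------------
# Kinetics presets for the four transport-efficiency classes

#: Target transport-index values at the decision timepoint used when
#: planting each efficiency class. Chosen near the centres of the class
#: bands so noisy recovery is a fair test of the pipeline, not of
#: borderline tie-breaking.
CLASS_TARGET_TI = {
    "soluble": {"very_high": 16.0, "high": 7.0, "moderate": 3.2, "none": 1.1},
    "transmembrane": {"very_high": 16.0, "high": 8.5, "moderate": 5.5, "none": 1.1},
}
DECISION_TIME_MIN = {"soluble": 30.0, "transmembrane": 15.0}


def kinetics_preset(
    transport_class: str,
    cargo_type: str = "soluble",
    f0: float = 0.02,
    timepoints_min: tuple[float, ...] = (0.0, 3.0, 7.0, 15.0, 30.0),
    cargo_total_intensity: float = 2.0e5,
) -> TransportKinetics:
    """Kinetics whose closed-form TI hits the class target at the decision
    time, rising smoothly (saturating-exponential time course) from 1."""
    try:
        ti_target = CLASS_TARGET_TI[cargo_type][transport_class]
    except KeyError:
        raise ParameterError(
            f"unknown cargo type {cargo_type!r} or class {transport_class!r}"
        ) from None
    t_dec = DECISION_TIME_MIN[cargo_type]
    tp = np.asarray(timepoints_min, dtype=float)
    tau = t_dec / 2.5
    shape = (1 - np.exp(-tp / tau)) / (1 - np.exp(-t_dec / tau))
    ti_curve = 1 + (ti_target - 1) * shape
    fractions = golgi_fraction_for_ti(ti_curve, f0)
    fractions[0] = f0
    return TransportKinetics(
        timepoints_min=tuple(tp),
        golgi_fraction=tuple(float(v) for v in fractions),
        cargo_total_intensity=cargo_total_intensity,
    )


# ---------------------------------------------------------------------------
# Vesicle movies

def generate_vesicle_movie(
    params: VesicleMovieParams,
) -> tuple[ImageStack, GroundTruth]:
    """Render a single-channel vesicle movie with planted sub-pixel tracks.

    Vesicles are Gaussian spots truncated to ``vesicle_area_px`` pixels.
    Motion models: directed (constant heading, constant speed), brownian
    (isotropic Gaussian steps whose mean length equals the stated speed),
    or stationary. Boundaries reflect, so tracks never leave the frame.
    A frame-wide factor exp(-bleach_rate*frame) is applied before noise.
    """
    rng = np.random.default_rng(params.seed)
    ny, nx = params.image_shape
    n, n_frames = params.n_vesicles, params.n_frames
    speeds = params.speeds

    spot_radius = float(np.sqrt(params.vesicle_area_px / np.pi))
    margin = spot_radius + 2.0
    lo_y, hi_y = margin, ny - 1 - margin
    lo_x, hi_x = margin, nx - 1 - margin

    pos = np.empty((n, 2))  # (x, y)
    pos[:, 0] = rng.uniform(lo_x, hi_x, size=n)
    pos[:, 1] = rng.uniform(lo_y, hi_y, size=n)
    if params.motion == "directed":
        theta = rng.uniform(0, 2 * np.pi, size=n)
        vel = np.stack([np.cos(theta), np.sin(theta)], axis=1) * speeds[:, None]

    tracks = np.empty((n, n_frames, 2))
    # brownian per-axis sigma so that E[step length] = speed
    sigma_b = speeds / np.sqrt(np.pi / 2)

    for t in range(n_frames):
        tracks[:, t] = pos
        if params.motion == "stationary" or t == n_frames - 1:
            step = None
        elif params.motion == "directed":
            step = vel
        else:  # brownian
            step = rng.normal(0.0, 1.0, size=(n, 2)) * sigma_b[:, None]
        if step is not None:
            pos = pos + step
            # reflecting boundaries, one bounce is enough at sane speeds
            for axis, (lo, hi) in enumerate([(lo_x, hi_x), (lo_y, hi_y)]):
                over = pos[:, axis] > hi
                pos[over, axis] = 2 * hi - pos[over, axis]
                under = pos[:, axis] < lo
                pos[under, axis] = 2 * lo - pos[under, axis]
                if params.motion == "directed":
                    vel[over | under, axis] *= -1.0

    frames = np.empty((n_frames, 1, ny, nx), dtype=float)
    sigma_spot = spot_radius / 1.5
    for t in range(n_frames):
        img = np.zeros((ny, nx))
        for i in range(n):
            _add_spot(
                img,
                tracks[i, t, 1],
                tracks[i, t, 0],
                spot_radius,
                sigma_spot,
                params.vesicle_amplitude,
            )
        img = (img + params.background_level) * np.exp(
            -params.bleach_rate_per_frame * t
        )
        frames[t, 0] = _apply_noise(
            img, params.noise_model, params.gaussian_sigma, rng
        )

    stack = ImageStack(
        data=frames,
        pixel_size_um=params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        channel_names=("vesicles",),
    )
    truth = GroundTruth(
        seed=params.seed,
        tracks_true=tracks,
        speed_true=(
            np.zeros(n) if params.motion == "stationary" else speeds
        ),
        bleach_rate_true=params.bleach_rate_per_frame,
        extras={"motion": params.motion},
    )
    return stack, truth


def _add_spot(
    img: np.ndarray, cy: float, cx: float, radius: float, sigma: float, amplitude: float
) -> None:
    """Add a Gaussian spot truncated to the disc of the given radius around
    its sub-pixel center."""
    half = int(np.ceil(radius)) + 1
    y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 2, img.shape[0])
    x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 2, img.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    spot = amplitude * np.exp(-d2 / (2 * sigma**2))
    spot[d2 > radius**2] = 0.0
    img[y0:y1, x0:x1] += spot


# ---------------------------------------------------------------------------
# Filament images

def generate_filament_image(
    scene: SceneParams,
    n_filaments: int = 12,
    filament_contrast: float = 3.0,
    cytosol_level: float = 100.0,
    thickness_px: int = 3,
) -> tuple[ImageStack, GroundTruth]:
    """Render bright curvilinear filaments over a dimmer cytosolic field.

    Filaments are smooth random walks (small heading changes per step)
    spanning the cell, drawn at ``filament_contrast`` times the cytosol
    intensity. Ground truth is the rasterized filament mask.
    """
    if n_filaments < 0:
        raise ParameterError("n_filaments must be >= 0")
    cells, rng = _cell_layout(scene)
    ny, nx = scene.image_shape
    cell_labels = np.zeros((ny, nx), dtype=np.uint16)
    fil_mask = np.zeros((ny, nx), dtype=bool)
    for cell in cells:
        cmask = _disc((ny, nx), cell["cy"], cell["cx"], cell["r_cell"])
        cell_labels[cmask] = cell["label"]
        for _ in range(n_filaments):
            fil_mask |= _draw_filament(cell, (ny, nx), rng)
    if thickness_px > 1:
        n_dil = (thickness_px - 1) // 2
        fil_mask = ndi.binary_dilation(
            fil_mask, structure=ndi.generate_binary_structure(2, 2), iterations=max(n_dil, 1)
        )
    fil_mask &= cell_labels > 0

    img = np.full((ny, nx), float(scene.background_level))
    img[cell_labels > 0] = cytosol_level
    img[fil_mask] = cytosol_level * filament_contrast
    img = _apply_noise(
        img, scene.noise_model, scene.gaussian_sigma,
        np.random.default_rng(np.random.default_rng(scene.seed).integers(2**31)),
    )
    stack = ImageStack(
        data=img[None, None],
        pixel_size_um=scene.pixel_size_um,
        channel_names=("tubulin",),
    )
    truth = GroundTruth(
        seed=scene.seed,
        cell_masks_true=cell_labels,
        filament_mask_true=fil_mask,
        filament_contrast_true=filament_contrast,
    )
    return stack, truth


def _draw_filament(cell: dict, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    r = cell["r_cell"]
    # start near the centre, walk outwards with gently drifting heading
    ang0 = rng.uniform(0, 2 * np.pi)
    y = cell["cy"] + rng.uniform(-0.2, 0.2) * r
    x = cell["cx"] + rng.uniform(-0.2, 0.2) * r
    heading = rng.uniform(0, 2 * np.pi)
    step = 4.0
    n_steps = int(1.8 * r / step)
    py, px = int(round(y)), int(round(x))
    for _ in range(n_steps):
        heading += rng.normal(0, 0.25)
        y2, x2 = y + step * np.sin(heading), x + step * np.cos(heading)
        if (y2 - cell["cy"]) ** 2 + (x2 - cell["cx"]) ** 2 > (0.95 * r) ** 2:
            break
        qy, qx = int(round(y2)), int(round(x2))
        rr, cc = line(py, px, qy, qx)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
        y, x, py, px = y2, x2, qy, qx
    return mask


# ---------------------------------------------------------------------------
# Biosensor ratio traces

def generate_ratio_trace(
    basal_level: float = 1.0,
    end_level: float = 0.6,
    n_points: int = 780,
    noise_sd: float = 0.0,
    seed: int = 0,
    total_time_s: float = 3900.0,
    basal_end_s: float = 300.0,
) -> tuple[RatioTrace, GroundTruth]:
    """A ratiometric biosensor trace: basal plateau, then a smooth
    (saturating-exponential) drift to ``end_level`` at the final sample.

    Defaults emulate a 5 min baseline followed by 60 min of recording at
    5 s sampling, the design behind the "maximal ratio change between basal
    values and 60 min" readout.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    t = np.linspace(0.0, total_time_s, n_points)
    ratio = np.full(n_points, float(basal_level))
    after = t > basal_end_s
    tau = (total_time_s - basal_end_s) / 3.0
    drift = 1 - np.exp(-(t[after] - basal_end_s) / tau)
    drift = drift / drift[-1] if drift[-1] > 0 else drift
    ratio[after] = basal_level + (end_level - basal_level) * drift
    if noise_sd > 0:
        ratio = ratio + np.random.default_rng(seed).normal(0, noise_sd, n_points)
    trace = RatioTrace(
        time_s=t, ratio=np.clip(ratio, 1e-9, None), basal_window_s=(0.0, basal_end_s)
    )
    truth = GroundTruth(seed=seed, basal_true=basal_level, end_true=end_level)
    return trace, truth
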