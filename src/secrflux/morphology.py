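"""Shape-based readouts: cargo form factor (circularity) and the
microtubule/cytosol mean-intensity ratio.

The form factor of a segmented structure is the ImageJ-style circularity
4*pi*area/perimeter^2 — 1 for a perfect disc, approaching 0 for elongated
shapes. Its per-cell median, computed per timepoint on the cargo channel
with the Golgi region excluded, rises as ER-localized aggregates
disaggregate into the fine ER network.

Perimeters use the Crofton estimator (4 directions), which is close to the
true boundary length for smooth shapes; values are clamped to 1 since
discretization can push compact discs slightly above the continuum bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import measure, morphology as skmorph

from . import ops
from .errors import DegenerateMaskError, InputError
from .stack import CellROI
from .transport import compute_golgi_mask


@dataclass
class FormFactorRecord:
    """Median form factor of non-Golgi fluorescent structures in one cell
    at one timepoint. ``empty`` flags the no-structures case."""

    cell_label: int
    time_min: float
    n_structures: int
    median_form_factor: float  # NaN when empty
    empty: bool = False


@dataclass
class FilamentRatio:
    position_label: int
    mt_mean_intensity: float
    cytosol_mean_intensity: float
    ratio: float


def form_factor(area: float, perimeter: float) -> float:
    """Circularity 4*pi*A/P^2, clamped to (0, 1]."""
    if perimeter <= 0:
        return float("nan")
    return float(min(4.0 * np.pi * area / perimeter**2, 1.0))


def structure_form_factors(mask: np.ndarray, min_area_px: int = 4) -> np.ndarray:
    """Form factor of every connected component with at least
    ``min_area_px`` pixels, using the Crofton perimeter."""
    labels = measure.label(mask)
    values = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        values.append(form_factor(region.area, region.perimeter_crofton))
    return np.array(values)


def compute_form_factors(
    cargo_image: np.ndarray,
    marker_image: np.ndarray,
    roi: CellROI,
    time_min: float = 0.0,
    window_px: int = 51,
    background_radius_px: float = 50,
    min_structure_px: int = 4,
) -> FormFactorRecord:
    """Median form factor of cargo structures outside the Golgi.

    Background-subtract the cargo frame, remove the Golgi region (mask
    segmented from the marker frame, as in the transport index), find
    aggregates with a local Otsu threshold inside the ROI, and take the
    median circularity over all structures. An empty structure set yields
    a flagged empty record, not an exception.
    """
    img = ops.rolling_ball_background_subtract(
        np.asarray(cargo_image, dtype=float), background_radius_px
    )
    golgi = compute_golgi_mask(marker_image, roi, background_radius_px)
    allowed = roi.mask & ~golgi
    work = img.copy()
    work[~allowed] = 0.0  # Golgi intensity can no longer influence anything
    window = min(window_px, _largest_odd(min(img.shape)))
    local_mask = ops.local_otsu_threshold(work, window) & allowed
    values = structure_form_factors(local_mask, min_structure_px)
    if values.size == 0:
        return FormFactorRecord(
            cell_label=roi.label,
            time_min=time_min,
            n_structures=0,
            median_form_factor=float("nan"),
            empty=True,
        )
    return FormFactorRecord(
        cell_label=roi.label,
        time_min=time_min,
        n_structures=int(values.size),
        median_form_factor=float(np.median(values)),
    )


def _largest_odd(n: int) -> int:
    return n if n % 2 == 1 else n - 1


def compute_microtubule_ratio(
    image: np.ndarray,
    roi: CellROI,
    background_radius_px: float = 50,
    median_size_px: int = 3,
    bandpass_small_px: float = 2.0,
    bandpass_large_px: float = 20.0,
    min_particle_px: int = 20,
) -> tuple[FilamentRatio, np.ndarray]:
    """Mean-intensity ratio of microtubule vs cytosolic regions.

    Mask construction: background subtraction, median filter, bandpass
    (suppressing both pixel noise and cell-scale structure), Otsu within
    the ROI, binary opening (3x3 disc) and a particle-size filter. The
    ratio itself is measured on the background-subtracted image; the
    cytosol region is the ROI minus the filament mask. Returns the ratio
    record and the filament mask.
    """
    img = np.asarray(image, dtype=float)
    if img[roi.mask].min() == img[roi.mask].max():
        raise InputError("image is constant within the ROI")
    subtracted = ops.rolling_ball_background_subtract(img, background_radius_px)
    work = ndi.median_filter(subtracted, size=median_size_px)
    work = ops.bandpass_filter(work, bandpass_small_px, bandpass_large_px)
    thr, _ = ops.otsu_threshold(work[roi.mask])
    mask = (work > thr) & roi.mask
    mask = skmorph.opening(mask, skmorph.disk(1))
    mask = skmorph.remove_small_objects(mask, max_size=min_particle_px - 1)
    if not mask.any():
        raise DegenerateMaskError("filament mask is empty")
    cytosol = roi.mask & ~mask
    if not cytosol.any():
        raise DegenerateMaskError("cytosol region is empty")
    mt_mean = float(subtracted[mask].mean())
    cy_mean = float(subtracted[cytosol].mean())
    record = FilamentRatio(
        position_label=roi.label,
        mt_mean_intensity=mt_mean,
        cytosol_mean_intensity=cy_mean,
        ratio=mt_mean / cy_mean if cy_mean > 0 else float("inf"),
    )
    return record, mask
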