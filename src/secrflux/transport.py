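"""Per-cell ER-to-Golgi transport index and transport-efficiency classes.

The transport index (TI) quantifies synchronized cargo release from the ER
into the Golgi in two-channel time-lapse data: at each timepoint a Golgi
mask is segmented from the red marker channel (rolling-ball background
subtraction, Otsu threshold within the cell ROI, two binary erosions), the
integrated cargo intensity is measured inside and outside the mask (both
restricted to the ROI), and the Golgi/non-Golgi ratio is normalized to the
first timepoint — transport initiation — so every trajectory starts at 1.

Cells are then classified into four transport-efficiency groups by their
TI at a cargo-specific decision time: 30 min for soluble (bulk-flow) cargo
with class bounds 10/5/2, 15 min for transmembrane (COPII-sorted) cargo
with bounds 10/7/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ops
from .errors import DegenerateMaskError, InputError, ParameterError
from .stack import CellROI, ImageStack

#: Class boundaries at the decision time, as half-open intervals
#: [lower, upper): a cell exactly on a boundary goes to the higher class.
CLASS_THRESHOLDS = {
    "soluble": (10.0, 5.0, 2.0),
    "transmembrane": (10.0, 7.0, 4.0),
}
DECISION_TIME_MIN = {"soluble": 30.0, "transmembrane": 15.0}
CLASS_ORDER = ("very_high", "high", "moderate", "none")


@dataclass
class TITrajectory:
    """Per-cell transport-index time series.

    raw_ratio is intensity_Golgi / intensity_nonGolgi per timepoint;
    ti is raw_ratio normalized to the initiation timepoint (ti[0] == 1).
    """

    cell_label: int
    timepoints_min: tuple[float, ...]
    raw_ratio: np.ndarray
    ti: np.ndarray
    cargo_type: str = "soluble"

    def __post_init__(self):
        self.raw_ratio = np.asarray(self.raw_ratio, dtype=float)
        self.ti = np.asarray(self.ti, dtype=float)
        if len(self.timepoints_min) != self.ti.size or self.ti.size != self.raw_ratio.size:
            raise InputError("timepoints and TI series lengths differ")
        if self.ti[0] != 1.0:
            raise InputError("TI must equal 1 at the initiation timepoint")
        if np.any(self.ti <= 0):
            raise InputError("TI must be positive at all timepoints")
        if self.cargo_type not in CLASS_THRESHOLDS:
            raise ParameterError(f"unknown cargo type {self.cargo_type!r}")

    def ti_at(self, time_min: float) -> float:
        tp = np.asarray(self.timepoints_min)
        match = np.nonzero(tp == time_min)[0]
        if match.size == 0:
            raise InputError(f"timepoint {time_min} min not in trajectory")
        return float(self.ti[match[0]])


@dataclass
class TransportClass:
    label: str
    cargo_type: str
    decision_time_min: float
    ti_at_decision: float


def compute_golgi_mask(
    golgi_marker_image: np.ndarray,
    roi: CellROI,
    background_radius_px: float = 50,
    erosions: int = 2,
) -> np.ndarray:
    """Segment the Golgi footprint from one marker-channel frame.

    Rolling-ball background subtraction, Otsu threshold computed from the
    pixels inside the ROI, then ``erosions`` binary erosions (3x3 cross).
    """
    img = ops.rolling_ball_background_subtract(
        np.asarray(golgi_marker_image, dtype=float), background_radius_px
    )
    inside = img[roi.mask]
    if inside.size == 0:
        raise InputError("ROI is empty")
    # Otsu on the ROI's own histogram; DegenerateHistogramError propagates
    thr, _ = ops.otsu_threshold(inside)
    mask = (img > thr) & roi.mask
    mask = ops.erode_binary(mask, erosions)
    if not mask.any():
        raise DegenerateMaskError(
            f"Golgi mask for ROI {roi.label} is empty after {erosions} erosions"
        )
    return mask


def compute_transport_index(
    cargo_stack: ImageStack,
    marker_stack: ImageStack,
    roi: CellROI,
    cargo_type: str = "soluble",
    background_radius_px: float = 50,
    cargo_background: str | None = "roi_median",
    erosions: int = 2,
) -> TITrajectory:
    """Compute the transport-index trajectory for one cell ROI.

    A fresh Golgi mask is segmented from the marker channel at every
    timepoint; integrated cargo densities are then measured inside the mask
    and in the rest of the ROI.

    cargo_background controls offset removal on the cargo frames:
    "roi_median" (default) subtracts the median intensity outside the ROI —
    a flat camera-offset/haze estimate that leaves cell-scale signal (the
    diffuse ER pool) untouched; "rolling_ball" applies the same rolling
    ball as the marker channel (which also removes structure wider than
    the ball, biasing the ratio when the ER signal is diffuse); None
    disables it.
    """
    if cargo_stack.n_frames != marker_stack.n_frames:
        raise InputError("cargo and marker stacks differ in frame count")
    tp = cargo_stack.timepoints_min
    if tp is None:
        raise InputError("cargo stack lacks timepoints_min")
    if marker_stack.timepoints_min is not None and tuple(marker_stack.timepoints_min) != tuple(tp):
        raise InputError("cargo and marker stacks have different timepoints")

    cargo = cargo_stack.data[:, 0].astype(float)
    marker = marker_stack.data[:, 0].astype(float)
    ratios = np.empty(cargo_stack.n_frames)
    for t in range(cargo_stack.n_frames):
        mask = compute_golgi_mask(marker[t], roi, background_radius_px, erosions)
        frame = cargo[t]
        if cargo_background == "roi_median":
            outside = frame[~roi.mask]
            offset = float(np.median(outside)) if outside.size else 0.0
            frame = np.clip(frame - offset, 0, None)
        elif cargo_background == "rolling_ball":
            frame = ops.rolling_ball_background_subtract(frame, background_radius_px)
        elif cargo_background is not None:
            raise ParameterError(
                f"unknown cargo_background mode {cargo_background!r}"
            )
        golgi_sum = float(frame[mask].sum())
        non_golgi = roi.mask & ~mask
        non_golgi_sum = float(frame[non_golgi].sum())
        if non_golgi_sum <= 0:
            raise InputError(
                f"non-Golgi integrated intensity is zero at timepoint index {t}"
            )
        ratios[t] = golgi_sum / non_golgi_sum
    ti = ratios / ratios[0]
    ti[0] = 1.0  # exact by contract
    return TITrajectory(
        cell_label=roi.label,
        timepoints_min=tuple(tp),
        raw_ratio=ratios,
        ti=ti,
        cargo_type=cargo_type,
    )


def classify_transport(traj: TITrajectory) -> TransportClass:
    """Assign the four-level transport-efficiency class from the TI at the
    cargo-specific decision time (30 min soluble, 15 min transmembrane).

    Intervals are half-open [lower, upper): a TI exactly on a boundary is
    assigned to the higher class.
    """
    t_dec = DECISION_TIME_MIN[traj.cargo_type]
    ti = traj.ti_at(t_dec)
    very_high, high, moderate = CLASS_THRESHOLDS[traj.cargo_type]
    if ti >= very_high:
        label = "very_high"
    elif ti >= high:
        label = "high"
    elif ti >= moderate:
        label = "moderate"
    else:
        label = "none"
    return TransportClass(
        label=label,
        cargo_type=traj.cargo_type,
        decision_time_min=t_dec,
        ti_at_decision=ti,
    )


def summarize_population(
    trajs: list[TITrajectory], condition: str = ""
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population summary across cells of one condition.

    Returns (timecourse, class_freq): per-timepoint mean +/- SEM of TI, and
    the class-frequency table (counts and percentages). With a single cell
    the SEM is undefined and reported as 0 with n = 1.
    """
    if not trajs:
        raise InputError("need at least one trajectory")
    tp = trajs[0].timepoints_min
    for tr in trajs:
        if tr.timepoints_min != tp:
            raise InputError("trajectories have inconsistent timepoints")
    ti_matrix = np.stack([tr.ti for tr in trajs])
    n = ti_matrix.shape[0]
    mean = ti_matrix.mean(axis=0)
    sem = (
        ti_matrix.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(tp))
    )
    timecourse = pd.DataFrame(
        {
            "condition": condition,
            "time_min": tp,
            "mean_ti": mean,
            "sem_ti": sem,
            "n_cells": n,
        }
    )
    classes = [classify_transport(tr).label for tr in trajs]
    counts = {c: classes.count(c) for c in CLASS_ORDER}
    class_freq = pd.DataFrame(
        {
            "condition": condition,
            "transport_class": list(CLASS_ORDER),
            "count": [counts[c] for c in CLASS_ORDER],
            "percent": [100.0 * counts[c] / n for c in CLASS_ORDER],
        }
    )
    return timecourse, class_freq


def compare_class_frequencies(
    class_freq_a: pd.DataFrame, class_freq_b: pd.DataFrame
) -> dict:
    """Chi-square test of class-frequency differences between two
    conditions (delegated to scipy); classes empty in both are dropped."""
    from scipy.stats import chi2_contingency

    a = class_freq_a.set_index("transport_class")["count"]
    b = class_freq_b.set_index("transport_class")["count"]
    table = pd.concat([a, b], axis=1).fillna(0)
    table = table[(table.sum(axis=1) > 0)]
    stat, p, dof, _ = chi2_contingency(table.to_numpy().T)
    return {"chi2": float(stat), "p_value": float(p), "dof": int(dof)}
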