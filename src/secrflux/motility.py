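"""Vesicle detection, track linking and per-ROI motility readouts.

Pipeline order is fixed: background subtraction -> bleach correction ->
Otsu threshold -> size filter (5-30 px components are candidate vesicles)
-> frame-to-frame linking -> summarization. Two readouts are reported per
ROI: MeanSpeed, the arithmetic mean over tracks of each track's mean
speed, and MeanDisplacement, the mean over tracks of the straight-line
distance between a track's first and last positions (a proxy for directed,
long-distance transport).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from . import ops
from .errors import DegenerateHistogramError, InputError, ParameterError
from .stack import CellROI, ImageStack


@dataclass
class Detection:
    frame: int
    x: float
    y: float
    area_px: int
    intensity: float


@dataclass
class VesicleTrack:
    track_id: int
    points: list[tuple[int, float, float]] = field(default_factory=list)  # (frame, x, y)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def xy(self) -> np.ndarray:
        return np.array([[p[1], p[2]] for p in self.points])

    def path_length(self) -> float:
        if self.n_points < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.xy, axis=0), axis=1)))

    def mean_speed(self) -> float:
        """Total path length over total elapsed frames (px/frame); robust
        to gap-closed links spanning more than one frame."""
        if self.n_points < 2:
            return 0.0
        elapsed = self.points[-1][0] - self.points[0][0]
        return self.path_length() / elapsed if elapsed > 0 else 0.0

    def displacement(self) -> float:
        """Euclidean distance between first and last positions (px)."""
        if self.n_points < 2:
            return 0.0
        return float(np.linalg.norm(self.xy[-1] - self.xy[0]))


@dataclass
class MotilitySummary:
    """Per-ROI motility readout; with no eligible tracks the means are
    reported as missing (NaN), never as zero."""

    roi_label: int
    n_tracks: int
    mean_speed: float  # NaN when n_tracks == 0
    mean_displacement: float
    units: str  # "px_per_frame" or "um_per_s"
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None


def detect_vesicles(
    frame_image: np.ndarray,
    roi: CellROI | None = None,
    min_area_px: int = 5,
    max_area_px: int = 30,
    threshold: float | None = None,
) -> list[Detection]:
    """Connected components above threshold, filtered to [min, max] area.

    The frame should already be background-subtracted and bleach-corrected.
    With ``threshold=None`` an Otsu threshold is computed from this frame
    alone; movie pipelines instead pass one movie-wide threshold (see
    :func:`analyze_movie`) — per-frame Otsu is scale-invariant and would
    hide photobleaching entirely. Centroids are intensity-weighted
    sub-pixel positions. A degenerate (constant) frame raises; pipeline
    drivers convert that to "no detections" for that frame.
    """
    if min_area_px >= max_area_px:
        raise ParameterError("min_area_px must be < max_area_px")
    img = np.asarray(frame_image, dtype=float)
    if threshold is None:
        threshold, _ = ops.otsu_threshold(img)
    mask = img > threshold
    if roi is not None:
        mask = mask & roi.mask
    labels, n = ndi.label(mask)
    if n == 0:
        return []
    areas = ndi.sum_labels(np.ones_like(img), labels, index=np.arange(1, n + 1))
    keep = np.nonzero((areas >= min_area_px) & (areas <= max_area_px))[0] + 1
    detections = []
    for lab in keep:
        sel = labels == lab
        yy, xx = np.nonzero(sel)
        w = img[yy, xx]
        wsum = w.sum()
        if wsum <= 0:
            cy, cx = float(yy.mean()), float(xx.mean())
        else:
            cy, cx = float((yy * w).sum() / wsum), float((xx * w).sum() / wsum)
        detections.append(
            Detection(frame=-1, x=cx, y=cy, area_px=int(sel.sum()), intensity=float(wsum))
        )
    return detections


def link_tracks(
    detections_by_frame: dict[int, list[Detection]],
    max_link_px: float = 5.0,
    max_gap_frames: int = 1,
) -> list[VesicleTrack]:
    """Greedy mutual-nearest-neighbour linking with a distance gate.

    At each frame, open track ends (last seen within 1 + max_gap_frames
    frames) and new detections are matched by repeatedly taking the
    globally closest pair within ``max_link_px``; unmatched detections
    start new tracks. This emulates the simple-LAP behaviour of common
    trackers for well-separated spots without implementing the full LAP.
    """
    if not detections_by_frame:
        return []
    frames = sorted(detections_by_frame)
    tracks: list[VesicleTrack] = []
    open_tracks: list[VesicleTrack] = []
    next_id = 0
    for frame in frames:
        dets = detections_by_frame[frame]
        # retire stale tracks
        open_tracks = [
            t for t in open_tracks if frame - t.points[-1][0] <= 1 + max_gap_frames
        ]
        assigned_dets: set[int] = set()
        if open_tracks and dets:
            ends = np.array([[t.points[-1][1], t.points[-1][2]] for t in open_tracks])
            pos = np.array([[d.x, d.y] for d in dets])
            dist = np.linalg.norm(ends[:, None, :] - pos[None, :, :], axis=2)
            dist = dist.copy()
            while True:
                i, j = np.unravel_index(np.argmin(dist), dist.shape)
                if dist[i, j] > max_link_px:
                    break
                open_tracks[i].points.append((frame, dets[j].x, dets[j].y))
                assigned_dets.add(j)
                dist[i, :] = np.inf
                dist[:, j] = np.inf
                if np.isinf(dist).all():
                    break
        for j, d in enumerate(dets):
            if j in assigned_dets:
                continue
            t = VesicleTrack(track_id=next_id, points=[(frame, d.x, d.y)])
            next_id += 1
            tracks.append(t)
            open_tracks.append(t)
    return tracks


def summarize_motility(
    tracks: list[VesicleTrack],
    roi: CellROI | None = None,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    min_track_len: int = 5,
) -> MotilitySummary:
    """Arithmetic means of per-track mean speed and displacement.

    Tracks shorter than ``min_track_len`` points are dropped; a track
    belongs to the ROI of its first point. Units are px/frame unless both
    calibrations are given, in which case um/s and um are reported.
    """
    if min_track_len < 2:
        raise ParameterError("min_track_len must be >= 2")
    eligible = [t for t in tracks if t.n_points >= min_track_len]
    if roi is not None:
        eligible = [
            t
            for t in eligible
            if _point_in_roi(t.points[0][2], t.points[0][1], roi)
        ]
    roi_label = roi.label if roi is not None else 0
    calibrated = pixel_size_um is not None and frame_interval_s is not None
    if not eligible:
        return MotilitySummary(
            roi_label=roi_label,
            n_tracks=0,
            mean_speed=float("nan"),
            mean_displacement=float("nan"),
            units="um_per_s" if calibrated else "px_per_frame",
            pixel_size_um=pixel_size_um,
            frame_interval_s=frame_interval_s,
        )
    speed = float(np.mean([t.mean_speed() for t in eligible]))
    disp = float(np.mean([t.displacement() for t in eligible]))
    if calibrated:
        speed = speed * pixel_size_um / frame_interval_s
        disp = disp * pixel_size_um
        units = "um_per_s"
    else:
        units = "px_per_frame"
    return MotilitySummary(
        roi_label=roi_label,
        n_tracks=len(eligible),
        mean_speed=speed,
        mean_displacement=disp,
        units=units,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
    )


def _point_in_roi(y: float, x: float, roi: CellROI) -> bool:
    iy, ix = int(round(y)), int(round(x))
    ny, nx = roi.mask.shape
    return 0 <= iy < ny and 0 <= ix < nx and bool(roi.mask[iy, ix])


def analyze_movie(
    stack: ImageStack,
    roi: CellROI | None = None,
    min_area_px: int = 5,
    max_area_px: int = 30,
    max_link_px: float = 5.0,
    max_gap_frames: int = 1,
    min_track_len: int = 5,
    background_radius_px: float = 10.0,
    bleach_correction: bool = True,
) -> tuple[list[VesicleTrack], MotilitySummary, "ops.BleachFit | None"]:
    """Full movie pipeline: background subtraction, bleach correction,
    detection, linking, summarization.

    Frames whose histogram is degenerate after preprocessing (e.g. no
    vesicle in view) contribute zero detections rather than failing.
    """
    movie = stack.data[:, 0].astype(float)
    subtracted = np.stack(
        [
            ops.rolling_ball_background_subtract(frame, background_radius_px)
            for frame in movie
        ]
    )
    work = ImageStack(
        data=subtracted[:, None],
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        channel_names=("vesicles",),
    )
    fit = None
    if bleach_correction:
        work, fit = ops.bleach_correct(work)
    # One movie-wide Otsu threshold (subsampled histogram): detection must
    # see residual bleaching, which a per-frame threshold would normalize
    # away, and must treat all frames of a corrected movie uniformly.
    sample = work.data[:: max(1, work.n_frames // 64), 0]
    try:
        threshold, _ = ops.otsu_threshold(sample)
    except DegenerateHistogramError:
        threshold = None
    detections_by_frame: dict[int, list[Detection]] = {}
    for t in range(work.n_frames):
        try:
            dets = detect_vesicles(
                work.data[t, 0],
                roi=roi,
                min_area_px=min_area_px,
                max_area_px=max_area_px,
                threshold=threshold,
            )
        except DegenerateHistogramError:
            dets = []
        for d in dets:
            d.frame = t
        detections_by_frame[t] = dets
    tracks = link_tracks(
        detections_by_frame, max_link_px=max_link_px, max_gap_frames=max_gap_frames
    )
    summary = summarize_motility(
        tracks,
        roi=roi,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        min_track_len=min_track_len,
    )
    return tracks, summary, fit


def tracks_to_frame(tracks: list[VesicleTrack]) -> pd.DataFrame:
    """Long-format table with columns track_id, frame, x, y."""
    rows = [
        {"track_id": t.track_id, "frame": f, "x": x, "y": y}
        for t in tracks
        for (f, x, y) in t.points
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
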