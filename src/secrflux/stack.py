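"""Core in-memory containers: calibrated image stacks and per-cell ROIs.

Conventions used throughout the package: 0-based indices, pixel centers at
integer coordinates, (y, x) axis order, stack axes (t, channel, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError


@dataclass
class ImageStack:
    """A time x channel x y x x intensity array with physical calibration.

    Parameters
    ----------
    data
        Non-negative intensity array of shape (t, channel, y, x).
    pixel_size_um
        Pixel edge length in micrometres, or None when uncalibrated
        (readouts then stay in pixel/frame units).
    frame_interval_s
        Time between consecutive frames in seconds (movies).
    timepoints_min
        Optional per-frame acquisition times in minutes (snapshot series
        such as the 0/3/7/15/30 min transport protocol).
    channel_names
        One label per channel axis entry.
    """

    data: np.ndarray
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    timepoints_min: tuple[float, ...] | None = None
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise InputError(
                f"stack data must be 4-D (t, channel, y, x), got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise InputError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise InputError("stack intensities must be non-negative")
        if self.timepoints_min is not None:
            self.timepoints_min = tuple(float(t) for t in self.timepoints_min)
            if len(self.timepoints_min) != self.n_frames:
                raise InputError(
                    "timepoints_min length must equal the number of frames"
                )
        if self.channel_names:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.n_channels:
                raise InputError(
                    "channel_names length must equal the number of channels"
                )
        else:
            self.channel_names = tuple(
                f"ch{i}" for i in range(self.n_channels)
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the (t, y, x) sub-stack for a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise InputError(
                f"no channel named {name!r}; have {self.channel_names}"
            ) from None
        return self.data[:, idx]


@dataclass
class CellROI:
    """A per-cell region of interest given as a binary footprint.

    In the original workflow ROIs are drawn manually; here they arrive as
    label-mask files or as simulator ground truth.
    """

    label: int
    mask: np.ndarray
    source: str = "manual_file"  # or "ground_truth"

    def __post_init__(self):
        if self.label < 1:
            raise ParameterError("ROI label must be >= 1")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InputError("ROI mask must be 2-D")
        if not self.mask.any():
            raise InputError(f"ROI {self.label} has an empty mask")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def rois_from_labels(label_image: np.ndarray, source: str = "manual_file") -> list[CellROI]:
    """Split a label image (0 = background) into one CellROI per label."""
    lab = np.asarray(label_image)
    if lab.ndim != 2:
        raise InputError("label image must be 2-D")
    if not np.issubdtype(lab.dtype, np.integer):
        if not np.allclose(lab, np.round(lab)):
            raise InputError("label image must contain integer values")
        lab = lab.astype(np.int64)
    labels = np.unique(lab)
    return [
        CellROI(label=int(v), mask=lab == v, source=source)
        for v in labels
        if v > 0
    ]
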