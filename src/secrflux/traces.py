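"""Ratiometric biosensor trace analysis.

FRET-based ATP sensors (acceptor/donor emission ratio) and Fura-2
(340/385 nm excitation ratio) are read out as a single ratio trace per
cell. The metrics here mirror the study's figures: a basal level averaged
over the baseline window, the maximal ratio change between basal values
and a stated endpoint, and per-epoch extrema under stimulation protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError


@dataclass
class RatioTrace:
    """A ratio time series with its basal (baseline) window.

    time_s must be strictly increasing; ratio values finite and > 0.
    """

    time_s: np.ndarray
    ratio: np.ndarray
    basal_window_s: tuple[float, float] = (0.0, 300.0)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.time_s.shape != self.ratio.shape or self.time_s.ndim != 1:
            raise InputError("time_s and ratio must be matching 1-D arrays")
        if np.any(np.diff(self.time_s) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.ratio)) or np.any(self.ratio <= 0):
            raise InputError("ratio values must be finite and > 0")
        b0, b1 = self.basal_window_s
        if not (self.time_s[0] <= b0 < b1 <= self.time_s[-1]):
            raise InputError("basal window must lie within the trace")

    def basal_mean(self) -> float:
        b0, b1 = self.basal_window_s
        sel = (self.time_s >= b0) & (self.time_s <= b1)
        if not sel.any():
            raise InputError("no samples inside the basal window")
        return float(self.ratio[sel].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "ratio": self.ratio})


def compute_ratio(
    time_s: np.ndarray,
    numerator: np.ndarray,
    denominator: np.ndarray,
    numerator_time_s: np.ndarray | None = None,
    basal_window_s: tuple[float, float] = (0.0, 300.0),
) -> RatioTrace:
    """Pointwise channel ratio (e.g. FRET acceptor/donor, Fura-2 340/385).

    Channels must be sampled on the same time base; a zero or negative
    denominator sample is reported with its index.
    """
    time_s = np.asarray(time_s, dtype=float)
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if numerator_time_s is not None and not np.array_equal(
        np.asarray(numerator_time_s, dtype=float), time_s
    ):
        raise InputError("channel time vectors are misaligned")
    if num.shape != time_s.shape or den.shape != time_s.shape:
        raise InputError("channels must match the time vector in length")
    bad = np.nonzero(den <= 0)[0]
    if bad.size:
        raise InputError(
            f"denominator is zero or negative at sample index {int(bad[0])}"
        )
    return RatioTrace(time_s=time_s, ratio=num / den, basal_window_s=basal_window_s)


@dataclass
class RatioChange:
    """Basal-to-endpoint ratio change. Positive = decline from basal."""

    change: float
    basal_mean: float
    endpoint_value: float
    endpoint_time_s: float


def max_ratio_change(trace: RatioTrace, endpoint_s: float) -> RatioChange:
    """Ratio change between the basal mean and the sample nearest the
    requested endpoint time (the actual sample time is echoed back).

    Sign convention: positive values are a decline from basal, matching
    how biosensor ratio drops under stress are reported as magnitudes.
    """
    if endpoint_s < trace.basal_window_s[1]:
        raise InputError("endpoint must not precede the end of the basal window")
    if endpoint_s > trace.time_s[-1]:
        raise InputError("endpoint lies beyond the trace")
    idx = int(np.argmin(np.abs(trace.time_s - endpoint_s)))
    basal = trace.basal_mean()
    end_val = float(trace.ratio[idx])
    return RatioChange(
        change=basal - end_val,
        basal_mean=basal,
        endpoint_value=end_val,
        endpoint_time_s=float(trace.time_s[idx]),
    )


def stimulus_response(
    trace: RatioTrace, epochs: list[tuple[str, float, float]]
) -> pd.DataFrame:
    """Per-epoch extrema for stimulation protocols (e.g. ATP + BHQ pulses).

    ``epochs`` is a list of (label, start_s, end_s), non-overlapping and in
    order. For each epoch the min, max, and maximum absolute deviation from
    the immediately preceding epoch's final value are returned — capturing
    both ER Ca2+ depletion depth and cytosolic transient height. The first
    epoch is referenced to the trace sample just before it starts (or its
    own first sample when it starts the trace).
    """
    if not epochs:
        raise InputError("need at least one epoch")
    prev_end = -np.inf
    rows = []
    ref_value = None
    for label, start, end in epochs:
        if start >= end:
            raise InputError(f"epoch {label!r} is empty or inverted")
        if start < prev_end:
            raise InputError("epochs must be non-overlapping and ordered")
        sel = (trace.time_s >= start) & (trace.time_s <= end)
        if not sel.any():
            raise InputError(f"epoch {label!r} contains no samples")
        if ref_value is None:
            before = trace.time_s < start
            ref_value = float(
                trace.ratio[before][-1] if before.any() else trace.ratio[sel][0]
            )
        seg = trace.ratio[sel]
        rows.append(
            {
                "epoch": label,
                "start_s": start,
                "end_s": end,
                "min": float(seg.min()),
                "max": float(seg.max()),
                "max_deviation": float(np.max(np.abs(seg - ref_value))),
                "reference_value": ref_value,
            }
        )
        ref_value = float(seg[-1])
        prev_end = end
    return pd.DataFrame(rows)
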