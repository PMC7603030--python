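"""TIFF / CSV / JSON input-output and run provenance.

Stacks are stored as multi-page TIFF with axes normalized to
(t, channel, y, x) on read; label masks as 16-bit single-page TIFF;
tables as CSV with fixed column order and 6-significant-digit numeric
formatting; each CLI run writes one JSON manifest recording all resolved
parameters, content digests of the inputs, software version and seed.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import InputError
from .stack import CellROI, ImageStack, rois_from_labels

logger = logging.getLogger("secrflux")


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    timepoints_min: tuple[float, ...] | None = None,
    channel_names: tuple[str, ...] = (),
    channel_axis: int | None = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF into a calibrated ImageStack.

    Axis normalization: 2-D -> (1, 1, y, x); 3-D -> (t, 1, y, x) unless
    ``channel_axis`` identifies the channel dimension; 4-D -> (t, c, y, x).
    Calibration overrides win over file metadata (with a logged warning on
    conflict); with no calibration anywhere, readouts stay in px/frame.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.imagej_metadata or {}
    except Exception as exc:  # noqa: BLE001 - report file context
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        if channel_axis is not None:
            data = np.moveaxis(data, channel_axis, 0)[None]
        else:
            data = data[:, None]
    elif data.ndim != 4:
        raise InputError(f"unsupported TIFF dimensionality {data.ndim} in {path}")

    meta_interval = meta.get("finterval")
    if frame_interval_s is None:
        frame_interval_s = meta_interval
    elif meta_interval is not None and not np.isclose(meta_interval, frame_interval_s):
        logger.warning(
            "frame interval override %s s conflicts with file metadata %s s; override wins",
            frame_interval_s,
            meta_interval,
        )
    return ImageStack(
        data=np.asarray(data, dtype=float),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        timepoints_min=timepoints_min,
        channel_names=channel_names,
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page float32 TIFF (pages = t*channel)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {}
    if stack.frame_interval_s is not None:
        meta["finterval"] = stack.frame_interval_s
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        imagej=True,
        metadata={"axes": "TCYX", **meta},
    )


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16))


def read_roi_labels(path: str | Path, source: str = "manual_file") -> list[CellROI]:
    """Read a label-image TIFF (0 = background) into one ROI per label."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise InputError("ROI label image must be a single 2-D page")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise InputError("ROI label image must contain integer values")
        arr = np.round(arr).astype(np.int64)
    return rois_from_labels(arr, source=source)


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    parameters: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    software_version: str = __version__
    seed: int | None = None
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def add_input(self, name: str, path: str | Path) -> None:
        self.input_hashes[name] = sha256_file(path)

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "parameters": self.parameters,
            "input_hashes": self.input_hashes,
            "software_version": self.software_version,
            "seed": self.seed,
            "timestamp": self.timestamp,
        }


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: dict[str, pd.DataFrame],
    manifest: RunManifest,
    out_dir: str | Path,
    force: bool = False,
) -> list[Path]:
    """Write CSV tables plus the JSON manifest with deterministic
    formatting (6 significant digits). Refuses to overwrite existing
    files unless ``force``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    targets = [out_dir / f"{name}.csv" for name in tables] + [out_dir / "manifest.json"]
    if not force:
        existing = [p for p in targets if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing[0]} (pass force=True / --force)"
            )
    written = []
    for name, table in tables.items():
        p = out_dir / f"{name}.csv"
        table.to_csv(p, index=False, float_format="%.6g")
        written.append(p)
    mp = out_dir / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(mp)
    return written


def load_config(path: str | Path) -> dict:
    """Flat key->value configuration from YAML or JSON; CLI flags override."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise InputError("config file must contain a flat key-value mapping")
    return cfg
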