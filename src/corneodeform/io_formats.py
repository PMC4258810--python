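"""Reading tonometer image sequences and writing analysis result tables.

Supported inputs are AVI files (uncompressed; see `_avi`) and directories or
globs of single-channel PNG/TIFF frames. The proprietary ``.cst`` container
used natively by the Corvis instrument is undocumented and is rejected with
an explicit message. A sidecar JSON file can carry acquisition metadata; when
absent, the nominal 230 µs frame interval of the instrument is assumed.

All indices are 0-based, both in memory and in the serialized tables.
Row coordinates follow the image convention (m grows downward); plotting in
the familiar "cornea bulges upward" orientation is a display-time sign flip.
"""

from __future__ import annotations

import glob as _glob
import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import _avi
from .errors import (DimensionError, TooShortSequenceError,
                     UnsupportedFormatError)

DEFAULT_FRAME_INTERVAL_US = 230.0

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".bmp"}


@dataclass
class SequenceMetadata:
    """Acquisition metadata carried alongside an image sequence."""

    frame_interval_us: float = DEFAULT_FRAME_INTERVAL_US
    pixel_scale_um: float | None = None
    source_path: str = ""
    acquisition_note: str | None = None

    def __post_init__(self):
        if not self.frame_interval_us > 0:
            raise ValueError("frame_interval_us must be positive")


@dataclass
class FrameSequence:
    """A grayscale deformation recording: an (I, M, N) uint8 cube.

    Axis order is (frame, row, column); rows grow downward as in the raw
    camera image.
    """

    frames: np.ndarray
    metadata: SequenceMetadata = field(default_factory=SequenceMetadata)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DimensionError(
                f"expected a 3-D (frame, row, column) array, got shape "
                f"{self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise TooShortSequenceError(
                f"sequence has {self.frames.shape[0]} frame(s); at least 2 "
                "are required (a reference frame plus one more)")
        if self.frames.dtype != np.uint8:
            lo, hi = self.frames.min(), self.frames.max()
            if lo < 0 or hi > 255:
                raise ValueError(
                    f"intensities must lie in [0, 255], got [{lo}, {hi}]")
            self.frames = self.frames.astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


def _to_gray_uint8(img: np.ndarray) -> np.ndarray:
    """Collapse channels by BT.601 luminance and normalize to uint8."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        rgb = arr[..., :3].astype(np.float64)
        arr = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    arr = np.asarray(arr, dtype=np.float64)
    if arr.max(initial=0.0) > 255:  # e.g. 16-bit TIFF
        arr = arr * (255.0 / arr.max())
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def _load_metadata(metadata_path, source_path) -> SequenceMetadata:
    candidates = []
    if metadata_path is not None:
        candidates.append(Path(metadata_path))
    else:
        p = Path(source_path)
        candidates.append(p.with_suffix(".json"))
    for cand in candidates:
        if cand.is_file():
            with open(cand) as fh:
                raw = json.load(fh)
            return SequenceMetadata(
                frame_interval_us=raw.get("frame_interval_us",
                                          DEFAULT_FRAME_INTERVAL_US),
                pixel_scale_um=raw.get("pixel_scale_um"),
                source_path=str(source_path),
                acquisition_note=raw.get("acquisition_note"))
    return SequenceMetadata(source_path=str(source_path))


def read_sequence(path, metadata_path=None) -> FrameSequence:
    """Read an image sequence from an AVI file or a PNG/TIFF frame stack.

    ``path`` may be an AVI file, a directory of frames, or a glob pattern;
    frames of a stack are ordered by sorted file name. The proprietary
    ``.cst`` format is rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()

    if suffix == ".cst":
        raise UnsupportedFormatError(
            f"{path}: the proprietary .cst container is not supported; "
            "accepted formats are .avi files and PNG/TIFF frame stacks")

    if suffix == ".avi":
        if not path.is_file():
            raise FileNotFoundError(path)
        frames, interval = _avi.read_avi(path)
        meta = _load_metadata(metadata_path, path)
        if metadata_path is None and not path.with_suffix(".json").is_file():
            meta.frame_interval_us = interval
        return FrameSequence(frames, meta)

    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in _IMAGE_EXTENSIONS)
    elif any(ch in str(path) for ch in "*?["):
        files = [Path(p) for p in sorted(_glob.glob(str(path)))]
    elif path.is_file() and suffix in _IMAGE_EXTENSIONS:
        files = [path]
    else:
        raise UnsupportedFormatError(
            f"{path}: unsupported format; accepted formats are .avi files "
            "and PNG/TIFF frame stacks (directory or glob)")

    if not files:
        raise UnsupportedFormatError(f"{path}: no image frames found")

    frames = [_to_gray_uint8(iio.imread(f)) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise DimensionError(
            f"{path}: frames have inconsistent dimensions: {sorted(shapes)}")
    meta = _load_metadata(metadata_path, path)
    return FrameSequence(np.stack(frames), meta)


def write_sequence(seq: FrameSequence, path) -> Path:
    """Write a sequence as an uncompressed 8-bit AVI plus a JSON sidecar."""
    path = Path(path)
    _avi.write_avi(path, seq.frames, seq.metadata.frame_interval_us)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump({"frame_interval_us": seq.metadata.frame_interval_us,
                   "pixel_scale_um": seq.metadata.pixel_scale_um,
                   "acquisition_note": seq.metadata.acquisition_note},
                  fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

_CONTOUR_HEADER = (
    "# corneodeform contour table; long format; 0-based frame_index and "
    "column_index; rows grow downward (image convention); values in pixels\n")
_PARAM_HEADER = (
    "# corneodeform per-frame parameter table; 0-based frame_index; empty "
    "cells mean the quantity is undefined at that frame\n")

_COMPONENTS = ("L_T", "L_TD", "L_TR", "L_TO")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_results(contours, params, out_dir, config=None,
                  version: str | None = None) -> dict[str, Path]:
    """Write contour/parameter tables and a JSON summary into ``out_dir``.

    Returns a mapping with keys ``contours``, ``parameters``, ``summary``.
    Numeric round-trip through `read_contour_table` / `read_parameter_table`
    is exact (floats serialized with 17 significant digits).
    """
    from . import __version__

    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    n_frames, n_cols = contours.l_t.shape
    if params is not None and params.n_frames != n_frames:
        raise ValueError("contours and params cover different frame counts")

    contour_path = out_dir / "contours.csv"
    grids = dict(zip(_COMPONENTS,
                     (contours.l_t, contours.l_td, contours.l_tr,
                      contours.l_to)))
    with open(contour_path, "w", newline="") as fh:
        fh.write(_CONTOUR_HEADER)
        fh.write("frame_index,column_index,component,value_pixels\n")
        for name, grid in grids.items():
            for i in range(n_frames):
                row = grid[i]
                for n in range(n_cols):
                    fh.write(f"{i},{n},{name},{_fmt(row[n])}\n")

    param_path = out_dir / "parameters.csv"
    with open(param_path, "w", newline="") as fh:
        fh.write(_PARAM_HEADER)
        fh.write("frame_index,L_DDTR,L_DDK,L_DDS,L_AATR,L_AAK,"
                 "ratio_DDS_TR,amplitude,smoothing_fallback\n")
        for i in range(n_frames):
            cells = [str(i)]
            for arr in (params.l_ddtr, params.l_ddk, params.l_dds,
                        params.l_aatr, params.l_aak, params.ratio,
                        params.amplitude):
                v = arr[i]
                cells.append("" if not np.isfinite(v) else _fmt(v))
            cells.append(str(int(params.smoothing_fallback[i])))
            fh.write(",".join(cells) + "\n")

    summary_path = out_dir / "summary.json"
    summary = {
        "software": "corneodeform",
        "version": version or __version__,
        "n_frames": int(n_frames),
        "n_columns": int(n_cols),
        "a1": None if params.a1 is None else int(params.a1),
        "a2": None if params.a2 is None else int(params.a2),
        "highest_concavity_frame":
            None if params.i_peak is None else int(params.i_peak),
        "max_amplitude_px":
            None if params.i_peak is None
            else float(np.nanmax(params.amplitude)),
        "config": _serialize_config(config),
    }
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1)

    return {"contours": contour_path, "parameters": param_path,
            "summary": summary_path}


def _serialize_config(config):
    if config is None:
        return None
    if hasattr(config, "__dataclass_fields__"):
        return asdict(config)
    return dict(config)


def read_contour_table(path):
    """Re-read a contour table written by `write_results` as a ContourSet."""
    from .contour_pipeline import ContourSet

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    n_frames = int(df["frame_index"].max()) + 1
    n_cols = int(df["column_index"].max()) + 1
    grids = {}
    for name in _COMPONENTS:
        sub = df[df["component"] == name]
        grid = np.full((n_frames, n_cols), np.nan)
        grid[sub["frame_index"].to_numpy(),
             sub["column_index"].to_numpy()] = sub["value_pixels"].to_numpy()
        grids[name] = grid
    return ContourSet(l_t=grids["L_T"], l_td=grids["L_TD"],
                      l_tr=grids["L_TR"], l_to=grids["L_TO"])


def read_parameter_table(path) -> pd.DataFrame:
    """Re-read a per-frame parameter table written by `write_results`."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")
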