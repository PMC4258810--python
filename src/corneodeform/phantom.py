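"""Synthetic air-puff deformation sequences with analytic ground truth.

The phantom emulates what the instrument's camera sees: a bright corneal
band over a dark background, whose anterior (topmost) edge follows

    m(n, i) = m_apex + (n - n_c)^2 / (2 R)                 static arc
            + A(i) * exp(-(n - n_c)^2 / (2 sigma^2))       air-puff indent
            + d(i)                                          whole-eye motion

in image coordinates (rows grow downward, so the indentation pushes the
contour toward larger rows). The static arc is parabolic rather than
circular: at corneal curvatures the difference over the field of view is
sub-pixel, and the parabola makes the applanation condition exactly
analytic — the apex of the contour is locally flat when the indentation
curvature cancels the arc curvature, i.e. when A(i) = sigma^2 / R. The two
frames where the amplitude envelope crosses that level are the ground-truth
applanation frames (a1*, a2*).

A(i) is a raised-cosine pulse over [i_on, i_off]; the whole-eye
retro-displacement d(i) is a delayed, lower raised-cosine, mimicking the
sluggish eyeball reaction that trails the corneal indentation. Both vanish
at frame 0, which the decomposition stage uses as its reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import FrameSequence, SequenceMetadata


@dataclass
class PhantomConfig:
    """Geometry and dynamics of a synthetic deformation sequence.

    Defaults reproduce the instrument's acquisition format (200 x 576
    pixels, 140 frames every 230 µs) with a deformation of realistic pixel
    scale: peak indentation 50 px, indentation width sigma = 60 px, arc
    radius 900 px, whole-eye retro-displacement up to 8 px starting 25
    frames after the puff. Rendering noise (intensity sd 6 plus 0.5 px edge
    jitter) is sized so the extracted contour carries roughly two pixels of
    noise amplitude — the level the binarization threshold p_r is meant to
    reject.
    """

    M: int = 200
    N: int = 576
    I: int = 140
    apex_row: float = 60.0
    corneal_radius: float = 900.0
    indent_center: float | None = None  # defaults to N/2
    indent_sigma: float = 60.0
    peak_amplitude: float = 50.0
    envelope_on: int = 20
    envelope_off: int = 120
    eye_displacement_max: float = 8.0
    eye_displacement_delay: int = 25
    band_thickness: int = 12
    band_intensity: float = 200.0
    background_intensity: float = 30.0
    noise_sd: float = 6.0
    contour_jitter_sd: float = 0.5
    frame_interval_us: float = 230.0
    seed: int = 0

    def __post_init__(self):
        if self.indent_center is None:
            self.indent_center = self.N / 2.0

    def validate(self) -> None:
        if self.indent_sigma <= 0:
            raise ConfigurationError("indent_sigma must be > 0")
        if self.corneal_radius <= 0:
            raise ConfigurationError("corneal_radius must be > 0")
        if not (0 <= self.envelope_on < self.envelope_off <= self.I - 1):
            raise ConfigurationError(
                f"envelope window must satisfy 0 <= envelope_on < "
                f"envelope_off <= I-1, got [{self.envelope_on}, "
                f"{self.envelope_off}] with I={self.I}")
        if self.I < 2:
            raise ConfigurationError("I must be at least 2")
        deepest = (self.apex_row + (self.N / 2.0) ** 2 / (2 * self.corneal_radius)
                   + self.peak_amplitude + self.eye_displacement_max
                   + self.band_thickness)
        if deepest >= self.M:
            raise ConfigurationError(
                f"contour leaves the image: apex_row + (N/2)^2/(2R) + "
                f"peak_amplitude + eye_displacement_max + band_thickness = "
                f"{deepest:.1f} must be < M = {self.M}")


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a generated sequence."""

    contour_true: np.ndarray          # (I, N) exact contour rows, px
    amplitude: np.ndarray             # A(i), px
    displacement: np.ndarray          # d(i), px
    applanation_frames: tuple[int, int] | None  # (a1*, a2*)
    peak_frame: int
    config: PhantomConfig = field(repr=False, default=None)


def _raised_cosine(i: np.ndarray, on: float, off: float, peak: float) -> np.ndarray:
    """Raised-cosine pulse: 0 outside [on, off], peak at the midpoint."""
    phase = (i - on) / (off - on)
    pulse = peak * np.sin(np.pi * np.clip(phase, 0.0, 1.0)) ** 2
    return np.where((i >= on) & (i <= off), pulse, 0.0)


def amplitude_envelope(config: PhantomConfig) -> np.ndarray:
    i = np.arange(config.I, dtype=np.float64)
    return _raised_cosine(i, config.envelope_on, config.envelope_off,
                          config.peak_amplitude)


def eye_displacement(config: PhantomConfig) -> np.ndarray:
    i = np.arange(config.I, dtype=np.float64)
    return _raised_cosine(i, config.envelope_on + config.eye_displacement_delay,
                          config.envelope_off + config.eye_displacement_delay,
                          config.eye_displacement_max)


def true_contour(config: PhantomConfig) -> np.ndarray:
    """Exact (I, N) contour rows, before rendering and noise."""
    n = np.arange(config.N, dtype=np.float64)
    x = n - config.indent_center
    arc = config.apex_row + x ** 2 / (2 * config.corneal_radius)
    indent = np.exp(-x ** 2 / (2 * config.indent_sigma ** 2))
    a = amplitude_envelope(config)
    d = eye_displacement(config)
    return arc[None, :] + a[:, None] * indent[None, :] + d[:, None]


def analytic_applanation(config: PhantomConfig) -> tuple[int, int] | None:
    """Frames bracketing the curvature-cancellation condition A(i) > sigma^2/R.

    Scans the sampled envelope; returns the first and last frame whose
    amplitude exceeds the flattening level, or None if the pulse never
    reaches it.
    """
    level = config.indent_sigma ** 2 / config.corneal_radius
    above = np.flatnonzero(amplitude_envelope(config) > level)
    if above.size == 0:
        return None
    return int(above[0]), int(above[-1])


def generate_phantom(config: PhantomConfig | None = None
                     ) -> tuple[FrameSequence, PhantomTruth]:
    """Render a synthetic deformation sequence and its ground truth.

    All randomness (edge jitter and intensity noise) is driven by
    ``config.seed``; two calls with equal configs are bit-identical.
    """
    config = config or PhantomConfig()
    config.validate()

    contour = true_contour(config)
    a = amplitude_envelope(config)
    d = eye_displacement(config)

    rng = np.random.default_rng(config.seed)
    if config.contour_jitter_sd > 0:
        jitter = rng.normal(0.0, config.contour_jitter_sd,
                            size=contour.shape)
    else:
        jitter = np.zeros_like(contour)
    top = np.round(contour + jitter).astype(np.int64)

    rows = np.arange(config.M)[None, :, None]               # (1, M, 1)
    band_top = top[:, None, :]                              # (I, 1, N)
    in_band = (rows >= band_top) & (rows < band_top + config.band_thickness)
    cube = np.where(in_band, config.band_intensity,
                    config.background_intensity).astype(np.float64)
    if config.noise_sd > 0:
        cube += rng.normal(0.0, config.noise_sd, size=cube.shape)
    frames = np.clip(np.round(cube), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames, SequenceMetadata(
        frame_interval_us=config.frame_interval_us,
        source_path=f"phantom(seed={config.seed})"))
    truth = PhantomTruth(
        contour_true=contour,
        amplitude=a,
        displacement=d,
        applanation_frames=analytic_applanation(config),
        peak_frame=int(np.argmax(a)),
        config=config)
    return seq, truth


def truth_contour_export(truth: PhantomTruth, out_dir) -> dict[str, Path]:
    """Serialize ground truth: contour CSV plus a JSON of A(i), d(i), a1*, a2*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    n_frames, n_cols = truth.contour_true.shape
    contour_path = out_dir / "truth_contour.csv"
    df = pd.DataFrame({
        "frame_index": np.repeat(np.arange(n_frames), n_cols),
        "column_index": np.tile(np.arange(n_cols), n_frames),
        "row_pixels": truth.contour_true.ravel(),
    })
    df.to_csv(contour_path, index=False,
              float_format="%.17g")

    json_path = out_dir / "truth.json"
    a12 = truth.applanation_frames
    payload = {
        "amplitude_px": [float(v) for v in truth.amplitude],
        "displacement_px": [float(v) for v in truth.displacement],
        "a1_star": None if a12 is None else a12[0],
        "a2_star": None if a12 is None else a12[1],
        "peak_frame": truth.peak_frame,
        "config": None if truth.config is None else asdict(truth.config),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return {"contour": contour_path, "truth": json_path}


def load_truth(out_dir) -> PhantomTruth:
    """Inverse of `truth_contour_export` (config is restored when present)."""
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "truth_contour.csv",
                     float_precision="round_trip")
    n_frames = int(df["frame_index"].max()) + 1
    n_cols = int(df["column_index"].max()) + 1
    contour = df["row_pixels"].to_numpy().reshape(n_frames, n_cols)
    with open(out_dir / "truth.json") as fh:
        payload = json.load(fh)
    a1, a2 = payload["a1_star"], payload["a2_star"]
    cfg = payload.get("config")
    return PhantomTruth(
        contour_true=contour,
        amplitude=np.asarray(payload["amplitude_px"]),
        displacement=np.asarray(payload["displacement_px"]),
        applanation_frames=None if a1 is None else (a1, a2),
        peak_frame=payload["peak_frame"],
        config=None if cfg is None else PhantomConfig(**cfg))
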