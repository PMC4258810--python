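"""Pre-processing: denoising, outer-contour extraction, motion decomposition.

The stage mirrors what must happen before any deformation parameter can be
measured on an air-puff recording:

1. a 3x3x3 spatio-temporal median filter knocks down shot noise and small
   optical-path artefacts without blurring the corneal band edge;
2. per-frame Canny edge detection (followed by a morphological close to
   bridge small gaps) finds the bright band's boundaries, and the anterior
   corneal contour L_T(n, i) is the topmost edge row of each column;
3. the contour is split into three additive components,

       L_T = L_TD + L_TR + L_TO,

   where L_TD is the static shape (the contour of the reference frame
   i = 0), L_TO is the whole-eye retro-displacement, and L_TR is the
   corneal deformation proper. L_TO is observable at the left and right
   image borders, where only sclera is visible and the air puff does not
   bend the surface: its border values are tracked there and linearly
   interpolated across interior columns. L_TR is then defined by
   subtraction, which makes the reconstruction identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.morphology import closing, disk

from .errors import ConfigurationError, ContourNotFoundError
from .io_formats import FrameSequence

#: fraction of columns that must contain an edge pixel for a frame to count
#: as having a visible corneal contour
MIN_EDGE_COLUMN_FRACTION = 0.10


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis pipeline.

    ``median_mask`` (3, 3, 3) and ``support_median_mask`` (3, 3) are the
    denoising masks applied to the raw cube and to the binarized deformation
    map. ``canny_low``/``canny_high`` are hysteresis thresholds relative to
    the frame's maximum Gaussian-gradient magnitude; ``min_edge_gradient``
    is an absolute floor (on 0–1 intensity scale) below which a frame is
    considered structureless. ``border_width`` is the number of border
    columns per side used to track the eyeball reaction (1 = track the
    single outermost column). ``p_r`` is the binarization threshold of the
    deformation map in pixels, set at the noise amplitude of the extracted
    contour (≈2 px). ``poly_degree`` smooths the contour before arc-length
    measurement; ``ratio_min_amplitude`` guards the length-to-amplitude
    ratio against division by near-zero amplitudes.
    """

    median_mask: tuple[int, int, int] = (3, 3, 3)
    canny_sigma: float = 2.0
    canny_low: float = 0.1
    canny_high: float = 0.25
    min_edge_gradient: float = 0.04
    close_radius: int = 3
    border_width: int = 5
    p_r: float = 2.0
    support_median_mask: tuple[int, int] = (3, 3)
    poly_degree: int = 8
    ratio_min_amplitude: float = 1.0

    def validate(self) -> None:
        for name in ("median_mask", "support_median_mask"):
            mask = getattr(self, name)
            if any(m <= 0 or m % 2 == 0 for m in mask):
                raise ConfigurationError(
                    f"{name} dimensions must be odd and positive, got {mask}")
        if not (0 < self.canny_low < self.canny_high < 1):
            raise ConfigurationError(
                "canny thresholds must satisfy 0 < low < high < 1, got "
                f"low={self.canny_low}, high={self.canny_high}")
        if self.border_width < 1:
            raise ConfigurationError("border_width must be >= 1")
        if self.p_r <= 0:
            raise ConfigurationError(f"p_r must be > 0, got {self.p_r}")


@dataclass
class ContourSet:
    """Per-column contour grids, all shaped (n_frames, n_columns), in pixels.

    Invariants: l_t == l_td + l_tr + l_to at every cell; l_td is the frame-0
    contour repeated over time; l_tr and l_to vanish on frame 0.
    """

    l_t: np.ndarray
    l_td: np.ndarray
    l_tr: np.ndarray
    l_to: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.l_t.shape[0]

    @property
    def n_columns(self) -> int:
        return self.l_t.shape[1]


def median_filter_3d(seq: FrameSequence,
                     mask: tuple[int, int, int] = (3, 3, 3)) -> FrameSequence:
    """Spatio-temporal median filter with replicate padding at all borders."""
    if any(m <= 0 or m % 2 == 0 for m in mask):
        raise ConfigurationError(
            f"median mask dimensions must be odd and positive, got {mask}")
    filtered = ndimage.median_filter(seq.frames, size=mask, mode="nearest")
    return FrameSequence(filtered, seq.metadata)


#: column padding (replicate) applied before edge detection so that the
#: detector, which cannot mark pixels on the image border, still yields an
#: edge in the outermost sclera columns used for eyeball tracking
_EDGE_PAD = 8

def _frame_edges(img01: np.ndarray, config: PipelineConfig,
                 footprint: np.ndarray) -> np.ndarray:
    """Closed Canny edge map with thresholds relative to the frame's peak
    gradient. Edge detection and the morphological close both run on a
    column-replicated image so that border columns behave like interior
    ones; the pad is cropped afterwards."""
    padded = np.pad(img01, ((0, 0), (_EDGE_PAD, _EDGE_PAD)), mode="edge")
    gx = ndimage.gaussian_filter(padded, config.canny_sigma, order=(0, 1))
    gy = ndimage.gaussian_filter(padded, config.canny_sigma, order=(1, 0))
    gmax = float(np.hypot(gx, gy).max())
    if gmax < config.min_edge_gradient:
        return np.zeros(img01.shape, dtype=bool)
    edges = canny(padded, sigma=config.canny_sigma,
                  low_threshold=config.canny_low * gmax,
                  high_threshold=config.canny_high * gmax)
    if edges.any():
        edges = closing(edges, footprint)
    return edges[:, _EDGE_PAD:-_EDGE_PAD]


def detect_outer_contour(seq: FrameSequence,
                         config: PipelineConfig | None = None) -> np.ndarray:
    """Extract the anterior contour L_T as an (I, N) array of row positions.

    Per frame: Canny edge map, morphological close, then the topmost edge
    row of each column. Columns without an edge pixel are filled by linear
    interpolation from their nearest detected neighbours (constant
    extrapolation at the image edges). Raises `ContourNotFoundError` for a
    frame where fewer than 10% of columns contain an edge.
    """
    config = config or PipelineConfig()
    config.validate()
    n_frames, height, width = seq.frames.shape
    footprint = disk(config.close_radius)
    all_cols = np.arange(width)
    l_t = np.empty((n_frames, width), dtype=np.float64)

    min_span = MIN_EDGE_COLUMN_FRACTION * width
    for i in range(n_frames):
        img01 = seq.frames[i].astype(np.float64) / 255.0
        edges = _frame_edges(img01, config, footprint)
        if edges.any():
            # keep only edge components that span a substantial column
            # range: the corneal band's boundary lines, not noise specks
            labels, n_labels = ndimage.label(edges, np.ones((3, 3), int))
            keep = np.zeros(n_labels + 1, dtype=bool)
            for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
                if sl is not None and sl[1].stop - sl[1].start >= min_span:
                    keep[lab] = True
            edges = keep[labels]
        has_edge = edges.any(axis=0)
        n_edge_cols = int(has_edge.sum())
        if n_edge_cols < MIN_EDGE_COLUMN_FRACTION * width:
            raise ContourNotFoundError(i, n_edge_cols, width)
        # Topmost True row, shifted by half a pixel: the detector marks the
        # edge at the dark/bright transition centre, i.e. half a pixel above
        # the first bright band row the contour refers to.
        top = edges.argmax(axis=0).astype(np.float64) + 0.5
        cols = all_cols[has_edge]
        l_t[i] = np.interp(all_cols, cols, top[has_edge])

    return l_t


def decompose_contour(l_t: np.ndarray,
                      config: PipelineConfig | None = None) -> ContourSet:
    """Split L_T into static shape, corneal deformation and eyeball reaction.

    The eyeball reaction at each border is the median, over the outermost
    ``border_width`` columns of that side, of the contour's displacement
    from its frame-0 position; interior columns get the linear interpolation
    between the left and right border values. The corneal deformation is
    the remainder, so L_TD + L_TR + L_TO reconstructs L_T to machine
    precision by construction.
    """
    config = config or PipelineConfig()
    config.validate()
    l_t = np.asarray(l_t, dtype=np.float64)
    if not np.isfinite(l_t).all():
        raise ValueError("L_T must be finite everywhere")
    n_frames, n_cols = l_t.shape
    k = min(config.border_width, n_cols // 2)

    base = l_t[0]
    shift = l_t - base[None, :]
    left = np.median(shift[:, :k], axis=1)
    right = np.median(shift[:, n_cols - k:], axis=1)

    w = np.linspace(0.0, 1.0, n_cols)
    l_to = left[:, None] * (1.0 - w)[None, :] + right[:, None] * w[None, :]
    l_td = np.broadcast_to(base, l_t.shape).copy()
    l_tr = l_t - l_td - l_to
    return ContourSet(l_t=l_t, l_td=l_td, l_tr=l_tr, l_to=l_to)


def extract_contours(seq: FrameSequence,
                     config: PipelineConfig | None = None) -> ContourSet:
    """Full pre-processing: 3-D median, contour detection, decomposition."""
    config = config or PipelineConfig()
    filtered = median_filter_3d(seq, config.median_mask)
    l_t = detect_outer_contour(filtered, config)
    return decompose_contour(l_t, config)
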