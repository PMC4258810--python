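"""The three deformation parameters measured on the decomposed contour.

Given the contour decomposition L_T = L_TD + L_TR + L_TO, this module
measures, per frame:

* the corneal reaction against its mirrored static position — the
  deformation support is found by thresholding L_TR at the contour noise
  amplitude p_r and median-filtering the binary map; the contour over that
  range is reflected across the chord (symmetry axis) through the range's
  extreme points c1, c2, and the area L_g between the mirrored curve and
  the deformation quantifies how far the cornea's reaction falls short of
  its inverted static shape;

* corneal length changes — polyline arc lengths of the deformed contour
  (L_DDTR), of the mirrored contour over the same range (L_DDK), and the
  chord between the range's endpoints (L_DDS); raw polyline sums are very
  noise-sensitive (each pixel of jitter inflates every segment), so both
  curves are also smoothed with a degree-8 least-squares polynomial before
  measuring (L_AATR, L_AAK);

* the deformation-length-to-amplitude ratio L_DDS/TR — the chord length
  divided by the frame's peak deformation amplitude. Its time course shows
  two peaks, one on each side of the highest-concavity frame, where the
  deformed zone is longest relative to how deep it is — i.e. where the
  cornea is flattest: the applanation instants a1 and a2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy import ndimage

from .contour_pipeline import ContourSet, PipelineConfig
from .errors import (ConfigurationError, DegenerateRangeError,
                     InsufficientDeformationError)

logger = logging.getLogger(__name__)


@dataclass
class DeformationSupport:
    """Binary deformation maps and the per-frame deformation column range.

    ``l_w`` is the raw thresholded map (L_TR > p_r), ``l_s`` its 3x3 median;
    ``ranges[i]`` is the (first, last) column of the largest connected run
    of ones in frame i, or None when the frame shows no deformation.
    """

    l_w: np.ndarray
    l_s: np.ndarray
    ranges: list[tuple[int, int] | None]


@dataclass
class ReflectionResult:
    """Contour mirrored across the symmetry axis of one frame.

    ``c1``/``c2`` are (row, column) endpoints of the deformation range on
    the contour; the axis is the chord through them. ``l_k`` is the full
    contour row with the range replaced by its point reflection across the
    axis, resampled onto integer columns; ``l_g`` is the trapezoidal area
    (px^2) between the mirrored curve and the deformation over the range,
    both taken after removal of the static component.
    """

    frame: int
    c1: tuple[float, int]
    c2: tuple[float, int]
    axis_point: np.ndarray
    axis_direction: np.ndarray
    l_k: np.ndarray
    l_g: float


@dataclass
class ParameterSeries:
    """Per-frame parameter traces; NaN marks frames where a value is undefined."""

    l_ddtr: np.ndarray
    l_ddk: np.ndarray
    l_dds: np.ndarray
    l_aatr: np.ndarray
    l_aak: np.ndarray
    ratio: np.ndarray
    amplitude: np.ndarray
    smoothing_fallback: np.ndarray
    a1: int | None = None
    a2: int | None = None
    i_peak: int | None = None

    @property
    def n_frames(self) -> int:
        return self.l_ddtr.shape[0]


def _largest_run(row: np.ndarray, center: float) -> tuple[int, int] | None:
    """Largest connected run of ones; ties go to the run nearest ``center``,
    then to the leftmost."""
    padded = np.concatenate(([0], row.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    if starts.size == 0:
        return None
    lengths = ends - starts
    best_len = lengths.max()
    cand = np.flatnonzero(lengths == best_len)
    if cand.size > 1:
        mid = (starts[cand] + ends[cand]) / 2.0
        dist = np.abs(mid - center)
        cand = cand[dist == dist.min()]
    j = cand[0]  # leftmost among remaining ties
    return int(starts[j]), int(ends[j])


def compute_support(l_tr: np.ndarray, p_r: float = 2.0,
                    mask: tuple[int, int] = (3, 3)) -> DeformationSupport:
    """Threshold the deformation map at ``p_r`` pixels and denoise it.

    The threshold sits at the noise amplitude of the extracted contour
    (about two pixels), so the binary map L_W marks genuine deformation
    only; a 2-D median over the (frame, column) plane removes isolated
    speckle, and the largest connected run of ones per frame delimits the
    deformation column range.
    """
    if p_r <= 0:
        raise ConfigurationError(f"p_r must be > 0, got {p_r}")
    if any(m <= 0 or m % 2 == 0 for m in mask):
        raise ConfigurationError(
            f"support median mask must be odd and positive, got {mask}")
    l_tr = np.asarray(l_tr, dtype=np.float64)
    l_w = (l_tr > p_r).astype(np.uint8)
    l_s = ndimage.median_filter(l_w, size=mask, mode="nearest")
    center = (l_tr.shape[1] - 1) / 2.0
    ranges = [_largest_run(l_s[i], center) for i in range(l_tr.shape[0])]
    return DeformationSupport(l_w=l_w, l_s=l_s, ranges=ranges)


def reflect_across_chord(rows: np.ndarray, cols: np.ndarray,
                         p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Point-reflect contour samples (col, row) across the line p1–p2,
    then resample the mirrored polyline back onto the input columns.

    p1, p2 and the returned values are in (column, row) coordinates. The
    line's endpoints are fixed points of the reflection, so the resampled
    curve meets the original contour at the range boundaries.
    """
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    u = p2 - p1
    norm = np.hypot(*u)
    if norm == 0:
        raise DegenerateRangeError("axis endpoints coincide")
    u = u / norm
    pts = np.stack([cols, rows], axis=1) - p1
    proj = pts @ u
    mirrored = 2.0 * (proj[:, None] * u[None, :]) - pts + p1
    order = np.argsort(mirrored[:, 0], kind="stable")
    return np.interp(cols, mirrored[order, 0], mirrored[order, 1])


def compute_reflection(contours: ContourSet, support: DeformationSupport,
                       frame: int) -> ReflectionResult:
    """Mirror the contour of one frame across its deformation-range chord."""
    rng = support.ranges[frame]
    if rng is None or rng[1] - rng[0] < 2:
        raise DegenerateRangeError(
            f"frame {frame}: deformation range "
            f"{rng} spans fewer than 3 columns")
    c1_col, c2_col = rng
    l_t_row = contours.l_t[frame]
    m1, m2 = l_t_row[c1_col], l_t_row[c2_col]
    cols = np.arange(c1_col, c2_col + 1, dtype=np.float64)
    p1 = np.array([c1_col, m1], dtype=np.float64)
    p2 = np.array([c2_col, m2], dtype=np.float64)
    reflected = reflect_across_chord(l_t_row[c1_col:c2_col + 1], cols, p1, p2)

    l_k = l_t_row.astype(np.float64).copy()
    l_k[c1_col:c2_col + 1] = reflected

    mirrored_dyn = reflected - contours.l_td[0, c1_col:c2_col + 1]
    deformation = contours.l_tr[frame, c1_col:c2_col + 1]
    l_g = float(np.trapezoid(np.abs(mirrored_dyn - deformation)))

    u = (p2 - p1) / np.hypot(*(p2 - p1))
    return ReflectionResult(frame=frame, c1=(float(m1), c1_col),
                            c2=(float(m2), c2_col), axis_point=p1,
                            axis_direction=u, l_k=l_k, l_g=l_g)


def polyline_length(rows: np.ndarray) -> float:
    """Arc length of a per-column polyline with unit column spacing."""
    d = np.diff(np.asarray(rows, dtype=np.float64))
    return float(np.sqrt(1.0 + d * d).sum())


def compute_lengths(contours: ContourSet, l_k: np.ndarray,
                    support: DeformationSupport,
                    frame: int) -> tuple[float, float, float]:
    """Arc lengths L_DDTR, L_DDK and chord L_DDS over the deformation range.

    L_DDTR is measured on the deformed contour with the whole-eye motion
    removed (L_TD + L_TR), L_DDK on the mirrored contour, and L_DDS is the
    Euclidean distance between the range's extreme contour points.
    """
    rng = support.ranges[frame]
    if rng is None:
        return (np.nan, np.nan, np.nan)
    c1_col, c2_col = rng
    sl = slice(c1_col, c2_col + 1)
    deformed = contours.l_td[0, sl] + contours.l_tr[frame, sl]
    l_ddtr = polyline_length(deformed)
    l_ddk = polyline_length(l_k[sl])
    l_t_row = contours.l_t[frame]
    l_dds = float(np.hypot(c2_col - c1_col,
                           l_t_row[c2_col] - l_t_row[c1_col]))
    return (l_ddtr, l_ddk, l_dds)


def _fit_polyline_length(cols: np.ndarray, rows: np.ndarray,
                         degree: int) -> float | None:
    """Length of the least-squares polynomial fit, or None if the fit is
    rank-deficient. Columns are mapped to [-1, 1] for conditioning."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        poly = Polynomial.fit(cols, rows, degree)
        if any(issubclass(w.category, np.exceptions.RankWarning)
               for w in caught):
            return None
    return polyline_length(poly(cols))


def fit_smoothed_lengths(contours: ContourSet, l_k: np.ndarray,
                         support: DeformationSupport, frame: int,
                         degree: int = 8) -> tuple[float, float, bool]:
    """Arc lengths L_AATR, L_AAK after degree-8 polynomial smoothing.

    Raw polyline sums amplify contour noise (every segment picks up
    sqrt(1 + delta^2) inflation); fitting a low-order polynomial over the
    range first recovers the underlying smooth length. When the range is
    too narrow for the requested degree (fewer than degree + 2 columns) or
    the fit is rank-deficient, the raw lengths are returned and the frame
    is flagged as a fallback.
    """
    rng = support.ranges[frame]
    if rng is None:
        return (np.nan, np.nan, False)
    c1_col, c2_col = rng
    raw_tr, raw_k, _ = compute_lengths(contours, l_k, support, frame)
    if c2_col - c1_col + 1 < degree + 2:
        logger.warning("frame %d: range width %d too narrow for degree-%d "
                       "smoothing; falling back to raw lengths",
                       frame, c2_col - c1_col + 1, degree)
        return (raw_tr, raw_k, True)
    sl = slice(c1_col, c2_col + 1)
    cols = np.arange(c1_col, c2_col + 1, dtype=np.float64)
    deformed = contours.l_td[0, sl] + contours.l_tr[frame, sl]
    len_tr = _fit_polyline_length(cols, deformed, degree)
    len_k = _fit_polyline_length(cols, l_k[sl], degree)
    if len_tr is None or len_k is None:
        logger.warning("frame %d: rank-deficient polynomial fit; falling "
                       "back to raw lengths", frame)
        return (raw_tr, raw_k, True)
    return (len_tr, len_k, False)


def compute_ratio(l_dds: np.ndarray, l_tr: np.ndarray,
                  eps: float = 1.0) -> np.ndarray:
    """Deformation-length-to-amplitude ratio L_DDS/TR per frame.

    The denominator is the frame's peak deformation amplitude
    max_n L_TR(n, i); the ratio is left undefined (NaN) where that
    amplitude does not exceed ``eps`` pixels, guarding against division by
    noise-level amplitudes.
    """
    l_dds = np.asarray(l_dds, dtype=np.float64)
    amplitude = np.asarray(l_tr, dtype=np.float64).max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((amplitude > eps) & np.isfinite(l_dds),
                         l_dds / amplitude, np.nan)
    return ratio


def detect_applanation(ratio: np.ndarray, l_tr: np.ndarray
                       ) -> tuple[int | None, int | None, int]:
    """Locate the applanation frames a1, a2 from the ratio's two peaks.

    The highest-concavity frame i_peak is where the deformation amplitude
    is largest; a1 and a2 are the frames of maximum ratio before and after
    it. Global maxima are used on each side (robust to the plateau the
    ratio shows between the applanations); ties are broken toward the frame
    closest to i_peak. A side with no defined ratio yields None with a
    warning. Returns (a1, a2, i_peak).
    """
    ratio = np.asarray(ratio, dtype=np.float64)
    defined = np.flatnonzero(np.isfinite(ratio))
    if defined.size < 5:
        raise InsufficientDeformationError(
            f"ratio is defined on only {defined.size} frame(s); at least 5 "
            "are needed to locate applanation peaks")
    amplitude = np.asarray(l_tr, dtype=np.float64).max(axis=1)
    # integer contour quantization can plateau the amplitude at its
    # maximum; take the middle of the plateau as the highest-concavity frame
    at_max = np.flatnonzero(amplitude == amplitude.max())
    i_peak = int(at_max[at_max.size // 2])

    def side_peak(mask: np.ndarray, prefer_late: bool) -> int | None:
        idx = defined[mask]
        if idx.size == 0:
            return None
        vals = ratio[idx]
        best = idx[vals == vals.max()]
        return int(best[-1] if prefer_late else best[0])

    a1 = side_peak(defined < i_peak, prefer_late=True)
    a2 = side_peak(defined > i_peak, prefer_late=False)
    if a1 is None:
        logger.warning("no defined ratio before the highest-concavity frame "
                       "%d; a1 undetermined", i_peak)
    if a2 is None:
        logger.warning("no defined ratio after the highest-concavity frame "
                       "%d; a2 undetermined", i_peak)
    return a1, a2, i_peak


def compute_parameters(contours: ContourSet,
                       config: PipelineConfig | None = None
                       ) -> tuple[ParameterSeries, DeformationSupport]:
    """Run support → reflection → lengths → ratio → peaks over all frames.

    Frames without a usable deformation range carry NaN in every series. A
    sequence with no (or too little) deformation yields a clean result with
    a1 = a2 = i_peak = None rather than an error.
    """
    config = config or PipelineConfig()
    config.validate()
    n_frames = contours.n_frames
    support = compute_support(contours.l_tr, config.p_r,
                              config.support_median_mask)

    nan = np.full(n_frames, np.nan)
    series = ParameterSeries(
        l_ddtr=nan.copy(), l_ddk=nan.copy(), l_dds=nan.copy(),
        l_aatr=nan.copy(), l_aak=nan.copy(), ratio=nan.copy(),
        amplitude=contours.l_tr.max(axis=1),
        smoothing_fallback=np.zeros(n_frames, dtype=bool))

    for i in range(n_frames):
        rng = support.ranges[i]
        if rng is None or rng[1] - rng[0] < 2:
            continue
        refl = compute_reflection(contours, support, i)
        (series.l_ddtr[i], series.l_ddk[i],
         series.l_dds[i]) = compute_lengths(contours, refl.l_k, support, i)
        (series.l_aatr[i], series.l_aak[i],
         series.smoothing_fallback[i]) = fit_smoothed_lengths(
            contours, refl.l_k, support, i, config.poly_degree)

    series.ratio = compute_ratio(series.l_dds, contours.l_tr,
                                 config.ratio_min_amplitude)
    if np.isfinite(series.ratio).sum() >= 5:
        series.a1, series.a2, series.i_peak = detect_applanation(
            series.ratio, contours.l_tr)
    else:
        logger.info("no deformation detected: ratio defined on %d frame(s)",
                    int(np.isfinite(series.ratio).sum()))
    return series, support


def threshold_sweep(contours: ContourSet, p_r_values,
                    config: PipelineConfig | None = None) -> pd.DataFrame:
    """Re-run the parameter pipeline for each binarization threshold.

    Returns a table with columns ``p_r``, ``a1``, ``a2``; a threshold whose
    run fails (or finds no deformation) yields a row with missing peaks and
    a logged reason.
    """
    from dataclasses import replace

    config = config or PipelineConfig()
    rows = []
    for p_r in p_r_values:
        try:
            series, _ = compute_parameters(contours, replace(config, p_r=p_r))
            rows.append({"p_r": p_r, "a1": series.a1, "a2": series.a2})
        except Exception as exc:  # noqa: BLE001 - per-threshold isolation
            logger.warning("threshold sweep failed at p_r=%s: %s", p_r, exc)
            rows.append({"p_r": p_r, "a1": None, "a2": None})
    return pd.DataFrame(rows, columns=["p_r", "a1", "a2"])
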