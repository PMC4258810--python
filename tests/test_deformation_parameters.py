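"""Support maps, reflection geometry, arc lengths, ratio and peak detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.integrate import quad

from corneodeform import (PhantomConfig, PipelineConfig, compute_parameters,
                          compute_ratio, compute_reflection, compute_support,
                          detect_applanation, threshold_sweep, write_results)
from corneodeform.contour_pipeline import ContourSet
from corneodeform.deformation_parameters import (DeformationSupport,
                                                 compute_lengths,
                                                 fit_smoothed_lengths,
                                                 polyline_length,
                                                 reflect_across_chord)
from corneodeform.errors import (ConfigurationError, DegenerateRangeError,
                                 InsufficientDeformationError)
from corneodeform.io_formats import read_parameter_table

from conftest import analytic_contours


def make_contours(rows: np.ndarray, base: np.ndarray | None = None) -> ContourSet:
    """ContourSet from explicit contour rows; frame 0 is the static shape."""
    rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    base = rows[0] if base is None else np.asarray(base, dtype=np.float64)
    l_td = np.broadcast_to(base, rows.shape).copy()
    l_to = np.zeros_like(rows)
    return ContourSet(l_t=rows, l_td=l_td, l_tr=rows - l_td, l_to=l_to)


def manual_support(n_frames: int, n_cols: int,
                   ranges: dict[int, tuple[int, int]]) -> DeformationSupport:
    l_s = np.zeros((n_frames, n_cols), dtype=np.uint8)
    range_list: list = [None] * n_frames
    for frame, (c1, c2) in ranges.items():
        l_s[frame, c1:c2 + 1] = 1
        range_list[frame] = (c1, c2)
    return DeformationSupport(l_w=l_s.copy(), l_s=l_s, ranges=range_list)


# ---------------------------------------------------------------------------
# support maps
# ---------------------------------------------------------------------------

def test_binarization_thresholds_row():
    l_tr = np.array([[0, 1, 3, 5, 3, 1, 0]], dtype=float)
    support = compute_support(l_tr, p_r=2.0)
    assert support.l_w.tolist() == [[0, 0, 1, 1, 1, 0, 0]]


def test_zero_deformation_has_no_ranges():
    support = compute_support(np.zeros((4, 20)), p_r=2.0)
    assert (support.l_s == 0).all()
    assert support.ranges == [None] * 4


def brute_force_median_2d(grid: np.ndarray) -> np.ndarray:
    padded = np.pad(grid, 1, mode="edge")
    out = np.empty_like(grid)
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            out[i, j] = np.sort(padded[i:i + 3, j:j + 3].ravel())[4]
    return out


def test_support_median_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    l_w = rng.integers(0, 2, size=(7, 7)).astype(float)
    support = compute_support(l_w * 10.0, p_r=2.0)  # >2 exactly where l_w=1
    assert np.array_equal(support.l_s, brute_force_median_2d(l_w.astype(np.uint8)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(arrays(np.uint8, (6, 8), elements=st.integers(0, 1)))
def test_support_median_majority_property(l_w):
    """l_s = 1 at a cell iff its replicate-padded 3x3 window holds >= 5 ones."""
    support = compute_support(l_w * 10.0, p_r=2.0)
    assert np.array_equal(support.l_s, brute_force_median_2d(l_w))


def test_largest_run_tie_breaks_to_center_then_left():
    # two 5-wide runs, equidistant from the center column -> leftmost
    row = np.zeros((3, 19))
    row[:, 2:7] = 5.0
    row[:, 12:17] = 5.0
    assert compute_support(row, p_r=2.0).ranges[1] == (2, 6)
    # off-center tie in length -> the run nearest the center wins
    row2 = np.zeros((3, 21))
    row2[:, 1:6] = 5.0
    row2[:, 12:17] = 5.0
    assert compute_support(row2, p_r=2.0).ranges[1] == (12, 16)


def test_nonpositive_threshold_rejected():
    with pytest.raises(ConfigurationError):
        compute_support(np.zeros((2, 5)), p_r=0.0)


# ---------------------------------------------------------------------------
# reflection
# ---------------------------------------------------------------------------

def test_reflection_across_horizontal_axis_closed_form():
    rows = np.full((2, 21), 50.0)
    rows[1, 6:15] = 50.0 + np.array([0, 3, 6, 8, 9, 8, 6, 3, 0], dtype=float)
    contours = make_contours(rows)
    support = manual_support(2, 21, {1: (6, 14)})
    refl = compute_reflection(contours, support, 1)
    expected = 2 * 50.0 - rows[1, 6:15]
    assert np.abs(refl.l_k[6:15] - expected).max() < 1e-9
    assert np.array_equal(refl.l_k[:6], rows[1, :6])  # untouched outside


def test_straight_line_contour_is_fixed_by_reflection():
    cols = np.arange(30, dtype=float)
    line = 40.0 + 0.3 * cols
    contours = make_contours(np.stack([line, line]))
    support = manual_support(2, 30, {1: (5, 25)})
    refl = compute_reflection(contours, support, 1)
    assert np.abs(refl.l_k - line).max() < 1e-9
    assert refl.l_g == pytest.approx(0.0, abs=1e-9)


def rotate_mirror_rotate(points, p1, p2):
    """Independent reflection oracle: translate to p1, rotate the axis onto
    the x-axis, mirror y, rotate and translate back."""
    theta = np.arctan2(p2[1] - p1[1], p2[0] - p1[0])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    local = (points - p1) @ rot.T
    local[:, 1] *= -1
    return local @ np.array([[c, -s], [s, c]]).T + p1


def test_tilted_axis_matches_geometric_oracle():
    cols = np.arange(10.0, 15.0)
    rows = np.array([52.0, 55.0, 57.0, 54.0, 58.0])
    contours = make_contours(np.stack([np.full(20, 50.0)] * 2))
    contours.l_t[1, 10:15] = rows
    contours.l_tr[1] = contours.l_t[1] - contours.l_td[0]
    support = manual_support(2, 20, {1: (10, 14)})
    refl = compute_reflection(contours, support, 1)

    pts = np.stack([cols, rows], axis=1)
    mirrored = rotate_mirror_rotate(pts, pts[0], pts[-1])
    order = np.argsort(mirrored[:, 0])
    expected = np.interp(cols, mirrored[order, 0], mirrored[order, 1])
    assert np.abs(refl.l_k[10:15] - expected).max() < 1e-9


def test_double_reflection_recovers_contour(default_contours):
    series, support = compute_parameters(default_contours)
    i = series.i_peak
    refl = compute_reflection(default_contours, support, i)
    c1, c2 = support.ranges[i]
    cols = np.arange(c1, c2 + 1, dtype=float)
    p1 = np.array([c1, default_contours.l_t[i, c1]])
    p2 = np.array([c2, default_contours.l_t[i, c2]])
    back = reflect_across_chord(refl.l_k[c1:c2 + 1], cols, p1, p2)
    assert np.abs(back - default_contours.l_t[i, c1:c2 + 1]).max() <= 0.5


def test_axis_endpoints_fixed_by_reflection(default_contours):
    series, support = compute_parameters(default_contours)
    i = series.i_peak
    refl = compute_reflection(default_contours, support, i)
    c1, c2 = support.ranges[i]
    assert refl.l_k[c1] == pytest.approx(default_contours.l_t[i, c1], abs=0.5)
    assert refl.l_k[c2] == pytest.approx(default_contours.l_t[i, c2], abs=0.5)


def test_degenerate_range_rejected():
    contours = make_contours(np.full((2, 10), 50.0))
    support = manual_support(2, 10, {1: (4, 5)})
    with pytest.raises(DegenerateRangeError):
        compute_reflection(contours, support, 1)


# ---------------------------------------------------------------------------
# lengths
# ---------------------------------------------------------------------------

def test_flat_contour_lengths():
    contours = make_contours(np.full((2, 20), 50.0))
    support = manual_support(2, 20, {1: (3, 13)})
    l_ddtr, l_ddk, l_dds = compute_lengths(contours, contours.l_t[1],
                                           support, 1)
    assert l_ddtr == pytest.approx(10.0)
    assert l_ddk == pytest.approx(10.0)
    assert l_dds == pytest.approx(10.0)


def test_pythagorean_segments_exact():
    # rise of 4 px over 3 columns (each segment is a 1-4/3-5/3 triangle),
    # then flat: polyline length = 3*(5/3) + 7 = 12
    row = np.full(11, 50.0)
    row[:4] = 50.0 + np.array([0.0, 4 / 3, 8 / 3, 4.0])
    row[4:] = 54.0
    contours = make_contours(np.stack([np.full(11, 50.0), row]))
    support = manual_support(2, 11, {1: (0, 10)})
    l_ddtr, _, l_dds = compute_lengths(contours, contours.l_t[1], support, 1)
    assert l_ddtr == pytest.approx(5.0 + 7.0)
    assert l_dds == pytest.approx(np.hypot(10.0, 4.0))


def test_polyline_length_matches_quadrature_on_half_sine():
    amp, width = 10.0, 100
    cols = np.arange(width + 1, dtype=float)
    rows = amp * np.sin(np.pi * cols / width)
    poly = polyline_length(rows)
    integral, _ = quad(
        lambda x: np.hypot(1.0, amp * np.pi / width * np.cos(np.pi * x / width)),
        0.0, float(width), limit=200)
    assert abs(poly - integral) / integral < 1e-3


def test_arc_never_shorter_than_chord(default_contours):
    series, _ = compute_parameters(default_contours)
    ok = np.isfinite(series.l_ddtr)
    assert (series.l_ddtr[ok] + 1e-9 >= series.l_dds[ok]).all()
    assert (series.l_ddk[ok] + 1e-9 >= series.l_dds[ok]).all()


# ---------------------------------------------------------------------------
# polynomial smoothing
# ---------------------------------------------------------------------------

def test_cubic_contour_reproduced_by_degree8_fit():
    cols = np.arange(40, dtype=float)
    cubic = 50.0 + 0.002 * (cols - 20) ** 3 + 0.05 * (cols - 20)
    contours = make_contours(np.stack([np.full(40, 50.0), cubic]))
    support = manual_support(2, 40, {1: (0, 39)})
    l_ddtr, _, _ = compute_lengths(contours, contours.l_t[1], support, 1)
    l_aatr, _, fallback = fit_smoothed_lengths(contours, contours.l_t[1],
                                               support, 1)
    assert not fallback
    assert l_aatr == pytest.approx(l_ddtr, abs=1e-6)


def test_smoothing_beats_raw_length_on_noisy_line():
    rng = np.random.default_rng(11)
    width = 100
    noisy = 60.0 + rng.normal(0, 2.0, size=width + 1)
    contours = make_contours(np.stack([np.full(width + 1, 60.0), noisy]))
    support = manual_support(2, width + 1, {1: (0, width)})
    l_ddtr, _, _ = compute_lengths(contours, contours.l_t[1], support, 1)
    l_aatr, _, _ = fit_smoothed_lengths(contours, contours.l_t[1], support, 1)
    true_len = float(width)
    assert abs(l_aatr - true_len) < abs(l_ddtr - true_len)


def test_narrow_range_falls_back_to_raw_lengths():
    rows = np.full((2, 12), 50.0)
    rows[1, 2:10] = 55.0
    contours = make_contours(rows)
    support = manual_support(2, 12, {1: (2, 9)})  # width 8 < degree + 2
    raw_tr, raw_k, _ = compute_lengths(contours, contours.l_t[1], support, 1)
    l_aatr, l_aak, fallback = fit_smoothed_lengths(contours, contours.l_t[1],
                                                   support, 1)
    assert fallback
    assert l_aatr == pytest.approx(raw_tr)
    assert l_aak == pytest.approx(raw_k)


# ---------------------------------------------------------------------------
# ratio and applanation peaks
# ---------------------------------------------------------------------------

def test_rectangular_deformation_gives_constant_ratio():
    n_frames, n_cols = 8, 300
    l_tr = np.zeros((n_frames, n_cols))
    l_tr[1:, 100:201] = 10.0
    l_t = 100.0 + l_tr
    contours = ContourSet(l_t=l_t, l_td=np.full_like(l_t, 100.0),
                          l_tr=l_tr, l_to=np.zeros_like(l_t))
    series, support = compute_parameters(contours)
    assert support.ranges[4] == (100, 200)
    defined = np.isfinite(series.ratio)
    assert defined[1:].all() and not defined[0]
    # interior frames see the full 100-column chord over amplitude 10; the
    # first/last deformed frames lose one corner column to the 3x3 median
    assert np.allclose(series.ratio[2:7], 10.0)
    assert (series.ratio[defined] >= 9.8 - 1e-9).all()
    assert (series.ratio[defined] <= 10.0 + 1e-9).all()


def test_ratio_undefined_below_amplitude_guard():
    l_dds = np.array([10.0, 10.0, 10.0])
    l_tr = np.array([[0.5], [0.9], [3.0]])
    ratio = compute_ratio(l_dds, l_tr, eps=1.0)
    assert np.isnan(ratio[0]) and np.isnan(ratio[1])
    assert ratio[2] == pytest.approx(10.0 / 3.0)


def test_ratio_matches_recomputation_from_exported_table(tmp_path,
                                                         default_contours):
    series, _ = compute_parameters(default_contours)
    paths = write_results(default_contours, series, tmp_path)
    table = read_parameter_table(paths["parameters"])
    ratio = table["ratio_DDS_TR"].to_numpy()
    recomputed = table["L_DDS"].to_numpy() / table["amplitude"].to_numpy()
    defined = np.isfinite(ratio)
    assert defined.any()
    assert np.allclose(ratio[defined], recomputed[defined], rtol=0, atol=0)


def test_symmetric_envelope_gives_symmetric_peaks(noise_free_contours):
    # symmetric amplitude envelope: the highest-concavity frame lies within
    # one frame of the midpoint between the two applanation peaks
    series, _ = compute_parameters(noise_free_contours)
    assert series.a1 is not None and series.a2 is not None
    assert abs((series.a1 + series.a2) / 2 - series.i_peak) <= 1


def test_default_phantom_peaks_near_analytic_truth(default_contours,
                                                   default_phantom):
    _, truth = default_phantom
    series, _ = compute_parameters(default_contours)
    a1s, a2s = truth.applanation_frames
    assert abs(series.a1 - a1s) <= 2
    assert abs(series.a2 - a2s) <= 2


def test_reaction_stays_below_mirrored_static_shape():
    # shallow, wide indentation: its amplitude is smaller than the depth of
    # the mirrored static arc, so the mirrored curve lies below (larger row
    # than) the deformation over the whole range at the deepest frame
    cfg = PhantomConfig(peak_amplitude=6.0, noise_sd=0.0,
                        contour_jitter_sd=0.0, seed=0)
    contours = analytic_contours(cfg)
    series, support = compute_parameters(contours)
    i = int(np.nanargmax(contours.l_tr.max(axis=1)))
    refl = compute_reflection(contours, support, i)
    c1, c2 = support.ranges[i]
    sl = slice(c1, c2 + 1)
    mirrored_dyn = refl.l_k[sl] - contours.l_td[0, sl]
    assert (mirrored_dyn - contours.l_tr[i, sl] > 0).all()


def test_insufficient_deformation_raises():
    ratio = np.full(10, np.nan)
    ratio[[3, 5, 7]] = 2.0
    with pytest.raises(InsufficientDeformationError):
        detect_applanation(ratio, np.ones((10, 4)))


def test_zero_deformation_yields_clean_empty_result():
    cfg = PhantomConfig(peak_amplitude=0.0, eye_displacement_max=0.0,
                        noise_sd=0.0, contour_jitter_sd=0.0, seed=0)
    series, support = compute_parameters(analytic_contours(cfg))
    assert series.a1 is None and series.a2 is None and series.i_peak is None
    assert all(r is None for r in support.ranges)
    assert np.isnan(series.l_ddtr).all()


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

def test_empty_sweep_gives_empty_table(default_contours):
    table = threshold_sweep(default_contours, [])
    assert len(table) == 0
    assert list(table.columns) == ["p_r", "a1", "a2"]


def test_sweep_trend_a1_up_a2_down(noise_free_contours):
    table = threshold_sweep(noise_free_contours,
                            [0.1, 0.5, 1.0, 2.0, 4.0, 6.0])
    a1 = table["a1"].to_numpy(dtype=float)
    a2 = table["a2"].to_numpy(dtype=float)
    assert np.isfinite(a1).all() and np.isfinite(a2).all()
    assert (np.diff(a1) >= 0).all()
    assert (np.diff(a2) <= 0).all()
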