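"""Metric closed forms, set-arithmetic oracles and aggregation behavior."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from echosynth.errors import DegenerateInputError, ValidationError
from echosynth.metrics import (
    MetricsRecord,
    aggregate,
    bias,
    compare_methods,
    dice,
    evaluate_pair,
    extract_contours,
    mad,
    mean_distance,
    simplicity,
)


def _disk(r, size=None, center=None):
    size = size or int(2 * r + 28)
    cy = cx = size / 2 if center is None else center
    yy, xx = np.mgrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


mask8 = arrays(np.bool_, (8, 8), elements=st.booleans())


@given(mask8, mask8)
@settings(max_examples=200, deadline=None)
def test_dice_matches_exhaustive_set_oracle_and_is_symmetric(a, b):
    inter = sum(1 for i in range(8) for j in range(8) if a[i, j] and b[i, j])
    na = int(a.sum())
    nb = int(b.sum())
    expected = 0.0 if na + nb == 0 else 200.0 * inter / (na + nb)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert dice(a, b) == expected == dice(b, a)
    if na:
        assert dice(a, a) == 100.0


@given(mask8, mask8)
@settings(max_examples=200, deadline=None)
def test_bias_matches_oracle_is_antisymmetric_and_bounded(a, b):
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        with pytest.raises(DegenerateInputError):
            bias(a, b)
        return
    expected = 200.0 * (na - nb) / (na + nb)
    assert bias(a, b) == pytest.approx(expected)
    assert bias(b, a) == pytest.approx(-expected)
    assert abs(bias(a, b)) <= 200.0


def test_dice_closed_form_examples():
    a = np.zeros((8, 8), bool)
    a[2:4, 2:4] = True
    b = np.zeros((8, 8), bool)
    b[2:4, 3:5] = True
    assert dice(a, b) == 50.0  # 200 * 2 / (4 + 4)
    assert dice(a, np.zeros_like(a)) == 0.0
    with pytest.warns(UserWarning):
        assert dice(np.zeros_like(a), np.zeros_like(a)) == 0.0
    with pytest.raises(ValidationError):
        dice(a, np.zeros((4, 4), bool))


def test_bias_closed_form_example():
    p = np.zeros((30, 30), bool)
    p[:10, :] = True  # 300 px
    r = np.zeros((30, 30), bool)
    r[:10, :10] = True  # 100 px
    assert bias(p, r) == 100.0  # 200 * 200 / 400


def test_simplicity_of_canonical_shapes():
    assert simplicity(np.zeros((16, 16), bool)) == 0.0
    assert abs(simplicity(_disk(50)) - 1.0) < 0.02
    strip = np.zeros((20, 120), bool)
    strip[10, 10:110] = True
    analytic = np.sqrt(400 * np.pi) / 202  # 1 x 100 px rectangle boundary
    assert abs(simplicity(strip) - analytic) / analytic < 0.03


def test_simplicity_bounded_and_monotone_under_elongation():
    values = []
    for elong in (1.0, 1.5, 2.5, 4.0, 6.0):
        # constant-area ellipses, aspect ratio elong**2
        yy, xx = np.mgrid[:160, :160]
        m = ((yy - 80) / (25.0 / elong)) ** 2 + ((xx - 80) / (25.0 * elong)) ** 2 <= 1
        s = simplicity(m)
        assert s <= 1.03
        values.append(s)
    assert all(a > b for a, b in zip(values, values[1:]))


def test_contours_are_closed_subpixel_polylines():
    cs = extract_contours(_disk(20))
    assert len(cs) == 1
    c = cs[0]
    assert len(c) >= 3
    assert np.linalg.norm(c[0] - c[-1]) < 1.5


def test_mean_distance_concentric_and_translated_shapes():
    inner, outer = _disk(40, size=128), _disk(50, size=128)
    assert abs(mean_distance(inner, outer) - 10.0) < 0.5
    sq = np.zeros((128, 128), bool)
    sq[30:90, 30:90] = True
    sq2 = np.roll(np.roll(sq, 3, axis=0), 4, axis=1)
    d = mean_distance(sq, sq2)
    assert 3.0 <= d <= 5.0  # translation by (3, 4) px
    assert mean_distance(sq, sq) == 0.0
    # pure translation of a convex contour never exceeds |t|
    assert d <= 5.0 + 1e-9
    with pytest.raises(DegenerateInputError):
        mean_distance(sq, np.zeros_like(sq))
    assert mean_distance(sq, sq2, symmetric=False) >= 0.0


def test_mad_and_aggregate_summaries():
    assert mad([1, 2, 3, 4, 5]) == 1.0
    assert mad([7, 7, 7]) == 0.0
    recs = [MetricsRecord("i0", "lv_endo", 90.0, 0.9, 5.0, 2.0)]
    table = aggregate(recs)
    assert table.loc[0, "D"] == 90.0 and table.loc[0, "D_MAD"] == 0.0
    recs = [MetricsRecord(f"i{k}", "lv_endo", d, 0.9, 0.0, 1.0) for k, d in enumerate([1, 2, 3, 4, 5])]
    table = aggregate(recs)
    assert table.loc[0, "D"] == 3.0 and table.loc[0, "D_MAD"] == 1.0
    with pytest.raises(ValidationError):
        aggregate([])


def _wilcoxon_enumeration(diffs):
    """Exact two-sided p by enumerating all sign assignments of |d| ranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    stats = np.array(stats)
    w_lo = min(w_obs, ranks.sum() - w_obs)
    p = np.mean((np.minimum(stats, ranks.sum() - stats)) <= w_lo)
    return min(1.0, p)


def test_wilcoxon_exact_p_matches_sign_enumeration():
    a = np.array([1.0, 2, 3, 4, 5, 6])
    assert compare_methods(a, np.zeros(6)) == pytest.approx(2 / 64)
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = int(rng.integers(6, 11))
        x = rng.normal(size=n)
        y = x + rng.normal(0.5, 1.0, size=n)
        assert compare_methods(x, y) == pytest.approx(_wilcoxon_enumeration(x - y), abs=1e-12)


def test_wilcoxon_degenerate_and_symmetry():
    a = np.array([1.0, 2, 3, 4, 5, 6, 7])
    b = a + np.array([0.3, -0.5, 0.8, -0.1, 0.9, -0.7, 0.2])
    assert compare_methods(a, b) == pytest.approx(compare_methods(b, a))
    with pytest.raises(DegenerateInputError):
        compare_methods(a, a)
    with pytest.raises(ValidationError):
        compare_methods(a, a[:3])


def test_evaluate_pair_produces_records_per_structure():
    task = ("lv_endo", "lv_epi", "la")
    pred = np.zeros((64, 64), np.int64)
    ref = np.zeros((64, 64), np.int64)
    pred[10:30, 10:30] = 1
    pred[5:35, 5:35][pred[5:35, 5:35] == 0] = 2
    ref[12:32, 10:30] = 1
    ref[7:37, 5:35][ref[7:37, 5:35] == 0] = 2
    recs = evaluate_pair(pred, ref, task, image_id="x")
    by = {r.structure: r for r in recs}
    assert set(by) == {"lv_endo", "lv_epi"}
    assert 0 < by["lv_endo"].dice < 100
    assert np.isfinite(by["lv_endo"].mean_dist)
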