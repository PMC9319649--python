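"""Dice, Jaccard, Hausdorff and report aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import smsegnet as sm


def _mask(coords, shape=(12, 12)):
    m = np.zeros(shape, dtype=bool)
    for c in coords:
        m[c] = True
    return m


# -- dice / jaccard ---------------------------------------------------------

def test_identical_and_disjoint_masks():
    a = _mask([(0, 0), (1, 1)])
    b = _mask([(5, 5), (6, 6)])
    assert sm.dice(a, a) == 1.0 and sm.jaccard(a, a) == 1.0
    assert sm.dice(a, b) == 0.0 and sm.jaccard(a, b) == 0.0


def test_half_overlap_dice():
    a = _mask([(0, 0), (0, 1)])
    b = _mask([(0, 1), (0, 2)])
    assert sm.dice(a, b) == 0.5  # 2*1 / (2+2)


def test_dice_097_prints_jaccard_094():
    # 100-voxel masks sharing 97 voxels: DSC = 0.97 exactly and the
    # standard Jaccard 97/103 rounds to the printed companion 0.94
    a = np.zeros(300, dtype=bool)
    b = np.zeros(300, dtype=bool)
    a[:100] = True
    b[3:103] = True
    d, j = sm.dice(a, b), sm.jaccard(a, b)
    assert d == pytest.approx(0.97)
    assert j == pytest.approx(97 / 103)
    assert round(d, 2) == 0.97 and round(j, 2) == 0.94


@settings(max_examples=50, deadline=None, derandomize=True)
@given(arrays(bool, (6, 6)), arrays(bool, (6, 6)))
def test_jaccard_dice_identity_and_symmetry(a, b):
    d, j = sm.dice(a, b), sm.jaccard(a, b)
    assert sm.dice(b, a) == d or (math.isnan(d) and math.isnan(sm.dice(b, a)))
    if math.isnan(d):
        assert math.isnan(j)
    else:
        assert j == pytest.approx(d / (2 - d), abs=1e-12)
        assert 0.0 <= j <= d <= 1.0


def test_growing_overlap_never_decreases_overlap_scores():
    size = 10
    prev_d, prev_j = -1.0, -1.0
    for overlap in range(1, size + 1):
        a = np.zeros(30, dtype=bool)
        b = np.zeros(30, dtype=bool)
        a[:size] = True
        b[size - overlap:2 * size - overlap] = True
        d, j = sm.dice(a, b), sm.jaccard(a, b)
        assert d >= prev_d and j >= prev_j
        prev_d, prev_j = d, j


# -- hausdorff --------------------------------------------------------------

def _brute_force_hausdorff(a, b):
    pa, pb = np.argwhere(a), np.argwhere(b)
    d_ab = max(min(np.linalg.norm(p - q) for q in pb) for p in pa)
    d_ba = max(min(np.linalg.norm(p - q) for q in pa) for p in pb)
    return max(d_ab, d_ba)


def test_hausdorff_examples():
    assert sm.hausdorff(_mask([(0, 0)]), _mask([(0, 0)])) == 0.0
    assert sm.hausdorff(_mask([(0, 0)]), _mask([(3, 4)])) == 5.0
    assert sm.hausdorff(_mask([(0, 0), (10, 0)]), _mask([(0, 0)])) == 10.0


def test_hausdorff_zero_iff_identical():
    a = _mask([(1, 1), (2, 5)])
    b = _mask([(1, 1), (2, 5), (3, 3)])
    assert sm.hausdorff(a, a) == 0.0
    assert sm.hausdorff(a, b) > 0.0


def test_hausdorff_empty_mask_is_missing():
    a = _mask([(0, 0)])
    assert math.isnan(sm.hausdorff(a, np.zeros_like(a)))
    assert math.isnan(sm.hausdorff(np.zeros_like(a), np.zeros_like(a)))


def test_hausdorff_spacing_scales_distances():
    a, b = _mask([(0, 0)]), _mask([(1, 0)])
    assert sm.hausdorff(a, b, spacing=(2.5, 1.0)) == 2.5


@settings(max_examples=40, deadline=None, derandomize=True)
@given(arrays(bool, (12, 12)), arrays(bool, (12, 12)))
def test_hausdorff_matches_brute_force_oracle(a, b):
    if not a.any() or not b.any():
        assert math.isnan(sm.hausdorff(a, b))
        return
    expected = _brute_force_hausdorff(a, b)
    assert sm.hausdorff(a, b) == pytest.approx(expected, abs=1e-12)
    assert sm.hausdorff(b, a) == pytest.approx(expected, abs=1e-12)


# -- evaluate ---------------------------------------------------------------

def test_perfect_prediction_report(small_phantom):
    _, lab = small_phantom
    report = sm.evaluate(lab, lab)
    for cls in ("CSF", "GM", "WM"):
        assert report.per_class[cls] == {"dsc": 1.0, "ji": 1.0, "hd": 0.0}
    assert report.means == {"dsc": 1.0, "ji": 1.0, "hd": 0.0}


def test_absent_class_reported_as_missing_not_zero():
    t = np.zeros((4, 4, 1), dtype=np.int16)
    p = np.zeros((4, 4, 1), dtype=np.int16)
    t[0, 0, 0] = 1
    p[0, 0, 0] = 1   # CSF present; GM/WM absent from both
    report = sm.evaluate(p, t)
    assert report.per_class["CSF"]["dsc"] == 1.0
    for cls in ("GM", "WM"):
        assert all(math.isnan(v) for v in report.per_class[cls].values())


def test_class_in_one_map_only_scores_zero_overlap():
    t = np.zeros((4, 4, 1), dtype=np.int16)
    p = np.zeros((4, 4, 1), dtype=np.int16)
    t[0, 0, 0] = 2   # GM only in the ground truth
    report = sm.evaluate(p, t)
    gm = report.per_class["GM"]
    assert gm["dsc"] == 0.0 and gm["ji"] == 0.0 and math.isnan(gm["hd"])


def test_evaluate_composes_per_class_metric_calls(rng):
    t = rng.integers(0, 4, (8, 8, 1)).astype(np.int16)
    p = rng.integers(0, 4, (8, 8, 1)).astype(np.int16)
    report = sm.evaluate(p, t)
    for c, name in ((1, "CSF"), (2, "GM"), (3, "WM")):
        assert report.per_class[name]["dsc"] == sm.dice(t == c, p == c)
        assert report.per_class[name]["ji"] == sm.jaccard(t == c, p == c)
        assert report.per_class[name]["hd"] == sm.hausdorff(t == c, p == c)


def test_evaluate_shape_mismatch():
    with pytest.raises(ValueError):
        sm.evaluate(np.zeros((2, 2, 2), dtype=int),
                    np.zeros((2, 2, 3), dtype=int))


def test_report_frame_and_json(rng):
    t = rng.integers(0, 4, (6, 6, 2)).astype(np.int16)
    report = sm.evaluate(t, t, subject="s0")
    frame = report.to_frame()
    assert set(frame["class"]) == {"CSF", "GM", "WM"}
    assert len(frame) == 9
    assert '"subject": "s0"' in report.to_json()
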