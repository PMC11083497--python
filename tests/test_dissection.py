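"""Straightening, slice features, SVM training and probability pooling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortaquant.dissection import (FEATURE_NAMES, StraightenedVolume,
                                   pool_probabilities, predict_dissection,
                                   slice_features, slice_labels_from_gt,
                                   straighten, train_dissection_classifier)
from aortaquant.errors import TrainingError
from aortaquant.geometry import Centerline
from aortaquant.volume import Mask, Volume

from conftest import make_cylinder_mask
from test_diametry import _straight_centerline


def _disc_slice(radius=15, n=81, lumen_hu=300.0, flap=False):
    """Constructed straightened slice: bright disc, optionally a dark flap line."""
    y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = n // 2
    comp = (x - c) ** 2 + (y - c) ** 2 <= radius ** 2
    img = np.where(comp, lumen_hu, -100.0).astype(float)
    if flap:
        img[np.abs(y - c) <= 1] = np.where(comp[np.abs(y - c) <= 1], 60.0, -100.0)
    return img, comp


def test_straightened_slice_count_arithmetic():
    """A 300 mm straight vessel sampled every 2 mm gives 151 slices."""
    mask, p0, p1, _ = make_cylinder_mask(radius_mm=14, length_mm=308, voxel_mm=2.0)
    vol = Volume(np.where(mask.voxels, 300.0, -50.0).astype(np.float32),
                 mask.spacing_mm)
    c = _straight_centerline(p0 + [0, 0, 2], p0 + [0, 0, 302.5], step=2.0)
    sv = straighten(vol, mask, c)
    assert sv.n_slices == int(np.floor(c.length / 2.0)) + 1 == 151


def test_straightened_cylinder_discs_constant(bulge_chain):
    vol, gt, mask, c = bulge_chain
    sv = straighten(vol, mask, c)
    assert sv.valid.all()
    # per-slice equivalent diameter tracks 2*r(s) within a voxel
    for i in range(5, sv.n_slices - 5, 7):
        area = sv.components[i].sum() * sv.inplane_mm ** 2
        eq_d = 2 * np.sqrt(area / np.pi)
        assert eq_d == pytest.approx(2 * float(gt.radius_fn(sv.s[i])),
                                     abs=1.5 * float(mask.spacing_mm.max()))


def test_uniform_disc_features():
    img, comp = _disc_slice()
    f, ok = slice_features(img, comp)
    assert ok and len(f) == len(FEATURE_NAMES) == 18
    names = dict(zip(FEATURE_NAMES, f))
    assert names["hu_sd"] == 0.0
    hist = [names[f"hist_{i}"] for i in range(8)]
    assert max(hist) == pytest.approx(1.0)          # all mass in one bin
    # residual boundary response only; the flap response is ~3 orders larger
    assert names["max_dark_ridge"] == pytest.approx(0.0, abs=0.5)
    assert names["dark_fraction"] == 0.0


def test_flap_raises_membrane_features():
    plain, comp = _disc_slice(flap=False)
    flapped, _ = _disc_slice(flap=True)
    fp, _ = slice_features(plain, comp)
    ff, _ = slice_features(flapped, comp)
    idx = {n: i for i, n in enumerate(FEATURE_NAMES)}
    assert ff[idx["max_dark_ridge"]] > fp[idx["max_dark_ridge"]]
    assert ff[idx["dark_fraction"]] > fp[idx["dark_fraction"]]


def test_empty_component_flagged():
    img = np.full((81, 81), -100.0)
    f, ok = slice_features(img, np.zeros((81, 81), dtype=bool))
    assert not ok and np.allclose(f, 0.0) and len(f) == 18


def _toy_straightened(flap_flags):
    slices, comps = [], []
    for flap in flap_flags:
        img, comp = _disc_slice(flap=flap)
        slices.append(img)
        comps.append(comp)
    n = len(slices)
    return StraightenedVolume(np.asarray(slices, dtype=np.float32),
                              np.asarray(comps), np.arange(n) * 2.0, None,
                              1.0, 2.0, np.ones(n, dtype=bool))


def test_svm_separates_constructed_slices_and_is_deterministic():
    sv_pos = _toy_straightened([True] * 10 + [False] * 10)
    labels = np.array([True] * 10 + [False] * 10)
    clf1 = train_dissection_classifier([(sv_pos, labels)], seed=0)
    clf2 = train_dissection_classifier([(sv_pos, labels)], seed=0)
    assert clf1.best_params == clf2.best_params
    probs = clf1.slice_probabilities(sv_pos)
    assert np.all((probs[:10] > 0.5)) and np.all(probs[10:] < 0.5)


def test_single_class_training_rejected():
    sv = _toy_straightened([False] * 6)
    with pytest.raises(TrainingError):
        train_dissection_classifier([(sv, np.zeros(6, dtype=bool))])


def test_pooling_extremes_and_topk():
    assert pool_probabilities(np.zeros(20))[0] == 0.0
    assert pool_probabilities(np.ones(20))[0] == 1.0
    p = np.full(30, 0.1)
    p[:3] = 0.9
    val, k = pool_probabilities(p, top_k=3)
    assert val == pytest.approx(0.9) and k == 3


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 27), st.integers(0, 19))
def test_pooling_monotone_in_any_slice(seed, j):
    rng = np.random.default_rng(seed)
    p = rng.random(20)
    base, _ = pool_probabilities(p)
    p2 = p.copy()
    p2[j] = min(1.0, p2[j] + rng.random())
    raised, _ = pool_probabilities(p2)
    assert raised >= base - 1e-12


def test_indeterminate_with_too_few_slices():
    sv = _toy_straightened([True, False])
    labels20 = np.array([True] * 10 + [False] * 10)
    clf = train_dissection_classifier(
        [(_toy_straightened([True] * 10 + [False] * 10), labels20)], seed=0)
    res = predict_dissection(clf, sv)
    assert res.indeterminate


def test_slice_labels_from_ground_truth(dissection_case, bulge_chain):
    vol, gt = dissection_case
    lo, hi = gt.dissected_slice_range
    sv = StraightenedVolume(np.zeros((100, 3, 3), dtype=np.float32),
                            np.zeros((100, 3, 3), dtype=bool),
                            np.arange(100) * 2.0, None, 1.0, 2.0,
                            np.ones(100, dtype=bool))
    labels = slice_labels_from_gt(sv, gt)
    assert labels.any()
    s = sv.s[labels]
    assert s.min() >= lo and s.max() < hi
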