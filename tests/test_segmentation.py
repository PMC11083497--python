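"""Segmentation: Dice metric, classical oracle, cutoff monotonicity, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortaquant import PhantomSpec, synth_case
from aortaquant.errors import InputError, NoAortaFoundError
from aortaquant.segmentation import (SegmenterConfig, TrainedSegmenter,
                                     classical_segment, dice, segment,
                                     train_segmenter, _postprocess)
from aortaquant.volume import Mask, Volume


def _cube_mask(lo, hi, shape=(10, 10, 10)):
    vox = np.zeros(shape, dtype=bool)
    vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return Mask(vox, [1, 1, 1])


def test_dice_identical_masks():
    m = _cube_mask((2, 2, 2), (6, 6, 6))
    assert dice(m, m) == 1.0


def test_dice_disjoint_masks():
    a = _cube_mask((0, 0, 0), (3, 3, 3))
    b = _cube_mask((5, 5, 5), (8, 8, 8))
    assert dice(a, b) == 0.0


def test_dice_half_overlapping_cubes():
    # 2x2x2 cubes sharing a 1x2x2 slab: 2*4/(8+8) = 0.5
    a = _cube_mask((0, 0, 0), (2, 2, 2))
    b = _cube_mask((1, 0, 0), (3, 2, 2))
    assert dice(a, b) == pytest.approx(0.5)


def test_dice_both_empty_convention():
    e = _cube_mask((0, 0, 0), (0, 0, 0))
    assert dice(e, e) == 1.0


def test_dice_raster_mismatch_rejected():
    a = _cube_mask((0, 0, 0), (2, 2, 2))
    b = Mask(np.zeros((10, 10, 10), dtype=bool), [2, 2, 2])
    with pytest.raises(InputError):
        dice(a, b)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 27 - 1))
def test_dice_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    a = Mask(rng.random((6, 6, 6)) > 0.5, [1, 1, 1])
    b = Mask(rng.random((6, 6, 6)) > 0.5, [1, 1, 1])
    d = dice(a, b)
    assert d == dice(b, a)
    assert 0.0 <= d <= 1.0


def test_classical_oracle_noiseless_dice(noiseless_case):
    vol, gt = noiseless_case
    m = classical_segment(vol, contrast=True, noise_sd_hu=0.0)
    assert dice(m, gt.rasterized_mask(vol)) >= 0.98


def test_classical_noncontrast_regime():
    vol, gt = synth_case(PhantomSpec(contrast=False, seed=3))
    m = classical_segment(vol, contrast=False, noise_sd_hu=10.0)
    assert dice(m, gt.rasterized_mask(vol)) >= 0.95


def test_classical_background_only_raises():
    v = Volume(np.full((20, 20, 20), -50.0, dtype=np.float32), [1, 1, 1])
    with pytest.raises(NoAortaFoundError):
        classical_segment(v, contrast=True, noise_sd_hu=0.0)


def test_classical_covers_both_lumina(dissection_case):
    """The closed mask bridges the flap: one component spanning both channels."""
    vol, gt = dissection_case
    m = classical_segment(vol, contrast=True, noise_sd_hu=10.0)
    truth = gt.rasterized_mask(vol)
    assert dice(m, truth) >= 0.95
    # the flap midpoint itself ends up inside the single closed component
    p = gt.point_at(0.5 * sum(gt.dissected_slice_range))
    idx = tuple(np.round(m.world_to_index(p)).astype(int))
    from scipy import ndimage
    lab, n = ndimage.label(m.voxels)
    assert n == 1 and lab[idx] == 1


def test_cutoff_monotonicity_untrained_net():
    """mask(0.9) is contained in mask(0.5) for any probability map."""
    net_seg = TrainedSegmenter(
        net=__import__("aortaquant.nnet", fromlist=["UNet3D"]).UNet3D(2, 2, seed=0),
        cfg=SegmenterConfig(depth=2, base_filters=2), loss_log=[], val_dice=0.0)
    vol = Volume(np.random.default_rng(0).normal(100, 120, (24, 24, 24))
                 .astype(np.float32), [2, 2, 2])
    prob, _ = segment(net_seg, vol, cutoff=0.4)
    m_lo = prob.voxels >= 0.45
    m_hi = prob.voxels >= 0.9
    assert np.all(m_lo[m_hi])


def test_postprocess_keeps_largest_component_and_fills_holes():
    vox = np.zeros((12, 12, 12), dtype=bool)
    vox[1:9, 1:9, 1:9] = True
    vox[4, 4, 4] = False          # internal hole
    vox[10, 10, 10] = True        # spurious speck
    out = _postprocess(vox)
    assert out[4, 4, 4]
    assert not out[10, 10, 10]


def test_training_split_and_determinism():
    """20% validation split; same seed -> same split and loss trajectory."""
    specs = [PhantomSpec(seed=i, voxel_mm=2.0, limb_length_mm=40.0,
                         arch_radius_mm=30.0, margin_mm=8.0) for i in range(5)]
    cases = [synth_case(s) for s in specs]
    cfg = SegmenterConfig(epochs=2, resample_mm=4.0, patch_size=16,
                          patches_per_case=1, seed=11)
    a = train_segmenter(cases, cfg)
    b = train_segmenter(cases, cfg)
    assert a.val_indices == b.val_indices
    assert len(a.val_indices) == 1  # round(0.2 * 5)
    assert a.loss_log == pytest.approx(b.loss_log, rel=1e-6)

    # native-resolution rescoring stays a valid Dice
    from aortaquant.segmentation import dice_at_native
    vol, gt = cases[a.val_indices[0]]
    d = dice_at_native(a, vol, gt)
    assert 0.0 <= d <= 1.0


def test_training_rejects_single_case(noiseless_case):
    with pytest.raises(Exception):
        train_segmenter([noiseless_case])


def test_sliding_window_inference_shape_and_bounds():
    from aortaquant.nnet import UNet3D
    from aortaquant.segmentation import sliding_window_proba
    net = UNet3D(depth=2, base_filters=2, seed=3)
    x = np.random.default_rng(0).random((40, 36, 44)).astype(np.float32)
    p = sliding_window_proba(net, x, tile=32)
    assert p.shape == x.shape
    assert np.all((p >= 0.0) & (p <= 1.0))
    # volumes smaller than a tile fall back to one padded pass
    small = x[:12, :10, :14]
    assert sliding_window_proba(net, small, tile=32).shape == small.shape
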