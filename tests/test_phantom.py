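"""Phantom generator: analytic oracle consistency, determinism, cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortaquant import PhantomSpec, ground_truth_diameter, synth_case
from aortaquant.errors import ConfigurationError, DomainError, SizingError
from aortaquant.phantom import (LANDMARK_NAMES, build_ground_truth,
                                make_cohort_specs)


def test_constant_radius_diameter_everywhere(noiseless_case):
    _, gt = noiseless_case
    for s in np.linspace(0, gt.total_length - 1e-9, 25):
        assert ground_truth_diameter(gt, s) == pytest.approx(30.0)


def test_bulge_apex_diameter(bulge_case):
    _, gt = bulge_case
    s0 = gt.spec.resolved_bulge_center()
    assert ground_truth_diameter(gt, s0) == pytest.approx(40.0)
    # far from the bulge the Gaussian has decayed
    assert ground_truth_diameter(gt, 5.0) == pytest.approx(30.0, abs=0.1)


def test_diameter_argmax_matches_bulge_center(bulge_case):
    _, gt = bulge_case
    grid = np.arange(0.0, gt.total_length, 0.1)
    d = 2.0 * gt.radius_fn(grid)
    assert abs(grid[np.argmax(d)] - gt.spec.resolved_bulge_center()) <= 0.1


def test_max_diameter_equals_r0_plus_amplitude():
    spec = PhantomSpec(base_radius_mm=14.0, bulge_amplitude_mm=7.0,
                       noise_sd_hu=0.0, seed=3)
    gt = build_ground_truth(spec)
    grid = np.arange(0.0, gt.total_length, 0.05)
    assert 2.0 * gt.radius_fn(grid).max() == pytest.approx(2 * (14.0 + 7.0))


def test_diameter_out_of_range_raises(noiseless_case):
    _, gt = noiseless_case
    with pytest.raises(DomainError):
        ground_truth_diameter(gt, gt.total_length + 1.0)
    with pytest.raises(DomainError):
        ground_truth_diameter(gt, -0.5)


def test_seeded_determinism():
    spec = dict(bulge_amplitude_mm=4.0, has_dissection=True, seed=9)
    v1, _ = synth_case(PhantomSpec(**spec))
    v2, _ = synth_case(PhantomSpec(**spec))
    assert np.array_equal(v1.voxels, v2.voxels)


def test_different_seed_changes_noise():
    v1, _ = synth_case(PhantomSpec(seed=1))
    v2, _ = synth_case(PhantomSpec(seed=2))
    assert not np.array_equal(v1.voxels, v2.voxels)


def test_landmarks_in_anatomical_order_and_inside_volume(noiseless_case):
    vol, gt = noiseless_case
    s_vals = [gt.spec.landmark_s[n] for n in LANDMARK_NAMES]
    assert s_vals == sorted(s_vals)
    ext = vol.extent_mm
    for p in gt.landmarks.values():
        assert np.all(p >= 0) and np.all(p <= ext)


def test_section_ranges_partition_total_length(noiseless_case):
    _, gt = noiseless_case
    r = gt.section_ranges
    assert r["ascending"][0] == 0.0
    assert r["ascending"][1] == r["arch"][0]
    assert r["arch"][1] == r["descending"][0]
    assert r["descending"][1] == pytest.approx(gt.total_length)


def test_sizing_error_for_too_small_grid():
    with pytest.raises(SizingError):
        synth_case(PhantomSpec(bulge_amplitude_mm=8.0, shape=(60, 30, 80), seed=0))


def test_bulge_center_outside_section_rejected():
    with pytest.raises(ConfigurationError):
        synth_case(PhantomSpec(bulge_amplitude_mm=5.0, bulge_section="ascending",
                               bulge_center_s0=200.0, seed=0))


def test_flap_darkens_lumen(dissection_case):
    vol, gt = dissection_case
    lo, hi = gt.dissected_slice_range
    assert gt.dissection_label
    # at the flap arc range, the voxel on the centerline carries flap HU
    # (60 +- noise), far below the 300 HU contrast blood pool
    p = gt.point_at(0.5 * (lo + hi))
    idx = tuple(np.round(vol.world_to_index(p)).astype(int))
    assert vol.voxels[idx] < 150


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(1, 200), prev=st.floats(0.0, 1.0))
def test_cohort_label_balance(n, prev):
    specs = make_cohort_specs(n, prev, seed=42)
    assert sum(s.has_dissection for s in specs) == round(n * prev)


def test_cohort_mirrors_study_prevalence():
    specs = make_cohort_specs(100, 0.42, seed=7)
    assert sum(s.has_dissection for s in specs) == 42


def test_cohort_specs_deterministic():
    a = make_cohort_specs(12, 0.5, seed=3)
    b = make_cohort_specs(12, 0.5, seed=3)
    assert a == b


def test_empty_spec_ranges_rejected():
    with pytest.raises(ConfigurationError):
        make_cohort_specs(5, 0.5, seed=0, spec_ranges={})


def test_make_cohort_materializes_volumes():
    from aortaquant import make_cohort
    cohort = make_cohort(2, 0.5, seed=5, spec_ranges={
        "limb_length_mm": (40.0, 45.0), "arch_radius_mm": (28.0, 30.0),
        "base_radius_mm": (12.0, 13.0)})
    assert len(cohort) == 2
    assert sum(gt.dissection_label for _, gt in cohort) == 1
    for vol, gt in cohort:
        assert vol.voxels.ndim == 3
        assert gt.total_length > 0
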