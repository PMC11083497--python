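"""Centerline: medial accuracy, frames, partitioning, rotation equivariance."""

import numpy as np
import pytest

from aortaquant.errors import DisconnectedAortaError, PartitionError
from aortaquant.geometry import extract_centerline, partition_sections
from aortaquant.landmarks import oracle_landmarks
from aortaquant.volume import Mask

from conftest import make_cylinder_mask


def test_straight_cylinder_centerline_on_axis():
    mask, p0, p1, center = make_cylinder_mask(radius_mm=15, length_mm=120)
    c = extract_centerline(mask, p0, p1, step_mm=2.0)
    # all samples within half a voxel of the analytic axis (x=center, y=center)
    dev = np.linalg.norm(c.points[:, :2] - center[:2], axis=1)
    assert dev.max() <= 0.5 * float(mask.spacing_mm.max()) + 1e-6


def test_candy_cane_arc_length_within_two_percent(bulge_chain):
    _, gt, _, c = bulge_chain
    assert c.length == pytest.approx(gt.total_length, rel=0.02)


def test_frames_orthonormal_everywhere(bulge_chain):
    _, _, _, c = bulge_chain
    t, u, v = c.tangent, c.u, c.v
    for a, b in [(t, u), (t, v), (u, v)]:
        assert np.abs((a * b).sum(axis=1)).max() < 1e-9
    for a in (t, u, v):
        assert np.abs(np.linalg.norm(a, axis=1) - 1).max() < 1e-9


def test_parallel_transport_has_no_flips(bulge_chain):
    _, _, _, c = bulge_chain
    cosang = np.clip((c.u[:-1] * c.u[1:]).sum(axis=1), -1, 1)
    assert np.degrees(np.arccos(cosang)).max() < 15.0


def test_centerline_lies_inside_mask(bulge_chain):
    _, _, mask, c = bulge_chain
    idx = np.round(c.points / mask.spacing_mm).astype(int)
    idx = np.clip(idx, 0, np.asarray(mask.shape) - 1)
    assert all(mask.voxels[tuple(i)] for i in idx)


def test_rotation_equivariance(bulge_chain):
    """Rotating mask + landmarks 90 deg about z rotates the centerline."""
    _, gt, mask, c = bulge_chain
    rot_vox = np.rot90(mask.voxels, k=1, axes=(0, 1))
    rot = Mask(rot_vox, mask.spacing_mm)

    def rot_pt(p):
        # np.rot90 over (x, y): in[i, j] -> out[n1-1-j, i]
        return np.array([(mask.shape[1] - 1) * mask.spacing_mm[1] - p[1],
                         p[0], p[2]])

    lm = oracle_landmarks(gt)
    c2 = extract_centerline(rot, rot_pt(lm["aortic_root"]), rot_pt(lm["celiac"]),
                            step_mm=2.0)
    n = min(c.n, c2.n)
    expected = np.stack([rot_pt(p) for p in c.points[:n]])
    dev = np.linalg.norm(c2.points[:n] - expected, axis=1)
    assert dev.max() <= 1.5 * float(mask.spacing_mm.max())


def test_disconnected_components_raise():
    vox = np.zeros((30, 10, 10), dtype=bool)
    vox[2:8, 3:7, 3:7] = True
    vox[20:28, 3:7, 3:7] = True
    m = Mask(vox, [1, 1, 1])
    with pytest.raises(DisconnectedAortaError):
        extract_centerline(m, np.array([4.0, 5, 5]), np.array([24.0, 5, 5]))


def test_partition_matches_ground_truth_ranges(bulge_chain):
    _, gt, _, c = bulge_chain
    step = c.step
    for sec in ("ascending", "arch", "descending"):
        lo, hi = c.section_range(sec)
        glo, ghi = gt.section_ranges[sec]
        assert lo == pytest.approx(glo, abs=step + 1e-9)
        assert hi == pytest.approx(ghi, abs=step + 1e-9)


def test_partition_requires_subclavian(bulge_chain):
    _, gt, _, c = bulge_chain
    lm = oracle_landmarks(gt)
    lm.pop("left_subclavian")
    with pytest.raises(PartitionError) as e:
        partition_sections(c, lm)
    assert e.value.landmark == "left_subclavian"


def test_partition_out_of_order_names_offender(bulge_chain):
    _, gt, _, c = bulge_chain
    lm = oracle_landmarks(gt)
    lm["brachiocephalic"], lm["left_subclavian"] = (lm["left_subclavian"],
                                                    lm["brachiocephalic"])
    with pytest.raises(PartitionError):
        partition_sections(c, lm)


def test_labels_contiguous_and_exhaustive(bulge_chain):
    _, _, _, c = bulge_chain
    assert c.section is not None and len(c.section) == c.n
    changes = sum(1 for a, b in zip(c.section[:-1], c.section[1:]) if a != b)
    assert changes == 2  # ascending -> arch -> descending, once each
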