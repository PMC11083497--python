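"""Shared fixtures: small seeded phantoms and derived pipeline artifacts."""

import numpy as np
import pytest

from aortaquant import PhantomSpec, synth_case
from aortaquant.geometry import extract_centerline, partition_sections
from aortaquant.landmarks import oracle_landmarks
from aortaquant.segmentation import classical_segment
from aortaquant.volume import Mask, Volume


@pytest.fixture(scope="session")
def noiseless_case():
    """Constant-radius candy cane, no noise: the cleanest oracle case."""
    return synth_case(PhantomSpec(noise_sd_hu=0.0, seed=1))


@pytest.fixture(scope="session")
def bulge_case():
    """r0=15, A=5 descending bulge, noiseless -> 40 mm apex, 30 mm elsewhere."""
    return synth_case(PhantomSpec(base_radius_mm=15.0, bulge_amplitude_mm=5.0,
                                  bulge_section="descending", noise_sd_hu=0.0,
                                  seed=1))


@pytest.fixture(scope="session")
def dissection_case():
    return synth_case(PhantomSpec(has_dissection=True, seed=5))


@pytest.fixture(scope="session")
def bulge_chain(bulge_case):
    """Mask + partitioned centerline for the bulge phantom (native 1 mm)."""
    vol, gt = bulge_case
    mask = classical_segment(vol, contrast=True, noise_sd_hu=0.0)
    lm = oracle_landmarks(gt)
    c = partition_sections(
        extract_centerline(mask, lm["aortic_root"], lm["celiac"]), lm)
    return vol, gt, mask, c


def make_cylinder_mask(radius_mm=15.0, length_mm=120.0, voxel_mm=1.0,
                       axis=np.array([0.0, 0.0, 1.0]), pad_mm=10.0):
    """Analytic cylinder mask along an arbitrary axis (for geometry tests)."""
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    half = length_mm / 2.0
    ext = np.abs(axis) * length_mm + 2 * (radius_mm + pad_mm)
    shape = np.ceil(ext / voxel_mm).astype(int)
    center = shape * voxel_mm / 2.0
    ax = [np.arange(n) * voxel_mm for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1) - center
    t = pts @ axis
    radial = np.linalg.norm(pts - t[..., None] * axis, axis=-1)
    vox = (radial <= radius_mm) & (np.abs(t) <= half)
    mask = Mask(vox, np.full(3, voxel_mm))
    p0 = center - half * axis
    p1 = center + half * axis
    return mask, p0, p1, center
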