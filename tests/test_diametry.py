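"""Diametry: circles, ellipses, tilt independence, section maxima."""

import numpy as np
import pytest

from aortaquant.diametry import cross_section_diameters, max_section_diameters
from aortaquant.geometry import Centerline, extract_centerline
from aortaquant.volume import Mask

from conftest import make_cylinder_mask


def _straight_centerline(p0, p1, step=2.0):
    length = np.linalg.norm(p1 - p0)
    n = int(length // step) + 1
    t = (p1 - p0) / length
    pts = p0 + np.arange(n)[:, None] * step * t
    u = np.array([1.0, 0, 0]) if abs(t[0]) < 0.9 else np.array([0.0, 1, 0])
    u = u - u.dot(t) * t
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return Centerline(points=pts, s=np.arange(n) * step,
                      tangent=np.tile(t, (n, 1)), u=np.tile(u, (n, 1)),
                      v=np.tile(v, (n, 1)))


def test_circle_cross_section_all_rays_equal():
    mask, p0, p1, _ = make_cylinder_mask(radius_mm=15, length_mm=60)
    c = _straight_centerline(p0 + [0, 0, 10], p1 - [0, 0, 10])
    cs = cross_section_diameters(mask, c, c.n // 2)
    assert cs.valid
    # each chord endpoint carries up to half-voxel rasterization error
    assert np.allclose(cs.ray_diameters, 30.0, atol=1.2)
    assert cs.average_diameter == pytest.approx(30.0, abs=0.5)
    assert cs.area == pytest.approx(np.pi * 15 ** 2, rel=0.03)


def test_elliptical_section_average_between_axes():
    # elliptical cylinder 40 x 20 mm axes
    vox = np.zeros((60, 40, 30), dtype=bool)
    x, y = np.meshgrid(np.arange(60), np.arange(40), indexing="ij")
    ell = ((x - 30) / 20.0) ** 2 + ((y - 20) / 10.0) ** 2 <= 1.0
    vox[:, :, 5:25] = ell[:, :, None]
    mask = Mask(vox, [1, 1, 1])
    c = _straight_centerline(np.array([30.0, 20.0, 8.0]), np.array([30.0, 20.0, 22.0]))
    cs = cross_section_diameters(mask, c, 2)
    assert 21.0 < cs.average_diameter < 39.0
    assert cs.ray_diameters.max() == pytest.approx(40.0, abs=1.5)
    assert cs.ray_diameters.min() == pytest.approx(20.0, abs=1.5)


@pytest.mark.parametrize("axis", [(0, 0, 1.0), (1.0, 0, 1.0), (1.0, 1.0, 1.0)],
                         ids=["grid-aligned", "tilt45", "diagonal"])
def test_tilted_cylinder_measured_perpendicular(axis):
    """Diameter perpendicular to the centerline is tilt-independent (not d*sqrt2)."""
    mask, p0, p1, _ = make_cylinder_mask(radius_mm=15, length_mm=110,
                                         axis=np.array(axis))
    c = extract_centerline(mask, p0, p1, step_mm=2.0)
    mid = c.n // 2
    ds = [cross_section_diameters(mask, c, i).average_diameter
          for i in (mid - 2, mid, mid + 2)]
    assert np.mean(ds) == pytest.approx(30.0, rel=0.03)


def test_max_section_diameters_on_bulge(bulge_chain):
    _, gt, mask, c = bulge_chain
    rep = max_section_diameters(mask, c)
    voxel = float(mask.spacing_mm.max())
    tol = max(voxel, 0.05 * 40.0)
    assert rep.sections["descending"]["max_avg_diameter_mm"] == pytest.approx(40.0, abs=tol)
    assert rep.sections["ascending"]["max_avg_diameter_mm"] == pytest.approx(30.0, abs=tol)
    assert abs(rep.sections["descending"]["s_mm"]
               - gt.spec.resolved_bulge_center()) <= gt.spec.bulge_width_sigma_s


def test_profile_matches_analytic_radius(bulge_chain):
    _, gt, mask, c = bulge_chain
    rep = max_section_diameters(mask, c)
    sel = np.isfinite(rep.profile[:, 1])
    # compare away from the free ends
    inner = sel & (rep.profile[:, 0] > 10) & (rep.profile[:, 0] < c.length - 10)
    truth = 2.0 * gt.radius_fn(rep.profile[inner, 0])
    assert np.abs(rep.profile[inner, 1] - truth).max() <= 2.0


def test_unpartitioned_centerline_rejected(bulge_chain):
    _, _, mask, c = bulge_chain
    from aortaquant.errors import InputError
    from aortaquant.geometry import Centerline
    bare = Centerline(c.points, c.s, c.tangent, c.u, c.v, None)
    with pytest.raises(InputError):
        max_section_diameters(mask, bare)


def test_empty_plane_recorded_as_gap():
    mask, p0, p1, _ = make_cylinder_mask(radius_mm=10, length_mm=40)
    # centerline extended far beyond the cylinder end: slices miss the mask
    c = _straight_centerline(p0, p1 + np.array([0, 0, 60.0]))
    cs = cross_section_diameters(mask, c, c.n - 1)
    assert not cs.valid
    assert np.isnan(cs.average_diameter)
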