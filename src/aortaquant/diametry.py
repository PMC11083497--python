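"""Cross-sectional diameter measurement perpendicular to the centerline.

At every centerline sample the mask is resampled (nearest-neighbor) on the
local (u, v) plane, the in-plane connected component containing the
centerline point is isolated, and the "average diameter" is computed as the
mean of centroid-chord lengths over uniformly spaced angles — a definition
that is rotation-robust and reduces to the true diameter on circles. Chord
endpoints are located with sub-pixel precision by linear interpolation of the
component indicator along each ray.

The headline output reports, for the ascending and descending sections, the
maximum of the average-diameter profile (samples within an edge-exclusion
band of the section boundaries are ignored) together with its arc-length
location. The arch profile is computed but not reported as a maximum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import InputError
from .geometry import Centerline
from .volume import Mask

__all__ = ["CrossSection", "DiameterReport", "cross_section_diameters",
           "max_section_diameters"]


@dataclass
class CrossSection:
    """One perpendicular slice's measurement."""

    s: float                          # arc length, mm
    centroid: np.ndarray              # (2,) in-plane mm, relative to centerline point
    boundary: np.ndarray | None       # (K, 2) in-plane mm polygon
    ray_diameters: np.ndarray         # (n_rays,) chord lengths, mm
    average_diameter: float           # mean of ray_diameters, mm
    area: float                       # mm^2
    valid: bool = True


@dataclass
class DiameterReport:
    """Per-section maxima plus the full diameter profile d(s)."""

    sections: dict                    # name -> {"max_avg_diameter_mm", "s_mm"}
    profile: np.ndarray               # (N, 2): [s, average diameter] (nan = gap)
    gaps: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            **{name: {k: float(v) for k, v in d.items()}
               for name, d in self.sections.items()},
            "profile": [[float(a), float(b)] for a, b in self.profile],
            "gaps": self.gaps,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _plane_mask(m: Mask, c: Centerline, i: int, inplane_mm: float,
                window_mm: float) -> tuple[np.ndarray, int]:
    """Nearest-neighbor sample of the mask on the (u, v) plane at sample i."""
    half = window_mm / 2.0
    n = int(round(window_mm / inplane_mm)) + 1
    offs = np.linspace(-half, half, n)
    p0, uu, vv = c.points[i], c.u[i], c.v[i]
    world = (p0[None, None, :] + offs[:, None, None] * uu[None, None, :]
             + offs[None, :, None] * vv[None, None, :])
    idx = (world - m.origin_mm) / m.spacing_mm
    plane = ndimage.map_coordinates(m.voxels.astype(np.float32),
                                    [idx[..., 0], idx[..., 1], idx[..., 2]],
                                    order=0, mode="constant", cval=0.0)
    return plane >= 0.5, n // 2


def _component_at_center(plane: np.ndarray, center: int) -> np.ndarray | None:
    lab, nlab = ndimage.label(plane)
    if nlab == 0:
        return None
    # centerline point should lie in the component; search a 3x3 neighborhood
    # to tolerate half-voxel offsets
    for di in (0, -1, 1):
        for dj in (0, -1, 1):
            l = lab[center + di, center + dj]
            if l > 0:
                return lab == l
    return None


def cross_section_diameters(m: Mask, c: Centerline, i: int,
                            inplane_mm: float = 0.5, n_rays: int = 90,
                            window_mm: float = 80.0) -> CrossSection:
    """Measure one perpendicular cross-section.

    Returns a CrossSection with ``valid=False`` (and NaN diameter) when the
    plane contains no aortic component at the centerline point — a recorded
    measurement gap, not an error.
    """
    if not (0 <= i < c.n):
        raise InputError(f"sample index {i} out of range")
    plane, center = _plane_mask(m, c, i, inplane_mm, window_mm)
    comp = _component_at_center(plane, center)
    s = float(c.s[i])
    if comp is None:
        return CrossSection(s, np.zeros(2), None, np.full(n_rays, np.nan),
                            float("nan"), 0.0, valid=False)

    ii, jj = np.nonzero(comp)
    centroid_px = np.array([ii.mean(), jj.mean()])
    area = float(comp.sum()) * inplane_mm ** 2

    # chords through the centroid at uniformly spaced angles, sub-pixel
    # endpoints by linear interpolation of the indicator along each ray
    angles = np.arange(n_rays) * np.pi / n_rays
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)    # px-space dirs
    t_px = np.arange(0.0, (window_mm / 2.0) / inplane_mm, 0.5)   # half-px steps
    comp_f = comp.astype(np.float32)

    # sample both ray directions in one call: (n_rays, 2 signs, n_t, 2)
    pos = (centroid_px[None, None, None, :]
           + dirs[:, None, None, :] * np.array([1.0, -1.0])[None, :, None, None]
           * t_px[None, None, :, None])
    vals = ndimage.map_coordinates(comp_f, [pos[..., 0].ravel(), pos[..., 1].ravel()],
                                   order=1, mode="constant", cval=0.0)
    vals = vals.reshape(n_rays, 2, len(t_px))

    inside = vals >= 0.5
    # first exit index along each ray
    exit_idx = np.argmin(inside, axis=2)
    never_exits = inside.all(axis=2)
    exit_idx[never_exits] = len(t_px) - 1
    e = np.maximum(exit_idx, 1)
    v0 = np.take_along_axis(vals, (e - 1)[..., None], axis=2)[..., 0]
    v1 = np.take_along_axis(vals, e[..., None], axis=2)[..., 0]
    frac = np.clip((v0 - 0.5) / np.maximum(v0 - v1, 1e-9), 0.0, 1.0)
    t_exit = t_px[e - 1] + frac * (t_px[1] - t_px[0])
    t_exit[never_exits] = t_px[-1]
    radii_mm = t_exit * inplane_mm
    ray_d = radii_mm.sum(axis=1)

    contours = measure.find_contours(comp_f, 0.5)
    boundary = None
    if contours:
        longest = max(contours, key=len)
        boundary = (longest - center) * inplane_mm

    centroid_mm = (centroid_px - center) * inplane_mm
    return CrossSection(s, centroid_mm, boundary, ray_d, float(ray_d.mean()),
                        area, valid=True)


def max_section_diameters(m: Mask, c: Centerline,
                          edge_exclusion_mm: float = 5.0,
                          inplane_mm: float = 0.5, n_rays: int = 90,
                          window_mm: float = 80.0) -> DiameterReport:
    """Average-diameter profile d(s) and per-section maxima.

    The ascending and descending maxima exclude samples within
    ``edge_exclusion_mm`` of the section boundaries (partition jitter); a
    section with no valid samples is reported absent.
    """
    if c.section is None:
        raise InputError("centerline must be partitioned into sections first")
    profile = np.full((c.n, 2), np.nan)
    profile[:, 0] = c.s
    gaps = []
    for i in range(c.n):
        cs = cross_section_diameters(m, c, i, inplane_mm, n_rays, window_mm)
        if cs.valid:
            profile[i, 1] = cs.average_diameter
        else:
            gaps.append(i)

    sections: dict = {}
    for name in ("ascending", "descending"):
        idx = c.section_indices(name)
        if len(idx) == 0:
            continue
        lo, hi = c.section_range(name)
        keep = idx[(c.s[idx] >= lo + edge_exclusion_mm)
                   & (c.s[idx] <= hi - edge_exclusion_mm)]
        keep = keep[np.isfinite(profile[keep, 1])]
        if len(keep) == 0:
            continue
        j = keep[int(np.argmax(profile[keep, 1]))]
        sections[name] = {"max_avg_diameter_mm": float(profile[j, 1]),
                          "s_mm": float(c.s[j])}
    return DiameterReport(sections=sections, profile=profile, gaps=gaps)
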