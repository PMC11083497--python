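"""Seeded synthetic thoracic-aorta phantoms with analytic ground truth.

The phantom is a "candy cane": a vertical ascending limb, a half-torus arch
and a vertical descending limb, all in the x–z plane. The outer vessel radius
along arc length s follows

    r(s) = r0 + A * exp(-(s - s0)^2 / (2 * sigma_s^2))

so an aneurysm is a Gaussian bulge of amplitude A centred at s0. The vessel
wall occupies the outermost ``wall_thickness_mm`` of that radius (aortic
diameters are conventionally outer-wall to outer-wall), the lumen fills the
interior at the contrast-dependent blood HU. Optional
pathology: a thin dissection flap (a planar membrane splitting the lumen into
two channels over an arc-length range) and a graft segment with metallic-bright
wall. Intensities are in Hounsfield units with separate contrast-enhanced and
non-contrast lumen regimes; boundary voxels get partial-volume intensities via
3x3x3 sub-voxel occupancy sampling, and Gaussian noise is added last.

Every case is fully determined by its :class:`PhantomSpec` (including the
seed), which makes the generator usable as an analytic oracle for the
segmentation, geometry, diametry and dissection stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DomainError, SizingError
from .volume import Mask, Volume

__all__ = [
    "DEFAULT_HU_MODEL",
    "PhantomSpec",
    "GroundTruth",
    "synth_case",
    "ground_truth_diameter",
    "make_cohort",
    "make_cohort_specs",
]

LANDMARK_NAMES = (
    "aortic_root",
    "brachiocephalic",
    "left_common_carotid",
    "left_subclavian",
    "celiac",
)

#: Arch arc fractions at which the three supra-aortic branch landmarks sit.
#: The phantom has no branch vessels, so the landmarks are defined directly on
#: the centerline; brachiocephalic and left subclavian double as the
#: ascending/arch and arch/descending section boundaries.
ARCH_FRACTIONS = {"brachiocephalic": 0.15, "left_common_carotid": 0.50, "left_subclavian": 0.85}

DEFAULT_HU_MODEL = {
    "lumen_contrast": 300.0,
    "lumen_noncontrast": 40.0,
    "wall": 50.0,
    "flap": 60.0,
    "graft": 500.0,
    "background": -50.0,
}


@dataclass
class PhantomSpec:
    """Complete description of one synthetic case.

    Lengths are mm; HU values come from ``hu_model``. ``bulge_center_s0=None``
    places the bulge at the middle of ``bulge_section``; ``flap_arc_range=None``
    with ``has_dissection=True`` covers the central 60% of the descending
    section.
    """

    limb_length_mm: float = 60.0
    arch_radius_mm: float = 35.0
    base_radius_mm: float = 15.0
    bulge_amplitude_mm: float = 0.0
    bulge_center_s0: float | None = None
    bulge_width_sigma_s: float = 15.0
    bulge_section: str = "descending"
    has_dissection: bool = False
    flap_thickness_mm: float = 2.0
    flap_arc_range: tuple[float, float] | None = None
    has_graft: bool = False
    graft_arc_range: tuple[float, float] | None = None
    contrast: bool = True
    wall_thickness_mm: float = 2.0
    voxel_mm: float = 1.0
    noise_sd_hu: float = 10.0
    hu_model: dict = field(default_factory=lambda: dict(DEFAULT_HU_MODEL))
    margin_mm: float = 12.0
    shape: tuple[int, int, int] | None = None
    seed: int = 0

    # ---- derived geometry -------------------------------------------------

    @property
    def arch_length(self) -> float:
        return float(np.pi * self.arch_radius_mm)

    @property
    def total_length(self) -> float:
        return 2.0 * self.limb_length_mm + self.arch_length

    @property
    def landmark_s(self) -> dict[str, float]:
        L, limb = self.total_length, self.limb_length_mm
        out = {"aortic_root": 0.0, "celiac": L}
        for name, f in ARCH_FRACTIONS.items():
            out[name] = limb + f * self.arch_length
        return out

    @property
    def section_ranges(self) -> dict[str, tuple[float, float]]:
        lm = self.landmark_s
        return {
            "ascending": (0.0, lm["brachiocephalic"]),
            "arch": (lm["brachiocephalic"], lm["left_subclavian"]),
            "descending": (lm["left_subclavian"], self.total_length),
        }

    def resolved_bulge_center(self) -> float:
        if self.bulge_center_s0 is not None:
            return float(self.bulge_center_s0)
        lo, hi = self.section_ranges[self.bulge_section]
        return 0.5 * (lo + hi)

    def resolved_flap_range(self) -> tuple[float, float] | None:
        if not self.has_dissection:
            return None
        if self.flap_arc_range is not None:
            return tuple(self.flap_arc_range)
        lo, hi = self.section_ranges["descending"]
        span = hi - lo
        return (lo + 0.2 * span, hi - 0.2 * span)

    def lumen_hu(self) -> float:
        key = "lumen_contrast" if self.contrast else "lumen_noncontrast"
        return float(self.hu_model[key])

    def validate(self) -> None:
        positives = {
            "limb_length_mm": self.limb_length_mm,
            "arch_radius_mm": self.arch_radius_mm,
            "base_radius_mm": self.base_radius_mm,
            "bulge_width_sigma_s": self.bulge_width_sigma_s,
            "flap_thickness_mm": self.flap_thickness_mm,
            "wall_thickness_mm": self.wall_thickness_mm,
            "voxel_mm": self.voxel_mm,
        }
        for name, val in positives.items():
            if val <= 0:
                raise ConfigurationError(f"{name} must be positive (got {val})")
        if self.bulge_amplitude_mm < 0 or self.noise_sd_hu < 0:
            raise ConfigurationError("bulge amplitude and noise sd must be non-negative")
        if self.bulge_section not in ("ascending", "descending"):
            raise ConfigurationError(f"unknown bulge_section {self.bulge_section!r}")
        if self.base_radius_mm <= self.wall_thickness_mm:
            raise ConfigurationError("base radius must exceed the wall thickness")
        s0 = self.resolved_bulge_center()
        lo, hi = self.section_ranges[self.bulge_section]
        if self.bulge_amplitude_mm > 0 and not (lo <= s0 < hi):
            raise ConfigurationError(
                f"bulge_center_s0={s0:.1f} outside {self.bulge_section} range [{lo:.1f}, {hi:.1f})")
        flap = self.resolved_flap_range()
        if flap is not None and not (0 <= flap[0] < flap[1] <= self.total_length):
            raise ConfigurationError(f"flap_arc_range {flap} not inside [0, {self.total_length:.1f}]")
        if self.arch_radius_mm <= self.max_radius():
            raise SizingError("arch radius too small: ascending and descending limbs would merge")

    def max_radius(self) -> float:
        return self.base_radius_mm + self.bulge_amplitude_mm

    def required_shape(self) -> tuple[int, int, int]:
        """Grid just large enough to hold the cane plus margins."""
        rmax = self.max_radius()
        ext_x = 2 * self.arch_radius_mm + 2 * rmax + 2 * self.margin_mm
        ext_y = 2 * rmax + 2 * self.margin_mm
        ext_z = self.limb_length_mm + self.arch_radius_mm + 2 * rmax + 2 * self.margin_mm
        return tuple(int(np.ceil(e / self.voxel_mm)) for e in (ext_x, ext_y, ext_z))


# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Analytic truth for one phantom: centerline, radius, landmarks, labels."""

    spec: PhantomSpec
    centerline_points: np.ndarray      # (N, 3) mm, dense sampling
    centerline_s: np.ndarray           # (N,) arc length mm
    landmarks: dict[str, np.ndarray]   # name -> (3,) mm
    section_ranges: dict[str, tuple[float, float]]
    dissection_label: bool
    dissected_slice_range: tuple[float, float] | None

    @property
    def total_length(self) -> float:
        return self.spec.total_length

    def radius_fn(self, s) -> np.ndarray:
        """Outer vessel radius r(s) in mm (wall outer surface)."""
        s = np.asarray(s, dtype=float)
        spec = self.spec
        r = np.full_like(s, spec.base_radius_mm, dtype=float)
        if spec.bulge_amplitude_mm > 0:
            s0 = spec.resolved_bulge_center()
            r = r + spec.bulge_amplitude_mm * np.exp(
                -((s - s0) ** 2) / (2.0 * spec.bulge_width_sigma_s ** 2))
        return r

    def point_at(self, s) -> np.ndarray:
        """Interpolated centerline point at arc length s (mm)."""
        s = float(s)
        if not (0 <= s <= self.total_length):
            raise DomainError(f"arc length {s} outside [0, {self.total_length:.1f}]")
        return np.array([np.interp(s, self.centerline_s, self.centerline_points[:, k])
                         for k in range(3)])

    def section_max_diameter(self, name: str, ds: float = 0.1) -> tuple[float, float]:
        """(max outer diameter, arg-max arc length) over a section, by dense scan."""
        lo, hi = self.section_ranges[name]
        grid = np.arange(lo, hi, ds)
        d = 2.0 * self.radius_fn(grid)
        j = int(np.argmax(d))
        return float(d[j]), float(grid[j])

    def section_of(self, s: float) -> str:
        for name, (lo, hi) in self.section_ranges.items():
            if lo <= s < hi or (name == "descending" and np.isclose(s, hi)):
                return name
        raise DomainError(f"arc length {s} outside [0, {self.total_length})")

    def rasterized_mask(self, like: Volume, include_wall: bool = True) -> Mask:
        """Ground-truth aorta mask on an arbitrary raster (lumen + wall)."""
        occ = _occupancy(self.spec, like, include_wall=include_wall)
        return Mask(occ >= 0.5, like.spacing_mm, like.origin_mm)

    # ---- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": _spec_to_jsonable(self.spec),
            "landmarks": {k: list(map(float, v)) for k, v in self.landmarks.items()},
            "section_ranges": {k: list(v) for k, v in self.section_ranges.items()},
            "dissection_label": bool(self.dissection_label),
            "dissected_slice_range": (list(self.dissected_slice_range)
                                      if self.dissected_slice_range else None),
            "total_length_mm": self.total_length,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        spec = _spec_from_jsonable(payload["spec"])
        gt = build_ground_truth(spec)
        return gt


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    for k in ("flap_arc_range", "graft_arc_range", "shape"):
        if d[k] is not None:
            d[k] = list(d[k])
    return d


def _spec_from_jsonable(d: dict) -> PhantomSpec:
    d = dict(d)
    for k in ("flap_arc_range", "graft_arc_range", "shape"):
        if d.get(k) is not None:
            d[k] = tuple(d[k])
    return PhantomSpec(**d)


# ---------------------------------------------------------------------------
# geometry helpers

def _grid_center_xy(spec: PhantomSpec, shape=None) -> np.ndarray:
    """(xc, yc, z0): arch axis position and the z of the cane's lower end.

    Always derived from the PhantomSpec's own generation grid so the anchor
    is a fixed world position, independent of any later resampling.
    """
    gen_shape = spec.shape if spec.shape is not None else spec.required_shape()
    ext = np.asarray(gen_shape) * spec.voxel_mm
    rmax = spec.max_radius()
    xc, yc = ext[0] / 2.0, ext[1] / 2.0
    z0 = spec.margin_mm + rmax
    return np.array([xc, yc, z0])


def _cane_points(spec: PhantomSpec, s: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Points on the candy-cane centerline at arc lengths s.

    anchor = (xc, yc, z0); ascending limb at x = xc + R rising from z0,
    arch = half circle of radius R in the x-z plane, descending limb at
    x = xc - R falling back to z0.
    """
    xc, yc, z0 = anchor
    R, limb = spec.arch_radius_mm, spec.limb_length_mm
    s = np.asarray(s, dtype=float)
    pts = np.empty(s.shape + (3,))
    asc = s < limb
    arch = (s >= limb) & (s < limb + spec.arch_length)
    desc = ~asc & ~arch
    pts[asc] = np.stack([np.full(asc.sum(), xc + R), np.full(asc.sum(), yc), z0 + s[asc]], axis=-1)
    theta = (s[arch] - limb) / R
    pts[arch] = np.stack([xc + R * np.cos(theta), np.full(arch.sum(), yc),
                          z0 + limb + R * np.sin(theta)], axis=-1)
    sd = s[desc] - limb - spec.arch_length
    pts[desc] = np.stack([np.full(desc.sum(), xc - R), np.full(desc.sum(), yc),
                          z0 + limb - sd], axis=-1)
    return pts


def _radius_at(spec: PhantomSpec, s: np.ndarray) -> np.ndarray:
    r = np.full_like(np.asarray(s, dtype=float), spec.base_radius_mm)
    if spec.bulge_amplitude_mm > 0:
        s0 = spec.resolved_bulge_center()
        r = r + spec.bulge_amplitude_mm * np.exp(-((np.asarray(s) - s0) ** 2)
                                                 / (2.0 * spec.bulge_width_sigma_s ** 2))
    return r


def _cane_dist_s(spec: PhantomSpec, pts: np.ndarray, anchor: np.ndarray):
    """Closed-form distance from points to the cane and the nearest arc length.

    The cane is two vertical segments plus a half circle in the x-z plane, so
    the nearest point decomposes per primitive; the minimum over the three
    candidates is exact.
    """
    xc, yc, z0 = anchor
    R, limb = spec.arch_radius_mm, spec.limb_length_mm
    zarch = z0 + limb
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    dy = y - yc

    dy2 = dy * dy
    zc = np.clip(z, z0, zarch)
    dzc2 = (z - zc) ** 2

    # ascending limb: x = xc + R, z in [z0, zarch]
    d2 = (x - (xc + R)) ** 2 + dy2 + dzc2
    s = zc - z0

    # descending limb: x = xc - R, same z span
    d2_desc = (x - (xc - R)) ** 2 + dy2 + dzc2
    m = d2_desc < d2
    d2 = np.where(m, d2_desc, d2)
    s = np.where(m, limb + spec.arch_length + (zarch - zc), s)

    # arch: half circle of radius R around (xc, zarch), theta in [0, pi];
    # for z < zarch the nearest arc point is an endpoint, already covered by
    # the limb candidates, so the arch candidate only applies above the plane
    above = z >= zarch
    if above.any():
        xa, za_, dya2 = x[above], z[above], dy2[above]
        rho = np.sqrt((xa - xc) ** 2 + (za_ - zarch) ** 2)
        d2_arch = (rho - R) ** 2 + dya2
        phi = np.arctan2(za_ - zarch, xa - xc)
        s_arch = limb + phi * R
        sub_d2, sub_s = d2[above], s[above]
        ma = d2_arch < sub_d2
        d2[above] = np.where(ma, d2_arch, sub_d2)
        s[above] = np.where(ma, s_arch, sub_s)

    return np.sqrt(d2), s


def _occupancy(spec: PhantomSpec, like: Volume, include_wall: bool) -> np.ndarray:
    """Fractional occupancy of (lumen [+ wall]) on the raster of `like`."""
    anchor = _grid_center_xy(spec, like.shape)
    pts = _voxel_centers(like)
    dist, s_near = _cane_dist_s(spec, pts, anchor)
    r = _radius_at(spec, s_near)
    router = r - (0.0 if include_wall else spec.wall_thickness_mm)
    signed = dist - router
    h = float(np.max(like.spacing_mm))
    occ = np.clip(0.5 - signed / h, 0.0, 1.0)  # linear partial volume
    return occ.reshape(like.shape)


def _voxel_centers(like: Volume) -> np.ndarray:
    ax = [np.arange(n) * sp + o for n, sp, o in zip(like.shape, like.spacing_mm, like.origin_mm)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


# ---------------------------------------------------------------------------
# main entry points

def build_ground_truth(spec: PhantomSpec, centerline_step: float = 1.0) -> GroundTruth:
    spec.validate()
    shape = spec.shape if spec.shape is not None else spec.required_shape()
    anchor = _grid_center_xy(spec, shape)
    n = int(np.ceil(spec.total_length / centerline_step)) + 1
    s = np.linspace(0.0, spec.total_length, n)
    pts = _cane_points(spec, s, anchor)
    lms = {name: _cane_points(spec, np.array([sv]), anchor)[0]
           for name, sv in spec.landmark_s.items()}
    return GroundTruth(
        spec=spec,
        centerline_points=pts,
        centerline_s=s,
        landmarks=lms,
        section_ranges=spec.section_ranges,
        dissection_label=spec.has_dissection,
        dissected_slice_range=spec.resolved_flap_range(),
    )


def synth_case(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Rasterize one phantom. Identical spec (incl. seed) => identical volume."""
    spec.validate()
    shape = spec.shape if spec.shape is not None else spec.required_shape()
    if spec.shape is not None:
        need = spec.required_shape()
        if any(s < r for s, r in zip(shape, need)):
            raise SizingError(
                f"phantom needs a grid of at least {need} voxels at "
                f"{spec.voxel_mm} mm but shape={tuple(shape)} was requested")
    vol = Volume(np.zeros(shape, dtype=np.float32), np.full(3, spec.voxel_mm))
    anchor = _grid_center_xy(spec, shape)

    pts = _voxel_centers(vol)
    dist, s_near = _cane_dist_s(spec, pts, anchor)
    r_outer = _radius_at(spec, s_near)
    r_lumen = r_outer - spec.wall_thickness_mm

    # sub-voxel occupancy: 3x3x3 supersampling, only in the boundary band
    h = spec.voxel_mm
    band = h * np.sqrt(3.0)
    near_lumen = np.abs(dist - r_lumen) < band
    near_outer = np.abs(dist - r_outer) < band
    shell = near_lumen | near_outer

    lumen_frac = (dist < r_lumen).astype(np.float64)
    outer_frac = (dist < r_outer).astype(np.float64)
    if shell.any():
        offs = (np.stack(np.meshgrid(*[[-1, 0, 1]] * 3, indexing="ij"), axis=-1)
                .reshape(-1, 3) * (h / 3.0))
        sub_flat = (pts[shell][:, None, :] + offs[None, :, :]).reshape(-1, 3)
        sdist, ss = _cane_dist_s(spec, sub_flat, anchor)
        sr = _radius_at(spec, ss)
        lumen_frac[shell] = (sdist < sr - spec.wall_thickness_mm).reshape(-1, 27).mean(axis=1)
        outer_frac[shell] = (sdist < sr).reshape(-1, 27).mean(axis=1)

    wall_frac = np.clip(outer_frac - lumen_frac, 0.0, 1.0)
    bg_frac = np.clip(1.0 - outer_frac, 0.0, 1.0)

    hu = spec.hu_model
    wall_hu = np.full(len(pts), float(hu["wall"]))
    if spec.has_graft:
        g = spec.graft_arc_range
        if g is None:
            lo, hi = spec.section_ranges["ascending"]
            g = (lo + (hi - lo) / 3.0, hi - (hi - lo) / 3.0)
        wall_hu[(s_near >= g[0]) & (s_near < g[1])] = float(hu["graft"])

    img = (lumen_frac * spec.lumen_hu() + wall_frac * wall_hu
           + bg_frac * float(hu["background"]))

    flap = spec.resolved_flap_range()
    if flap is not None:
        yc = anchor[1]
        in_flap = ((lumen_frac > 0.5)
                   & (np.abs(pts[:, 1] - yc) < spec.flap_thickness_mm / 2.0)
                   & (s_near >= flap[0]) & (s_near < flap[1]))
        img[in_flap] = float(hu["flap"])

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd_hu, size=img.shape)

    vol.voxels = img.reshape(shape).astype(np.float32)
    return vol, build_ground_truth(spec)


def ground_truth_diameter(gt: GroundTruth, s: float) -> float:
    """Analytic lumen diameter 2*r(s) at arc length s (mm)."""
    if not (0 <= s <= gt.total_length):
        raise DomainError(f"arc length {s} outside [0, {gt.total_length:.1f}]")
    return float(2.0 * gt.radius_fn(s))


# ---------------------------------------------------------------------------
# cohorts

DEFAULT_SPEC_RANGES: dict = {
    "limb_length_mm": (50.0, 70.0),
    "arch_radius_mm": (30.0, 40.0),
    "base_radius_mm": (13.0, 17.0),
    "bulge_amplitude_mm": (0.0, 8.0),
    "bulge_width_sigma_s": (12.0, 20.0),
    "bulge_section": ("ascending", "descending"),
    "contrast": (True, False),
    "noise_sd_hu": 10.0,
    "voxel_mm": 1.0,
}


def make_cohort_specs(n: int, dissection_prevalence: float, seed: int,
                      spec_ranges: dict | None = None) -> list[PhantomSpec]:
    """Draw reproducible per-case specs; exactly round(n*prevalence) dissections."""
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    if not (0.0 <= dissection_prevalence <= 1.0):
        raise ConfigurationError("prevalence must lie in [0, 1]")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges is not None:
        if not spec_ranges:
            raise ConfigurationError("spec_ranges must not be empty")
        ranges.update(spec_ranges)

    rng = np.random.default_rng(seed)
    n_pos = int(round(n * dissection_prevalence))
    labels = np.zeros(n, dtype=bool)
    labels[rng.permutation(n)[:n_pos]] = True

    specs = []
    for i in range(n):
        kw: dict = {}
        for key, val in ranges.items():
            if isinstance(val, tuple) and len(val) == 2 and all(
                    isinstance(v, (int, float)) and not isinstance(v, bool) for v in val):
                kw[key] = float(rng.uniform(*val))
            elif isinstance(val, tuple):
                kw[key] = val[int(rng.integers(len(val)))]
            else:
                kw[key] = val
        kw["has_dissection"] = bool(labels[i])
        kw["seed"] = int(rng.integers(0, 2 ** 31 - 1))
        specs.append(PhantomSpec(**kw))
    return specs


def make_cohort(n: int, dissection_prevalence: float, seed: int,
                spec_ranges: dict | None = None) -> list[tuple[Volume, GroundTruth]]:
    return [synth_case(s) for s in make_cohort_specs(n, dissection_prevalence, seed, spec_ranges)]
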