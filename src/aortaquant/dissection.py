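"""Aortic dissection screening.

The volume is reformatted into a straightened ("curved planar reformation")
stack: one 2D slice per centerline sample (2.0 mm apart), each sampled on the
perpendicular (u, v) plane at 1.0 mm in-plane resolution and masked to the
aortic component. A fixed 18-value feature vector is extracted per slice —
shape, intensity statistics, an 8-bin intensity histogram, and
membrane-sensitive responses (dark-ridge filter, dark-pixel fraction, radial
profile variance) that light up when a dissection flap crosses the lumen. An
RBF-kernel SVM scores each slice with a calibrated probability, and the slice
probabilities are pooled by a top-k mean into one patient-level probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure

from .errors import InputError, TrainingError
from .geometry import Centerline
from .phantom import GroundTruth
from .volume import Mask, Volume

__all__ = ["StraightenedVolume", "DissectionResult", "straighten",
           "slice_features", "FEATURE_NAMES", "slice_labels_from_gt",
           "DissectionClassifier", "train_dissection_classifier",
           "predict_dissection", "pool_probabilities"]

_FILL_HU = -100.0

FEATURE_NAMES = (
    "area_mm2", "equivalent_diameter_mm", "eccentricity",
    "hu_mean", "hu_sd", "hu_skewness", "hu_kurtosis",
    "hist_0", "hist_1", "hist_2", "hist_3", "hist_4", "hist_5", "hist_6", "hist_7",
    "max_dark_ridge", "dark_fraction", "radial_profile_variance",
)


@dataclass
class StraightenedVolume:
    """Stack of perpendicular slices along the centerline."""

    slices: np.ndarray          # (n, H, W) HU, masked to the aorta
    components: np.ndarray      # (n, H, W) bool, in-plane aortic component
    s: np.ndarray               # (n,) arc length mm
    section: np.ndarray | None  # (n,) labels or None
    inplane_mm: float
    spacing_mm: float           # between slices
    valid: np.ndarray = field(default=None)  # (n,) bool

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def straighten(v: Volume, m: Mask, c: Centerline, window_mm: float = 80.0,
               inplane_mm: float = 1.0) -> StraightenedVolume:
    """Resample the volume into a straightened stack along the centerline.

    Intensities are linearly interpolated; the in-plane aortic component is
    the mask's connected component containing the centerline point. Slices
    whose plane misses the mask are kept but flagged invalid.
    """
    half = window_mm / 2.0
    npix = int(round(window_mm / inplane_mm)) + 1
    offs = np.linspace(-half, half, npix)
    n = c.n
    slices = np.full((n, npix, npix), _FILL_HU, dtype=np.float32)
    comps = np.zeros((n, npix, npix), dtype=bool)
    valid = np.zeros(n, dtype=bool)
    center = npix // 2
    vox = np.asarray(v.voxels, dtype=np.float32)
    mvox = m.voxels.astype(np.float32)
    for i in range(n):
        p0, uu, vv = c.points[i], c.u[i], c.v[i]
        world = (p0[None, None, :] + offs[:, None, None] * uu[None, None, :]
                 + offs[None, :, None] * vv[None, None, :])
        vi = (world - v.origin_mm) / v.spacing_mm
        hu = ndimage.map_coordinates(vox, [vi[..., 0], vi[..., 1], vi[..., 2]],
                                     order=1, mode="constant", cval=_FILL_HU)
        mi = (world - m.origin_mm) / m.spacing_mm
        plane_mask = ndimage.map_coordinates(mvox, [mi[..., 0], mi[..., 1], mi[..., 2]],
                                             order=0, mode="constant", cval=0.0) >= 0.5
        lab, nlab = ndimage.label(plane_mask)
        comp = None
        if nlab:
            for di in (0, -1, 1):
                for dj in (0, -1, 1):
                    l = lab[center + di, center + dj]
                    if l > 0:
                        comp = lab == l
                        break
                if comp is not None:
                    break
        if comp is None:
            continue
        slices[i] = np.where(comp, hu, _FILL_HU)
        comps[i] = comp
        valid[i] = True
    return StraightenedVolume(slices, comps, c.s.copy(),
                              None if c.section is None else c.section.copy(),
                              inplane_mm, float(c.step), valid)


def slice_features(slice_hu: np.ndarray, lumen_component: np.ndarray,
                   inplane_mm: float = 1.0) -> tuple[np.ndarray, bool]:
    """18-value feature vector for one straightened slice.

    Returns (features, valid); an empty component yields a zero vector with
    ``valid=False``. Feature order is :data:`FEATURE_NAMES`.
    """
    comp = lumen_component.astype(bool)
    npx = int(comp.sum())
    if npx == 0:
        return np.zeros(len(FEATURE_NAMES)), False
    vals = slice_hu[comp].astype(float)

    area = npx * inplane_mm ** 2
    eq_d = 2.0 * np.sqrt(area / np.pi)
    props = measure.regionprops(comp.astype(np.uint8))[0]
    ecc = float(props.eccentricity)

    mu = float(vals.mean())
    sd = float(vals.std())
    skw = float(stats.skew(vals)) if sd > 1e-9 else 0.0
    kur = float(stats.kurtosis(vals)) if sd > 1e-9 else 0.0

    hist, _ = np.histogram(vals, bins=8, range=(-100.0, 500.0))
    hist = hist / max(1, npx)

    # dark-ridge (membrane) response: Sato tubeness of dark lines, evaluated
    # away from the component boundary so the rim does not dominate
    ridge = filters.sato(slice_hu.astype(float), sigmas=[1.0, 2.0],
                         black_ridges=True)
    inner = ndimage.binary_erosion(comp, iterations=3)
    max_ridge = float(ridge[inner].max()) if inner.any() else 0.0

    med = float(np.median(vals))
    dark_frac = float(np.mean(vals < med - 50.0))

    ii, jj = np.nonzero(comp)
    ci, cj = ii.mean(), jj.mean()
    r = np.hypot(ii - ci, jj - cj)
    nb = 8
    edges = np.linspace(0.0, max(r.max(), 1e-6) + 1e-6, nb + 1)
    which = np.clip(np.digitize(r, edges) - 1, 0, nb - 1)
    sums = np.bincount(which, weights=vals, minlength=nb)
    cnts = np.bincount(which, minlength=nb)
    prof = sums[cnts > 0] / cnts[cnts > 0]
    rad_var = float(prof.var()) if len(prof) > 1 else 0.0

    feats = np.array([area, eq_d, ecc, mu, sd, skw, kur, *hist,
                      max_ridge, dark_frac, rad_var])
    return feats, True


def slice_labels_from_gt(sv: StraightenedVolume, gt: GroundTruth) -> np.ndarray:
    """Per-slice dissection labels from the phantom's dissected arc range."""
    labels = np.zeros(sv.n_slices, dtype=bool)
    rng = gt.dissected_slice_range
    if rng is not None:
        labels = (sv.s >= rng[0]) & (sv.s < rng[1])
    return labels


@dataclass
class DissectionResult:
    slice_probabilities: np.ndarray
    patient_probability: float
    decision: bool
    threshold: float
    top_k: int
    indeterminate: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "slice_probabilities": [float(p) for p in self.slice_probabilities],
            "patient_probability": float(self.patient_probability),
            "decision": bool(self.decision),
            "threshold": float(self.threshold),
            "top_k": int(self.top_k),
            "indeterminate": bool(self.indeterminate),
        }, indent=2))


class DissectionClassifier:
    """Standardizer + calibrated RBF-SVM over slice features."""

    def __init__(self, scaler_mean, scaler_sd, svm, best_params: dict, seed: int):
        self.scaler_mean = scaler_mean
        self.scaler_sd = scaler_sd
        self.svm = svm
        self.best_params = best_params
        self.seed = seed

    def slice_probabilities(self, sv: StraightenedVolume) -> np.ndarray:
        probs = np.zeros(sv.n_slices)
        feats = []
        valid_idx = []
        for i in range(sv.n_slices):
            if sv.valid is not None and not sv.valid[i]:
                continue
            f, ok = slice_features(sv.slices[i], sv.components[i], sv.inplane_mm)
            if ok:
                feats.append(f)
                valid_idx.append(i)
        if feats:
            X = (np.asarray(feats) - self.scaler_mean) / self.scaler_sd
            probs[valid_idx] = self.svm.predict_proba(X)[:, 1]
        return probs

    def save(self, path: str | Path) -> None:
        import joblib
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "DissectionClassifier":
        import joblib
        return joblib.load(path)


def train_dissection_classifier(cohort: list[tuple[StraightenedVolume, np.ndarray]],
                                svm_cfg: dict | None = None,
                                seed: int = 0) -> DissectionClassifier:
    """Fit the slice-level SVM on (straightened volume, per-slice labels) pairs.

    Features are standardized with training-set statistics; C and the kernel
    width are selected by 3-fold grid search; probabilities come from the
    SVM's internal cross-validated sigmoid calibration. Deterministic for a
    fixed seed.
    """
    from sklearn.model_selection import GridSearchCV
    from sklearn.svm import SVC

    X, y = [], []
    for sv, labels in cohort:
        labels = np.asarray(labels, dtype=bool)
        if len(labels) != sv.n_slices:
            raise InputError("label vector length must match slice count")
        for i in range(sv.n_slices):
            if sv.valid is not None and not sv.valid[i]:
                continue
            f, ok = slice_features(sv.slices[i], sv.components[i], sv.inplane_mm)
            if ok:
                X.append(f)
                y.append(labels[i])
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("need both dissected and non-dissected slices")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - mean) / sd

    grid = svm_cfg or {"C": [1.0, 10.0, 100.0], "gamma": ["scale", 0.1, 0.01]}
    search = GridSearchCV(SVC(kernel="rbf", probability=True, random_state=seed),
                          grid, cv=3, n_jobs=1)
    search.fit(Xs, y)
    return DissectionClassifier(mean, sd, search.best_estimator_,
                                dict(search.best_params_), seed)


def pool_probabilities(slice_probs: np.ndarray, top_k: int | None = None) -> tuple[float, int]:
    """Top-k mean pooling; k defaults to max(3, 10% of slices)."""
    p = np.asarray(slice_probs, dtype=float)
    if top_k is None:
        top_k = max(3, int(np.ceil(0.1 * len(p))))
    top_k = min(top_k, len(p))
    top = np.sort(p)[::-1][:top_k]
    return float(top.mean()), int(top_k)


def predict_dissection(classifier: DissectionClassifier, sv: StraightenedVolume,
                       threshold: float = 0.5,
                       top_k: int | None = None) -> DissectionResult:
    """Per-slice probabilities pooled to one patient-level decision.

    Fewer than 3 valid slices flags the result indeterminate (probability
    still reported over whatever slices exist).
    """
    probs = classifier.slice_probabilities(sv)
    n_valid = int(sv.valid.sum()) if sv.valid is not None else sv.n_slices
    patient_p, k = pool_probabilities(probs, top_k)
    return DissectionResult(probs, patient_p, patient_p >= threshold,
                            threshold, k, indeterminate=n_valid < 3)
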