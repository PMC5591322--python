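"""MRI arm: lesion filling, rigid coregistration, tissue segmentation,
white-matter-hyperintensity (WMH) extraction, periventricular vs deep
classification, quadrant partition and regional volumes in cc.

WMHs are bright on FLAIR.  They are extracted by thresholding FLAIR within
white matter at ``mean + k_sigma * sd`` of normal-appearing WM (robustly
estimated in two passes), labelled with 26-connectivity, classified as
periventricular (PVH) or deep (DWMH) by Euclidean distance to the ventricle
mask, split into four areas by the midsagittal plane (longitudinal fissure)
and a coronal plane through the central sulcus, and reported as eight region
volumes in cubic centimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from ._exceptions import (
    RegistrationError,
    SegmentationError,
    ValidationError,
)
from .core_io import LabelMap, RigidTransform, Volume3D, resample

__all__ = [
    "TissueMap",
    "WMHThresholdParams",
    "LesionComponentMap",
    "WMHRegionVolumes",
    "PartitionPlanes",
    "fill_lesions",
    "register_rigid",
    "segment_tissues",
    "extract_ventricles",
    "extract_wmh",
    "classify_pvh_dwmh",
    "partition_quadrants",
    "compute_region_volumes",
]

CSF, GM, WM = 1, 2, 3
TISSUE_NAMES = {CSF: "CSF", GM: "GM", WM: "WM"}
QUADRANTS = {1: "RA", 2: "RP", 3: "LA", 4: "LP"}
QUADRANT_IDS = {v: k for k, v in QUADRANTS.items()}

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TissueMap:
    """3-class tissue segmentation: 1 CSF, 2 GM, 3 WM (0 background)."""

    labels: LabelMap
    class_means: dict[int, float]

    def __post_init__(self) -> None:
        m = self.class_means
        if not (m[CSF] < m[GM] < m[WM]):
            raise ValidationError("class means must satisfy CSF < GM < WM")

    def mask(self, tissue: int) -> np.ndarray:
        return self.labels.labels == tissue


@dataclass
class WMHThresholdParams:
    """Threshold = mean + k_sigma*sd of normal-appearing WM on FLAIR."""

    k_sigma: float = 3.0
    min_component_voxels: int = 5
    wm_stats: tuple[float, float] | None = None  # filled by extract_wmh

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValidationError("k_sigma must be > 0")
        if self.min_component_voxels < 1:
            raise ValidationError("min_component_voxels must be >= 1")


@dataclass
class PartitionPlanes:
    """World-mm planes dividing the brain into the four areas."""

    midsagittal_x: float
    central_y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.midsagittal_x) and np.isfinite(self.central_y)):
            raise ValidationError("partition planes must be finite")


@dataclass
class LesionComponentMap:
    """Labelled WMH connected components with per-component attributes.

    ``components`` has one row per component: id, n_voxels, volume_cc and,
    once assigned, class ('PVH'/'DWMH') and quadrant ('RA'/'RP'/'LA'/'LP').
    """

    labels: np.ndarray          # 0 background, 1..n component ids
    affine: np.ndarray
    components: pd.DataFrame

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def as_labelmap(self) -> LabelMap:
        lut = {int(r.component): f"wmh_{int(r.component)}"
               for r in self.components.itertuples()}
        return LabelMap(self.labels, self.affine, lut)


@dataclass
class WMHRegionVolumes:
    """The eight region volumes (cc) and their total.

    Ordered as the report layout: PVH then DWMH, right before left,
    anterior before posterior.
    """

    pvh_ra: float
    pvh_rp: float
    pvh_la: float
    pvh_lp: float
    dwmh_ra: float
    dwmh_rp: float
    dwmh_la: float
    dwmh_lp: float
    total: float = field(default=None)  # type: ignore[assignment]

    _CELLS = ("pvh_ra", "pvh_rp", "pvh_la", "pvh_lp",
              "dwmh_ra", "dwmh_rp", "dwmh_la", "dwmh_lp")

    def __post_init__(self) -> None:
        cells = [getattr(self, c) for c in self._CELLS]
        if any(v < 0 for v in cells):
            raise ValidationError("region volumes must be >= 0")
        s = float(sum(cells))
        if self.total is None:
            self.total = s
        elif abs(self.total - s) > 1e-9:
            raise ValidationError("total must equal the sum of the 8 cells")

    def to_series(self) -> pd.Series:
        d = {"total": self.total}
        d.update({c: getattr(self, c) for c in self._CELLS})
        return pd.Series(d)


# ---------------------------------------------------------------------------
# Lesion filling
# ---------------------------------------------------------------------------

def fill_lesions(t1: Volume3D, lesion_prior: LabelMap, seed: int,
                 ring_mm: float = 10.0,
                 wm_mask: np.ndarray | None = None) -> Volume3D:
    """Replace lesion voxels on T1 with plausible WM-like intensities.

    For each lesion connected component the replacement values are drawn
    from a Normal with the mean/sd of the non-lesion WM intensities inside
    a ``ring_mm`` dilation ring around that component (``wm_mask``
    restricts the ring to white matter; without it every non-lesion ring
    voxel is used).  Deterministic given ``seed``; all non-lesion voxels
    pass through unchanged.
    """
    if t1.shape != lesion_prior.shape:
        raise ValidationError("t1 and lesion_prior must share one grid")
    mask = lesion_prior.mask()
    out = np.array(t1.voxels, dtype=float, copy=True)
    if not mask.any():
        return t1.like(out)

    rng = np.random.default_rng(seed)
    spacing = np.sqrt((t1.affine[:3, :3] ** 2).sum(axis=0))
    comp, n = ndimage.label(mask, structure=_STRUCT26)
    reference_ok = ~mask if wm_mask is None else (np.asarray(wm_mask, bool)
                                                  & ~mask)
    objects = ndimage.find_objects(comp)
    pad = np.ceil(ring_mm / spacing).astype(int) + 1
    for c in range(1, n + 1):
        sl = objects[c - 1]
        grown = tuple(
            slice(max(0, s.start - p), min(dim, s.stop + p))
            for s, p, dim in zip(sl, pad, t1.shape))
        cmask = comp[grown] == c
        dist = ndimage.distance_transform_edt(~cmask, sampling=spacing)
        ring = (dist <= ring_mm) & reference_ok[grown]
        if not ring.any():
            raise ValidationError(
                f"lesion component {c}: no reference intensities in "
                f"{ring_mm} mm ring")
        ref = out[grown][ring]
        mu, sd = float(ref.mean()), float(ref.std())
        out[grown][cmask] = rng.normal(mu, sd, size=int(cmask.sum()))
    return t1.like(out)


# ---------------------------------------------------------------------------
# Rigid registration by normalized mutual information
# ---------------------------------------------------------------------------

def _nmi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Normalized mutual information (H(a)+H(b))/H(a,b) of two samples."""
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hx = -np.nansum(np.where(px > 0, px * np.log(px), 0.0))
        hy = -np.nansum(np.where(py > 0, py * np.log(py), 0.0))
        hxy = -np.nansum(np.where(p > 0, p * np.log(p), 0.0))
    if hxy <= 0:
        return 2.0
    return float((hx + hy) / hxy)


def _params_to_transform(p: np.ndarray, center: np.ndarray) -> RigidTransform:
    """(rx,ry,rz deg, tx,ty,tz mm) -> rigid map rotating about ``center``."""
    t = RigidTransform.from_euler(p[:3], (0.0, 0.0, 0.0))
    translation = center - t.rotation @ center + np.asarray(p[3:6], dtype=float)
    return RigidTransform(t.rotation, translation)


def register_rigid(moving: Volume3D, fixed: Volume3D,
                   init: RigidTransform | None = None,
                   bins: int = 32, smooth_sigma: float = 1.0) -> RigidTransform:
    """Rigid coregistration maximizing normalized mutual information.

    Returns the transform mapping fixed world coordinates into moving world
    coordinates (the pull-back convention of :func:`core_io.resample`), so
    ``resample(moving, fixed, result)`` aligns the moving image with the
    fixed one.  A two-level pyramid with Powell refinement from ``init``.
    """
    if init is None:
        init = RigidTransform.identity()

    fsm = fixed.like(ndimage.gaussian_filter(
        np.asarray(fixed.voxels, dtype=float), smooth_sigma))
    msm = moving.like(ndimage.gaussian_filter(
        np.asarray(moving.voxels, dtype=float), smooth_sigma))

    # overlap check at init: some fixed voxels must land inside moving
    probe = resample(msm, fsm, init, interp="nearest", fill=np.nan)
    if np.isnan(probe.voxels).all():
        raise RegistrationError("no overlap between volumes at init")

    center = fixed.voxel_to_world((np.asarray(fixed.shape) - 1) / 2.0)
    fvals_full = np.asarray(fsm.voxels, dtype=float).ravel()

    def cost_on(fixed_level: Volume3D, fvals: np.ndarray):
        def cost(p: np.ndarray) -> float:
            t = init.compose(_params_to_transform(p, center))
            mov = resample(msm, fixed_level, t, interp="trilinear",
                           fill=np.nan)
            mv = mov.voxels.ravel()
            ok = np.isfinite(mv)
            if ok.sum() < 100:
                return 0.0
            return -_nmi(fvals[ok], mv[ok], bins=bins)
        return cost

    # coarse level: downsample fixed grid by 2 (affine preserved)
    coarse_vox = fsm.voxels[::2, ::2, ::2]
    coarse_aff = fsm.affine.copy()
    coarse_aff[:3, :3] *= 2.0
    coarse = Volume3D(np.asarray(coarse_vox, dtype=float), coarse_aff,
                      fsm.units)

    p = np.zeros(6)
    for level, fv, maxfev in (
            (coarse, np.asarray(coarse.voxels).ravel(), 800),
            (fsm, fvals_full, 250)):
        res = optimize.minimize(
            cost_on(level, fv), p, method="Powell",
            options={"xtol": 5e-3, "ftol": 1e-7, "maxfev": maxfev})
        p = res.x
    return init.compose(_params_to_transform(p, center))


# ---------------------------------------------------------------------------
# Tissue segmentation (3-class EM Gaussian mixture)
# ---------------------------------------------------------------------------

def segment_tissues(t1_filled: Volume3D, brain_mask: LabelMap, seed: int = 0,
                    max_iter: int = 100, tol: float = 1e-6) -> TissueMap:
    """Segment brain voxels into CSF/GM/WM by a 3-class Gaussian mixture.

    EM on the T1 intensity histogram within the brain mask, initialized
    from the 0.1/0.5/0.9 intensity quantiles; classes are relabelled so
    mean(CSF) < mean(GM) < mean(WM) regardless of the EM start.
    """
    if t1_filled.shape != brain_mask.shape:
        raise ValidationError("t1 and brain mask must share one grid")
    mask = brain_mask.mask()
    if not mask.any():
        raise ValidationError("brain mask is empty")
    x = np.asarray(t1_filled.voxels, dtype=float)[mask]
    if x.std() <= 0:
        raise SegmentationError("constant intensity within brain mask")

    k = 3
    mu = np.quantile(x, [0.1, 0.5, 0.9]).astype(float)
    if len(np.unique(mu)) < k:
        raise SegmentationError("fewer than 3 distinguishable intensity modes")
    var = np.full(k, x.var() / k)
    w = np.full(k, 1.0 / k)
    ll_old = -np.inf
    min_var = max(1e-10, 1e-8 * x.var())
    for _ in range(max_iter):
        # E step: responsibilities under current Gaussians
        diff = x[:, None] - mu[None, :]
        log_pdf = (-0.5 * diff**2 / var[None, :]
                   - 0.5 * np.log(2 * np.pi * var[None, :]))
        log_r = np.log(w[None, :]) + log_pdf
        m = log_r.max(axis=1, keepdims=True)
        r = np.exp(log_r - m)
        rs = r.sum(axis=1, keepdims=True)
        r /= rs
        ll = float((m.ravel() + np.log(rs.ravel())).sum())
        # M step
        nk = r.sum(axis=0)
        if np.any(nk < 1e-8):
            raise SegmentationError("EM collapsed: empty mixture component")
        w = nk / nk.sum()
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < min_var):
            raise SegmentationError("EM degenerate covariance")
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            break
        ll_old = ll

    order = np.argsort(mu)  # CSF < GM < WM on T1
    hard = np.argmax(r, axis=1)
    relabel = np.empty(k, dtype=int)
    relabel[order] = [CSF, GM, WM]
    labels = np.zeros(t1_filled.shape, dtype=np.int16)
    labels[mask] = relabel[hard]
    lm = LabelMap(labels, t1_filled.affine.copy(), dict(TISSUE_NAMES))
    means = {int(relabel[j]): float(mu[j]) for j in range(k)}
    return TissueMap(lm, means)


# ---------------------------------------------------------------------------
# Ventricle extraction
# ---------------------------------------------------------------------------

def extract_ventricles(tissue: TissueMap, brain_mask: LabelMap) -> LabelMap:
    """CSF components interior to the brain: the ventricle mask.

    Keeps CSF connected components that do not touch the brain-mask
    boundary and whose centroid lies within the central 50% of the brain
    bounding box along every axis.  Surface CSF (sulci rim) is rejected.
    """
    csf = tissue.mask(CSF)
    brain = brain_mask.mask()
    affine = tissue.labels.affine
    if not csf.any():
        return LabelMap(np.zeros(csf.shape, dtype=np.int16), affine, {})

    outside = ~brain
    near_boundary = ndimage.binary_dilation(outside, structure=_STRUCT26)
    idx = np.argwhere(brain)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    span = hi - lo
    c_lo = lo + 0.25 * span
    c_hi = lo + 0.75 * span

    comp, n = ndimage.label(csf, structure=_STRUCT26)
    keep = np.zeros(csf.shape, dtype=bool)
    for c in range(1, n + 1):
        cmask = comp == c
        if (cmask & near_boundary).any():
            continue
        centroid = np.array(ndimage.center_of_mass(cmask))
        if np.all(centroid >= c_lo) and np.all(centroid <= c_hi):
            keep |= cmask
    if not keep.any():
        warnings.warn("no interior CSF component found: empty ventricle mask",
                      stacklevel=2)
        return LabelMap(np.zeros(csf.shape, dtype=np.int16), affine, {})
    return LabelMap.from_mask(keep, affine, "ventricles")


# ---------------------------------------------------------------------------
# WMH extraction
# ---------------------------------------------------------------------------

def robust_wm_stats(flair: Volume3D, wm_mask: np.ndarray,
                    k_sigma: float, passes: int = 2) -> tuple[float, float]:
    """Mean/sd of normal-appearing WM, iteratively excluding hyperintense
    voxels above mean + k_sigma*sd (``passes`` exclusion passes)."""
    x = np.asarray(flair.voxels, dtype=float)[wm_mask]
    if x.size == 0:
        raise ValidationError("empty WM mask")
    mu, sd = float(x.mean()), float(x.std())
    for _ in range(passes):
        keep = x <= mu + k_sigma * sd
        if not keep.any():
            break
        x = x[keep]
        mu, sd = float(x.mean()), float(x.std())
    return mu, sd


def extract_wmh(flair: Volume3D, wm_mask: LabelMap,
                params: WMHThresholdParams) -> LesionComponentMap:
    """Threshold FLAIR within WM at mean + k_sigma*sd of normal WM.

    Connected components use 26-connectivity; components smaller than
    ``min_component_voxels`` are discarded as noise.  Classes and quadrants
    are left unset (see :func:`classify_pvh_dwmh` and
    :func:`compute_region_volumes`).
    """
    if flair.shape != wm_mask.shape:
        raise ValidationError("flair and wm_mask must share one grid")
    mask = wm_mask.mask()
    mu, sd = robust_wm_stats(flair, mask, params.k_sigma)
    params.wm_stats = (mu, sd)
    thr = mu + params.k_sigma * sd
    wmh = mask & (np.asarray(flair.voxels, dtype=float) > thr)

    comp, n = ndimage.label(wmh, structure=_STRUCT26)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n + 1))
        keep_ids = np.flatnonzero(sizes >= params.min_component_voxels) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep_ids] = np.arange(1, len(keep_ids) + 1)
        comp = relabel[comp]
        sizes = sizes[keep_ids - 1]
    else:
        sizes = np.array([])

    vv = float(abs(np.linalg.det(flair.affine[:3, :3])))
    table = pd.DataFrame({
        "component": np.arange(1, len(sizes) + 1, dtype=int),
        "n_voxels": sizes.astype(int),
        "volume_cc": sizes * vv / 1000.0,
        "class": pd.Series([None] * len(sizes), dtype=object),
        "quadrant": pd.Series([None] * len(sizes), dtype=object),
    })
    return LesionComponentMap(comp.astype(np.int32), flair.affine.copy(), table)


def classify_pvh_dwmh(lesions: LesionComponentMap, ventricles: LabelMap,
                      d_mm: float = 3.0) -> LesionComponentMap:
    """Assign PVH/DWMH by minimum Euclidean distance to the ventricles.

    A component is periventricular iff its minimum world-mm distance to any
    ventricle voxel is <= d_mm (inclusive); otherwise deep.  With an empty
    ventricle mask every component is DWMH (with a warning).
    """
    if lesions.labels.shape != ventricles.shape:
        raise ValidationError("lesions and ventricles must share one grid")
    table = lesions.components.copy()
    if lesions.n_components == 0:
        return LesionComponentMap(lesions.labels, lesions.affine, table)
    vmask = ventricles.mask()
    if not vmask.any():
        warnings.warn("empty ventricle mask: all components classified DWMH",
                      stacklevel=2)
        table["class"] = "DWMH"
        return LesionComponentMap(lesions.labels, lesions.affine, table)
    spacing = np.sqrt((np.asarray(lesions.affine)[:3, :3] ** 2).sum(axis=0))
    dist = ndimage.distance_transform_edt(~vmask, sampling=spacing)
    min_d = ndimage.minimum(dist, labels=lesions.labels,
                            index=table["component"].to_numpy())
    table["class"] = np.where(np.atleast_1d(min_d) <= d_mm, "PVH", "DWMH")
    table["ventricle_distance_mm"] = np.atleast_1d(min_d)
    return LesionComponentMap(lesions.labels, lesions.affine, table)


# ---------------------------------------------------------------------------
# Quadrant partition and region volumes
# ---------------------------------------------------------------------------

def partition_quadrants(grid: Volume3D, planes: PartitionPlanes) -> LabelMap:
    """Label every voxel RA/RP/LA/LP by its world-space centre.

    x >= midsagittal_x is right, y >= central_y is anterior (boundary
    voxels are assigned right/anterior).
    """
    x, y, _ = grid.world_coordinates()
    right = x >= planes.midsagittal_x
    anterior = y >= planes.central_y
    labels = np.empty(grid.shape, dtype=np.int16)
    labels[right & anterior] = QUADRANT_IDS["RA"]
    labels[right & ~anterior] = QUADRANT_IDS["RP"]
    labels[~right & anterior] = QUADRANT_IDS["LA"]
    labels[~right & ~anterior] = QUADRANT_IDS["LP"]
    return LabelMap(labels, grid.affine.copy(), dict(QUADRANTS))


def compute_region_volumes(lesions: LesionComponentMap,
                           quadrants: LabelMap) -> WMHRegionVolumes:
    """The eight PVH/DWMH x quadrant volumes in cc.

    A component spanning a plane contributes voxelwise to each side; the
    total equals the sum of the eight cells exactly.
    """
    if lesions.labels.shape != quadrants.shape:
        raise ValidationError("lesions and quadrants must share one grid")
    if lesions.n_components and lesions.components["class"].isna().any():
        raise ValidationError("lesions must be classified before volumetry")
    vv = lesions.voxel_volume_mm3
    cells = {f"{cls}_{q}": 0.0
             for cls in ("pvh", "dwmh") for q in ("ra", "rp", "la", "lp")}
    if lesions.n_components:
        n_comp = int(lesions.components["component"].max())
        cls_of = np.zeros(n_comp + 1, dtype=np.int8)  # 1 PVH, 2 DWMH
        comp_ids = lesions.components["component"].to_numpy()
        cls_of[comp_ids] = np.where(
            lesions.components["class"].to_numpy() == "PVH", 1, 2)
        lesion_vox = lesions.labels > 0
        cls_vox = cls_of[lesions.labels[lesion_vox]]
        q_vox = quadrants.labels[lesion_vox]
        for ci, cname in ((1, "pvh"), (2, "dwmh")):
            for qid, qname in QUADRANTS.items():
                n = int(((cls_vox == ci) & (q_vox == qid)).sum())
                cells[f"{cname}_{qname.lower()}"] = n * vv / 1000.0
    return WMHRegionVolumes(**cells)
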