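"""Synthetic phantoms with known ground truth for every pipeline arm.

Three generators:

* :func:`make_mri_phantom` — an ellipsoidal brain with a surface CSF rim,
  a GM mantle, a WM core, bilateral ventricle cavities and spherical WMH
  lesions of known volume/class/quadrant, rendered as T1 (lesions
  hypointense) and FLAIR (lesions at WM mean + 6 sd) volumes.
* :func:`make_spect_phantom` — dynamic radionuclide-angiography frames
  obeying the Patlak model Cb = K*intCa + V*Ca with a gamma-variate aortic
  input, plus a static count volume produced by the Lassen saturation law
  from known segment flows painted into the ROI template.
* :func:`make_cohort` — subject tables with predictors drawn from
  realistic distributions and outcomes drawn from a log-link GLM with
  known coefficients.

All randomness flows through one seeded generator per call; identical
specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._exceptions import ValidationError
from .core_io import DynamicSeries, LabelMap, Volume3D
from .spect import CBFCalibration, lassen_forward
from .template import ANALYSIS_REGIONS, ROITemplate, build_template
from .wmh import CSF, GM, WM, TISSUE_NAMES, PartitionPlanes, QUADRANTS

__all__ = [
    "LesionSpec",
    "MriPhantomSpec",
    "SpectPhantomSpec",
    "CohortSpec",
    "make_mri_phantom",
    "make_spect_phantom",
    "make_cohort",
]


# ---------------------------------------------------------------------------
# MRI phantom
# ---------------------------------------------------------------------------

@dataclass
class LesionSpec:
    """One spherical WMH lesion: centre/radius in world mm + intended truth."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    intended_class: Literal["PVH", "DWMH"]
    intended_quadrant: Literal["RA", "RP", "LA", "LP"]


def _default_lesions(radius_scale: float = 1.0) -> list[LesionSpec]:
    # One DWMH per quadrant placed mid-WM (>= 9 mm from the ventricle
    # surface, so well clear of the 3 mm decision boundary) plus one PVH
    # per quadrant overlapping the ventricle wall (ventricles sit at
    # x = +-11 mm, semi-axes (7, 22, 9) mm).  Radii may be scaled in
    # [0.9, 1.1] without violating the WM-shell or separation margins.
    s = radius_scale
    return [
        LesionSpec((30, 22, 8), 5.5 * s, "DWMH", "RA"),
        LesionSpec((28, -26, 6), 6.5 * s, "DWMH", "RP"),
        LesionSpec((-30, 21, 6), 5.0 * s, "DWMH", "LA"),
        LesionSpec((-28, -25, 7), 6.0 * s, "DWMH", "LP"),
        LesionSpec((19, 11, -2), 5.5 * s, "PVH", "RA"),
        LesionSpec((19, -13, -2), 6.0 * s, "PVH", "RP"),
        LesionSpec((-19, 12, -2), 5.5 * s, "PVH", "LA"),
        LesionSpec((-19, -14, -2), 6.0 * s, "PVH", "LP"),
    ]


@dataclass
class MriPhantomSpec:
    """Geometry, intensities and lesions of the MRI phantom."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_mm: float = 1.0
    brain_semiaxes_mm: tuple[float, float, float] = (52.0, 60.0, 50.0)
    wm_scale: float = 0.85       # WM core = brain ellipsoid scaled by this
    csf_rim_scale: float = 0.95  # outside this scale the brain is surface CSF
    ventricle_centers_mm: Sequence[tuple[float, float, float]] = (
        (11.0, 0.0, 0.0), (-11.0, 0.0, 0.0))
    ventricle_semiaxes_mm: tuple[float, float, float] = (7.0, 22.0, 9.0)
    lesions: list[LesionSpec] = field(default_factory=_default_lesions)
    t1_means: dict[int, float] = field(
        default_factory=lambda: {CSF: 30.0, GM: 70.0, WM: 110.0})
    t1_lesion_mean: float = 60.0
    t1_sd: float = 5.0
    flair_means: dict[int, float] = field(
        default_factory=lambda: {CSF: 30.0, GM: 90.0, WM: 100.0})
    flair_sd: float = 2.0
    flair_lesion_sigmas: float = 6.0  # lesion = WM mean + this many sd
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 8:
            raise ValidationError("phantom grid too small")
        for les in self.lesions:
            if les.radius_mm <= self.voxel_mm:
                raise ValidationError("lesion radius must exceed voxel size")


def _centered_affine(shape, voxel_mm: float) -> np.ndarray:
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    return aff


def _world_grids(shape, affine):
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    x = affine[0, 0] * ii + affine[0, 3]
    y = affine[1, 1] * jj + affine[1, 3]
    z = affine[2, 2] * kk + affine[2, 3]
    return x, y, z


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def make_mri_phantom(spec: MriPhantomSpec):
    """Render the MRI phantom.

    Returns ``(t1, flair, truth)`` where ``truth`` is a dict with the
    generating tissue LabelMap, ventricle mask, lesion LabelMap (one label
    per lesion), a per-lesion table (class/quadrant/volume cc by voxel
    count), the eight-cell region-volume table, and the partition planes
    (midsagittal x = 0, central-sulcus y = 0 by construction).
    """
    affine = _centered_affine(spec.shape, spec.voxel_mm)
    x, y, z = _world_grids(spec.shape, affine)
    origin = (0.0, 0.0, 0.0)

    brain = _ellipsoid(x, y, z, origin, spec.brain_semiaxes_mm)
    wm_core = _ellipsoid(x, y, z, origin,
                         np.asarray(spec.brain_semiaxes_mm) * spec.wm_scale)
    inner = _ellipsoid(x, y, z, origin,
                       np.asarray(spec.brain_semiaxes_mm) * spec.csf_rim_scale)
    ventricles = np.zeros(spec.shape, dtype=bool)
    for c in spec.ventricle_centers_mm:
        ventricles |= _ellipsoid(x, y, z, c, spec.ventricle_semiaxes_mm)
    ventricles &= wm_core

    tissue = np.zeros(spec.shape, dtype=np.int16)
    tissue[brain] = CSF          # surface rim by default
    tissue[inner] = GM
    tissue[wm_core] = WM
    tissue[ventricles] = CSF

    wm_mask = tissue == WM
    lesion_labels = np.zeros(spec.shape, dtype=np.int16)
    vv_cc = spec.voxel_mm ** 3 / 1000.0
    lesion_rows = []
    for i, les in enumerate(spec.lesions, start=1):
        sphere = _ellipsoid(x, y, z, les.center_mm, (les.radius_mm,) * 3)
        if not sphere.any():
            raise ValidationError(f"lesion {i} rasterizes to zero voxels")
        if not np.all(wm_mask[sphere] | ventricles[sphere]):
            raise ValidationError(
                f"lesion {i} at {les.center_mm} extends outside the WM shell")
        sphere &= wm_mask  # clip at the ventricle wall, never inside CSF
        lesion_labels[sphere] = i
        lesion_rows.append({
            "component": i, "class": les.intended_class,
            "quadrant": les.intended_quadrant,
            "n_voxels": int(sphere.sum()),
            "volume_cc": float(sphere.sum() * vv_cc),
        })
    lesion_table = pd.DataFrame(lesion_rows)

    # truth region volumes by voxel counting (quadrant by world sign)
    region = {f"{cls}_{q}": 0.0
              for cls in ("pvh", "dwmh") for q in ("ra", "rp", "la", "lp")}
    for i, les in enumerate(spec.lesions, start=1):
        sel = lesion_labels == i
        right = x[sel] >= 0
        anterior = y[sel] >= 0
        for qname, qsel in (("ra", right & anterior),
                            ("rp", right & ~anterior),
                            ("la", ~right & anterior),
                            ("lp", ~right & ~anterior)):
            region[f"{les.intended_class.lower()}_{qname}"] += (
                float(qsel.sum()) * vv_cc)

    rng = np.random.default_rng(spec.seed)
    t1 = np.zeros(spec.shape, dtype=float)
    flair = np.zeros(spec.shape, dtype=float)
    for cls in (CSF, GM, WM):
        sel = tissue == cls
        n = int(sel.sum())
        t1[sel] = rng.normal(spec.t1_means[cls], spec.t1_sd, n)
        flair[sel] = rng.normal(spec.flair_means[cls], spec.flair_sd, n)
    lesion_any = lesion_labels > 0
    n_les = int(lesion_any.sum())
    t1[lesion_any] = rng.normal(spec.t1_lesion_mean, spec.t1_sd, n_les)
    # lesion FLAIR intensity is the deterministic WM mean + 6 sd: lesions
    # sit exactly at their nominal contrast so threshold recovery is exact
    flair[lesion_any] = (spec.flair_means[WM]
                         + spec.flair_lesion_sigmas * spec.flair_sd)

    truth = {
        "tissue": LabelMap(tissue, affine, dict(TISSUE_NAMES)),
        "brain_mask": LabelMap.from_mask(brain, affine, "brain"),
        "ventricles": LabelMap.from_mask(ventricles, affine, "ventricles"),
        "lesions": LabelMap(lesion_labels, affine),
        "lesion_table": lesion_table,
        "region_volumes_cc": region,
        "planes": PartitionPlanes(midsagittal_x=0.0, central_y=0.0),
    }
    return (Volume3D(t1, affine, "intensity"),
            Volume3D(flair, affine, "intensity"),
            truth)


# ---------------------------------------------------------------------------
# SPECT phantom
# ---------------------------------------------------------------------------

@dataclass
class SpectPhantomSpec:
    """Forward model for dynamic angiography + static SPECT counts.

    Default segment flows are realistic resting AD-cohort values
    (mL/100 g/min); the static forward model applies the saturation law
    with ``alpha`` to flow ratios normalized so the whole-brain mean count
    ratio is exactly 1 (the reference convention of the inversion).
    """

    region_flows: dict[str, float] = field(default_factory=lambda: {
        "callosomarginal": 37.2, "precentral": 40.1, "central": 40.7,
        "parietal": 38.8, "angular": 42.8, "temporal": 36.9,
        "occipital": 42.7, "pericallosal": 37.5, "lentiform_nucleus": 36.9,
        "thalamus": 32.4, "hippocampus": 27.6, "cerebellum": 47.0,
        "posterior_cingulate": 42.1,
    })
    alpha: float = 2.59
    bpi_true: float = 0.12        # Patlak influx constant K
    dist_volume: float = 0.30     # Patlak intercept V
    aorta_amplitude: float = 1000.0
    aorta_onset_s: float = 8.0
    aorta_shape: float = 3.0
    aorta_scale_s: float = 3.0
    n_frames: int = 120
    frame_interval_s: float = 1.0
    matrix: int = 128
    noise_level: float = 0.01     # fractional sd on the brain TAC
    count_scale: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.region_flows.values()):
            raise ValidationError("flows must be > 0")
        if self.bpi_true <= 0 or self.alpha <= 1:
            raise ValidationError("need K > 0 and alpha > 1")


def gamma_variate(t, amplitude, onset, shape, scale):
    """Gamma-variate bolus curve, zero before onset."""
    t = np.asarray(t, dtype=float)
    s = np.clip((t - onset) / scale, 0.0, None)
    return amplitude * s ** shape * np.exp(shape * (1.0 - s))


def make_spect_phantom(spec: SpectPhantomSpec,
                       template: ROITemplate | None = None):
    """Dynamic frames, static counts, ROI masks and ground truth.

    Returns ``(dynamic, static, rois, truth)``.  ``rois`` is a 2D label
    map on the dynamic frames (1 aortic arch, 2 left hemisphere, 3 right
    hemisphere).  ``truth`` holds the generating BPI, mCBF (= voxel-mean
    of true flows), the self-consistent BPI->mCBF calibration, the
    per-region/segment flows and the voxelwise flow volume.
    """
    rng = np.random.default_rng(spec.seed)
    if template is None:
        template = build_template()

    # --- dynamic series --------------------------------------------------
    t = np.arange(spec.n_frames, dtype=float) * spec.frame_interval_s
    ca = gamma_variate(t, spec.aorta_amplitude, spec.aorta_onset_s,
                       spec.aorta_shape, spec.aorta_scale_s)
    int_ca = np.concatenate([[0.0], np.cumsum(
        (ca[1:] + ca[:-1]) / 2.0 * np.diff(t))])
    cb = spec.bpi_true * int_ca + spec.dist_volume * ca
    if spec.noise_level > 0:
        scale = spec.noise_level * max(cb.max(), 1e-12)
        cb = np.clip(cb + rng.normal(0.0, scale, cb.shape), 0.0, None)

    m = spec.matrix
    frames = np.zeros((spec.n_frames, m, m), dtype=float)
    rois = np.zeros((m, m), dtype=np.int16)
    q = m // 4
    rois[3 * q:3 * q + q // 2, q:3 * q] = 1              # aortic arch band
    rois[q // 2:2 * q, q:2 * q - 2] = 2                   # left hemisphere
    rois[q // 2:2 * q, 2 * q + 2:3 * q] = 3               # right hemisphere
    frames[:, rois == 1] = ca[:, None]
    frames[:, rois == 2] = cb[:, None]
    frames[:, rois == 3] = cb[:, None]
    dynamic = DynamicSeries(frames, t)
    roi_map = LabelMap(rois, np.eye(4), {1: "aortic_arch",
                                         2: "hemisphere_L",
                                         3: "hemisphere_R"})

    # --- static counts in template space ---------------------------------
    labels = template.labels.labels
    brain = labels > 0
    flow = np.zeros(labels.shape, dtype=float)
    region_of = dict(zip(template.lookup["roi_id"], template.lookup["region"]))
    for roi_id, region in region_of.items():
        flow[labels == roi_id] = spec.region_flows[region]
    mcbf_true = float(flow[brain].mean())

    # reference flow such that the mean observed count ratio over the brain
    # is exactly 1 — the whole-brain-mean convention of the inversion
    fvals = flow[brain]

    def mean_ratio(fref):
        return float(lassen_forward(fvals / fref, spec.alpha).mean()) - 1.0

    f_ref = optimize.brentq(mean_ratio, fvals.min() / 4, fvals.max() * 4)
    ratio = np.zeros_like(flow)
    ratio[brain] = lassen_forward(fvals / f_ref, spec.alpha)
    static = Volume3D(spec.count_scale * ratio,
                      template.labels.affine.copy(), units="counts")
    brain_mask = LabelMap.from_mask(brain, template.labels.affine, "brain")

    calib = CBFCalibration(a_slope=mcbf_true / spec.bpi_true, b_intercept=0.0)
    segment_flows = {}
    for region in ANALYSIS_REGIONS:
        for hemi in ("R", "L"):
            segment_flows[f"{region}_{hemi}"] = spec.region_flows[region]
    truth = {
        "bpi": spec.bpi_true,
        "dist_volume": spec.dist_volume,
        "mcbf": mcbf_true,
        "calibration": calib,
        "reference_flow": f_ref,
        "region_flows": dict(spec.region_flows),
        "segment_flows": segment_flows,
        "flow_volume": Volume3D(flow, template.labels.affine.copy(),
                                units="mL/100g/min"),
        "brain_mask": brain_mask,
        "aorta_curve": ca,
        "brain_curve_clean": spec.bpi_true * int_ca + spec.dist_volume * ca,
    }
    return dynamic, static, roi_map, truth


# ---------------------------------------------------------------------------
# Cohort phantom
# ---------------------------------------------------------------------------

PREDICTORS = ["age", "pvh_a", "pvh_p", "dwmh_a", "dwmh_p",
              "cbf_parietal", "cbf_temporal", "cbf_post_cingulate"]

# (mean, sd) styled on an AD memory-clinic cohort: age in years, WMH
# region volumes in cc (anterior/posterior, hemispheres summed), bilateral
# segment flows in mL/100 g/min.
_PREDICTOR_DIST = {
    "age": (73.1, 7.9),
    "pvh_a": (4.3, 2.6), "pvh_p": (3.8, 1.8),
    "dwmh_a": (4.3, 4.7), "dwmh_p": (6.2, 6.0),
    "cbf_parietal": (38.9, 7.0), "cbf_temporal": (36.6, 6.4),
    "cbf_post_cingulate": (41.1, 7.7),
}


@dataclass
class CohortSpec:
    """Synthetic cohort with known log-scale GLM coefficients.

    ``outcomes`` maps outcome name -> (family, coefficient dict).  The
    coefficient dict has an 'intercept' entry plus one log-scale beta per
    predictor; the outcome mean is exp(intercept + sum beta_j * x_j) with
    predictors centred at their population means so the intercept sets the
    outcome scale directly.
    """

    n: int = 29
    predictor_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_PREDICTOR_DIST))
    outcomes: dict[str, tuple[str, dict[str, float]]] = field(
        default_factory=lambda: {
            "wf_category": ("poisson", {
                "intercept": np.log(10.5), "age": np.log(0.99),
                "pvh_a": np.log(1.08), "pvh_p": np.log(1.05),
                "dwmh_a": np.log(1.02), "dwmh_p": np.log(0.89),
                "cbf_parietal": np.log(0.98), "cbf_temporal": np.log(1.01),
                "cbf_post_cingulate": np.log(1.01)}),
            "tmt_a_s": ("gamma", {
                "intercept": np.log(250.0), "age": np.log(1.01),
                "pvh_a": np.log(1.17), "pvh_p": np.log(0.87),
                "dwmh_a": np.log(0.91), "dwmh_p": np.log(1.08),
                "cbf_parietal": np.log(0.92), "cbf_temporal": np.log(1.05),
                "cbf_post_cingulate": np.log(0.99)}),
        })
    gamma_shape: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValidationError("cohort needs n >= 10")
        for name, (family, betas) in self.outcomes.items():
            if family not in ("poisson", "gamma", "gaussian-log"):
                raise ValidationError(f"unknown family {family!r} for {name}")
            extra = set(betas) - {"intercept"} - set(self.predictor_dist)
            if extra:
                raise ValidationError(
                    f"{name}: coefficients for unknown predictors {extra}")


def make_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table and return it with its generating truth."""
    rng = np.random.default_rng(spec.seed)
    data = {"subject_id": [f"S{i:04d}" for i in range(1, spec.n + 1)]}
    for name, (mu, sd) in spec.predictor_dist.items():
        data[name] = np.clip(rng.normal(mu, sd, spec.n), 0.0, None)
    df = pd.DataFrame(data)

    truth = {"coefficients": {}, "families": {}}
    for name, (family, betas) in spec.outcomes.items():
        eta = np.full(spec.n, betas.get("intercept", 0.0))
        for pred, (mu, _) in spec.predictor_dist.items():
            b = betas.get(pred, 0.0)
            eta = eta + b * (df[pred].to_numpy() - mu)
        mean = np.exp(eta)
        if family == "poisson":
            y = rng.poisson(mean).astype(float)
        elif family == "gamma":
            y = rng.gamma(spec.gamma_shape, mean / spec.gamma_shape)
        else:  # gaussian-log
            y = np.clip(rng.normal(mean, 0.05 * mean), 1e-9, None)
        df[name] = y
        truth["coefficients"][name] = dict(betas)
        truth["families"][name] = family
    return df, truth
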