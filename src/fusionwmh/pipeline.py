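"""End-to-end per-subject drivers tying the arms together.

``run_mri`` goes from T1 + FLAIR to the eight region volumes;
``run_spect`` from dynamic angiography + static counts to segment rCBF.
Both return small result bundles that :mod:`fusionwmh.fusion` combines
into cohort rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import LabelMap, RigidTransform, Volume3D
from .spect import (
    CBFCalibration,
    LassenParams,
    PerfusionIndex,
    RCBFMap,
    ROIStats,
    apply_roi_template,
    bpi_to_mcbf,
    counts_to_rcbf,
    extract_tac,
    patlak_bpi,
)
from .template import ROITemplate, build_template
from .wmh import (
    LesionComponentMap,
    PartitionPlanes,
    TissueMap,
    WMHRegionVolumes,
    WMHThresholdParams,
    classify_pvh_dwmh,
    compute_region_volumes,
    extract_ventricles,
    extract_wmh,
    fill_lesions,
    partition_quadrants,
    register_rigid,
    robust_wm_stats,
    segment_tissues,
)

__all__ = ["MriResult", "SpectResult", "run_mri", "run_spect",
           "estimate_brain_mask"]


@dataclass
class MriResult:
    volumes: WMHRegionVolumes
    lesions: LesionComponentMap
    quadrants: LabelMap
    tissue: TissueMap
    ventricles: LabelMap
    brain_mask: LabelMap
    t1_to_flair: RigidTransform


@dataclass
class SpectResult:
    bpi: PerfusionIndex
    mcbf: float
    rcbf: RCBFMap
    roistats: ROIStats


def estimate_brain_mask(vol: Volume3D, frac: float = 0.1) -> LabelMap:
    """Foreground mask: voxels above ``frac`` of the 99th percentile,
    holes filled and restricted to the largest connected component."""
    x = np.asarray(vol.voxels, dtype=float)
    pos = x[x > 0]
    thr = frac * np.percentile(pos, 99) if pos.size else 0.0
    mask = x > thr
    mask = ndimage.binary_fill_holes(mask)
    comp, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp,
                                   index=np.arange(1, n + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    return LabelMap.from_mask(mask, vol.affine, "brain")


def run_mri(t1: Volume3D, flair: Volume3D, planes: PartitionPlanes,
            params: WMHThresholdParams | None = None,
            pvh_distance_mm: float = 3.0,
            brain_mask: LabelMap | None = None,
            lesion_prior: LabelMap | None = None,
            assume_aligned: bool = False,
            seed: int = 0) -> MriResult:
    """Full MRI arm: align, fill, segment, extract, classify, measure.

    When no lesion prior is supplied a first-pass prior is derived by the
    same robust hyperintensity threshold applied to the whole brain mask;
    the final WMH extraction then runs on segmented WM joined with that
    prior, so lesions mislabelled by the tissue model are not lost.
    """
    if params is None:
        params = WMHThresholdParams()
    if assume_aligned or (t1.shape == flair.shape
                          and np.allclose(t1.affine, flair.affine)):
        transform = RigidTransform.identity()
        t1_on_flair = t1
    else:
        transform = register_rigid(t1, flair)
        from .core_io import resample
        t1_on_flair = resample(t1, flair, transform)

    if brain_mask is None:
        brain_mask = estimate_brain_mask(flair)
    ref_wm = None
    if lesion_prior is None:
        # first pass on the raw T1: lesions are hypointense there and land
        # in the GM/CSF classes, but the WM class it yields is clean enough
        # to set the normal-appearing-WM FLAIR statistics
        tissue0 = segment_tissues(t1_on_flair, brain_mask, seed=seed)
        ref_wm = tissue0.mask(3)
        mu, sd = robust_wm_stats(flair, ref_wm, params.k_sigma)
        # threshold over the whole brain: CSF is FLAIR-suppressed, so only
        # genuine hyperintensities cross, including lesion voxels the raw
        # T1 pass mislabelled as CSF
        prior = brain_mask.mask() & (
            np.asarray(flair.voxels, float) > mu + params.k_sigma * sd)
        lesion_prior = LabelMap.from_mask(prior, flair.affine, "lesion_prior")

    t1_filled = fill_lesions(t1_on_flair, lesion_prior, seed=seed,
                             wm_mask=ref_wm)
    tissue = segment_tissues(t1_filled, brain_mask, seed=seed)
    ventricles = extract_ventricles(tissue, brain_mask)
    wm = tissue.mask(3) | lesion_prior.mask()
    wm_mask = LabelMap.from_mask(wm, flair.affine, "wm")
    lesions = extract_wmh(flair, wm_mask, params)
    lesions = classify_pvh_dwmh(lesions, ventricles, d_mm=pvh_distance_mm)
    quadrants = partition_quadrants(flair, planes)
    volumes = compute_region_volumes(lesions, quadrants)
    return MriResult(volumes, lesions, quadrants, tissue, ventricles,
                     brain_mask, transform)


def run_spect(dynamic, rois: LabelMap, static: Volume3D,
              brain_mask: LabelMap,
              calib: CBFCalibration | None = None,
              params: LassenParams | None = None,
              template: ROITemplate | None = None,
              subject_to_template: RigidTransform | None = None,
              window: tuple[float, float] | None = None) -> SpectResult:
    """Full SPECT arm: TACs -> Patlak BPI -> mCBF -> voxel rCBF -> ROI stats.

    ``rois`` labels the dynamic frames: 1 aortic arch, 2/3 the left/right
    hemisphere; the brain curve is the mean over both hemispheres.
    """
    if calib is None:
        calib = CBFCalibration()
    if params is None:
        params = LassenParams()
    if template is None:
        template = build_template()
    aorta = extract_tac(dynamic, rois, label=1, roi_name="aortic_arch")
    hemi = LabelMap((rois.labels >= 2).astype(np.int16), rois.affine,
                    {1: "hemispheres"})
    brain_tac = extract_tac(dynamic, hemi, label=1, roi_name="whole_brain")
    bpi = patlak_bpi(brain_tac, aorta, window)
    mcbf = bpi_to_mcbf(bpi, calib)
    rcbf = counts_to_rcbf(static, brain_mask, mcbf, params)
    roistats = apply_roi_template(rcbf, template, subject_to_template)
    return SpectResult(bpi, mcbf, rcbf, roistats)
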