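"""SPECT arm: time-activity curves, Patlak brain perfusion index, BPI to
mean CBF calibration, Lassen linearization, voxelwise rCBF scaling and
stereotactic ROI-template quantification.

The tracer (99mTc-ECD) accumulates sublinearly with flow; the observed
count ratio R relates to the true flow ratio F through the saturation law
``R = alpha*F / (1 + (alpha-1)*F)``.  Lassen's correction inverts this:
``F = R / (alpha - (alpha-1)*R)``.  Absolute scaling comes from the mean
CBF (mCBF), itself calibrated from the brain perfusion index (BPI), the
Patlak-plot slope of the brain vs aortic-arch time-activity curves from
dynamic radionuclide angiography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import integrate

from ._exceptions import CalibrationError, DomainError, FitError, ValidationError
from .core_io import DynamicSeries, LabelMap, RigidTransform, Volume3D, resample
from .template import REGIONS, ROITemplate

logger = logging.getLogger(__name__)

__all__ = [
    "TimeActivityCurve",
    "PerfusionIndex",
    "LassenParams",
    "CBFCalibration",
    "RCBFMap",
    "ROIStats",
    "extract_tac",
    "default_fit_window",
    "patlak_bpi",
    "bpi_to_mcbf",
    "lassen_forward",
    "lassen_correct",
    "counts_to_rcbf",
    "apply_roi_template",
]


@dataclass
class TimeActivityCurve:
    """Mean ROI counts per frame vs time (s from injection)."""

    times: np.ndarray
    activity: np.ndarray
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.times.shape != self.activity.shape or self.times.ndim != 1:
            raise ValidationError("times and activity must be equal 1D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.activity < 0):
            raise ValidationError("activity must be >= 0")


@dataclass
class PerfusionIndex:
    """Patlak-slope brain perfusion index with its fit window and r^2."""

    bpi: float
    fit_window: tuple[float, float]
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValidationError("r_squared must lie in [0, 1]")


@dataclass
class LassenParams:
    """Linearization factor alpha (> 1) and the reference-region strategy.

    alpha defaults to 2.59, the standard linearization factor for
    99mTc-ECD brain uptake.
    """

    alpha: float = 2.59
    reference_strategy: Literal[
        "whole_brain_mean", "cerebellum_mean"] = "whole_brain_mean"

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValidationError("alpha must be > 1")

    @property
    def saturation_bound(self) -> float:
        """Supremum of admissible observed ratios: alpha/(alpha-1)."""
        return self.alpha / (self.alpha - 1.0)


@dataclass
class CBFCalibration:
    """mCBF = a_slope * BPI + b_intercept (mL/100 g/min)."""

    a_slope: float = 1.0
    b_intercept: float = 0.0

    def __post_init__(self) -> None:
        if not self.a_slope > 0:
            raise ValidationError("a_slope must be > 0")


@dataclass
class RCBFMap:
    """Voxelwise rCBF in mL/100 g/min, normalized to the brain-mask mean."""

    volume: Volume3D
    brain_mask: LabelMap
    mcbf: float
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if self.volume.units != "mL/100g/min":
            raise ValidationError("RCBFMap volume must carry mL/100g/min units")
        if np.any(self.volume.voxels < 0):
            raise ValidationError("rCBF values must be >= 0")
        mean = float(self.volume.voxels[self.brain_mask.mask()].mean())
        if abs(mean - self.mcbf) > 1e-6 * max(1.0, abs(self.mcbf)):
            raise ValidationError("brain-mask mean must equal mCBF")


@dataclass
class ROIStats:
    """Per-ROI, per-region (R/L) and per-segment mean rCBF."""

    per_roi: pd.DataFrame       # roi_id, region, hemisphere, segment,
                                # n_voxels, mean_rcbf (NaN if missing)
    per_region: pd.DataFrame    # region, hemisphere, mean_rcbf (table order)
    per_segment: pd.DataFrame   # segment, mean_rcbf

    def segment_mean(self, segment: str) -> float:
        row = self.per_segment.loc[self.per_segment["segment"] == segment]
        if row.empty:
            raise KeyError(segment)
        return float(row["mean_rcbf"].iloc[0])

    def bilateral_mean(self, region: str) -> float:
        """Voxel-weighted bilateral mean over one region's ROIs."""
        sub = self.per_roi[(self.per_roi["region"] == region)
                           & self.per_roi["mean_rcbf"].notna()]
        if sub.empty:
            raise KeyError(region)
        w = sub["n_voxels"].to_numpy(float)
        return float(np.average(sub["mean_rcbf"].to_numpy(float), weights=w))


# ---------------------------------------------------------------------------
# Time-activity curves and the Patlak plot
# ---------------------------------------------------------------------------

def extract_tac(series: DynamicSeries, roi: LabelMap,
                label: int | None = None, roi_name: str = "") -> TimeActivityCurve:
    """Mean counts within an ROI at every frame of a dynamic series."""
    if roi.labels.shape != series.grid_shape:
        raise ValidationError("ROI grid does not match the dynamic series")
    mask = roi.mask(label)
    if not mask.any():
        raise ValidationError("empty ROI")
    activity = series.frames[:, mask].mean(axis=1)
    return TimeActivityCurve(series.frame_times.copy(), activity, roi_name)


def default_fit_window(aorta: TimeActivityCurve,
                       start_after_peak_s: float = 4.0,
                       end_after_peak_s: float = 14.0) -> tuple[float, float]:
    """Fit window relative to the aortic bolus peak (argmax of the TAC)."""
    t_peak = float(aorta.times[int(np.argmax(aorta.activity))])
    return (t_peak + start_after_peak_s, t_peak + end_after_peak_s)


def patlak_bpi(brain: TimeActivityCurve, aorta: TimeActivityCurve,
               window: tuple[float, float] | None = None) -> PerfusionIndex:
    """Brain perfusion index as the Patlak-plot slope.

    Regresses y(t) = Cb(t)/Ca(t) on x(t) = int_0^t Ca / Ca(t) (trapezoidal
    integral) over the frames inside ``window`` (default: 4-14 s after the
    aortic peak).  For a tissue obeying Cb = K*intCa + V*Ca the slope is
    exactly the influx constant K.
    """
    if brain.times.shape != aorta.times.shape or \
            not np.allclose(brain.times, aorta.times):
        raise ValidationError("brain and aorta TACs must share frame times")
    if window is None:
        window = default_fit_window(aorta)
    t0, t1 = float(window[0]), float(window[1])
    if t0 >= t1:
        raise ValidationError("fit window must have t_start < t_end")

    t = aorta.times
    ca = aorta.activity
    cb = brain.activity
    sel = (t >= t0) & (t <= t1)
    if sel.sum() < 3:
        raise FitError("fewer than 3 frames in the Patlak fit window")
    if np.any(ca[sel] <= 0):
        raise ValidationError("nonpositive aortic activity in the fit window")

    int_ca = integrate.cumulative_trapezoid(ca, t, initial=0.0)
    xs = int_ca[sel] / ca[sel]
    ys = cb[sel] / ca[sel]
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    if ss_tot <= 0:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return PerfusionIndex(float(slope), (t0, t1), r2)


def bpi_to_mcbf(index: PerfusionIndex, calib: CBFCalibration) -> float:
    """mCBF (mL/100 g/min) = a * BPI + b; must be positive."""
    mcbf = calib.a_slope * index.bpi + calib.b_intercept
    if mcbf <= 0:
        raise CalibrationError(
            f"calibration produced nonpositive mCBF ({mcbf:g})")
    return float(mcbf)


# ---------------------------------------------------------------------------
# Lassen linearization
# ---------------------------------------------------------------------------

def lassen_forward(flow_ratio, alpha: float):
    """Saturation law R = alpha*F / (1 + (alpha-1)*F) mapping flow ratio to
    observed count ratio (the phantom forward model)."""
    f = np.asarray(flow_ratio, dtype=float)
    return alpha * f / (1.0 + (alpha - 1.0) * f)


def lassen_correct(ratio_obs, params: LassenParams | float):
    """Invert the uptake saturation: F = R / (alpha - (alpha-1)*R).

    Strictly increasing in R with a fixed point at R = 1; defined for
    0 <= R < alpha/(alpha-1).
    """
    alpha = params.alpha if isinstance(params, LassenParams) else float(params)
    if not alpha > 1:
        raise ValidationError("alpha must be > 1")
    r = np.asarray(ratio_obs, dtype=float)
    bound = alpha / (alpha - 1.0)
    if np.any(r < 0) or np.any(r >= bound):
        raise DomainError(
            f"observed ratio outside [0, {bound:g}) for alpha={alpha:g}")
    out = r / (alpha - (alpha - 1.0) * r)
    if np.isscalar(ratio_obs):
        return float(out)
    return out


def counts_to_rcbf(static: Volume3D, brain_mask: LabelMap, mcbf: float,
                   params: LassenParams,
                   reference_mask: LabelMap | None = None) -> RCBFMap:
    """Convert a static SPECT count volume into voxelwise rCBF.

    Count ratios relative to the reference mean are linearized with
    Lassen's correction and rescaled so that the brain-mask mean equals
    ``mcbf``.  Ratios at or beyond the saturation bound (isolated hot
    voxels) are clamped to bound - 1e-6 and counted.  Scale-invariant in
    the raw counts.
    """
    if static.shape != brain_mask.shape:
        raise ValidationError("static volume and brain mask must share a grid")
    if mcbf <= 0:
        raise ValidationError("mcbf must be > 0")
    brain = brain_mask.mask()
    if not brain.any():
        raise ValidationError("empty brain mask")
    counts = np.asarray(static.voxels, dtype=float)

    if params.reference_strategy == "cerebellum_mean":
        if reference_mask is None:
            raise ValidationError(
                "cerebellum_mean strategy requires a reference mask")
        ref = reference_mask.mask()
    else:
        ref = brain
    ref_mean = float(counts[ref].mean())
    if ref_mean <= 0:
        raise ValidationError("reference mean counts must be > 0")

    ratio = np.zeros_like(counts)
    ratio[brain] = counts[brain] / ref_mean
    bound = params.saturation_bound
    over = ratio >= bound
    n_clamped = int(over.sum())
    if n_clamped:
        logger.warning("%d voxels at/above the saturation bound clamped",
                       n_clamped)
        ratio[over] = bound - 1e-6
    flow = np.zeros_like(counts)
    flow[brain] = lassen_correct(ratio[brain], params)
    scale = mcbf / float(flow[brain].mean())
    rcbf = flow * scale
    vol = Volume3D(rcbf, static.affine.copy(), units="mL/100g/min")
    return RCBFMap(vol, brain_mask, float(mcbf), n_clamped)


# ---------------------------------------------------------------------------
# ROI-template quantification
# ---------------------------------------------------------------------------

def apply_roi_template(rcbf: RCBFMap, template: ROITemplate,
                       transform: RigidTransform | None = None) -> ROIStats:
    """Quantify mean rCBF per template ROI, region (R/L) and segment.

    ``transform`` maps subject space into template space (identity if
    None); the rCBF map is pulled into template space with nearest
    interpolation.  ROIs with no overlapping voxels are reported with NaN
    mean, never silently as zero.
    """
    if transform is None:
        transform = RigidTransform.identity()
    tgrid = template.labels.as_volume()
    pulled = resample(rcbf.volume, tgrid, transform.inverse(),
                      interp="nearest", fill=np.nan)
    vals = np.asarray(pulled.voxels, dtype=float)

    rows = []
    for r in template.lookup.itertuples():
        sel = template.labels.labels == r.roi_id
        v = vals[sel]
        ok = np.isfinite(v)
        rows.append({
            "roi_id": int(r.roi_id), "region": r.region,
            "hemisphere": r.hemisphere, "segment": r.segment,
            "n_voxels": int(ok.sum()),
            "mean_rcbf": float(v[ok].mean()) if ok.any() else np.nan,
        })
    per_roi = pd.DataFrame(rows)
    missing = per_roi["mean_rcbf"].isna().sum()
    if missing:
        logger.warning("%d ROIs with no overlapping voxels reported missing",
                       missing)

    def _weighted(df: pd.DataFrame) -> float:
        ok = df["mean_rcbf"].notna() & (df["n_voxels"] > 0)
        if not ok.any():
            return np.nan
        return float(np.average(df.loc[ok, "mean_rcbf"],
                                weights=df.loc[ok, "n_voxels"]))

    region_rows = []
    for region in REGIONS:
        for hemi in ("R", "L"):
            sub = per_roi[(per_roi["region"] == region)
                          & (per_roi["hemisphere"] == hemi)]
            region_rows.append({"region": region, "hemisphere": hemi,
                                "mean_rcbf": _weighted(sub)})
    per_region = pd.DataFrame(region_rows)

    seg_rows = []
    for seg in template.lookup["segment"].unique():
        sub = per_roi[per_roi["segment"] == seg]
        seg_rows.append({"segment": seg, "mean_rcbf": _weighted(sub)})
    per_segment = pd.DataFrame(seg_rows)
    return ROIStats(per_roi, per_region, per_segment)
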