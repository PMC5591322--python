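"""Per-subject fusion of the MRI (WMH volumes) and SPECT (segment rCBF)
results, plus the overlay volume used for visual review.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .core_io import LabelMap, RigidTransform, Volume3D, resample, save_volume
from .spect import RCBFMap, ROIStats
from .wmh import LesionComponentMap, WMHRegionVolumes

__all__ = [
    "FusedSubjectRecord",
    "OverlayVolume",
    "fuse_subject",
    "make_overlay",
    "save_overlay",
    "records_to_frame",
]

SCORE_FIELDS = ["mmse", "rcpm_score", "rcpm_time_s", "rbmt_sps", "rbmt_ss",
                "tmt_a_s", "wf_category", "wf_letter",
                "construction_cube", "construction_necker"]
COVARIATE_FIELDS = ["age", "sex", "education_years"]
SEGMENT_FIELDS = ["cbf_parietal", "cbf_temporal", "cbf_post_cingulate"]


@dataclass
class FusedSubjectRecord:
    """One subject's WMH volumes, segment flows, covariates and scores.

    Missing neuropsychological scores are preserved as NaN, never imputed;
    construction scores must be integers 0-3 when present.
    """

    subject_id: str
    volumes: WMHRegionVolumes
    segment_cbf: dict[str, float]
    covariates: dict[str, float] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("construction_cube", "construction_necker"):
            v = self.scores.get(key)
            if v is not None and not np.isnan(v) and v not in (0, 1, 2, 3):
                raise ValidationError(
                    f"{key} must be one of 0-3 (poor/fair/good/excellent), "
                    f"got {v!r}")
        for name, v in self.segment_cbf.items():
            if v < 0:
                raise ValidationError(f"negative flow for {name}")

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update(self.volumes.to_series().to_dict())
        row.update({k: self.segment_cbf.get(k, np.nan)
                    for k in SEGMENT_FIELDS})
        row.update({k: self.covariates.get(k, np.nan)
                    for k in COVARIATE_FIELDS})
        row.update({k: self.scores.get(k, np.nan) for k in SCORE_FIELDS})
        return row


def fuse_subject(subject_id: str,
                 volumes: WMHRegionVolumes,
                 roistats: ROIStats,
                 cohort_row: pd.Series | dict) -> FusedSubjectRecord:
    """Build one validated fused record from the three per-subject inputs.

    ``cohort_row`` must carry a matching ``subject_id`` plus covariates
    and neuropsychological scores; missing scores stay missing.
    """
    row = dict(pd.Series(cohort_row))
    row_id = str(row.get("subject_id", subject_id))
    if row_id != str(subject_id):
        raise ValidationError(
            f"subject id mismatch: {subject_id!r} vs cohort row {row_id!r}")
    segment_cbf = {
        "cbf_parietal": roistats.bilateral_mean("parietal"),
        "cbf_temporal": roistats.bilateral_mean("temporal"),
        "cbf_post_cingulate": roistats.bilateral_mean("posterior_cingulate"),
    }
    covariates = {k: float(row[k]) for k in COVARIATE_FIELDS if k in row
                  and pd.notna(row[k])}
    scores = {k: float(row[k]) for k in SCORE_FIELDS if k in row
              and pd.notna(row[k])}
    return FusedSubjectRecord(str(subject_id), volumes, segment_cbf,
                              covariates, scores)


def records_to_frame(records: list[FusedSubjectRecord]) -> pd.DataFrame:
    """Stack fused records into the cohort analysis table."""
    return pd.DataFrame([r.to_row() for r in records])


@dataclass
class OverlayVolume:
    """FLAIR background + lesion channel + rCBF channel on one grid."""

    background: Volume3D
    lesion_channel: Volume3D
    rcbf_channel: Volume3D

    def __post_init__(self) -> None:
        if not (self.background.shape == self.lesion_channel.shape
                == self.rcbf_channel.shape):
            raise ValidationError("overlay channels must share one grid")


def make_overlay(flair: Volume3D, lesions: LesionComponentMap,
                 rcbf: RCBFMap,
                 transform: RigidTransform | None = None) -> OverlayVolume:
    """Fuse lesions and rCBF onto the FLAIR grid.

    ``transform`` maps SPECT world coordinates into FLAIR world
    coordinates (identity if None).  rCBF is pulled trilinearly, the
    lesion channel nearest-neighbour; the FLAIR background is untouched.
    """
    if transform is None:
        transform = RigidTransform.identity()
    if lesions.labels.shape != flair.shape:
        raise ValidationError("lesions must live on the FLAIR grid")
    lesion_vol = Volume3D(lesions.labels, lesions.affine, units="label")
    lesion_on_flair = resample(lesion_vol, flair, None, interp="nearest")
    rcbf_on_flair = resample(rcbf.volume, flair, transform.inverse(),
                             interp="trilinear")
    return OverlayVolume(flair, lesion_on_flair, rcbf_on_flair)


def save_overlay(overlay: OverlayVolume, out_prefix: str | os.PathLike,
                 montage_slices: int = 6) -> list[str]:
    """Persist the overlay as NIfTI channels plus a PNG montage."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = os.fspath(out_prefix)
    paths = []
    for name, vol in (("background", overlay.background),
                      ("lesions", overlay.lesion_channel),
                      ("rcbf", overlay.rcbf_channel)):
        p = f"{prefix}_{name}.nii.gz"
        save_volume(vol, p)
        paths.append(p)

    nz = overlay.background.shape[2]
    picks = np.linspace(nz // 4, 3 * nz // 4, montage_slices).astype(int)
    fig, axes = plt.subplots(1, montage_slices,
                             figsize=(3 * montage_slices, 3.2))
    for ax, k in zip(np.atleast_1d(axes), picks):
        bg = np.asarray(overlay.background.voxels[:, :, k], dtype=float).T
        ax.imshow(bg, cmap="gray", origin="lower")
        rc = np.asarray(overlay.rcbf_channel.voxels[:, :, k], dtype=float).T
        ax.imshow(np.ma.masked_where(rc <= 0, rc), cmap="jet",
                  origin="lower", alpha=0.35)
        les = np.asarray(overlay.lesion_channel.voxels[:, :, k]).T
        ax.contour(les > 0, levels=[0.5], colors="w", linewidths=0.8)
        ax.set_axis_off()
        ax.set_title(f"z={k}", fontsize=8)
    fig.tight_layout()
    png = f"{prefix}_montage.png"
    fig.savefig(png, dpi=110)
    plt.close(fig)
    paths.append(png)
    return paths
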