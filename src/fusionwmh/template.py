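"""Synthetic stereotactic ROI template for automated rCBF quantification.

The template mimics the organisation of fixed stereotactic ROI sets used in
clinical SPECT software: 636 small ROIs (318 per hemisphere) grouped into 13
anatomically named regions per hemisphere, of which the bilateral parietal,
temporal and posterior cingulate regions form the six analysis segments used
by the cohort statistics.  The geometry is synthetic — a deterministic
partition of an ellipsoidal brain volume — because the true commercial
template anatomy is proprietary; only the counting structure (ROI/region/
segment bookkeeping) is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .core_io import LabelMap

__all__ = ["ROITemplate", "build_template", "REGIONS", "ANALYSIS_REGIONS"]

# Report row order (region x R/L), matching the regional rCBF table layout.
REGIONS = [
    "callosomarginal", "precentral", "central", "parietal", "angular",
    "temporal", "occipital", "pericallosal", "lentiform_nucleus",
    "thalamus", "hippocampus", "cerebellum", "posterior_cingulate",
]

# Regions whose bilateral segments feed the cognition models.
ANALYSIS_REGIONS = ("parietal", "temporal", "posterior_cingulate")

# ROIs per region within one hemisphere; sums to 318 (636 bilaterally).
_ROIS_PER_REGION = {
    "callosomarginal": 30, "precentral": 24, "central": 24, "parietal": 36,
    "angular": 18, "temporal": 42, "occipital": 24, "pericallosal": 12,
    "lentiform_nucleus": 18, "thalamus": 18, "hippocampus": 18,
    "cerebellum": 36, "posterior_cingulate": 18,
}
N_ROIS = 2 * sum(_ROIS_PER_REGION.values())  # 636


@dataclass
class ROITemplate:
    """Label volume + lookup: ROI id -> (region, hemisphere, segment)."""

    labels: LabelMap
    lookup: pd.DataFrame      # columns: roi_id, region, hemisphere, segment
    segments: pd.DataFrame    # columns: segment, region, hemisphere

    def __post_init__(self) -> None:
        ids = set(self.lookup["roi_id"])
        present = set(np.unique(self.labels.labels).tolist()) - {0}
        if present - ids:
            raise ValidationError("template volume has ROIs missing from lookup")
        if self.lookup["roi_id"].duplicated().any():
            raise ValidationError("duplicate roi_id in lookup")

    @property
    def n_rois(self) -> int:
        return len(self.lookup)


def _segment_name(region: str, hemisphere: str) -> str:
    if region in ANALYSIS_REGIONS:
        return f"{region}_{hemisphere}"
    return f"other_{hemisphere}"


def build_template(shape: tuple[int, int, int] = (64, 80, 64),
                   voxel_mm: float = 2.0) -> ROITemplate:
    """Build the packaged 636-ROI template on a template-space grid.

    The brain is an ellipsoid centred at the world origin; each hemisphere's
    voxels are split into 13 contiguous anterior-to-posterior region bands
    sized by ROI count, and each band into its ROIs.  Deterministic.
    """
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    x = ii * voxel_mm + affine[0, 3]
    y = jj * voxel_mm + affine[1, 3]
    z = kk * voxel_mm + affine[2, 3]
    semi = (np.asarray(shape) - 4) / 2.0 * voxel_mm * 0.9
    brain = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    roi_id = 0
    for hemi, hmask in (("R", brain & (x >= 0)), ("L", brain & (x < 0))):
        idx = np.argwhere(hmask)
        # anterior-to-posterior, then inferior-to-superior, then lateral:
        # a deterministic fill order giving compact region bands
        order = np.lexsort((idx[:, 0], idx[:, 2], -idx[:, 1]))
        idx = idx[order]
        n_hemi = len(idx)
        counts = np.array([_ROIS_PER_REGION[r] for r in REGIONS])
        bounds = np.round(np.cumsum(counts) / counts.sum() * n_hemi).astype(int)
        start = 0
        for region, stop, n_rois in zip(REGIONS, bounds, counts):
            block = idx[start:stop]
            start = stop
            if len(block) < n_rois:
                raise ValidationError(
                    f"template grid too coarse for {n_rois} ROIs in {region}")
            splits = np.array_split(block, n_rois)
            for chunk in splits:
                roi_id += 1
                labels[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = roi_id
                rows.append({"roi_id": roi_id, "region": region,
                             "hemisphere": hemi,
                             "segment": _segment_name(region, hemi)})

    lookup = pd.DataFrame(rows)
    assert len(lookup) == N_ROIS
    lut = {int(r.roi_id): f"{r.region}_{r.hemisphere}_{int(r.roi_id)}"
           for r in lookup.itertuples()}
    seg = (lookup[["segment", "region", "hemisphere"]]
           .drop_duplicates().reset_index(drop=True))
    return ROITemplate(LabelMap(labels, affine, lut), lookup, seg)
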