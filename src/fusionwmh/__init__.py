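"""fusionwmh: fused MRI WMH volumetrics + SPECT rCBF quantification.

Quantifies white-matter-hyperintensity volumes from FLAIR/T1 MRI by region
class (PVH/DWMH x left/right x anterior/posterior), regional cerebral blood
flow from 99mTc-ECD SPECT (Patlak BPI, Lassen linearization, stereotactic
ROI template), fuses both per subject, and runs the cohort statistics
(repeated-measures ANOVA with Ryan pairwise comparisons, log-link GLMs of
cognition on WMH + rCBF).
"""

from ._exceptions import (
    CalibrationError,
    DomainError,
    FitError,
    FormatError,
    FusionError,
    RegistrationError,
    SegmentationError,
    ValidationError,
)
from .core_io import (
    DynamicSeries,
    LabelMap,
    RigidTransform,
    Volume3D,
    load_volume,
    resample,
    save_volume,
)
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
    segment_tissues,
)
from .spect import (
    CBFCalibration,
    LassenParams,
    PerfusionIndex,
    RCBFMap,
    ROIStats,
    TimeActivityCurve,
    apply_roi_template,
    bpi_to_mcbf,
    counts_to_rcbf,
    extract_tac,
    lassen_correct,
    lassen_forward,
    patlak_bpi,
)
from .template import ROITemplate, build_template
from .fusion import (
    FusedSubjectRecord,
    OverlayVolume,
    fuse_subject,
    make_overlay,
    records_to_frame,
)
from .stats import (
    AnovaResult,
    PairwiseTable,
    RegressionResult,
    analyze_cohort,
    fit_glm_log,
    rm_anova,
    ryan_adjusted_alpha,
    ryan_pairwise,
)
from .phantom import (
    CohortSpec,
    LesionSpec,
    MriPhantomSpec,
    SpectPhantomSpec,
    make_cohort,
    make_mri_phantom,
    make_spect_phantom,
)
from .pipeline import MriResult, SpectResult, run_mri, run_spect

__version__ = "0.1.0"
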