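"""Compartment volumes and the 11-feature volumetric panel.

Five volumes are measured per patient — necrosis, contrast enhancing,
T2-FLAIR hyperintensity, tumor bulk and total tumor, all in mm^3 — and six
derivative ratios are formed from them.  Tumor bulk is the sum of necrosis
and enhancing volumes on the T1C grid; total tumor is measured on the
FLAIR grid; the hyperintensity (edema envelope plus nonenhancing tumor)
volume is the *scalar* difference total - bulk, computed across the two
native grids rather than voxelwise.

Ratios with a zero denominator are stored as missing (NaN) and flagged,
never as 0 or infinity; downstream statistics drop missing values per
feature per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_io import ImageVolume, MaskVolume
from .segmentation import SegmentationResult

__all__ = [
    "FEATURE_NAMES",
    "VOLUME_FEATURES",
    "RATIO_FEATURES",
    "VolumetricPanel",
    "compute_volume",
    "derive_hyperintensity",
    "build_panel",
    "panel_from_volumes",
    "panels_to_frame",
]

VOLUME_FEATURES = [
    "necrosis_mm3",
    "enhancing_mm3",
    "flair_hyper_mm3",
    "bulk_mm3",
    "total_mm3",
]
RATIO_FEATURES = [
    "ratio_necrosis_over_enhancing",
    "ratio_enhancing_over_bulk",
    "ratio_enhancing_over_total",
    "ratio_necrosis_over_total",
    "ratio_hyper_over_total",
    "ratio_bulk_over_total",
]
#: Canonical feature names, in canonical order, used by every report.
FEATURE_NAMES = VOLUME_FEATURES + RATIO_FEATURES

#: QC flags that exclude a patient from association analysis by default.
EXCLUSION_FLAGS = frozenset({"hyperintensity_negative"})


@dataclass
class VolumetricPanel:
    """The 11 named volumetric features of one patient, plus QC flags."""

    patient_id: str
    necrosis_mm3: float
    enhancing_mm3: float
    flair_hyper_mm3: float
    bulk_mm3: float
    total_mm3: float
    ratio_necrosis_over_enhancing: float
    ratio_enhancing_over_bulk: float
    ratio_enhancing_over_total: float
    ratio_necrosis_over_total: float
    ratio_hyper_over_total: float
    ratio_bulk_over_total: float
    qc_flags: set[str] = field(default_factory=set)

    def as_dict(self) -> dict:
        d = {"patient_id": self.patient_id}
        d.update({name: getattr(self, name) for name in FEATURE_NAMES})
        d["qc_flags"] = ";".join(sorted(self.qc_flags))
        return d

    @property
    def excluded(self) -> bool:
        """True when a QC flag marks this patient for exclusion from
        association analysis."""
        return bool(self.qc_flags & EXCLUSION_FLAGS)


def compute_volume(mask: MaskVolume, voxel_dims: tuple[float, float, float]) -> float:
    """Volume of a mask in mm^3: voxel count times the voxel size."""
    voxel_volume = float(np.prod([float(d) for d in voxel_dims]))
    return mask.n_voxels * voxel_volume


def derive_hyperintensity(total_mm3: float, bulk_mm3: float) -> float:
    """T2-FLAIR hyperintensity volume: total tumor minus tumor bulk.

    This is a scalar subtraction across the two native grids.  A negative
    result (bulk measured larger than total, possible because the two
    masks live on different series) is returned as-is; the caller flags it
    as a QC failure.
    """
    if total_mm3 < 0 or bulk_mm3 < 0:
        raise ValueError("volumes must be non-negative")
    return total_mm3 - bulk_mm3


def _safe_ratio(num: float, den: float, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(f"undefined_{name}")
        return float("nan")
    return num / den


def panel_from_volumes(
    patient_id: str,
    necrosis_mm3: float,
    enhancing_mm3: float,
    total_mm3: float,
    qc_flags: set[str] | None = None,
) -> VolumetricPanel:
    """Assemble the full 11-feature panel from the three measured volumes.

    ``bulk = necrosis + enhancing`` holds exactly (same grid, additive
    voxel counts) and ``total = bulk + hyper`` holds by construction of
    the hyperintensity volume.
    """
    flags: set[str] = set(qc_flags or ())
    bulk = necrosis_mm3 + enhancing_mm3
    hyper = derive_hyperintensity(total_mm3, bulk)
    if hyper < 0:
        flags.add("hyperintensity_negative")
    return VolumetricPanel(
        patient_id=patient_id,
        necrosis_mm3=necrosis_mm3,
        enhancing_mm3=enhancing_mm3,
        flair_hyper_mm3=hyper,
        bulk_mm3=bulk,
        total_mm3=total_mm3,
        ratio_necrosis_over_enhancing=_safe_ratio(
            necrosis_mm3, enhancing_mm3, "ratio_necrosis_over_enhancing", flags
        ),
        ratio_enhancing_over_bulk=_safe_ratio(
            enhancing_mm3, bulk, "ratio_enhancing_over_bulk", flags
        ),
        ratio_enhancing_over_total=_safe_ratio(
            enhancing_mm3, total_mm3, "ratio_enhancing_over_total", flags
        ),
        ratio_necrosis_over_total=_safe_ratio(
            necrosis_mm3, total_mm3, "ratio_necrosis_over_total", flags
        ),
        ratio_hyper_over_total=_safe_ratio(hyper, total_mm3, "ratio_hyper_over_total", flags),
        ratio_bulk_over_total=_safe_ratio(bulk, total_mm3, "ratio_bulk_over_total", flags),
        qc_flags=flags,
    )


def build_panel(
    seg: SegmentationResult,
    t1c: ImageVolume,
    flair: ImageVolume,
    total_mask: MaskVolume,
    patient_id: str | None = None,
    qc_flags: set[str] | None = None,
) -> VolumetricPanel:
    """Measure all 11 features for one patient.

    Necrosis and enhancing volumes come from the segmentation on the T1C
    grid; the total tumor volume from the rater's mask on the FLAIR grid.
    QC failures propagate as flags, not exceptions.
    """
    necrosis = compute_volume(seg.necrosis_mask, t1c.voxel_dims)
    enhancing = compute_volume(seg.enhancing_mask, t1c.voxel_dims)
    total = compute_volume(total_mask.bound_to(flair), flair.voxel_dims)
    return panel_from_volumes(
        patient_id=patient_id if patient_id is not None else t1c.id,
        necrosis_mm3=necrosis,
        enhancing_mm3=enhancing,
        total_mm3=total,
        qc_flags=qc_flags,
    )


def panels_to_frame(panels: list[VolumetricPanel]) -> pd.DataFrame:
    """Patient x feature table with canonical column names and order."""
    frame = pd.DataFrame([p.as_dict() for p in panels])
    if frame.empty:
        frame = pd.DataFrame(columns=["patient_id", *FEATURE_NAMES, "qc_flags"])
    return frame.set_index("patient_id")
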