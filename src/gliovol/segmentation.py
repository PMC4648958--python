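"""Intensity stratification of the T1C tumor bulk into necrosis and
contrast-enhancing compartments.

The tumor bulk mask (drawn by a rater on the T1-contrast series) is split
into a dark compartment (necrosis) and a bright compartment (contrast
enhancement) by two-class K-means on the in-mask voxel intensities.  For
one-dimensional data the optimal two-class K-means solution is a
contiguous split of the sorted values, so instead of Lloyd iterations with
random restarts the globally optimal split is found exactly by scanning
every admissible split point with prefix sums.  This makes the
segmentation deterministic and seed-free.

Spatial regularization and partial-volume modelling are intentionally not
applied; the clustering is intensity-only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateInputError, GridMismatchError
from .image_io import ImageVolume, MaskVolume, write_mask

__all__ = [
    "SegmentationResult",
    "kmeans_two_class",
    "stratify_bulk",
    "dice",
    "write_segmentation",
]


@dataclass(eq=False)
class SegmentationResult:
    """Necrosis/enhancing partition of a tumor-bulk mask.

    The two masks are disjoint, their union is exactly the input bulk
    mask, and the partition is a threshold partition: every necrosis
    intensity is <= every enhancing intensity.
    """

    necrosis_mask: MaskVolume
    enhancing_mask: MaskVolume
    centroid_dark: float
    centroid_bright: float

    @property
    def threshold(self) -> float:
        """Midpoint of the two centroids; any value between the darkest
        enhancing voxel and the brightest necrotic voxel is equivalent."""
        return 0.5 * (self.centroid_dark + self.centroid_bright)

    def qc_record(self) -> dict:
        return {
            "centroid_dark": self.centroid_dark,
            "centroid_bright": self.centroid_bright,
            "n_necrosis_voxels": self.necrosis_mask.n_voxels,
            "n_enhancing_voxels": self.enhancing_mask.n_voxels,
        }


def kmeans_two_class(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Exact two-class K-means for one-dimensional data.

    Returns ``(labels, (centroid_dark, centroid_bright))`` where
    ``labels[i]`` is 0 for the low-intensity cluster and 1 for the
    high-intensity cluster.  The partition globally minimizes the total
    within-cluster sum of squared deviations: all n-1 contiguous splits of
    the sorted values are scanned with prefix sums (splits are only placed
    between distinct values so equal values are never divided across
    clusters).  Equal-SSE splits break toward the larger dark cluster.

    Raises
    ------
    DegenerateInputError
        If fewer than two values are given or all values are identical.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    n = v.size
    if n < 2:
        raise DegenerateInputError(f"two-class clustering needs >= 2 values, got {n}")
    order = np.argsort(v, kind="stable")
    s = v[order]
    if s[0] == s[-1]:
        raise DegenerateInputError("two-class clustering needs >= 2 distinct values")

    # prefix sums; split k means s[:k] dark, s[k:] bright
    c1 = np.cumsum(s)
    c2 = np.cumsum(s * s)
    k = np.arange(1, n)
    left_sum = c1[k - 1]
    left_sq = c2[k - 1]
    right_sum = c1[-1] - left_sum
    right_sq = c2[-1] - left_sq
    sse = (left_sq - left_sum**2 / k) + (right_sq - right_sum**2 / (n - k))
    # admissible splits fall between distinct sorted values
    valid = s[k - 1] < s[k]
    sse = np.where(valid, sse, np.inf)
    # last argmin -> ties go to the larger dark cluster
    k_best = int(n - 1 - np.argmin(sse[::-1]))

    labels = np.zeros(n, dtype=np.int8)
    labels[order[k_best:]] = 1
    centroid_dark = float(s[:k_best].mean())
    centroid_bright = float(s[k_best:].mean())
    return labels, (centroid_dark, centroid_bright)


def stratify_bulk(t1c: ImageVolume, bulk: MaskVolume) -> SegmentationResult:
    """Split the tumor bulk into necrosis (dark) and enhancing (bright).

    Applies :func:`kmeans_two_class` to the T1C intensities under the bulk
    mask; the lower-centroid cluster becomes the necrosis mask and the
    higher-centroid cluster the contrast-enhancing mask.

    Raises
    ------
    GridMismatchError
        If the bulk mask is not bound to ``t1c``.
    DegenerateInputError
        If the bulk mask is empty, has a single voxel, or is constant in
        intensity.  The error message carries the image id so the pipeline
        can attribute the failure to a patient.
    """
    if bulk.reference_id != t1c.id:
        raise GridMismatchError(
            f"bulk mask references '{bulk.reference_id}', not T1C image '{t1c.id}'"
        )
    if bulk.shape != t1c.shape:
        raise GridMismatchError(
            f"bulk mask shape {bulk.shape} does not match T1C shape {t1c.shape}"
        )
    inside = bulk.grid.astype(bool)
    intensities = t1c.grid[inside]
    if intensities.size < 2:
        raise DegenerateInputError(
            f"'{t1c.id}': bulk mask has {intensities.size} voxel(s); need >= 2"
        )
    if intensities.min() == intensities.max():
        raise DegenerateInputError(
            f"'{t1c.id}': bulk mask has constant intensity {intensities.min():g}"
        )
    labels, (c_dark, c_bright) = kmeans_two_class(intensities)

    necrosis = np.zeros(t1c.shape, dtype=np.uint8)
    enhancing = np.zeros(t1c.shape, dtype=np.uint8)
    idx = np.nonzero(inside)
    necrosis[idx] = (labels == 0).astype(np.uint8)
    enhancing[idx] = (labels == 1).astype(np.uint8)
    return SegmentationResult(
        necrosis_mask=MaskVolume(necrosis, reference_id=t1c.id),
        enhancing_mask=MaskVolume(enhancing, reference_id=t1c.id),
        centroid_dark=c_dark,
        centroid_bright=c_bright,
    )


def dice(a: np.ndarray | MaskVolume, b: np.ndarray | MaskVolume) -> float:
    """Dice overlap coefficient 2|A∩B| / (|A|+|B|) between two binary masks.

    Returns 1.0 when both masks are empty (perfect agreement on nothing).
    """
    ga = a.grid if isinstance(a, MaskVolume) else np.asarray(a)
    gb = b.grid if isinstance(b, MaskVolume) else np.asarray(b)
    ga = ga.astype(bool)
    gb = gb.astype(bool)
    denom = ga.sum() + gb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(ga, gb).sum() / denom


def write_segmentation(
    out_dir: str | Path,
    patient_id: str,
    seg: SegmentationResult,
    voxel_dims: tuple[float, float, float],
    extra_flags: list[str] | None = None,
) -> None:
    """Write necrosis/enhancing masks as NIfTI plus a JSON QC record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(out / f"{patient_id}_necrosis.nii.gz", seg.necrosis_mask, voxel_dims)
    write_mask(out / f"{patient_id}_enhancing.nii.gz", seg.enhancing_mask, voxel_dims)
    record = seg.qc_record()
    record["patient_id"] = patient_id
    record["flags"] = sorted(extra_flags or [])
    with open(out / f"{patient_id}_seg_qc.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
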