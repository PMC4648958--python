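"""End-to-end orchestration: generate/load -> segment -> quantify -> associate.

A run reads either a synthetic cohort preset or a directory of per-patient
NIfTI series plus mutation/clinical tables, and writes a fixed set of
machine-readable outputs to the output directory:

``features.csv``
    patient x 11-feature panel (canonical names) plus QC flags.
``association.csv``
    gene x feature association/prediction table.
``normality.csv``, ``correlation.csv``, ``clusters.csv``, ``cluster_tests.csv``
    Shapiro-Wilk screen, Pearson feature correlations, two-group patient
    clustering and its clinical-independence chi-squared tests.
``qc.json``
    per-patient QC records and the exclusion list.
``run_meta.json``
    seed, options, stage timings and package version.

Per-patient failures are QC-flagged and excluded, never silently dropped;
the run fails only if fewer than four usable patients remain.  Given the
same configuration and seed, reruns produce byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import DegenerateInputError, PipelineError
from .image_io import ImageVolume, MaskVolume, read_mask, read_volume
from .segmentation import SegmentationResult, stratify_bulk
from .volumetrics import (
    FEATURE_NAMES,
    VolumetricPanel,
    build_panel,
    compute_volume,
    panel_from_volumes,
    panels_to_frame,
)
from .association import (
    MutationTable,
    association_scan,
    cluster_and_test,
    correlation_matrix,
    normality_screen,
)
from .synthetic_data import Cohort, preset_cohort, simulate_cohort

logger = logging.getLogger("gliovol")

__all__ = ["RunConfig", "run_pipeline", "segment_patient", "load_cohort_dir"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    mode: str = "synthetic"  # "synthetic" | "directory"
    preset: str = "null"
    n_patients: int = 76
    shape: tuple[int, int, int] = (64, 64, 64)
    input_dir: str | None = None
    seed: int = 0
    min_mut: int = 5
    alpha: float = 0.05
    multiplicity: str = "none"  # "none" | "bh"
    auc_p_method: str = "normal"  # "normal" | "permutation"
    out_dir: str = "gliovol_run"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise PipelineError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_mut < 1:
            raise PipelineError(f"min_mut must be >= 1, got {self.min_mut}")
        if self.mode not in ("synthetic", "directory"):
            raise PipelineError(f"unknown input mode: {self.mode!r}")
        if self.mode == "directory" and not self.input_dir:
            raise PipelineError("directory mode requires input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "shape" in raw:
            raw["shape"] = tuple(raw["shape"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(d["shape"])
        return d


@dataclass
class PatientInput:
    patient_id: str
    t1c: ImageVolume
    flair: ImageVolume
    bulk_mask: MaskVolume
    total_mask: MaskVolume


def segment_patient(patient: PatientInput) -> tuple[SegmentationResult | None, set[str]]:
    """Stratify one patient's bulk, applying the degenerate-bulk policy.

    A constant-intensity bulk cannot be split into bright and dark; the
    whole bulk is then assigned to the enhancing compartment (necrosis
    0 mm^3, preserving volume additivity) and the anomaly surfaced as a
    ``constant_bulk_all_enhancing`` QC flag.  Empty or single-voxel bulks
    are unrecoverable and yield ``(None, flags)``.
    """
    flags: set[str] = set()
    try:
        return stratify_bulk(patient.t1c, patient.bulk_mask), flags
    except DegenerateInputError as exc:
        if patient.bulk_mask.n_voxels >= 2:
            flags.add("constant_bulk_all_enhancing")
            inside = patient.bulk_mask.grid.astype(bool)
            value = float(patient.t1c.grid[inside][0])
            seg = SegmentationResult(
                necrosis_mask=MaskVolume(
                    np.zeros(patient.t1c.shape, np.uint8), reference_id=patient.t1c.id
                ),
                enhancing_mask=MaskVolume(
                    patient.bulk_mask.grid.copy(), reference_id=patient.t1c.id
                ),
                centroid_dark=value,
                centroid_bright=value,
            )
            return seg, flags
        flags.add(f"segmentation_failed:{exc}")
        return None, flags


def _synthetic_inputs(config: RunConfig) -> tuple[list[PatientInput], MutationTable, pd.DataFrame]:
    spec = preset_cohort(
        config.preset, n_patients=config.n_patients, seed=config.seed, shape=config.shape
    )
    cohort: Cohort = simulate_cohort(spec, render_images=True)
    patients = [
        PatientInput(
            rec.patient_id,
            rec.phantom.t1c,
            rec.phantom.flair,
            rec.phantom.bulk_mask,
            rec.phantom.total_mask,
        )
        for rec in cohort.patients
    ]
    return patients, cohort.mutation_table(), cohort.clinical


def load_cohort_dir(input_dir: str | Path) -> tuple[list[PatientInput], MutationTable, pd.DataFrame]:
    """Load a cohort from the directory layout written by ``write_cohort``.

    Each patient subdirectory must contain ``t1c.nii.gz``,
    ``flair.nii.gz``, ``bulk_mask.nii.gz`` and ``total_mask.nii.gz`` (or
    uncompressed ``.nii`` variants); ``mutations.csv`` and
    ``clinical.csv`` sit at the top level.
    """
    root = Path(input_dir)
    if not root.is_dir():
        raise PipelineError(f"input directory not found: {root}")

    def _find(pdir: Path, stem: str) -> Path:
        for suffix in (".nii.gz", ".nii"):
            cand = pdir / f"{stem}{suffix}"
            if cand.exists():
                return cand
        raise PipelineError(f"{pdir}: missing {stem}.nii[.gz]")

    patients = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        pid = pdir.name
        t1c = read_volume(_find(pdir, "t1c"), id=f"{pid}_t1c")
        flair = read_volume(_find(pdir, "flair"), id=f"{pid}_flair")
        patients.append(
            PatientInput(
                pid,
                t1c,
                flair,
                read_mask(_find(pdir, "bulk_mask"), t1c),
                read_mask(_find(pdir, "total_mask"), flair),
            )
        )
    if not patients:
        raise PipelineError(f"no patient subdirectories under {root}")
    mutations = MutationTable.from_csv(root / "mutations.csv")
    clinical_path = root / "clinical.csv"
    clinical = (
        pd.read_csv(clinical_path, index_col=0)
        if clinical_path.exists()
        else pd.DataFrame(index=mutations.status.index)
    )
    return patients, mutations, clinical


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    # fixed formatting (full repr precision, '\n' terminator) so that
    # reruns with an identical config are byte-identical
    frame.to_csv(path, index=index, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write every report; returns a run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.mode == "synthetic":
        patients, mutations, clinical = _synthetic_inputs(config)
    else:
        patients, mutations, clinical = load_cohort_dir(config.input_dir)
    timings["load_or_simulate_s"] = round(time.perf_counter() - t0, 3)
    logger.info("inputs ready: %d patients, %d genes", len(patients), len(mutations.genes))

    t0 = time.perf_counter()
    panels: list[VolumetricPanel] = []
    qc_patients: dict[str, dict] = {}
    exclusions: dict[str, list[str]] = {}
    for patient in patients:
        seg, flags = segment_patient(patient)
        if seg is None:
            exclusions[patient.patient_id] = sorted(flags)
            logger.warning("%s excluded: %s", patient.patient_id, sorted(flags))
            continue
        panel = build_panel(
            seg,
            patient.t1c,
            patient.flair,
            patient.total_mask,
            patient_id=patient.patient_id,
            qc_flags=flags,
        )
        qc_patients[patient.patient_id] = {**seg.qc_record(), "flags": sorted(panel.qc_flags)}
        if panel.excluded:
            exclusions[patient.patient_id] = sorted(panel.qc_flags)
            logger.warning("%s excluded by QC: %s", patient.patient_id, sorted(panel.qc_flags))
            continue
        panels.append(panel)
    timings["segment_quantify_s"] = round(time.perf_counter() - t0, 3)

    if len(panels) < 4:
        raise PipelineError(
            f"only {len(panels)} usable patients after QC; need >= 4"
        )

    features = panels_to_frame(panels)
    _write_csv(features, out / "features.csv")

    t0 = time.perf_counter()
    scan = association_scan(
        features,
        mutations,
        min_mut=config.min_mut,
        alpha=config.alpha,
        multiplicity=config.multiplicity,
        auc_p_method=config.auc_p_method,
        seed=config.seed,
    )
    _write_csv(scan, out / "association.csv", index=False)
    _write_csv(normality_screen(features), out / "normality.csv", index=False)
    corr, corr_flags = correlation_matrix(features)
    _write_csv(corr, out / "correlation.csv")
    cluster = cluster_and_test(features, clinical)
    _write_csv(cluster.assignments.to_frame(), out / "clusters.csv")
    _write_csv(cluster.tests, out / "cluster_tests.csv", index=False)
    timings["associate_s"] = round(time.perf_counter() - t0, 3)

    qc = {
        "patients": qc_patients,
        "exclusions": exclusions,
        "correlation_flags": corr_flags,
        "cluster_flags": list(cluster.flags),
    }
    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)

    meta = {
        "version": __version__,
        "config": config.to_dict(),
        "timings_s": timings,
        "n_patients_input": len(patients),
        "n_patients_used": len(panels),
        "n_genes_tested": int(scan["gene"].nunique()) if len(scan) else 0,
    }
    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)

    summary = dict(meta)
    summary["n_significant_t"] = int(scan["significant_t"].sum()) if len(scan) else 0
    summary["out_dir"] = str(out)
    return summary
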