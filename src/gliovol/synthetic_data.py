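"""Seeded synthetic phantom images and cohorts with known ground truth.

Each phantom patient is a set of three nested ellipsoids on a regular
grid: a dark necrotic core, a bright contrast-enhancing rim around it
(core + rim = tumor bulk, visible on the T1C image) and an outer edema
envelope (bulk + envelope = total tumor extent, hyperintense on the
FLAIR image).  Ellipsoids are deliberately simple shapes: every feature
the pipeline measures is a volume or a ratio of volumes, both of which
are shape-agnostic, and ellipsoids admit exact analytic volume oracles.

A cohort draws per-patient mutation statuses independently per gene,
scales compartment semi-axes multiplicatively for mutants, jitters the
overall tumor size log-normally (so volumes stay positive and are
near-normal on the scale tested), and draws clinical variables
independently of the imaging features — a null association by
construction.  Everything is reproducible from a single master seed;
per-patient streams are derived deterministically so generation order
does not matter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import GliovolError
from .image_io import ImageVolume, MaskVolume, write_mask, write_volume
from .volumetrics import VolumetricPanel, panel_from_volumes

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Phantom",
    "GeneEffect",
    "CohortSpec",
    "PatientRecord",
    "Cohort",
    "generate_phantom",
    "simulate_cohort",
    "preset_cohort",
    "write_cohort",
    "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# single phantom


@dataclass
class PhantomSpec:
    """Geometry, intensity model and noise of one phantom patient.

    Semi-axes are in voxel units; intensities in arbitrary MR units.
    Defaults give a well-separated dark core (40) and bright rim (160) on
    T1C, and a hyperintense lesion (150) over background (30) on FLAIR.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] | None = None
    core_semiaxes: tuple[float, float, float] = (6.0, 7.0, 5.0)
    bulk_semiaxes: tuple[float, float, float] = (10.0, 12.0, 8.0)
    total_semiaxes: tuple[float, float, float] = (15.0, 17.0, 12.0)
    t1c_background: float = 30.0
    t1c_necrosis: float = 40.0
    t1c_enhancing: float = 160.0
    flair_background: float = 30.0
    flair_lesion: float = 150.0
    noise_sd_t1c: float = 0.0
    noise_sd_flair: float = 0.0
    seed: int = 0
    id: str = "phantom"

    def __post_init__(self) -> None:
        core = np.asarray(self.core_semiaxes, dtype=float)
        bulk = np.asarray(self.bulk_semiaxes, dtype=float)
        total = np.asarray(self.total_semiaxes, dtype=float)
        if np.any(core <= 0) or np.any(core > bulk) or np.any(bulk > total):
            raise GliovolError(
                f"semi-axes must satisfy 0 < core <= bulk <= total per axis, got "
                f"core={tuple(core)}, bulk={tuple(bulk)}, total={tuple(total)}"
            )
        if self.noise_sd_t1c < 0 or self.noise_sd_flair < 0:
            raise GliovolError("noise sd must be >= 0")
        center = self.center
        if center is None:
            center = tuple((s - 1) / 2.0 for s in self.shape)
            object.__setattr__(self, "center", center)
        lo = np.asarray(center) - total
        hi = np.asarray(center) + total
        if np.any(lo < -0.5) or np.any(hi > np.asarray(self.shape) - 0.5):
            raise GliovolError(
                f"outer ellipsoid (semi-axes {tuple(total)} at {center}) exceeds "
                f"grid of shape {self.shape}"
            )


@dataclass
class PhantomTruth:
    """Exact compartment masks and volumes of a generated phantom."""

    core_mask: np.ndarray  # necrosis
    rim_mask: np.ndarray  # contrast enhancing
    edema_mask: np.ndarray  # envelope outside bulk
    bulk_mask: np.ndarray  # core + rim
    total_mask: np.ndarray  # bulk + edema
    volumes_mm3: dict[str, float]  # keyed by panel volume names


@dataclass
class Phantom:
    t1c: ImageVolume
    flair: ImageVolume
    bulk_mask: MaskVolume  # the "rater" mask on T1C
    total_mask: MaskVolume  # the "rater" mask on FLAIR
    truth: PhantomTruth


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    """Boolean voxel-center-in-ellipsoid rasterization."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize the nested-ellipsoid phantom and render both series."""
    rng = np.random.default_rng(spec.seed)
    core = _ellipsoid(spec.shape, spec.center, spec.core_semiaxes)
    bulk = _ellipsoid(spec.shape, spec.center, spec.bulk_semiaxes)
    total = _ellipsoid(spec.shape, spec.center, spec.total_semiaxes)
    # nesting of the boolean masks follows from the semi-axis ordering
    rim = bulk & ~core
    edema = total & ~bulk

    t1c_grid = np.full(spec.shape, spec.t1c_background, dtype=np.float64)
    t1c_grid[core] = spec.t1c_necrosis
    t1c_grid[rim] = spec.t1c_enhancing
    if spec.noise_sd_t1c > 0:
        t1c_grid += rng.normal(0.0, spec.noise_sd_t1c, size=spec.shape)

    flair_grid = np.full(spec.shape, spec.flair_background, dtype=np.float64)
    flair_grid[total] = spec.flair_lesion
    if spec.noise_sd_flair > 0:
        flair_grid += rng.normal(0.0, spec.noise_sd_flair, size=spec.shape)

    t1c = ImageVolume(t1c_grid, spec.voxel_dims, id=f"{spec.id}_t1c")
    flair = ImageVolume(flair_grid, spec.voxel_dims, id=f"{spec.id}_flair")
    truth = _truth_from_masks(core, rim, edema, bulk, total, spec.voxel_dims)
    return Phantom(
        t1c=t1c,
        flair=flair,
        bulk_mask=MaskVolume(bulk.astype(np.uint8), reference_id=t1c.id),
        total_mask=MaskVolume(total.astype(np.uint8), reference_id=flair.id),
        truth=truth,
    )


def _truth_from_masks(core, rim, edema, bulk, total, voxel_dims) -> PhantomTruth:
    vox = float(np.prod(voxel_dims))
    volumes = {
        "necrosis_mm3": float(core.sum()) * vox,
        "enhancing_mm3": float(rim.sum()) * vox,
        "flair_hyper_mm3": float(edema.sum()) * vox,
        "bulk_mm3": float(bulk.sum()) * vox,
        "total_mm3": float(total.sum()) * vox,
    }
    return PhantomTruth(
        core_mask=core, rim_mask=rim, edema_mask=edema,
        bulk_mask=bulk, total_mask=total, volumes_mm3=volumes,
    )


def true_volumes(spec: PhantomSpec) -> dict[str, float]:
    """Rasterize only the masks of a phantom and return exact volumes.

    Much faster than :func:`generate_phantom` when the noisy images are
    not needed (e.g. large calibration studies on true volumes).
    """
    core = _ellipsoid(spec.shape, spec.center, spec.core_semiaxes)
    bulk = _ellipsoid(spec.shape, spec.center, spec.bulk_semiaxes)
    total = _ellipsoid(spec.shape, spec.center, spec.total_semiaxes)
    truth = _truth_from_masks(core, bulk & ~core, total & ~bulk, bulk, total, spec.voxel_dims)
    return truth.volumes_mm3


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GeneEffect:
    """Mutation frequency and phenotypic effect of one gene.

    Mutant tumors have their compartment semi-axes multiplied by the
    corresponding factor; 1.0 everywhere means the mutation has no
    imaging phenotype.  Volumes scale as the cube of a semi-axis factor.
    """

    name: str
    p_mut: float
    core_mult: float = 1.0
    bulk_mult: float = 1.0
    total_mult: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_mut <= 1.0:
            raise GliovolError(f"{self.name}: mutation probability must be in [0, 1]")
        if min(self.core_mult, self.bulk_mult, self.total_mult) <= 0:
            raise GliovolError(f"{self.name}: effect multipliers must be > 0")


@dataclass
class CohortSpec:
    """Simulation parameters of a synthetic patient cohort."""

    n_patients: int = 76
    genes: list[GeneEffect] = field(default_factory=list)
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    core_frac: tuple[float, float, float] = (0.10, 0.11, 0.09)
    bulk_frac: tuple[float, float, float] = (0.155, 0.17, 0.14)
    total_frac: tuple[float, float, float] = (0.24, 0.26, 0.21)
    size_jitter_sd: float = 0.10  # log-normal sd of the per-patient scale
    compartment_jitter_sd: float = 0.06  # extra independent per-compartment jitter
    noise_sd_t1c: float = 12.0
    noise_sd_flair: float = 12.0
    clinical_missing_rate: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise GliovolError(f"cohort needs >= 4 patients, got {self.n_patients}")

    def base_semiaxes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        shape = np.asarray(self.shape, dtype=float)
        return (
            shape * np.asarray(self.core_frac),
            shape * np.asarray(self.bulk_frac),
            shape * np.asarray(self.total_frac),
        )


@dataclass
class PatientRecord:
    patient_id: str
    spec: PhantomSpec
    truth_volumes: dict[str, float]
    phantom: Phantom | None = None

    def truth_panel(self) -> VolumetricPanel:
        v = self.truth_volumes
        return panel_from_volumes(
            self.patient_id, v["necrosis_mm3"], v["enhancing_mm3"], v["total_mm3"]
        )


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[PatientRecord]
    mutations: "pd.DataFrame"  # patient x gene, 0/1
    clinical: pd.DataFrame

    def mutation_table(self):
        from .association import MutationTable

        return MutationTable(self.mutations)

    def truth_panels(self) -> list[VolumetricPanel]:
        return [p.truth_panel() for p in self.patients]


def _patient_rng(master_seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-patient stream, independent of generation order."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, index, stream]))


def simulate_cohort(spec: CohortSpec, render_images: bool = True) -> Cohort:
    """Draw mutations, sizes and clinical covariates; build every phantom.

    With ``render_images=False`` only the exact truth masks are
    rasterized (no noisy image rendering), which is the fast path for
    calibration and power studies that operate on true volumes.
    """
    core_base, bulk_base, total_base = spec.base_semiaxes()

    patients: list[PatientRecord] = []
    mutation_rows = {}
    clinical_rows = {}
    for i in range(spec.n_patients):
        pid = f"SYN-{i:03d}"
        rng = _patient_rng(spec.master_seed, i)
        status = {g.name: int(rng.random() < g.p_mut) for g in spec.genes}
        mutation_rows[pid] = status

        core_mult = bulk_mult = total_mult = 1.0
        for g in spec.genes:
            if status[g.name]:
                core_mult *= g.core_mult
                bulk_mult *= g.bulk_mult
                total_mult *= g.total_mult
        def _jitter(sd: float) -> float:
            if sd <= 0:
                return 1.0
            return float(np.exp(np.clip(rng.normal(0.0, sd), -3 * sd, 3 * sd)))

        # shared overall size jitter plus independent per-compartment
        # jitter, so ratios of compartment volumes vary across patients
        scale = _jitter(spec.size_jitter_sd)
        comp = spec.compartment_jitter_sd
        core = core_base * scale * _jitter(comp) * core_mult
        bulk = bulk_base * scale * _jitter(comp) * bulk_mult
        total = total_base * scale * _jitter(comp) * total_mult
        # composed effects may break nesting; clip and let volumetrics
        # surface any residual anomaly downstream
        core = np.minimum(core, bulk)
        bulk = np.maximum(bulk, core)
        total = np.maximum(total, bulk)

        pspec = PhantomSpec(
            shape=spec.shape,
            voxel_dims=spec.voxel_dims,
            core_semiaxes=tuple(core),
            bulk_semiaxes=tuple(bulk),
            total_semiaxes=tuple(total),
            noise_sd_t1c=spec.noise_sd_t1c,
            noise_sd_flair=spec.noise_sd_flair,
            seed=int(_patient_rng(spec.master_seed, i, stream=1).integers(2**31)),
            id=pid,
        )
        if render_images:
            phantom = generate_phantom(pspec)
            volumes = phantom.truth.volumes_mm3
        else:
            phantom = None
            volumes = true_volumes(pspec)
        patients.append(PatientRecord(pid, pspec, volumes, phantom))

        crng = _patient_rng(spec.master_seed, i, stream=2)
        clinical = {
            "gender": "M" if crng.random() < 0.5 else "F",
            "dfs": int(crng.random() < 0.5),
            "kps": int(crng.choice([40, 60, 80, 100])),
            "age": int(crng.integers(21, 86)),
        }
        for key in list(clinical):
            if crng.random() < spec.clinical_missing_rate:
                clinical[key] = None
        clinical_rows[pid] = clinical

    mutations = pd.DataFrame.from_dict(mutation_rows, orient="index").astype(int)
    mutations = mutations[[g.name for g in spec.genes]]
    mutations.index.name = "patient_id"
    clinical = pd.DataFrame.from_dict(clinical_rows, orient="index")
    clinical.index.name = "patient_id"
    return Cohort(spec=spec, patients=patients, mutations=mutations, clinical=clinical)


# ---------------------------------------------------------------------------
# presets

#: Gene set and per-gene mutation probabilities emulating a 76-patient
#: adult-GBM cohort (frequently altered genes; expected counts in
#: parentheses): TP53 (26), PTEN (24), NF1 (9), EGFR (24), IDH1 (7),
#: PIK3R1 (8), RB1 (8), PIK3CA (6), PDGFRA (6).
_GBM_GENE_FREQS = {
    "TP53": 26 / 76,
    "PTEN": 24 / 76,
    "NF1": 9 / 76,
    "EGFR": 24 / 76,
    "IDH1": 7 / 76,
    "PIK3R1": 8 / 76,
    "RB1": 8 / 76,
    "PIK3CA": 6 / 76,
    "PDGFRA": 6 / 76,
}

# Mutant semi-axis multipliers per preset.  With the default global size
# jitter (sd 0.10) plus per-compartment jitter (sd 0.06) a compartment
# volume has a relative sd near 0.35, so a semi-axis factor of 0.86
# (volume factor 0.64) plants close to a 1.0 pooled-SD reduction in
# enhancing volume.
_PRESET_EFFECTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "null": {},
    # smaller core and rim (hence smaller necrosis, enhancing and bulk)
    "tp53_like": {"TP53": (0.86, 0.86, 1.0)},
    # smaller edema envelope at similar bulk
    "rb1_like": {"RB1": (1.0, 1.0, 0.85)},
    # larger core, same bulk (so smaller rim), similar total extent:
    # shifts the necrosis/enhancing balance at similar total volume
    "egfr_like": {"EGFR": (1.18, 1.0, 1.0)},
}

PRESET_NAMES = tuple(_PRESET_EFFECTS)


def preset_cohort(
    name: str,
    n_patients: int = 76,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd_t1c: float = 12.0,
    noise_sd_flair: float = 12.0,
) -> CohortSpec:
    """A documented cohort specification for a named study condition.

    ``tp53_like``: mutants have smaller necrotic core and enhancing rim.
    ``rb1_like``: mutants have a smaller edema envelope at similar bulk.
    ``egfr_like``: mutants have a larger core inside an unchanged bulk,
    shifting the necrosis/enhancing ratio at similar total volume.
    ``null``: all effect multipliers 1.0 (no imaging phenotype).
    """
    if name not in _PRESET_EFFECTS:
        raise GliovolError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
        )
    effects = _PRESET_EFFECTS[name]
    genes = [
        GeneEffect(g, p, *effects.get(g, (1.0, 1.0, 1.0)))
        for g, p in _GBM_GENE_FREQS.items()
    ]
    return CohortSpec(
        n_patients=n_patients,
        genes=genes,
        shape=shape,
        voxel_dims=voxel_dims,
        noise_sd_t1c=noise_sd_t1c,
        noise_sd_flair=noise_sd_flair,
        master_seed=seed,
    )


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a rendered cohort to a directory layout.

    ``<out>/<patient>/{t1c,flair,bulk_mask,total_mask}.nii.gz`` per
    patient plus cohort-level ``mutations.csv``, ``clinical.csv`` and
    ``truth.json`` (exact per-patient compartment volumes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = {}
    for rec in cohort.patients:
        if rec.phantom is None:
            raise GliovolError(
                f"{rec.patient_id}: cohort was simulated without rendered images"
            )
        pdir = out / rec.patient_id
        pdir.mkdir(exist_ok=True)
        write_volume(pdir / "t1c.nii.gz", rec.phantom.t1c)
        write_volume(pdir / "flair.nii.gz", rec.phantom.flair)
        write_mask(pdir / "bulk_mask.nii.gz", rec.phantom.bulk_mask, rec.spec.voxel_dims)
        write_mask(pdir / "total_mask.nii.gz", rec.phantom.total_mask, rec.spec.voxel_dims)
        truth[rec.patient_id] = rec.truth_volumes
    cohort.mutations.to_csv(out / "mutations.csv")
    cohort.clinical.to_csv(out / "clinical.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
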