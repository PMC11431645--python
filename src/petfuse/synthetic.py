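"""Synthetic PET/CT phantom cohorts with known prognostic structure.

Each phantom patient has a CT volume (HU: air background, a soft-tissue body
ellipsoid, slightly denser lesions, Gaussian noise), a PET volume on a coarser
grid (SUV: background ~ 1, tumor uptake drawn per patient, intratumoral
heterogeneity realised as a smoothed Gaussian random field), an ellipsoidal
primary tumor mask (GTVp), 0-3 spherical nodal masks (GTVn), clinical
covariates, and a right-censored recurrence-free-survival outcome.

The outcome follows an exponential model with log-linear hazard: the true
log-risk is a linear combination of mean tumor uptake, heterogeneity, and log
lesion volume (optionally age), so downstream stages can be tested against a
known signal. Censoring is independent uniform, with its upper bound
calibrated by Monte Carlo so the expected censored fraction matches
``censor_rate``. Everything is deterministic given ``(spec, seed)``.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .errors import ParameterError
from .imaging import LesionMask, Volume3D, write_volume

CENTERS = tuple(range(1, 10))  # nine contributing centers


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a phantom cohort.

    Effects are log-hazard coefficients: per SUV unit of mean tumor uptake,
    per SUV unit of heterogeneity (random-field sd), and per log-cm3 of
    lesion volume. ``baseline_scale`` sets the time scale in days.
    """

    n_patients: int = 60
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    ct_spacing: float = 2.0
    pet_spacing: float = 4.0
    tumor_radius_range: tuple[float, float] = (6.0, 12.0)
    node_count_range: tuple[int, int] = (0, 3)
    node_radius_range: tuple[float, float] = (3.0, 6.0)
    uptake_range: tuple[float, float] = (3.0, 12.0)
    heterogeneity_range: tuple[float, float] = (0.0, 2.0)
    background_blob_count_range: tuple[int, int] = (2, 4)
    background_blob_uptake_range: tuple[float, float] = (2.0, 10.0)
    background_blob_radius_range: tuple[float, float] = (4.0, 9.0)
    brain_uptake_range: tuple[float, float] = (10.0, 15.0)
    brain_radius_range: tuple[float, float] = (10.0, 16.0)
    pet_uptake_effect: float = 0.25
    texture_effect: float = 0.5
    volume_effect: float = 0.5
    age_effect: float = 0.0
    baseline_scale: float = 1000.0
    censor_rate: float = 0.3
    noise_sd: float = 0.15
    ct_noise_hu: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ParameterError("censor_rate must be in [0, 1]")
        extent = min(n * self.ct_spacing for n in self.grid_shape)
        if 2 * self.tumor_radius_range[1] * 1.25 > extent:
            raise ParameterError(
                f"largest tumor (diameter ~{2 * self.tumor_radius_range[1]:.0f} mm) "
                f"does not fit the {extent:.0f} mm grid"
            )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.ct_spacing for n in self.grid_shape)  # type: ignore[return-value]

    @property
    def pet_shape(self) -> tuple[int, int, int]:
        return tuple(
            max(1, int(round(e / self.pet_spacing))) for e in self.extent_mm
        )  # type: ignore[return-value]


@dataclass(frozen=True)
class SurvivalOutcome:
    time: float  # days
    event: int  # 1 = recurrence observed, 0 = censored

    def __post_init__(self):
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ParameterError(f"outcome time must be positive and finite, got {self.time}")


@dataclass
class SyntheticPatient:
    patient_id: str
    ct: Volume3D
    pet: Volume3D
    gtvp: LesionMask
    gtvn: list[LesionMask]
    clinical: dict
    outcome: SurvivalOutcome
    truth: dict


def _voxel_centers(shape, spacing):
    axes = [(np.arange(n) + 0.5) * spacing for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(shape, spacing, center, semiaxes) -> np.ndarray:
    xx, yy, zz = _voxel_centers(shape, spacing)
    q = (
        ((xx - center[0]) / semiaxes[0]) ** 2
        + ((yy - center[1]) / semiaxes[1]) ** 2
        + ((zz - center[2]) / semiaxes[2]) ** 2
    )
    return q <= 1.0


def _reference_log_risk(spec: CohortSpec) -> float:
    """Population-centre log-risk, so event times stay near baseline_scale."""
    r_mid = 0.5 * (spec.tumor_radius_range[0] + spec.tumor_radius_range[1])
    vol_ref = 4.0 / 3.0 * math.pi * r_mid**3 / 1000.0  # cm3
    return (
        spec.pet_uptake_effect * 0.5 * sum(spec.uptake_range)
        + spec.texture_effect * 0.5 * sum(spec.heterogeneity_range)
        + spec.volume_effect * math.log(vol_ref)
    )


@functools.lru_cache(maxsize=32)
def _censoring_bound(spec: CohortSpec) -> float:
    """Upper bound of the uniform censoring law matching the target rate.

    For T ~ Exp(scale s) and C ~ U(0, c), P(censored) = (s/c)(1 - exp(-c/s)).
    The bound is solved against a 20k-draw Monte Carlo sample of the
    population of per-patient scales (deterministic given the spec).
    """
    if spec.censor_rate <= 0:
        return math.inf
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 987654321)))
    m = 20_000
    uptake = rng.uniform(*spec.uptake_range, m)
    het = rng.uniform(*spec.heterogeneity_range, m)
    r = rng.uniform(*spec.tumor_radius_range, m)
    vol = 4.0 / 3.0 * math.pi * r**3 / 1000.0
    eta = (
        spec.pet_uptake_effect * uptake
        + spec.texture_effect * het
        + spec.volume_effect * np.log(vol)
    )
    scales = spec.baseline_scale * np.exp(-(eta - _reference_log_risk(spec)))

    def censored_frac(c: float) -> float:
        x = c / scales
        return float(np.mean(np.where(x > 1e-12, (1.0 - np.exp(-x)) / x, 1.0)))

    lo, hi = 1e-6 * spec.baseline_scale, 1e6 * spec.baseline_scale
    return float(brentq(lambda c: censored_frac(c) - spec.censor_rate, lo, hi, xtol=1e-6))


def simulate_outcome(truth: dict, spec: CohortSpec, rng: np.random.Generator) -> SurvivalOutcome:
    """Exponential event time with log-linear hazard, plus uniform censoring."""
    eta = truth["eta"]
    scale = spec.baseline_scale * math.exp(-(eta - _reference_log_risk(spec)))
    t_event = float(rng.exponential(scale))
    if spec.censor_rate <= 0:
        return SurvivalOutcome(max(t_event, 1e-3), 1)
    c = float(rng.uniform(0.0, _censoring_bound(spec)))
    if c < t_event:
        return SurvivalOutcome(max(c, 1e-3), 0)
    return SurvivalOutcome(max(t_event, 1e-3), 1)


def _place_nodes(rng, spec, center, tumor_r):
    """Spherical nodal lesions around the primary, kept inside the grid."""
    n_nodes = int(rng.integers(spec.node_count_range[0], spec.node_count_range[1] + 1))
    extent = np.asarray(spec.extent_mm)
    nodes = []
    for _ in range(n_nodes):
        node_r = float(rng.uniform(*spec.node_radius_range))
        for _attempt in range(50):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = tumor_r + node_r + float(rng.uniform(2.0, 6.0))
            pos = np.asarray(center) + dist * direction
            if np.all(pos - node_r >= 0.5) and np.all(pos + node_r <= extent - 0.5):
                nodes.append((tuple(pos), node_r))
                break
    return nodes


def _place_background_blobs(rng, spec, center, tumor_r, nodes):
    """Physiological uptake regions (salivary glands and the like).

    Their uptake is drawn independently of the outcome, so they are pure
    distractors: tissue near the tumor that carries no prognostic signal.
    """
    n_blobs = int(
        rng.integers(spec.background_blob_count_range[0],
                     spec.background_blob_count_range[1] + 1)
    )
    extent = np.asarray(spec.extent_mm)
    blobs = []
    for _ in range(n_blobs):
        blob_r = float(rng.uniform(*spec.background_blob_radius_range))
        uptake = float(rng.uniform(*spec.background_blob_uptake_range))
        for _attempt in range(40):
            pos = rng.uniform(blob_r, extent - blob_r)
            if np.linalg.norm(pos - center) < tumor_r + blob_r + 3.0:
                continue
            if any(
                np.linalg.norm(pos - np.asarray(npos)) < nr + blob_r + 2.0
                for npos, nr in nodes
            ):
                continue
            blobs.append((tuple(pos), blob_r, uptake))
            break
    return blobs


def _place_brain(rng, spec, center, tumor_r):
    """One dominant physiological uptake region (the brain in H&N FDG-PET).

    Always present, with SUV above most tumors, placed toward the volume
    periphery away from the lesion — the structure that makes max-type
    features saturate once a peritumoral expansion reaches it.
    """
    extent = np.asarray(spec.extent_mm)
    brain_r = float(rng.uniform(*spec.brain_radius_range))
    uptake = float(rng.uniform(*spec.brain_uptake_range))
    for _attempt in range(60):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = float(rng.uniform(0.55, 0.85)) * float(extent.min()) / 2 + tumor_r
        pos = np.asarray(center) + dist * direction
        pos = np.clip(pos, brain_r * 0.6, extent - brain_r * 0.6)
        if np.linalg.norm(pos - center) >= tumor_r + brain_r * 0.7 + 3.0:
            return (tuple(pos), brain_r, uptake)
    return None


def generate_patient(spec: CohortSpec, index: int) -> SyntheticPatient:
    """One deterministic phantom patient (seeded by ``(spec.seed, index)``)."""
    if index >= spec.n_patients:
        raise ParameterError(f"index {index} out of range for n_patients={spec.n_patients}")
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, index)))
    extent = np.asarray(spec.extent_mm)
    ct_spacing = (spec.ct_spacing,) * 3
    pet_spacing = (spec.pet_spacing,) * 3

    # --- geometry -----------------------------------------------------------
    base_r = float(rng.uniform(*spec.tumor_radius_range))
    semiaxes = base_r * rng.uniform(0.85, 1.2, size=3)
    center = extent / 2 + rng.uniform(-0.08, 0.08, size=3) * extent
    nodes = _place_nodes(rng, spec, center, float(semiaxes.max()))
    blobs = _place_background_blobs(rng, spec, center, float(semiaxes.max()), nodes)
    brain = _place_brain(rng, spec, center, float(semiaxes.max()))
    if brain is not None and not any(
        np.linalg.norm(np.asarray(brain[0]) - np.asarray(npos)) < nr + brain[1] * 0.7
        for npos, nr in nodes
    ):
        blobs.append(brain)

    gtvp_arr = _ellipsoid(spec.grid_shape, spec.ct_spacing, center, semiaxes)
    gtvp = LesionMask(gtvp_arr, "GTVp", ct_spacing)
    gtvn = []
    for pos, node_r in nodes:
        arr = _ellipsoid(spec.grid_shape, spec.ct_spacing, pos, (node_r,) * 3)
        arr &= ~gtvp_arr
        if arr.any():
            gtvn.append(LesionMask(arr, "GTVn", ct_spacing))

    # --- PET ----------------------------------------------------------------
    uptake = float(rng.uniform(*spec.uptake_range))
    het = float(rng.uniform(*spec.heterogeneity_range))
    pet_shape = spec.pet_shape
    pet_arr = np.ones(pet_shape)
    field_ = gaussian_filter(rng.normal(size=pet_shape), sigma=0.8)
    tumor_pet = _ellipsoid(pet_shape, spec.pet_spacing, center, semiaxes)
    # normalise the field over tumor voxels so the heterogeneity parameter IS
    # the within-tumor sd and the uptake parameter IS the within-tumor mean
    f_t = field_[tumor_pet]
    if f_t.size >= 2 and f_t.std() > 0:
        field_ = (field_ - f_t.mean()) / f_t.std()
    else:
        field_ = np.zeros(pet_shape)
    pet_arr[tumor_pet] = uptake + het * field_[tumor_pet]
    for pos, node_r in nodes:
        node_pet = _ellipsoid(pet_shape, spec.pet_spacing, pos, (node_r,) * 3)
        pet_arr[node_pet] = 0.6 * uptake + het * field_[node_pet]
    for pos, blob_r, blob_uptake in blobs:
        blob_pet = _ellipsoid(pet_shape, spec.pet_spacing, pos, (blob_r,) * 3)
        pet_arr[blob_pet] = blob_uptake
    pet_arr = pet_arr + rng.normal(0.0, spec.noise_sd, size=pet_shape)
    pet = Volume3D(pet_arr, pet_spacing, modality="PET")

    # --- CT -----------------------------------------------------------------
    ct_arr = np.full(spec.grid_shape, -1000.0)
    body = _ellipsoid(spec.grid_shape, spec.ct_spacing, extent / 2, extent * 0.47)
    ct_arr[body] = 40.0
    ct_arr[gtvp_arr] = 55.0
    for m in gtvn:
        ct_arr[m.data] = 50.0
    for pos, blob_r, _ in blobs:
        blob_ct = _ellipsoid(spec.grid_shape, spec.ct_spacing, pos, (blob_r,) * 3)
        ct_arr[blob_ct & body] = 45.0
    ct_arr = gaussian_filter(ct_arr, sigma=0.8)
    ct_arr += rng.normal(0.0, spec.ct_noise_hu, size=spec.grid_shape)
    ct = Volume3D(ct_arr, ct_spacing, modality="CT")

    # --- clinical record ----------------------------------------------------
    age = float(rng.normal(60.0, 9.0))
    clinical = dict(
        patient_id=f"P{index:03d}",
        center=int(rng.choice(CENTERS)),
        age=round(age, 1),
        gender=str(rng.choice(["M", "F"], p=[0.75, 0.25])),
        weight=round(float(rng.normal(75.0, 12.0)), 1) if rng.random() > 0.05 else np.nan,
        tobacco=str(rng.choice(["yes", "no", "missing"], p=[0.35, 0.45, 0.2])),
        alcohol=str(rng.choice(["yes", "no", "missing"], p=[0.35, 0.45, 0.2])),
        performance_status=int(rng.integers(0, 3)),
        hpv_status=str(rng.choice(["positive", "negative", "missing"], p=[0.5, 0.3, 0.2])),
        treatment=str(rng.choice(["radiotherapy", "chemoradiotherapy"], p=[0.3, 0.7])),
    )

    # --- truth and outcome --------------------------------------------------
    voxel_cm3 = spec.ct_spacing**3 / 1000.0
    lesion_voxels = gtvp.voxel_count + sum(m.voxel_count for m in gtvn)
    volume_cm3 = lesion_voxels * voxel_cm3
    eta = (
        spec.pet_uptake_effect * uptake
        + spec.texture_effect * het
        + spec.volume_effect * math.log(volume_cm3)
        + spec.age_effect * (age - 60.0) / 10.0
    )
    truth = dict(
        uptake=uptake,
        heterogeneity=het,
        volume_cm3=volume_cm3,
        eta=eta,
        tumor_center=tuple(np.round(center, 4)),
        tumor_semiaxes=tuple(np.round(semiaxes, 4)),
        n_nodes=len(gtvn),
    )
    outcome = simulate_outcome(truth, spec, rng)
    clinical["rfs_days"] = round(outcome.time, 2)
    clinical["event"] = outcome.event
    return SyntheticPatient(clinical["patient_id"], ct, pet, gtvp, gtvn, clinical, outcome, truth)


def generate_cohort(
    spec: CohortSpec, out_dir: Optional[str | Path] = None
) -> list[SyntheticPatient]:
    """Generate all patients; optionally write the pipeline's input layout.

    Layout: ``images/{pid}__CT.nii.gz``, ``images/{pid}__PT.nii.gz``,
    ``masks/{pid}__GTVp.nii.gz``, ``masks/{pid}__GTVn{i}.nii.gz``,
    ``clinical.csv`` and a ``truth.csv`` manifest for recovery tests.
    """
    patients = [generate_patient(spec, i) for i in range(spec.n_patients)]
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        for p in patients:
            write_volume(p.ct, out / "images" / f"{p.patient_id}__CT.nii.gz")
            write_volume(p.pet, out / "images" / f"{p.patient_id}__PT.nii.gz")
            write_volume(p.gtvp, out / "masks" / f"{p.patient_id}__GTVp.nii.gz")
            for i, m in enumerate(p.gtvn):
                write_volume(m, out / "masks" / f"{p.patient_id}__GTVn{i}.nii.gz")
        pd.DataFrame([p.clinical for p in patients]).to_csv(out / "clinical.csv", index=False)
        truth_rows = [
            {"patient_id": p.patient_id, **{k: v for k, v in p.truth.items()}}
            for p in patients
        ]
        pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    return patients


def outcome_arrays(patients: list[SyntheticPatient]) -> np.ndarray:
    """(n, 2) array of [time, event] rows, the package's survival-label format."""
    return np.array([[p.outcome.time, p.outcome.event] for p in patients], dtype=float)
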