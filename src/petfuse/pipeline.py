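"""End-to-end experiment arms: sweeps, comparisons and risk stratification.

Every arm follows the same recipe: build a patients-by-features table for the
arm's modality/fusion/lesion/radius setting, z-score it, obtain out-of-fold
predictions from the stacked ensemble, and summarise them as one metric row
(RMSLE, MAPE, Pearson r and p, C-index). All randomness flows from the single
experiment seed, and the same seed drives the fold split of every arm, so
arms that receive identical tables produce identical rows.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .evaluation import evaluate_arm, km_estimate, log_rank
from .features import (
    RadiomicsConfig,
    SCHEMA_VERSION,
    extract_all,
    peritumoral_mask,
)
from .fusion import (
    DEFAULT_WP_GRID,
    FusionConfig,
    assemble_combination,
    fuse_features,
    fuse_images,
    zscore_table,
)
from .imaging import LesionMask, read_mask, read_volume, resample_to_grid
from .survival import ModelConfig, cross_validated_predictions, stratify_risk, pack_outcome
from .synthetic import CohortSpec, SyntheticPatient, generate_cohort

logger = logging.getLogger(__name__)

ARMS = (
    "modality_sweep",
    "combination_sweep",
    "lesion_comparison",
    "radius_sweep",
    "feature_set_comparison",
    "km_stratification",
)

KM_ARMS = ("image_fusion", "feature_fusion", "CT", "PET", "clinical", "combined")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment run needs, seeded and hashable."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: Optional[str] = None  # load a cohort from disk instead of synthesising
    arms: tuple[str, ...] = ARMS
    wp_grid: tuple[float, ...] = DEFAULT_WP_GRID
    wp: float = 0.9  # weight for single-wp arms (combination, lesion, radius, KM)
    fusion_level: str = "feature"
    radius_grid: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                                      60.0, 70.0, 80.0, 90.0, 100.0)
    radius_mode: str = "inclusive"
    radius_source: str = "WF"  # which table the radius sweep models: CT, PET or WF
    lesion_set: str = "combined"
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ParameterError(f"unknown arms: {sorted(unknown)}")
        if not self.arms:
            raise ParameterError("at least one arm is required")
        if not self.wp_grid or not self.radius_grid:
            raise ParameterError("wp and radius grids must be nonempty")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]

    def seeded(self) -> "ExperimentConfig":
        """Propagate the experiment seed into cohort and model sub-configs."""
        return replace(
            self,
            cohort=replace(self.cohort, seed=self.seed),
            model=replace(self.model, seed=self.seed),
        )


# ---------------------------------------------------------------------------
# cohort loading and table building
# ---------------------------------------------------------------------------

def load_cohort_from_dir(path: str | Path) -> list[SyntheticPatient]:
    """Read the NIfTI + clinical CSV layout written by ``generate_cohort``."""
    from .synthetic import SurvivalOutcome

    path = Path(path)
    clinical = pd.read_csv(path / "clinical.csv")
    patients = []
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        ct = read_volume(path / "images" / f"{pid}__CT.nii.gz", "CT")
        pet = read_volume(path / "images" / f"{pid}__PT.nii.gz", "PET")
        gtvp = read_mask(path / "masks" / f"{pid}__GTVp.nii.gz", "GTVp")
        gtvn = []
        i = 0
        while (path / "masks" / f"{pid}__GTVn{i}.nii.gz").exists():
            gtvn.append(read_mask(path / "masks" / f"{pid}__GTVn{i}.nii.gz", "GTVn"))
            i += 1
        outcome = SurvivalOutcome(float(row["rfs_days"]), int(row["event"]))
        patients.append(
            SyntheticPatient(pid, ct, pet, gtvp, gtvn, row.to_dict(), outcome, {})
        )
    return patients


def get_cohort(cfg: ExperimentConfig) -> list[SyntheticPatient]:
    if cfg.input_dir is not None:
        return load_cohort_from_dir(cfg.input_dir)
    return generate_cohort(cfg.cohort)


def lesion_mask_for(p: SyntheticPatient, lesion_set: str) -> Optional[LesionMask]:
    """GTVp, union of nodal lesions, or the union of everything."""
    if lesion_set == "GTVp":
        return p.gtvp
    if lesion_set == "GTVn":
        if not p.gtvn:
            return None  # missing-lesion marker: patient has no nodal disease
        mask = p.gtvn[0]
        for m in p.gtvn[1:]:
            mask = mask.union(m, "GTVn")
        return LesionMask(mask.data, "GTVn", mask.spacing, mask.origin)
    if lesion_set == "combined":
        mask = p.gtvp
        for m in p.gtvn:
            mask = mask.union(m, "COMBINED")
        return LesionMask(mask.data, "COMBINED", mask.spacing, mask.origin)
    raise ParameterError(f"unknown lesion set {lesion_set!r}")


def _prepared_mask(p, lesion_set, radius, radius_mode):
    mask = lesion_mask_for(p, lesion_set)
    if mask is None:
        return None
    if radius > 0:
        mask = peritumoral_mask(mask, radius, radius_mode)
    return mask


def extract_modality_tables(
    patients: Sequence[SyntheticPatient],
    lesion_set: str = "combined",
    radius: float = 0.0,
    radius_mode: str = "inclusive",
    radiomics_cfg: Optional[RadiomicsConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-modality feature tables (CT, PET-on-CT-grid) over the same mask."""
    cfg = radiomics_cfg or RadiomicsConfig()
    rows_ct, rows_pet, ids = [], [], []
    for p in patients:
        mask = _prepared_mask(p, lesion_set, radius, radius_mode)
        if mask is None:
            logger.info("patient %s lacks lesion set %s; skipped", p.patient_id, lesion_set)
            continue
        pet_ct = resample_to_grid(p.pet, p.ct)
        rows_ct.append(extract_all(p.ct, mask, cfg))
        rows_pet.append(extract_all(pet_ct, mask, cfg))
        ids.append(p.patient_id)
    if not ids:
        raise DegenerateInputError(f"no patient carries lesion set {lesion_set!r}")
    f_ct = pd.DataFrame(rows_ct, index=pd.Index(ids, name="patient_id"))
    f_pet = pd.DataFrame(rows_pet, index=pd.Index(ids, name="patient_id"))
    f_ct.attrs = {"modality": "CT", "lesion": lesion_set, "radius_mm": radius}
    f_pet.attrs = {"modality": "PET", "lesion": lesion_set, "radius_mm": radius}
    return f_ct, f_pet


def extract_single_modality_table(
    patients: Sequence[SyntheticPatient],
    modality: str,
    lesion_set: str = "combined",
    radius: float = 0.0,
    radius_mode: str = "inclusive",
    radiomics_cfg: Optional[RadiomicsConfig] = None,
) -> pd.DataFrame:
    """Feature table for one modality only (PET is resampled onto the CT grid)."""
    if modality not in ("CT", "PET"):
        raise ParameterError(f"modality must be 'CT' or 'PET', got {modality!r}")
    cfg = radiomics_cfg or RadiomicsConfig()
    rows, ids = [], []
    for p in patients:
        mask = _prepared_mask(p, lesion_set, radius, radius_mode)
        if mask is None:
            continue
        vol = p.ct if modality == "CT" else resample_to_grid(p.pet, p.ct)
        rows.append(extract_all(vol, mask, cfg))
        ids.append(p.patient_id)
    if not ids:
        raise DegenerateInputError(f"no patient carries lesion set {lesion_set!r}")
    out = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"))
    out.attrs = {"modality": modality, "lesion": lesion_set, "radius_mm": radius}
    return out


def extract_image_fusion_table(
    patients: Sequence[SyntheticPatient],
    wp: float,
    lesion_set: str = "combined",
    radius: float = 0.0,
    radius_mode: str = "inclusive",
    radiomics_cfg: Optional[RadiomicsConfig] = None,
) -> pd.DataFrame:
    """Features extracted from the voxelwise-fused volume at PET weight wp."""
    cfg = radiomics_cfg or RadiomicsConfig()
    fusion_cfg = FusionConfig(wp=wp, level="image")
    rows, ids = [], []
    for p in patients:
        mask = _prepared_mask(p, lesion_set, radius, radius_mode)
        if mask is None:
            continue
        pet_ct = resample_to_grid(p.pet, p.ct)
        fused = fuse_images(p.ct, pet_ct, fusion_cfg)
        rows.append(extract_all(fused, mask, cfg))
        ids.append(p.patient_id)
    if not ids:
        raise DegenerateInputError(f"no patient carries lesion set {lesion_set!r}")
    out = pd.DataFrame(rows, index=pd.Index(ids, name="patient_id"))
    out.attrs = {"modality": "FUSED", "wp": wp, "level": "image",
                 "lesion": lesion_set, "radius_mm": radius}
    return out


def clinical_feature_table(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    """Clinical covariates as model features.

    Categoricals are one-hot encoded with missing values kept as their own
    ``missing`` category; numeric gaps are median-imputed (body weight first
    passes through the 75 kg SUV fallback convention only at SUV time, not
    here — here it is simply a covariate).
    """
    df = pd.DataFrame([p.clinical for p in patients]).set_index("patient_id")
    df = df.drop(columns=[c for c in ("rfs_days", "event") if c in df.columns])
    numeric = [c for c in ("age", "weight", "performance_status") if c in df.columns]
    categorical = [c for c in df.columns if c not in numeric]
    out = df[numeric].astype(float)
    out = out.fillna(out.median())
    cats = df[categorical].astype(object).where(df[categorical].notna(), "missing")
    dummies = pd.get_dummies(cats.astype(str), prefix_sep="=").astype(float)
    out = pd.concat([out, dummies], axis=1)
    out.attrs = {"modality": "clinical"}
    return out


def outcome_for(patients: Sequence[SyntheticPatient], index: pd.Index) -> np.ndarray:
    by_id = {p.patient_id: p.outcome for p in patients}
    return pack_outcome(
        [by_id[i].time for i in index], [by_id[i].event for i in index]
    )


def fill_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Median-impute non-finite feature values (e.g. undefined correlation)."""
    arr = table.to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        med = np.nanmedian(np.where(np.isfinite(arr), arr, np.nan), axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        arr = np.where(bad, med[None, :], arr)
    out = pd.DataFrame(arr, index=table.index, columns=table.columns)
    out.attrs = dict(table.attrs)
    return out


# ---------------------------------------------------------------------------
# arm evaluation
# ---------------------------------------------------------------------------

def evaluate_table_arm(
    name: str,
    table: pd.DataFrame,
    patients: Sequence[SyntheticPatient],
    model_cfg: ModelConfig,
) -> dict:
    """One metric row: z-score -> out-of-fold predictions -> metric suite."""
    table = zscore_table(fill_missing(table))
    y = outcome_for(patients, table.index)
    preds = cross_validated_predictions(table, y, model_cfg)
    rep = evaluate_arm(preds["predicted_time"], preds["risk_score"], y[:, 0], y[:, 1])
    return {"arm": name, **rep.as_dict()}


def arm_predictions(
    table: pd.DataFrame, patients: Sequence[SyntheticPatient], model_cfg: ModelConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    table = zscore_table(fill_missing(table))
    y = outcome_for(patients, table.index)
    return cross_validated_predictions(table, y, model_cfg), y


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def run_modality_sweep(cfg: ExperimentConfig, patients=None, tables=None) -> pd.DataFrame:
    """CT, PET, and weighted fusion at every wp in the grid."""
    cfg = cfg.seeded()
    patients = patients if patients is not None else get_cohort(cfg)
    if tables is None:
        f_ct, f_pet = extract_modality_tables(
            patients, cfg.lesion_set, radiomics_cfg=cfg.radiomics
        )
    else:
        f_ct, f_pet = tables
    rows = [
        evaluate_table_arm("CT", f_ct, patients, cfg.model),
        evaluate_table_arm("PET", f_pet, patients, cfg.model),
    ]
    for wp in cfg.wp_grid:
        if cfg.fusion_level == "feature":
            fused = fuse_features(f_ct, f_pet, FusionConfig(wp=wp, level="feature"))
        else:
            fused = extract_image_fusion_table(
                patients, wp, cfg.lesion_set, radiomics_cfg=cfg.radiomics
            )
        rows.append(
            evaluate_table_arm(f"WF(wp={wp:g})", fused, patients, cfg.model)
        )
    return pd.DataFrame(rows)


def run_combination_sweep(cfg: ExperimentConfig, patients=None, tables=None) -> pd.DataFrame:
    """The seven combination arms: CT, PET, WF, CT_PET, CT_WF, PET_WF, CT_PET_WF."""
    cfg = cfg.seeded()
    patients = patients if patients is not None else get_cohort(cfg)
    if tables is None:
        f_ct, f_pet = extract_modality_tables(
            patients, cfg.lesion_set, radiomics_cfg=cfg.radiomics
        )
    else:
        f_ct, f_pet = tables
    wf = fuse_features(f_ct, f_pet, FusionConfig(wp=cfg.wp, level="feature"))
    named = {"CT": zscore_table(fill_missing(f_ct)),
             "PET": zscore_table(fill_missing(f_pet)),
             "WF": zscore_table(fill_missing(wf))}
    combos = {
        "CT": ["CT"],
        "PET": ["PET"],
        f"WF(wp={cfg.wp:g})": ["WF"],
        "CT_PET": ["CT", "PET"],
        f"CT_WF(wp={cfg.wp:g})": ["CT", "WF"],
        f"PET_WF(wp={cfg.wp:g})": ["PET", "WF"],
        f"CT_PET_WF(wp={cfg.wp:g})": ["CT", "PET", "WF"],
    }
    rows = []
    for name, combo in combos.items():
        table = assemble_combination(named, combo)
        rows.append(evaluate_table_arm(name, table, patients, cfg.model))
    return pd.DataFrame(rows)


def run_lesion_comparison(cfg: ExperimentConfig, patients=None) -> pd.DataFrame:
    """Primary tumor vs nodal lesions vs their union, at the configured fusion."""
    cfg = cfg.seeded()
    patients = patients if patients is not None else get_cohort(cfg)
    rows = []
    for lesion in ("GTVp", "GTVn", "combined"):
        try:
            f_ct, f_pet = extract_modality_tables(
                patients, lesion, radiomics_cfg=cfg.radiomics
            )
        except DegenerateInputError:
            rows.append({"arm": lesion, "note": "no patient carries this lesion set"})
            continue
        fused = fuse_features(f_ct, f_pet, FusionConfig(wp=cfg.wp, level="feature"))
        rows.append(evaluate_table_arm(lesion, fused, patients, cfg.model))
    return pd.DataFrame(rows)


def _radius_table(cfg, patients, r):
    if cfg.radius_source in ("CT", "PET"):
        return extract_single_modality_table(
            patients, cfg.radius_source, cfg.lesion_set, radius=r,
            radius_mode=cfg.radius_mode, radiomics_cfg=cfg.radiomics,
        )
    f_ct, f_pet = extract_modality_tables(
        patients, cfg.lesion_set, radius=r, radius_mode=cfg.radius_mode,
        radiomics_cfg=cfg.radiomics,
    )
    return fuse_features(f_ct, f_pet, FusionConfig(wp=cfg.wp, level="feature"))


def run_radius_sweep(cfg: ExperimentConfig, patients=None) -> pd.DataFrame:
    """Peritumoral context: one row per dilation radius (mm)."""
    cfg = cfg.seeded()
    patients = patients if patients is not None else get_cohort(cfg)
    rows = []
    for r in cfg.radius_grid:
        table = _radius_table(cfg, patients, float(r))
        row = evaluate_table_arm(f"r={r:g}", table, patients, cfg.model)
        row["radius_mm"] = float(r)
        rows.append(row)
    return pd.DataFrame(rows)


def run_feature_set_comparison(cfg: ExperimentConfig, patients=None, tables=None) -> pd.DataFrame:
    """Clinical-only vs radiomics-only vs their concatenation."""
    cfg = cfg.seeded()
    patients = patients if patients is not None else get_cohort(cfg)
    if tables is None:
        f_ct, f_pet = extract_modality_tables(
            patients, cfg.lesion_set, radiomics_cfg=cfg.radiomics
        )
    else:
        f_ct, f_pet = tables
    radiomics = fuse_features(f_ct, f_pet, FusionConfig(wp=cfg.wp, level="feature"))
    clinical = clinical_feature_table(patients).loc[radiomics.index]
    named = {
        "clinical": zscore_table(fill_missing(clinical)),
        "radiomics": zscore_table(fill_missing(radiomics)),
    }
    rows = [
        evaluate_table_arm("clinical", named["clinical"], patients, cfg.model),
        evaluate_table_arm("radiomics", named["radiomics"], patients, cfg.model),
        evaluate_table_arm(
            "combined", assemble_combination(named, ["clinical", "radiomics"]),
            patients, cfg.model,
        ),
    ]
    return pd.DataFrame(rows)


def run_km_stratification(cfg: ExperimentConfig, patients=None) -> dict:
    """Median-split risk groups, KM curves and the log-rank p for six arms."""
    cfg = cfg.seeded()
    patients = patients if patients is not None else get_cohort(cfg)
    f_ct, f_pet = extract_modality_tables(patients, cfg.lesion_set,
                                          radiomics_cfg=cfg.radiomics)
    feature_fused = fuse_features(f_ct, f_pet, FusionConfig(wp=cfg.wp, level="feature"))
    clinical = clinical_feature_table(patients).loc[feature_fused.index]
    combined = assemble_combination(
        {"clinical": zscore_table(fill_missing(clinical)),
         "radiomics": zscore_table(fill_missing(feature_fused))},
        ["clinical", "radiomics"],
    )
    tables = {
        "image_fusion": extract_image_fusion_table(
            patients, cfg.wp, cfg.lesion_set, radiomics_cfg=cfg.radiomics
        ),
        "feature_fusion": feature_fused,
        "CT": f_ct,
        "PET": f_pet,
        "clinical": clinical,
        "combined": combined,
    }
    results = {}
    for name, table in tables.items():
        preds, y = arm_predictions(table, patients, cfg.model)
        try:
            groups = stratify_risk(preds["risk_score"].to_numpy())
        except DegenerateInputError as exc:
            logger.warning("arm %s skipped: %s", name, exc)
            results[name] = {"skipped": str(exc)}
            continue
        low = groups == "low"
        curves = {
            "low": km_estimate(y[low, 0], y[low, 1], group="low"),
            "high": km_estimate(y[~low, 0], y[~low, 1], group="high"),
        }
        chi2, p = log_rank(y[low, 0], y[low, 1], y[~low, 0], y[~low, 1])
        results[name] = {"curves": curves, "chi2": chi2, "p": p,
                         "groups": groups, "y": y}
    return results


def _km_to_frame(results: dict) -> pd.DataFrame:
    rows = []
    for arm, res in results.items():
        if "curves" not in res:
            continue
        for gname, curve in res["curves"].items():
            for t, s, nr in zip(curve.times, curve.survival, curve.at_risk):
                rows.append({"arm": arm, "group": gname, "time": t,
                             "survival": s, "at_risk": nr, "logrank_p": res["p"]})
    return pd.DataFrame(rows)


def plot_km(results: dict, path: str | Path) -> None:
    """Panelled KM plot for the stratification arms (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arms = [a for a in results if "curves" in results[a]]
    fig, axes = plt.subplots(2, max(1, (len(arms) + 1) // 2),
                             figsize=(4 * max(1, (len(arms) + 1) // 2), 7))
    axes = np.atleast_1d(axes).ravel()
    for ax, arm in zip(axes, arms):
        res = results[arm]
        for gname, color in (("low", "tab:blue"), ("high", "tab:red")):
            c = res["curves"][gname]
            ax.step(c.times, c.survival, where="post", color=color, label=gname)
        ax.set_title(f"{arm} (log-rank p={res['p']:.3f})", fontsize=9)
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("days")
        ax.set_ylabel("RFS probability")
        ax.legend(fontsize=8)
    for ax in axes[len(arms):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all(cfg: ExperimentConfig, out_dir: Optional[str | Path] = None) -> dict:
    """Run every configured arm; optionally write one CSV per table analogue."""
    cfg = cfg.seeded()
    patients = get_cohort(cfg)
    shared = extract_modality_tables(patients, cfg.lesion_set, radiomics_cfg=cfg.radiomics)
    results: dict = {}
    if "modality_sweep" in cfg.arms:
        results["modality_sweep"] = run_modality_sweep(cfg, patients, shared)
    if "combination_sweep" in cfg.arms:
        results["combination_sweep"] = run_combination_sweep(cfg, patients, shared)
    if "lesion_comparison" in cfg.arms:
        results["lesion_comparison"] = run_lesion_comparison(cfg, patients)
    if "radius_sweep" in cfg.arms:
        results["radius_sweep"] = run_radius_sweep(cfg, patients)
    if "feature_set_comparison" in cfg.arms:
        results["feature_set_comparison"] = run_feature_set_comparison(cfg, patients, shared)
    if "km_stratification" in cfg.arms:
        results["km_stratification"] = run_km_stratification(cfg, patients)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = (
            f"# config_hash: {cfg.config_hash()}\n"
            f"# seed: {cfg.seed}\n"
            f"# schema_version: {SCHEMA_VERSION}\n"
        )
        for name, res in results.items():
            if name == "km_stratification":
                frame = _km_to_frame(res)
                with open(out / "km_curves.csv", "w") as fh:
                    fh.write(header)
                    frame.to_csv(fh, index=False)
                plot_km(res, out / "km_curves.png")
            else:
                with open(out / f"{name}.csv", "w") as fh:
                    fh.write(header)
                    res.to_csv(fh, index=False)
        manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                    "schema_version": SCHEMA_VERSION, "arms": list(results)}
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        from .features import feature_schema_manifest

        (out / "feature_schema.txt").write_text(feature_schema_manifest())
    return results
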