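"""Weighted CT/PET fusion at the image level and at the feature level.

Both levels realise the same convex combination with PET weight ``wp``:

* image level:   ``F = (1 - wp) * CT' + wp * PET'`` voxelwise, on a common grid;
* feature level: ``g_k = (1 - wp) * z(ct_k) + wp * z(pet_k)`` per paired feature.

``'`` / ``z`` denote per-volume / per-feature z-score standardization, applied
by default: HU and SUV live on incommensurate scales, and without it CT would
dominate numerically at every weight. The two levels are distinct experimental
arms — features extracted from a fused image are not expected to equal fused
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, NamingError, ParameterError
from .imaging import Volume3D, zscore_normalize

logger = logging.getLogger(__name__)

#: PET weights swept in the modality experiments.
DEFAULT_WP_GRID: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class FusionConfig:
    """PET weight and fusion level."""

    wp: float = 0.9
    level: str = "feature"
    standardize_before: bool = True

    def __post_init__(self):
        if not 0.0 <= self.wp <= 1.0:
            raise ParameterError(f"wp must be in [0, 1], got {self.wp}")
        if self.level not in ("image", "feature"):
            raise ParameterError(f"level must be 'image' or 'feature', got {self.level!r}")


def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature population z-score across patients; constant columns map to 0."""
    arr = table.to_numpy(dtype=float)
    mu = arr.mean(axis=0)
    sd = arr.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (arr - mu) / sd_safe
    z[:, sd == 0] = 0.0
    out = pd.DataFrame(z, index=table.index, columns=table.columns)
    out.attrs = dict(table.attrs)
    return out


def fuse_images(ct: Volume3D, pet: Volume3D, cfg: FusionConfig) -> Volume3D:
    """Voxelwise convex combination of CT and PET on a shared grid."""
    if cfg.level != "image":
        raise ParameterError("fuse_images requires cfg.level == 'image'")
    if not ct.same_grid(pet):
        raise AlignmentError(
            "CT and PET must share shape/spacing/origin; resample PET onto the CT grid first"
        )
    a = zscore_normalize(ct) if cfg.standardize_before else ct
    b = zscore_normalize(pet) if cfg.standardize_before else pet
    fused = (1.0 - cfg.wp) * a.data + cfg.wp * b.data
    return Volume3D(fused, ct.spacing, ct.origin, "FUSED")


def fuse_features(f_ct: pd.DataFrame, f_pet: pd.DataFrame, cfg: FusionConfig) -> pd.DataFrame:
    """Per-feature convex combination of paired CT and PET feature tables.

    Features are paired by name (same extractor run per modality); unpaired
    features are dropped with a warning. Patients must overlap; the fused
    table covers the common patient set.
    """
    if cfg.level != "feature":
        raise ParameterError("fuse_features requires cfg.level == 'feature'")
    patients = f_ct.index.intersection(f_pet.index)
    if len(patients) == 0:
        raise AlignmentError("CT and PET feature tables have disjoint patient sets")
    shared = [c for c in f_ct.columns if c in set(f_pet.columns)]
    dropped = (set(f_ct.columns) | set(f_pet.columns)) - set(shared)
    if dropped:
        logger.warning("dropping %d unpaired features: %s", len(dropped), sorted(dropped)[:5])
    if not shared:
        raise AlignmentError("no paired feature names between CT and PET tables")
    a = f_ct.loc[patients, shared]
    b = f_pet.loc[patients, shared]
    if cfg.standardize_before:
        a = zscore_table(a)
        b = zscore_table(b)
    fused = (1.0 - cfg.wp) * a + cfg.wp * b
    fused.attrs = {
        "wp": cfg.wp,
        "level": "feature",
        "sources": ("CT", "PET"),
        "standardize_before": cfg.standardize_before,
    }
    return fused


def assemble_combination(tables: dict[str, pd.DataFrame], combo: list[str]) -> pd.DataFrame:
    """Column-wise concatenation of named tables with source-prefixed feature names.

    Supports the combination arms CT, PET, WF, CT_PET, CT_WF, PET_WF, CT_PET_WF.
    """
    missing = [name for name in combo if name not in tables]
    if missing:
        raise ParameterError(f"unknown table names in combo: {missing}")
    if not combo:
        raise ParameterError("combo must name at least one table")
    patients = tables[combo[0]].index
    for name in combo[1:]:
        if not tables[name].index.equals(patients):
            raise AlignmentError(f"table {name!r} has a different patient set")
    parts = []
    for name in combo:
        t = tables[name].copy()
        t.columns = [f"{name}__{c}" for c in t.columns]
        parts.append(t)
    out = pd.concat(parts, axis=1)
    if out.columns.duplicated().any():
        dup = out.columns[out.columns.duplicated()].tolist()
        raise NamingError(f"duplicate prefixed feature names: {dup[:5]}")
    out.attrs = {"sources": tuple(combo)}
    return out


def write_table(table: pd.DataFrame, path, **provenance) -> None:
    """Write a feature table as CSV with a ``#``-prefixed provenance header."""
    meta = {**table.attrs, **provenance}
    with open(path, "w") as fh:
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        table.to_csv(fh, index_label="patient_id")


def read_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_table`."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, index_col="patient_id")
    table.attrs = meta
    return table
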