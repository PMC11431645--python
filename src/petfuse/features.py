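"""Radiomic feature extraction: first-order, shape, and gray-level texture matrices.

The extractor computes, inside a (possibly peritumorally dilated) lesion mask:

* first-order intensity statistics on the raw voxel values,
* shape descriptors of the binary mask on its physical grid,
* texture features from four gray-level matrices computed on a discretized
  copy of the in-mask intensities: co-occurrence (GLCM), run length (GLRLM),
  size zone (GLSZM) and dependence (GLDM).

Texture conventions: 13 unique 3D direction offsets (symmetric co-occurrence
accumulation), per-direction feature computation averaged over directions,
26-connectivity for zones and dependence neighbourhoods. Discretization
defaults to a fixed bin count of 32 equal-width bins over the in-mask range,
which keeps small lesions from producing empty bins; both fixed-bin-count and
fixed-bin-width modes are available.
"""

from __future__ import annotations

import math
import warnings
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .errors import AlignmentError, DegenerateInputError, ParameterError
from .imaging import LesionMask, Volume3D, bounding_box_of

SCHEMA_VERSION = "1"

def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                d = (a, b, c)
                if d == (0, 0, 0):
                    continue
                if tuple(-x for x in d) in dirs:
                    continue
                dirs.append(d)
    return tuple(dirs)


#: The 13 unique (up to sign) 3D neighbour offsets at Chebyshev distance 1.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = _unique_directions()
assert len(DIRECTIONS_13) == 13

ALL_26_OFFSETS: tuple[tuple[int, int, int], ...] = DIRECTIONS_13 + tuple(
    tuple(-x for x in d) for d in DIRECTIONS_13
)


@dataclass(frozen=True)
class DiscretizationConfig:
    """Gray-level discretization for the texture matrices."""

    mode: str = "fixed_bin_count"
    n_bins: int = 32
    bin_width: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ParameterError(f"unknown discretization mode {self.mode!r}")
        if self.mode == "fixed_bin_count" and self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")
        if self.mode == "fixed_bin_width" and (self.bin_width is None or self.bin_width <= 0):
            raise ParameterError("bin_width must be > 0 in fixed_bin_width mode")


@dataclass(frozen=True)
class RadiomicsConfig:
    """Configuration for the full extractor."""

    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    glcm_distances: tuple[int, ...] = (1,)
    glcm_symmetric: bool = True
    gldm_alpha: int = 0


def _in_mask_values(v: Volume3D, mask: LesionMask) -> np.ndarray:
    if v.data.shape != mask.data.shape:
        raise AlignmentError(
            f"mask shape {mask.data.shape} does not match volume shape {v.data.shape}"
        )
    values = v.data[mask.data]
    if values.size == 0:
        raise DegenerateInputError("mask is empty")
    return values


def discretize(
    v: Volume3D, mask: LesionMask, cfg: Optional[DiscretizationConfig] = None
) -> tuple[np.ndarray, int]:
    """Map in-mask intensities to integer gray levels ``1..Ng`` (0 outside).

    ``fixed_bin_count`` uses equal-width bins over the in-mask [min, max];
    ``fixed_bin_width`` anchors bins at the in-mask minimum.
    """
    cfg = cfg or DiscretizationConfig()
    values = _in_mask_values(v, mask)
    lo = float(values.min())
    hi = float(values.max())
    levels = np.zeros(v.data.shape, dtype=np.int32)
    if hi == lo:
        levels[mask.data] = 1
        return levels, 1
    if cfg.mode == "fixed_bin_count":
        n = cfg.n_bins
        lv = np.floor((values - lo) / (hi - lo) * n).astype(np.int32) + 1
        lv[lv > n] = n  # the maximum lands exactly on the upper edge
        levels[mask.data] = lv
        return levels, n
    # fixed_bin_width, anchored at the minimum
    w = float(cfg.bin_width)  # type: ignore[arg-type]
    lv = np.floor((values - lo) / w).astype(np.int32) + 1
    levels[mask.data] = lv
    return levels, int(lv.max())


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES = (
    "mean",
    "median",
    "minimum",
    "maximum",
    "range",
    "variance",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "p10",
    "p90",
    "iqr",
    "rmad",
)


def first_order_features(
    v: Volume3D, mask: LesionMask, cfg: Optional[DiscretizationConfig] = None
) -> "OrderedDict[str, float]":
    """Histogram statistics of the in-mask intensities.

    Variance is the population variance; kurtosis is the non-excess (Pearson)
    form; entropy is Shannon entropy (bits) of the discretized gray levels;
    ``rmad`` is the mean absolute deviation of the values inside the
    [10th, 90th] percentile band.
    """
    x = _in_mask_values(v, mask)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    band = x[(x >= p10) & (x <= p90)]
    var = float(x.var())
    if var > 0:
        skew = float(_skew(x, bias=True))
        kurt = float(_kurtosis(x, fisher=False, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    levels, ng = discretize(v, mask, cfg)
    counts = np.bincount(levels[mask.data], minlength=ng + 1)[1:]
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    return OrderedDict(
        mean=float(x.mean()),
        median=float(p50),
        minimum=float(x.min()),
        maximum=float(x.max()),
        range=float(x.max() - x.min()),
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        energy=float((x**2).sum()),
        entropy=entropy,
        p10=float(p10),
        p90=float(p90),
        iqr=float(p75 - p25),
        rmad=float(np.abs(band - band.mean()).mean()) if band.size else 0.0,
    )


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

SHAPE_NAMES = (
    "volume_mm3",
    "surface_mm2",
    "surface_to_volume",
    "sphericity",
    "max_diameter_mm",
    "major_axis_mm",
    "minor_axis_mm",
    "least_axis_mm",
    "elongation",
    "flatness",
    "z_extent_mm",
)


def _surface_area(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Exposed-face surface area: faces between an in-mask voxel and outside."""
    dx, dy, dz = spacing
    face_areas = (dy * dz, dx * dz, dx * dy)
    padded = np.pad(mask, 1)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += np.abs(diff).sum() * fa
    return float(area)


def _max_diameter(coords_mm: np.ndarray) -> float:
    if len(coords_mm) < 2:
        return 0.0
    pts = np.unique(coords_mm, axis=0)
    if len(pts) > 400:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # flat point set; fall through to direct pairwise
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape_features(mask: LesionMask) -> "OrderedDict[str, float]":
    """Geometric descriptors of the binary mask on its physical grid."""
    coords = np.argwhere(mask.data)
    if coords.size == 0:
        raise DegenerateInputError("mask is empty")
    spacing = np.asarray(mask.spacing)
    voxel_volume = float(np.prod(spacing))
    n = len(coords)
    volume = n * voxel_volume
    area = _surface_area(mask.data, mask.spacing)
    sphericity = (math.pi ** (1 / 3)) * (6 * volume) ** (2 / 3) / area

    # surface voxels only, for the maximum 3D diameter
    eroded = ndimage.binary_erosion(mask.data)
    surf = mask.data & ~eroded
    max_diam = _max_diameter(np.argwhere(surf) * spacing)

    centered = coords * spacing - (coords * spacing).mean(axis=0)
    cov = centered.T @ centered / n
    eigs = np.clip(np.linalg.eigvalsh(cov), 0.0, None)  # ascending
    least, minor, major = (4.0 * np.sqrt(eigs)).tolist()
    if eigs[2] > 0:
        elongation = float(np.sqrt(eigs[1] / eigs[2]))
        flatness = float(np.sqrt(eigs[0] / eigs[2]))
    else:
        elongation = flatness = 1.0

    z_extent = float((coords[:, 2].max() - coords[:, 2].min() + 1) * spacing[2])
    return OrderedDict(
        volume_mm3=volume,
        surface_mm2=area,
        surface_to_volume=area / volume,
        sphericity=float(sphericity),
        max_diameter_mm=max_diam,
        major_axis_mm=major,
        minor_axis_mm=minor,
        least_axis_mm=least,
        elongation=elongation,
        flatness=flatness,
        z_extent_mm=z_extent,
    )


# ---------------------------------------------------------------------------
# texture matrices
# ---------------------------------------------------------------------------

def _offset_slices(shape, off):
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_matrices(
    levels: np.ndarray, ng: int, distance: int = 1, symmetric: bool = True
) -> np.ndarray:
    """Co-occurrence count matrices, one ``Ng x Ng`` slab per direction (13, Ng, Ng)."""
    out = np.zeros((len(DIRECTIONS_13), ng, ng), dtype=np.float64)
    for k, d in enumerate(DIRECTIONS_13):
        off = tuple(distance * c for c in d)
        if any(abs(o) >= n for o, n in zip(off, levels.shape)):
            continue
        s_src, s_dst = _offset_slices(levels.shape, off)
        a = levels[s_src].ravel()
        b = levels[s_dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid] - 1) * ng + (b[valid] - 1)
        m = np.bincount(idx, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
        out[k] = m + m.T if symmetric else m
    return out


GLCM_NAMES = (
    "contrast",
    "correlation",
    "joint_energy",
    "joint_entropy",
    "inverse_difference",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
)


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sx = math.sqrt(float(((i - mux) ** 2 * px).sum()))
    sy = math.sqrt(float(((i - muy) ** 2 * py).sum()))
    nz = p[p > 0]
    corr = float(((ii - mux) * (jj - muy) * p).sum() / (sx * sy)) if sx > 0 and sy > 0 else np.nan
    return dict(
        contrast=float(((ii - jj) ** 2 * p).sum()),
        correlation=corr,
        joint_energy=float((p**2).sum()),
        joint_entropy=float(-(nz * np.log2(nz)).sum()),
        inverse_difference=float((p / (1.0 + np.abs(ii - jj))).sum()),
        dissimilarity=float((np.abs(ii - jj) * p).sum()),
        cluster_shade=float(((ii + jj - mux - muy) ** 3 * p).sum()),
        cluster_prominence=float(((ii + jj - mux - muy) ** 4 * p).sum()),
    )


def glcm_features(
    levels: np.ndarray,
    ng: int,
    distances: Sequence[int] = (1,),
    symmetric: bool = True,
) -> "OrderedDict[str, float]":
    """Direction-averaged GLCM features; correlation is NaN when Ng = 1."""
    per_dir: list[dict[str, float]] = []
    for dist in distances:
        mats = glcm_matrices(levels, ng, dist, symmetric)
        for m in mats:
            tot = m.sum()
            if tot == 0:
                continue
            per_dir.append(_glcm_features_one(m / tot))
    if not per_dir:
        raise DegenerateInputError("no valid voxel pairs for GLCM")
    out: "OrderedDict[str, float]" = OrderedDict()
    for name in GLCM_NAMES:
        vals = np.array([f[name] for f in per_dir])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
    return out


def glrlm_matrix_one_direction(levels: np.ndarray, ng: int, direction) -> np.ndarray:
    """Run-length count matrix ``R[g-1, r-1]`` for one direction.

    Run lengths are solved with whole-array shifts by pointer jumping, so the
    loop runs O(log max-run-length) times.
    """
    in_mask = levels > 0
    shape = levels.shape
    same = np.zeros(shape, dtype=bool)
    s_src, s_dst = _offset_slices(shape, direction)
    same[s_src] = in_mask[s_src] & in_mask[s_dst] & (levels[s_src] == levels[s_dst])
    if not in_mask.any():
        return np.zeros((ng, 1), dtype=np.float64)
    # pointer jumping: after m rounds, run_len[v] = min(true length, 2^m) and
    # chain[v] marks runs continuing beyond 2^m steps
    run_len = in_mask.astype(np.int64)
    chain = same.copy()
    step = 1
    while chain.any():
        off = tuple(step * c for c in direction)
        if any(abs(o) >= n for o, n in zip(off, shape)):
            break
        a_src, a_dst = _offset_slices(shape, off)
        r_shift = np.zeros_like(run_len)
        r_shift[a_src] = run_len[a_dst]
        c_shift = np.zeros_like(chain)
        c_shift[a_src] = chain[a_dst]
        run_len = run_len + chain * r_shift
        chain = chain & c_shift
        step *= 2
    prev_same = np.zeros(shape, dtype=bool)
    prev_same[s_dst] = same[s_src]
    starts = in_mask & ~prev_same
    grays = levels[starts]
    lengths = run_len[starts]
    mat = np.zeros((ng, int(lengths.max())), dtype=np.float64)
    np.add.at(mat, (grays - 1, lengths - 1), 1.0)
    return mat


GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_run_emphasis",
    "high_gray_run_emphasis",
)


def _glrlm_features_one(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, nr_max = mat.shape
    g = np.arange(1, ng + 1)[:, None].astype(float)
    r = np.arange(1, nr_max + 1)[None, :].astype(float)
    nr = mat.sum()
    return dict(
        short_run_emphasis=float((mat / r**2).sum() / nr),
        long_run_emphasis=float((mat * r**2).sum() / nr),
        gray_level_nonuniformity=float((mat.sum(axis=1) ** 2).sum() / nr),
        run_length_nonuniformity=float((mat.sum(axis=0) ** 2).sum() / nr),
        run_percentage=float(nr / n_voxels),
        low_gray_run_emphasis=float((mat / g**2).sum() / nr),
        high_gray_run_emphasis=float((mat * g**2).sum() / nr),
    )


def glrlm_features(levels: np.ndarray, ng: int) -> "OrderedDict[str, float]":
    """Run-length features averaged over the 13 directions."""
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise DegenerateInputError("mask is empty")
    feats = [
        _glrlm_features_one(glrlm_matrix_one_direction(levels, ng, d), n_voxels)
        for d in DIRECTIONS_13
    ]
    return OrderedDict(
        (name, float(np.mean([f[name] for f in feats]))) for name in GLRLM_NAMES
    )


def glszm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone count matrix ``Z[g-1, s-1]``; zones are 26-connected components."""
    structure = np.ones((3, 3, 3), dtype=bool)
    zones: list[tuple[int, int]] = []
    coords = np.argwhere(levels > 0)
    if coords.size:
        grays_present = np.unique(levels[levels > 0])
    else:
        grays_present = np.array([], dtype=levels.dtype)
    for g in grays_present:
        where = levels == g
        # label only the bounding box of this gray level
        idx = np.argwhere(where)
        lo = idx.min(axis=0)
        hi = idx.max(axis=0) + 1
        sub = where[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        lab, nlab = ndimage.label(sub, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    if not zones:
        return np.zeros((ng, 1), dtype=np.float64)
    max_size = max(s for _, s in zones)
    mat = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1.0
    return mat


GLSZM_NAMES = (
    "small_area_emphasis",
    "large_area_emphasis",
    "gray_level_nonuniformity",
    "zone_size_nonuniformity",
    "zone_percentage",
)


def glszm_features(levels: np.ndarray, ng: int) -> "OrderedDict[str, float]":
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise DegenerateInputError("mask is empty")
    mat = glszm_matrix(levels, ng)
    nz = mat.sum()
    s = np.arange(1, mat.shape[1] + 1)[None, :].astype(float)
    return OrderedDict(
        small_area_emphasis=float((mat / s**2).sum() / nz),
        large_area_emphasis=float((mat * s**2).sum() / nz),
        gray_level_nonuniformity=float((mat.sum(axis=1) ** 2).sum() / nz),
        zone_size_nonuniformity=float((mat.sum(axis=0) ** 2).sum() / nz),
        zone_percentage=float(nz / n_voxels),
    )


def gldm_matrix(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix ``D[g-1, d]``, d = number of dependent 26-neighbours.

    A neighbour is dependent when it is in-mask and its gray level differs by
    at most ``alpha``. The matrix total equals the in-mask voxel count.
    """
    in_mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in ALL_26_OFFSETS:
        s_src, s_dst = _offset_slices(levels.shape, off)
        ok = (
            in_mask[s_src]
            & in_mask[s_dst]
            & (np.abs(levels[s_src] - levels[s_dst]) <= alpha)
        )
        dep[s_src] += ok
    mat = np.zeros((ng, 27), dtype=np.float64)
    np.add.at(mat, (levels[in_mask] - 1, dep[in_mask]), 1.0)
    return mat


GLDM_NAMES = (
    "small_dependence_emphasis",
    "large_dependence_emphasis",
    "dependence_nonuniformity",
    "gray_level_nonuniformity",
)


def gldm_features(levels: np.ndarray, ng: int, alpha: int = 0) -> "OrderedDict[str, float]":
    n_voxels = int((levels > 0).sum())
    if n_voxels == 0:
        raise DegenerateInputError("mask is empty")
    mat = gldm_matrix(levels, ng, alpha)
    # dependence size j = neighbour count + 1 (the voxel itself), so the
    # emphasis terms are defined even for isolated voxels
    j = np.arange(1, 28)[None, :].astype(float)
    tot = mat.sum()
    return OrderedDict(
        small_dependence_emphasis=float((mat / j**2).sum() / tot),
        large_dependence_emphasis=float((mat * j**2).sum() / tot),
        dependence_nonuniformity=float((mat.sum(axis=0) ** 2).sum() / tot),
        gray_level_nonuniformity=float((mat.sum(axis=1) ** 2).sum() / tot),
    )


# ---------------------------------------------------------------------------
# peritumoral context
# ---------------------------------------------------------------------------

def peritumoral_mask(mask: LesionMask, r_mm: float, mode: str = "inclusive") -> LesionMask:
    """Expand a lesion mask by a physical radius ``r_mm``.

    ``inclusive`` (default) returns tumor plus margin — a spacing-aware
    dilation by a Euclidean ball, computed exactly via the distance transform;
    ``ring`` returns the margin shell only (undefined at r = 0).
    """
    if r_mm < 0:
        raise ParameterError("peritumoral radius must be >= 0")
    if mode not in ("inclusive", "ring"):
        raise ParameterError(f"mode must be 'inclusive' or 'ring', got {mode!r}")
    if mode == "ring" and r_mm == 0:
        raise DegenerateInputError("ring mode is empty at r = 0")
    if mask.voxel_count == 0:
        raise DegenerateInputError("mask is empty")
    if r_mm == 0:
        return LesionMask(mask.data.copy(), mask.label, mask.spacing, mask.origin)
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)
    grown = dist <= r_mm
    if mode == "ring":
        grown = grown & ~mask.data
        if not grown.any():
            raise DegenerateInputError("ring region is empty (mask fills the grid)")
    return LesionMask(grown, mask.label, mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"firstorder__{n}" for n in FIRST_ORDER_NAMES)
    + tuple(f"shape__{n}" for n in SHAPE_NAMES)
    + tuple(f"glcm__{n}" for n in GLCM_NAMES)
    + tuple(f"glrlm__{n}" for n in GLRLM_NAMES)
    + tuple(f"glszm__{n}" for n in GLSZM_NAMES)
    + tuple(f"gldm__{n}" for n in GLDM_NAMES)
)


def extract_all(
    v: Volume3D, mask: LesionMask, cfg: Optional[RadiomicsConfig] = None
) -> "OrderedDict[str, float]":
    """All features for one (volume, mask) pair, in the canonical schema order.

    The texture stage works on the mask's bounding box for speed; GLCM and
    friends only ever see in-mask voxels, so cropping does not change them.
    """
    cfg = cfg or RadiomicsConfig()
    _in_mask_values(v, mask)  # validates alignment / emptiness
    out: "OrderedDict[str, float]" = OrderedDict()
    for name, val in first_order_features(v, mask, cfg.discretization).items():
        out[f"firstorder__{name}"] = val
    for name, val in shape_features(mask).items():
        out[f"shape__{name}"] = val

    box = bounding_box_of(mask)
    sub_v = Volume3D(v.data[box.slices], v.spacing, v.origin, v.modality)
    sub_m = LesionMask(mask.data[box.slices], mask.label, mask.spacing, mask.origin)
    levels, ng = discretize(sub_v, sub_m, cfg.discretization)
    for name, val in glcm_features(levels, ng, cfg.glcm_distances, cfg.glcm_symmetric).items():
        out[f"glcm__{name}"] = val
    for name, val in glrlm_features(levels, ng).items():
        out[f"glrlm__{name}"] = val
    for name, val in glszm_features(levels, ng).items():
        out[f"glszm__{name}"] = val
    for name, val in gldm_features(levels, ng, cfg.gldm_alpha).items():
        out[f"gldm__{name}"] = val
    assert tuple(out) == FEATURE_NAMES
    return out


def feature_schema_manifest() -> str:
    """Versioned plain-text manifest of the frozen feature registry."""
    lines = [f"# petfuse feature schema v{SCHEMA_VERSION}", f"# n_features: {len(FEATURE_NAMES)}"]
    lines += list(FEATURE_NAMES)
    return "\n".join(lines) + "\n"
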