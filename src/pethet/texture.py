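"""3D gray-level co-occurrence texture features for PET lesions.

Implements the five heterogeneity parameters used for response screening —
COV, GLCM entropy, GLCM homogeneity, GLCM contrast, and a voxel-to-voxel
"size variation" statistic — plus SUVmean as the conventional comparator,
and the per-patient, per-site aggregation of lesion features.

Conventions
-----------
* Gray levels: equal-width bins between the VOI's own min and max SUV,
  ``ng`` levels (default 64); a constant VOI maps to a single level. Min–max
  quantization makes every GLCM feature invariant to affine rescaling of the
  SUVs inside the VOI.
* Co-occurrence: the 13 unique 3D direction offsets at distance ``d`` (default
  1), pooled into ONE symmetric matrix before normalization. Pooling all
  directions makes the features invariant under axis permutations and flips.
* Size variation: for every in-mask voxel with at least one in-mask
  26-neighbor, the absolute difference between its gray level and the mean
  gray level of its in-mask neighbors, averaged over voxels (a
  neighborhood-gray-tone-difference-style statistic). It is 0 for a constant
  lesion and grows when intensity alternates between adjacent voxels. The
  source software's exact definition of this third-order parameter is not
  public; this interpretation is documented in docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import PETVolume, VOIMask, VOISample, extract_voi

__all__ = [
    "TextureConfig",
    "QuantizedVOI",
    "NGLCM",
    "LesionFeatures",
    "quantize_values",
    "quantize_voi",
    "build_nglcm",
    "glcm_entropy",
    "glcm_homogeneity",
    "glcm_contrast",
    "histogram_cov",
    "size_variation",
    "extract_features",
    "aggregate_patient",
    "aggregate_patients",
    "features_frame",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["suv_mean", "cov", "entropy", "homogeneity", "contrast", "size_variation"]

# the 13 unique direction offsets of the 26-neighborhood (one per +/- pair)
OFFSETS_3D_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(OFFSETS_3D_13) == 13


@dataclass
class TextureConfig:
    """Feature-extraction settings.

    ng: gray-level count for quantization (>= 2).
    distance: co-occurrence offset length in voxels.
    log_base: base of the entropy logarithm (2 -> bits).
    sd_mode: 'population' (ddof=0) or 'sample' (ddof=1) SD in the COV.
    min_voxels: lesions below this voxel count are flagged (not dropped);
        default 62, the voxel count of the smallest lesion the analysis
        was designed for.
    size_variation_connectivity: 26 (full neighborhood) or 6 (faces only).
    """

    ng: int = 64
    distance: int = 1
    log_base: float = 2.0
    sd_mode: str = "population"
    min_voxels: int = 62
    size_variation_connectivity: int = 26

    def __post_init__(self) -> None:
        if self.ng < 2:
            raise ValueError(f"ng must be >= 2, got {self.ng}")
        if self.distance < 1:
            raise ValueError(f"distance must be >= 1, got {self.distance}")
        if self.log_base <= 1:
            raise ValueError(f"log_base must be > 1, got {self.log_base}")
        if self.sd_mode not in ("population", "sample"):
            raise ValueError(f"sd_mode must be 'population' or 'sample', got {self.sd_mode!r}")
        if self.size_variation_connectivity not in (6, 26):
            raise ValueError("size_variation_connectivity must be 6 or 26")


@dataclass
class QuantizedVOI:
    """Gray-level representation of one VOI.

    ``levels`` lists the foreground voxel levels (1..ng, raster order);
    ``grid_levels`` is the full 3D grid with 0 as the background sentinel.
    """

    levels: np.ndarray
    ng: int
    grid_levels: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.grid_levels = np.asarray(self.grid_levels, dtype=np.int64)
        if self.ng < 2:
            raise ValueError(f"ng must be >= 2, got {self.ng}")
        if self.levels.size < 1:
            raise ValueError("quantized VOI is empty")
        if self.levels.min() < 1 or self.levels.max() > self.ng:
            raise ValueError("levels must lie in 1..ng")


@dataclass
class NGLCM:
    """Normalized (symmetric) gray-level co-occurrence matrix."""

    p: np.ndarray
    offsets_used: tuple
    pair_count: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("p must be square")
        if (self.p < 0).any():
            raise ValueError("p has negative entries")
        if not np.allclose(self.p, self.p.T, atol=1e-12):
            raise ValueError("p must be symmetric")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError(f"p must sum to 1, sums to {self.p.sum()}")
        if self.pair_count < 1:
            raise ValueError("pair_count must be >= 1")


@dataclass
class LesionFeatures:
    """The six per-lesion features plus geometry and a small-lesion flag."""

    suv_mean: float
    cov: float
    entropy: float
    homogeneity: float
    contrast: float
    size_variation: float
    volume_cm3: float
    n_voxels: int
    below_min_voxels: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "volume_cm3": self.volume_cm3,
            "suv_mean": self.suv_mean,
            "cov": self.cov,
            "entropy": self.entropy,
            "homogeneity": self.homogeneity,
            "contrast": self.contrast,
            "size_variation": self.size_variation,
        }


def quantize_values(values: np.ndarray, ng: int) -> np.ndarray:
    """Map SUVs to integer levels 1..ng with equal-width min–max bins.

    The maximum maps to level ng; a constant input maps everything to 1.
    """
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")
    values = np.asarray(values, dtype=np.float64)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.ones(values.shape, dtype=np.int64)
    levels = 1 + np.floor((values - vmin) / (vmax - vmin) * ng).astype(np.int64)
    return np.minimum(levels, ng)


def quantize_voi(volume: PETVolume, mask: VOIMask, ng: int = 64) -> QuantizedVOI:
    """Quantize the in-mask voxels of a volume; background gets sentinel 0."""
    sample = extract_voi(volume, mask)
    levels = quantize_values(sample.suv_values, ng)
    grid = np.zeros(volume.values.shape, dtype=np.int64)
    # same min-max mapping applied on the grid; sentinel stays 0 outside
    fg = mask.mask
    vmin, vmax = sample.suv_values.min(), sample.suv_values.max()
    if vmax == vmin:
        grid[fg] = 1
    else:
        g = 1 + np.floor((volume.values[fg] - vmin) / (vmax - vmin) * ng).astype(np.int64)
        grid[fg] = np.minimum(g, ng)
    return QuantizedVOI(levels=levels, ng=ng, grid_levels=grid)


def _shifted_views(grid: np.ndarray, offset: tuple[int, int, int]):
    sl_a, sl_b = [], []
    for d, n in zip(offset, grid.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return grid[tuple(sl_a)], grid[tuple(sl_b)]


def build_nglcm(qvoi: QuantizedVOI, distance: int = 1) -> NGLCM:
    """Accumulate a symmetric NGLCM over the 13 unique 3D directions.

    Only pairs with both voxels inside the mask contribute; both orderings of
    each pair are counted, and counts are normalized to probabilities.
    """
    g = qvoi.grid_levels
    ng = qvoi.ng
    counts = np.zeros((ng, ng), dtype=np.float64)
    offsets = tuple(tuple(distance * c for c in off) for off in OFFSETS_3D_13)
    for off in offsets:
        a, b = _shifted_views(g, off)
        valid = (a > 0) & (b > 0)
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    counts = counts + counts.T  # symmetric accumulation (both orderings)
    total = counts.sum()
    if total == 0:
        raise ValueError(
            "no co-occurring voxel pair inside the mask "
            "(isolated voxels cannot form a co-occurrence matrix)"
        )
    return NGLCM(p=counts / total, offsets_used=offsets, pair_count=int(round(total)))


def glcm_entropy(nglcm: NGLCM, log_base: float = 2.0) -> float:
    """-sum p log p over the matrix, 0*log0 = 0; base 2 gives bits."""
    p = nglcm.p[nglcm.p > 0]
    return float(-(p * np.log(p)).sum() / np.log(log_base) + 0.0)


def glcm_homogeneity(nglcm: NGLCM) -> float:
    """sum p(i,j) / (1 + |i-j|); 1 iff all mass on the diagonal."""
    i, j = np.indices(nglcm.p.shape)
    return float((nglcm.p / (1.0 + np.abs(i - j))).sum())


def glcm_contrast(nglcm: NGLCM) -> float:
    """sum (i-j)^2 p(i,j); 0 iff all mass on the diagonal."""
    i, j = np.indices(nglcm.p.shape)
    return float(((i - j) ** 2 * nglcm.p).sum())


def histogram_cov(sample: VOISample | np.ndarray, sd_mode: str = "population") -> float:
    """Coefficient of variation of the raw (unquantized) VOI SUVs."""
    values = sample.suv_values if isinstance(sample, VOISample) else np.asarray(sample, float)
    mean = values.mean()
    if mean <= 0:
        raise ValueError(f"COV undefined for non-positive mean SUV ({mean})")
    ddof = 0 if sd_mode == "population" else 1
    if values.size == 1 and ddof == 1:
        raise ValueError("sample SD undefined for a single voxel")
    if values.max() == values.min():  # exactly constant -> exactly zero
        return 0.0
    return float(values.std(ddof=ddof) / mean)


def size_variation(qvoi: QuantizedVOI, connectivity: int = 26) -> float:
    """Mean absolute difference between a voxel's level and its neighborhood.

    For each in-mask voxel with >= 1 in-mask neighbor (26- or 6-connectivity),
    take |level - mean(in-mask neighbor levels)| and average over voxels.
    """
    if connectivity == 26:
        kernel = np.ones((3, 3, 3))
        kernel[1, 1, 1] = 0.0
    elif connectivity == 6:
        kernel = np.zeros((3, 3, 3))
        kernel[0, 1, 1] = kernel[2, 1, 1] = 1.0
        kernel[1, 0, 1] = kernel[1, 2, 1] = 1.0
        kernel[1, 1, 0] = kernel[1, 1, 2] = 1.0
    else:
        raise ValueError("connectivity must be 6 or 26")
    inmask = qvoi.grid_levels > 0
    lv = qvoi.grid_levels.astype(np.float64) * inmask
    nb_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(inmask.astype(np.float64), kernel, mode="constant", cval=0.0)
    nb_cnt = np.round(nb_cnt)
    has_nb = inmask & (nb_cnt > 0)
    if not has_nb.any():
        raise ValueError("no in-mask voxel has an in-mask neighbor")
    diffs = np.abs(lv[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    return float(diffs.mean())


def extract_features(
    volume: PETVolume, mask: VOIMask, config: TextureConfig | None = None
) -> LesionFeatures:
    """Compute SUVmean + the five heterogeneity features for one lesion.

    Deterministic given inputs and config. Lesions below ``config.min_voxels``
    are flagged via ``below_min_voxels`` (and a warning), never dropped.
    """
    config = config or TextureConfig()
    sample = extract_voi(volume, mask)
    small = sample.n_voxels < config.min_voxels
    if small:
        warnings.warn(
            f"lesion {mask.patient_id}/{mask.lesion_id}: {sample.n_voxels} voxels "
            f"is below the {config.min_voxels}-voxel floor; features may be unstable",
            stacklevel=2,
        )
    qvoi = quantize_voi(volume, mask, config.ng)
    nglcm = build_nglcm(qvoi, config.distance)
    return LesionFeatures(
        suv_mean=float(sample.suv_values.mean()),
        cov=histogram_cov(sample, config.sd_mode),
        entropy=glcm_entropy(nglcm, config.log_base),
        homogeneity=glcm_homogeneity(nglcm),
        contrast=glcm_contrast(nglcm),
        size_variation=size_variation(qvoi, config.size_variation_connectivity),
        volume_cm3=sample.volume_cm3,
        n_voxels=sample.n_voxels,
        below_min_voxels=small,
    )


def features_frame(records) -> pd.DataFrame:
    """Tabulate (patient_id, site, lesion_id, LesionFeatures) records."""
    rows = []
    for patient_id, site, lesion_id, feats in records:
        rows.append(
            {"patient_id": patient_id, "site": site, "lesion_id": lesion_id, **feats.as_dict()}
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "site", "lesion_id", "volume_cm3", *FEATURE_COLUMNS]
    )


def aggregate_patient(site_features: dict[str, list[LesionFeatures]]) -> dict[str, LesionFeatures]:
    """Per-site unweighted mean of lesion features for one patient."""
    out: dict[str, LesionFeatures] = {}
    for site, feats in site_features.items():
        if not feats:
            continue
        out[site] = LesionFeatures(
            suv_mean=float(np.mean([f.suv_mean for f in feats])),
            cov=float(np.mean([f.cov for f in feats])),
            entropy=float(np.mean([f.entropy for f in feats])),
            homogeneity=float(np.mean([f.homogeneity for f in feats])),
            contrast=float(np.mean([f.contrast for f in feats])),
            size_variation=float(np.mean([f.size_variation for f in feats])),
            volume_cm3=float(np.mean([f.volume_cm3 for f in feats])),
            n_voxels=int(np.sum([f.n_voxels for f in feats])),
            below_min_voxels=any(f.below_min_voxels for f in feats),
        )
    return out


def aggregate_patients(lesion_table: pd.DataFrame) -> pd.DataFrame:
    """Mean lesion features per (patient, site), as used for the final screen."""
    cols = ["volume_cm3", *FEATURE_COLUMNS]
    grouped = (
        lesion_table.groupby(["patient_id", "site"], sort=True)[cols]
        .mean()
        .reset_index()
    )
    counts = (
        lesion_table.groupby(["patient_id", "site"], sort=True)
        .size()
        .rename("n_lesions")
        .reset_index()
    )
    return grouped.merge(counts, on=["patient_id", "site"])
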