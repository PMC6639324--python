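"""Requantization, masked GLCMs, Haralick features and directional summaries.

The texture stage turns one parametric map + VOI mask into 300 named features:
20 co-occurrence (Haralick-family) features x 5 gray-level settings
(G = 8, 16, 32, 64, 256) x 3 rotation-invariant summaries (average, range and
angular variance over the four in-plane directions at distance 1 voxel).

Conventions, centralized here:

* Requantization: equal-width bins spanning [min, max] of the masked values;
  the masked maximum maps to level G; a constant VOI maps to level 1.  Because
  bin edges are tied to the masked min/max, any positive-affine intensity
  transform a*x + b (a > 0) leaves the quantized volume unchanged.
* GLCM accumulation: pair counts pooled over ALL axial slices of the 3D VOI
  into a single matrix per (direction, G); a pair contributes only when both
  voxels lie inside the mask.  Matrices are symmetrized by adding the
  transpose, so the sign of each direction offset is immaterial.
* Directions: (0,1), (-1,1), (-1,0), (-1,-1) in (row, col) = 0/45/90/135 deg.
* Feature formulas: Haralick/Soh-Tsatsoulis/Clausi set, logs base 2 with
  eps = 1e-12 inside logs; GLCM "variance" (sum of squares) is taken about the
  GLCM mean mu = sum_ij i*p(i,j); IMC2 = sqrt(1 - exp(-2(HXY2 - HXY))) clamped
  to [0, 1]; correlation clamped to [-1, 1].
* Angular variance: population variance (divisor 4) of the four per-direction
  values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .histogram import HISTOGRAM_FEATURE_NAMES, compute_histogram_features
from .io import (
    IN_PLANE_DIRECTIONS,
    ClassLabel,
    CohortManifest,
    FeatureTable,
    MapKind,
    ParametricVolume,
    RunConfig,
    VOIMask,
)

logger = logging.getLogger(__name__)

EPS = 1e-12
LOG2_EPS_GUARD = EPS

HARALICK_FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_shade",
    "cluster_prominence",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "maximum_probability",
    "variance",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "inverse_difference_moment",
    "normalized_inverse_difference_moment",
)

SUMMARY_NAMES: tuple[str, ...] = ("avg", "range", "angvar")

__all__ = [
    "QuantizedVolume",
    "GLCMatrix",
    "DirectionalSummary",
    "HARALICK_FEATURE_NAMES",
    "SUMMARY_NAMES",
    "requantize",
    "compute_glcm",
    "normalize_glcm",
    "haralick_features",
    "directional_summary",
    "texture_feature_names",
    "extract_texture_features",
    "map_feature_names",
    "extract_map_features",
    "extract_subject_features",
    "extract_cohort_features",
]


@dataclass
class QuantizedVolume:
    """Integer gray levels 1..G inside the mask, sentinel 0 outside."""

    levels: np.ndarray
    G: int


@dataclass
class GLCMatrix:
    """G x G co-occurrence counts (or probabilities) for one direction."""

    counts: np.ndarray
    direction: tuple[int, int]
    distance: int = 1
    normalized: bool = False

    @property
    def G(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class DirectionalSummary:
    average: float
    range: float
    angular_variance: float


def requantize(volume: ParametricVolume, mask: VOIMask, G: int) -> QuantizedVolume:
    """Map masked intensities to integer gray levels 1..G by equal-width binning."""
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    mask.check_companion(volume)
    m = mask.voxels
    x = volume.voxels
    vals = x[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(x.shape, dtype=np.int32)
    if hi > lo:
        width = (hi - lo) / G
        lv = np.floor((x[m] - lo) / width).astype(np.int64) + 1
        np.clip(lv, 1, G, out=lv)
        levels[m] = lv
    else:
        levels[m] = 1  # constant VOI: everything at level 1
    return QuantizedVolume(levels=levels, G=G)


def compute_glcm(
    q: QuantizedVolume,
    mask: VOIMask,
    direction: tuple[int, int],
    distance: int = 1,
) -> GLCMatrix:
    """Accumulate a symmetrized co-occurrence matrix over all axial slices.

    A voxel pair (v, v + distance*direction) contributes one count when both
    voxels are inside the mask; counts from every slice pool into one matrix.
    """
    dr, dc = direction
    if (dr, dc) not in {(d[0], d[1]) for d in IN_PLANE_DIRECTIONS} | {
        (-d[0], -d[1]) for d in IN_PLANE_DIRECTIONS
    }:
        raise ValueError(f"direction {direction} is not one of the 4 in-plane offsets")
    G = q.G
    L = q.levels
    m = mask.voxels
    orow, ocol = dr * distance, dc * distance
    nr, nc = L.shape[0], L.shape[1]

    # index ranges so that both (r, c) and (r+orow, c+ocol) stay in bounds
    r0, r1 = max(0, -orow), min(nr, nr - orow)
    c0, c1 = max(0, -ocol), min(nc, nc - ocol)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"degenerate VOI for direction {direction}: offset exceeds grid")

    a = L[r0:r1, c0:c1, :]
    b = L[r0 + orow : r1 + orow, c0 + ocol : c1 + ocol, :]
    valid = m[r0:r1, c0:c1, :] & m[r0 + orow : r1 + orow, c0 + ocol : c1 + ocol, :]
    if not valid.any():
        raise ValueError(f"degenerate VOI for direction {direction}: no in-mask pair")

    ai = a[valid] - 1
    bi = b[valid] - 1
    flat = np.bincount(ai * G + bi, minlength=G * G)
    counts = flat.reshape(G, G).astype(np.float64)
    counts = counts + counts.T  # symmetrize
    if counts.sum() < G:
        logger.warning(
            "sparse GLCM: %d pair counts for G=%d, direction %s", int(counts.sum()), G, direction
        )
    return GLCMatrix(counts=counts, direction=(dr, dc), distance=distance, normalized=False)


def normalize_glcm(m: GLCMatrix) -> GLCMatrix:
    total = m.counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize a zero-total GLCM")
    return GLCMatrix(
        counts=m.counts / total,
        direction=m.direction,
        distance=m.distance,
        normalized=True,
    )


def _entropy_bits(p: np.ndarray) -> float:
    # restricting to p > 0 plays the role of an eps guard inside the log
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick_features(m: GLCMatrix) -> dict[str, float]:
    """The 20 co-occurrence features of a normalized, symmetric GLCM.

    Sums run over the nonzero entries only (GLCMs at large G are sparse for
    small VOIs); marginal-entropy terms use the closed form
    HXY1 = HXY2 = HX + HY, which holds identically because
    log(px * py) = log px + log py.
    """
    if not m.normalized:
        raise ValueError("haralick_features requires a normalized GLCM")
    P = m.counts
    G = m.G
    ri, ci = np.nonzero(P)
    pv = P[ri, ci]
    iv = (ri + 1).astype(np.float64)
    jv = (ci + 1).astype(np.float64)
    idx = np.arange(1, G + 1, dtype=np.float64)

    px = P.sum(axis=1)  # symmetric => px == py
    py = P.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))

    sum_iv = (ri + ci + 2).astype(np.int64)  # 2..2G
    diff_iv = np.abs(ri - ci).astype(np.int64)  # 0..G-1
    p_sum = np.bincount(sum_iv, weights=pv, minlength=2 * G + 1)[2:]
    p_diff = np.bincount(diff_iv, weights=pv, minlength=G)
    k_sum = np.arange(2, 2 * G + 1, dtype=np.float64)
    k_diff = np.arange(0, G, dtype=np.float64)

    adiff = np.abs(iv - jv)
    autocorrelation = float((iv * jv * pv).sum())
    contrast = float((adiff**2 * pv).sum())
    if sigma_x * sigma_y > EPS:
        correlation = (autocorrelation - mu_x * mu_y) / (sigma_x * sigma_y)
        correlation = float(np.clip(correlation, -1.0, 1.0))
    else:
        correlation = 0.0
    cluster_shade = float(((iv + jv - mu_x - mu_y) ** 3 * pv).sum())
    cluster_prominence = float(((iv + jv - mu_x - mu_y) ** 4 * pv).sum())
    dissimilarity = float((adiff * pv).sum())
    energy = float((pv**2).sum())
    entropy = _entropy_bits(pv)
    homogeneity = float((pv / (1.0 + adiff)).sum())
    maximum_probability = float(pv.max())
    glcm_mean = float((iv * pv).sum())  # mu = sum_ij i * p(i,j)
    variance = float(((iv - glcm_mean) ** 2 * pv).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _entropy_bits(p_sum)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _entropy_bits(p_diff)

    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    hxy1 = hxy2 = hx + hy
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > EPS else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(np.clip(imc2_arg, 0.0, 1.0)))

    inverse_difference_moment = float((pv / (1.0 + adiff**2)).sum())
    normalized_idm = float((pv / (1.0 + (adiff / G) ** 2)).sum())

    return {
        "autocorrelation": autocorrelation,
        "contrast": contrast,
        "correlation": correlation,
        "cluster_shade": cluster_shade,
        "cluster_prominence": cluster_prominence,
        "dissimilarity": dissimilarity,
        "energy": energy,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "maximum_probability": maximum_probability,
        "variance": variance,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": float(imc1),
        "imc2": imc2,
        "inverse_difference_moment": inverse_difference_moment,
        "normalized_inverse_difference_moment": normalized_idm,
    }


def directional_summary(values) -> DirectionalSummary:
    """Average, range and angular (population, divisor-4) variance of 4 values."""
    v = np.asarray(values, dtype=np.float64)
    if v.shape != (4,):
        raise ValueError(f"expected exactly 4 per-direction values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite per-direction feature value")
    return DirectionalSummary(
        average=float(v.mean()),
        range=float(v.max() - v.min()),
        angular_variance=float(v.var()),
    )


def texture_feature_names(map_name: str, config: RunConfig | None = None) -> list[str]:
    config = config or RunConfig()
    return [
        f"{map_name}|glcm|G{g}|{feat}|{summ}"
        for g in config.gray_levels
        for feat in HARALICK_FEATURE_NAMES
        for summ in SUMMARY_NAMES
    ]


def extract_texture_features(
    volume: ParametricVolume, mask: VOIMask, config: RunConfig | None = None
) -> dict[str, float]:
    """All 300 summarized texture features of one map (20 x 5 gray levels x 3)."""
    config = config or RunConfig()
    map_name = volume.map_kind.value
    out: dict[str, float] = {}
    for g in config.gray_levels:
        q = requantize(volume, mask, g)
        per_direction = []
        for direction in config.directions:
            glcm = compute_glcm(q, mask, direction, distance=config.distance)
            per_direction.append(haralick_features(normalize_glcm(glcm)))
        for feat in HARALICK_FEATURE_NAMES:
            summ = directional_summary([d[feat] for d in per_direction])
            out[f"{map_name}|glcm|G{g}|{feat}|avg"] = summ.average
            out[f"{map_name}|glcm|G{g}|{feat}|range"] = summ.range
            out[f"{map_name}|glcm|G{g}|{feat}|angvar"] = summ.angular_variance
    return out


def map_feature_names(map_name: str, config: RunConfig | None = None) -> list[str]:
    """The 310 column names for one map: 10 histogram + 300 texture."""
    hist = [f"{map_name}|hist|{n}" for n in HISTOGRAM_FEATURE_NAMES]
    return hist + texture_feature_names(map_name, config)


def extract_map_features(
    volume: ParametricVolume, mask: VOIMask, config: RunConfig | None = None
) -> dict[str, float]:
    """All 310 features of one parametric map (histogram + texture)."""
    map_name = volume.map_kind.value
    hist = compute_histogram_features(volume, mask)
    out = {f"{map_name}|hist|{n}": v for n, v in hist.as_dict().items()}
    out.update(extract_texture_features(volume, mask, config))
    return out


def extract_subject_features(
    ktrans: tuple[ParametricVolume, VOIMask] | None,
    rcbv: tuple[ParametricVolume, VOIMask] | None,
    config: RunConfig | None = None,
) -> dict[str, float]:
    """Fused per-subject feature vector: 310 per map, 620 when both maps present."""
    if ktrans is None and rcbv is None:
        raise ValueError("at least one parametric map is required")
    out: dict[str, float] = {}
    if ktrans is not None:
        out.update(extract_map_features(ktrans[0], ktrans[1], config))
    if rcbv is not None:
        out.update(extract_map_features(rcbv[0], rcbv[1], config))
    return out


def extract_cohort_features(
    manifest: CohortManifest,
    config: RunConfig | None = None,
    maps: str = "both",
    base_dir=None,
) -> FeatureTable:
    """Extract the cohort FeatureTable (n x 310 per map, n x 620 fused).

    ``maps`` is one of ``ktrans``, ``rcbv`` or ``both``; relative manifest paths
    resolve against ``base_dir``.
    """
    from pathlib import Path

    from .io import read_mask, read_volume

    if maps not in {"ktrans", "rcbv", "both"}:
        raise ValueError(f"maps must be ktrans, rcbv or both, got {maps!r}")
    config = config or RunConfig()
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    names: list[str] | None = None
    rows = []
    for row in manifest.rows:
        feats: dict[str, float] = {}
        if maps in {"ktrans", "both"}:
            vol = read_volume(_resolve(row.ktrans_path), MapKind.KTRANS, row.subject_id)
            msk = read_mask(_resolve(row.ktrans_mask_path), companion=vol)
            feats.update(extract_map_features(vol, msk, config))
        if maps in {"rcbv", "both"}:
            vol = read_volume(_resolve(row.rcbv_path), MapKind.RCBV, row.subject_id)
            msk = read_mask(_resolve(row.rcbv_mask_path), companion=vol)
            feats.update(extract_map_features(vol, msk, config))
        if names is None:
            names = list(feats.keys())
        rows.append([feats[n] for n in names])
    assert names is not None
    return FeatureTable(
        subject_ids=manifest.subject_ids,
        feature_names=names,
        values=np.asarray(rows, dtype=np.float64),
        labels=list(manifest.labels),
    )
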