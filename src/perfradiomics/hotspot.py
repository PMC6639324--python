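"""Hotspot-ROI perfusion readout and group comparison.

The conventional (non-radiomic) analysis: place four small circular ROIs
(default area 10.55 mm^2) on the highest-valued parts of the parametric map
inside the VOI, average the four ROI means, and compare the per-subject pooled
means between groups with a Mann-Whitney U test.

The ROI placement here is an automated surrogate for the manual delineation it
mimics: a greedy search that repeatedly centers a disc at the in-mask position
maximizing the disc-mean value, excludes those pixels, and repeats.  Ties break
in row-major (slice, row, col) order, so placement is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ParametricVolume, VOIMask

__all__ = ["HotspotROI", "HotspotROISet", "MannWhitneyResult", "find_hotspot_rois", "compare_groups"]


@dataclass(frozen=True)
class HotspotROI:
    slice_index: int
    center: tuple[int, int]  # (row, col)
    radius_mm: float
    mean_value: float


@dataclass(frozen=True)
class HotspotROISet:
    rois: tuple[HotspotROI, ...]

    @property
    def pooled_mean(self) -> float:
        return float(np.mean([r.mean_value for r in self.rois]))


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first group
    p_value: float
    n1: int
    n2: int


def _disc_offsets(area_mm2: float, spacing_rc: tuple[float, float]) -> np.ndarray:
    """In-plane (drow, dcol) offsets of a discrete disc of the target area.

    Takes the round(area / pixel_area) pixels closest to the center (ties
    broken row-major), so the discretized ROI area matches the requested one
    to within half a pixel at any spacing.
    """
    sr, sc = spacing_rc
    n_pixels = max(1, round(area_mm2 / (sr * sc)))
    reach = int(np.ceil(np.sqrt(n_pixels))) + 2
    cand = [
        ((dr * sr) ** 2 + (dc * sc) ** 2, dr, dc)
        for dr in range(-reach, reach + 1)
        for dc in range(-reach, reach + 1)
    ]
    cand.sort()
    return np.array([(dr, dc) for _, dr, dc in cand[:n_pixels]], dtype=np.int64)


def find_hotspot_rois(
    volume: ParametricVolume,
    mask: VOIMask,
    n_rois: int = 4,
    area_mm2: float = 10.55,
) -> HotspotROISet:
    """Greedy placement of ``n_rois`` disjoint hotspot discs inside the VOI.

    Every pixel of a disc must lie inside the mask and outside previously
    placed discs; the search runs over all slices.  Raises if the mask cannot
    host the requested number of discs, naming the achievable count.
    """
    mask.check_companion(volume)
    radius_mm = float(np.sqrt(area_mm2 / np.pi))
    offsets = _disc_offsets(area_mm2, (volume.spacing[0], volume.spacing[1]))
    nr, nc, ns = volume.shape
    vox = volume.voxels
    available = mask.voxels.copy()

    rois: list[HotspotROI] = []
    for _ in range(n_rois):
        best = None  # (value, slice, row, col)
        for s in range(ns):
            avail = available[:, :, s]
            if not avail.any():
                continue
            plane = vox[:, :, s]
            # candidate centers: every disc pixel in-bounds and available
            rows, cols = np.nonzero(avail)
            rr = rows[:, None] + offsets[:, 0][None, :]
            cc = cols[:, None] + offsets[:, 1][None, :]
            inb = (rr >= 0) & (rr < nr) & (cc >= 0) & (cc < nc)
            ok = inb.all(axis=1)
            if not ok.any():
                continue
            rr, cc = rr[ok], cc[ok]
            rows, cols = rows[ok], cols[ok]
            good = avail[rr, cc].all(axis=1)
            if not good.any():
                continue
            means = plane[rr[good], cc[good]].mean(axis=1)
            rows, cols = rows[good], cols[good]
            # row-major tie-break: first index among maxima in (row, col) order
            order = np.lexsort((cols, rows))
            means_o = means[order]
            k = int(np.argmax(means_o))
            cand = (float(means_o[k]), s, int(rows[order][k]), int(cols[order][k]))
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            raise ValueError(
                f"mask too small for {n_rois} disjoint ROIs of area {area_mm2} mm^2; "
                f"only {len(rois)} placed"
            )
        value, s, r, c = best
        rois.append(HotspotROI(slice_index=s, center=(r, c), radius_mm=radius_mm, mean_value=value))
        available[r + offsets[:, 0], c + offsets[:, 1], s] = False
    return HotspotROISet(rois=tuple(rois))


def compare_groups(values_a, values_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U comparison of two groups of per-subject scalars.

    Uses the exact null distribution for small untied samples (n1*n2 <= 400);
    otherwise the normal approximation with tie correction (no continuity
    correction, so identical groups give p = 1).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = a.size * b.size <= 400
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return MannWhitneyResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=a.size,
        n2=b.size,
    )
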