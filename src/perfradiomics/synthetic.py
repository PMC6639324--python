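"""Two-class synthetic cohorts of textured lesion phantoms.

Each phantom is an ellipsoidal lesion (jittered semi-axes and center) on a 3D
grid; within-mask intensities are a stationary Gaussian random field made by
Gaussian-kernel smoothing of white noise.  The class gap is a single dial: the
texture correlation length.  PD-like lesions get a SHORT correlation length
(rough texture: high co-occurrence entropy, low autocorrelation), PsP-like
lesions a LONG one (smooth texture) — the direction of the separation the
radiomic analysis is designed to pick up.

The field is affinely mapped to the map kind's plausible intensity range
(Ktrans around 0.15 min^-1, rCBV around 4 mL/100 mL); texture features are
invariant to that affine map, so the classes differ in spatial texture, not in
raw intensity scale.  Everything is bitwise-deterministic given
(config.seed, subject_seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import (
    ClassLabel,
    CohortManifest,
    ManifestRow,
    MapKind,
    ParametricVolume,
    VOIMask,
    write_manifest,
    write_mask,
    write_volume,
)

__all__ = ["SyntheticCohortConfig", "generate_lesion", "generate_cohort"]


@dataclass
class SyntheticCohortConfig:
    """Study-condition knobs for the phantom cohort generator.

    Defaults mirror the two-class cohort the analysis targets: 76 PD-like vs
    22 PsP-like subjects, 5 mm slices, lesions of a few cm^3.
    """

    n_pd: int = 76
    n_psp: int = 22
    shape: tuple[int, int, int] = (32, 32, 12)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    semi_axes_mm: tuple[float, float, float] = (8.0, 8.0, 10.0)
    semi_axes_jitter: float = 0.15  # fractional jitter on each semi-axis
    center_jitter_mm: float = 2.0
    mask_jitter_mm: float = 0.75  # extra per-map mask jitter (Ktrans vs rCBV VOIs differ)
    corr_length_pd: float = 1.5  # mm; short = rough texture
    corr_length_psp: float = 4.0  # mm; long = smooth texture
    intensity_mean: dict[MapKind, float] = field(
        default_factory=lambda: {MapKind.KTRANS: 0.15, MapKind.RCBV: 4.0}
    )
    intensity_scale: dict[MapKind, float] = field(
        default_factory=lambda: {MapKind.KTRANS: 0.05, MapKind.RCBV: 1.5}
    )
    noise_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd < 0 or self.n_psp < 0:
            raise ValueError("class sizes must be non-negative")
        if self.corr_length_pd <= 0 or self.corr_length_psp <= 0:
            raise ValueError("correlation lengths must be positive")

    def corr_length(self, label: ClassLabel) -> float:
        return self.corr_length_pd if label is ClassLabel.PD else self.corr_length_psp


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    semi_axes_mm: np.ndarray,
) -> np.ndarray:
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semi_axes_mm))
    return d2 <= 1.0


def generate_lesion(
    config: SyntheticCohortConfig,
    class_label: ClassLabel,
    subject_seed: int,
) -> dict[MapKind, tuple[ParametricVolume, VOIMask]]:
    """One phantom subject: per map kind, a textured volume and its VOI mask."""
    extent_mm = np.array(config.shape) * np.array(config.spacing)
    base_axes = np.asarray(config.semi_axes_mm, dtype=float)
    if np.any(2 * base_axes * (1 + config.semi_axes_jitter) > extent_mm):
        raise ValueError(
            f"lesion (semi-axes {tuple(base_axes)} mm) does not fit inside the "
            f"grid extent {tuple(extent_mm)} mm"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(subject_seed)]))
    axes = base_axes * (1 + config.semi_axes_jitter * rng.uniform(-1, 1, size=3))
    lo = axes.copy()
    hi = extent_mm - axes
    center = extent_mm / 2 + rng.uniform(-1, 1, size=3) * config.center_jitter_mm
    center = np.clip(center, lo, hi)

    corr = config.corr_length(class_label)
    sigma_vox = corr / np.asarray(config.spacing, dtype=float)
    out: dict[MapKind, tuple[ParametricVolume, VOIMask]] = {}
    for kind in (MapKind.KTRANS, MapKind.RCBV):
        jitter = rng.uniform(-1, 1, size=3) * config.mask_jitter_mm
        c = np.clip(center + jitter, lo, hi)
        mask_arr = _ellipsoid_mask(config.shape, config.spacing, c, axes)
        white = rng.standard_normal(config.shape)
        smooth = gaussian_filter(white, sigma=sigma_vox, mode="wrap")
        sd = smooth.std()
        z = (smooth - smooth.mean()) / sd if sd > 0 else np.zeros_like(smooth)
        vox = np.zeros(config.shape, dtype=np.float64)
        vox[mask_arr] = (
            config.intensity_mean[kind]
            + config.intensity_scale[kind] * config.noise_amplitude * z[mask_arr]
        )
        vol = ParametricVolume(
            voxels=vox, spacing=config.spacing, map_kind=kind, subject_id=""
        )
        out[kind] = (vol, VOIMask(voxels=mask_arr))
    return out


def generate_cohort(config: SyntheticCohortConfig, out_dir: str | Path) -> CohortManifest:
    """Write a full phantom cohort (2 maps + 2 masks per subject) and its manifest.

    Manifest paths are relative to ``out_dir`` so the cohort directory is
    relocatable; two runs with the same config are file-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    subjects = [(ClassLabel.PD, i) for i in range(config.n_pd)] + [
        (ClassLabel.PSP, i) for i in range(config.n_psp)
    ]
    for subject_seed, (label, i) in enumerate(subjects):
        sid = f"{label.value}-{i + 1:03d}"
        lesion = generate_lesion(config, label, subject_seed)
        paths = {}
        for kind, (vol, mask) in lesion.items():
            vol.subject_id = sid
            vol_name = f"{sid}_{kind.value}.nii.gz"
            mask_name = f"{sid}_{kind.value}_mask.nii.gz"
            write_volume(vol, out_dir / vol_name)
            write_mask(mask, out_dir / mask_name, spacing=config.spacing)
            paths[kind] = (vol_name, mask_name)
        rows.append(
            ManifestRow(
                subject_id=sid,
                label=label,
                ktrans_path=paths[MapKind.KTRANS][0],
                ktrans_mask_path=paths[MapKind.KTRANS][1],
                rcbv_path=paths[MapKind.RCBV][0],
                rcbv_mask_path=paths[MapKind.RCBV][1],
            )
        )
    manifest = CohortManifest(rows=rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
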