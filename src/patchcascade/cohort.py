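"""Synthetic gray-matter-density cohorts with localized, class-dependent atrophy.

The generator emulates the statistical structure a patch-sampling study
assumes of spatially normalized gray-matter density maps, with no claim to
real anatomy:

* a fixed smooth pseudo-anatomy template (superposition of broad
  low-frequency bumps, smoothed at a configurable scale), identical across
  subjects up to a per-subject random sub-voxel affine jitter — the
  stand-in for spatial normalization residuals;
* "atrophy": multiplicative intensity reduction by a factor (1−δ) inside a
  sphere with a 2-voxel soft edge at each configured site, applied to
  disease-class (AD) subjects only;
* disease heterogeneity: a configurable fraction of AD subjects whose
  first listed site is spared, mimicking patients whose primary region is
  preserved;
* independent additive Gaussian voxel noise, applied after atrophy, with
  intensities clipped to remain in [0, 1 + 5·noise_sd].

Cohorts are written as NIfTI volumes plus a headered CSV subject table;
generation is byte-deterministic given the configuration (including seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import fwhm_to_sigma_voxels
from .volume import Volume, save_volume

__all__ = [
    "AtrophySite",
    "CohortConfig",
    "SubjectRecord",
    "build_template",
    "generate_cohort_arrays",
    "generate_cohort",
    "write_cohort_table",
    "read_cohort_table",
]

LABELS = ("AD", "CN")
SPLITS = ("train", "val", "test", "unassigned")

_TEMPLATE_SEED = 20230202  # fixed: the pseudo-anatomy is shared across cohorts


@dataclass(frozen=True)
class AtrophySite:
    """A spherical lesion site: center voxel, radius (voxels), effect size δ.

    δ is the fractional intensity reduction applied inside the sphere for
    disease-class subjects (0 = no signal, 1 = complete loss).
    """

    center: tuple[int, int, int]
    radius: float
    delta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(int(c) for c in self.center))
        if self.radius <= 0:
            raise ValueError(f"site radius must be positive, got {self.radius}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"effect size delta must be in [0,1], got {self.delta}")


def _default_sites(volume_shape: tuple[int, int, int]) -> tuple[AtrophySite, ...]:
    """Mirrored medial-temporal-like sites at fixed fractional coordinates.

    On the standard 121×145×121 grid this places spheres of radius 8 at
    (42, 62, 42) and (78, 62, 42); smaller grids scale proportionally.
    """
    sx, sy, sz = volume_shape
    y = round(0.43 * (sy - 1))
    z = round(0.35 * (sz - 1))
    radius = max(2.0, round(0.066 * sx))
    return (
        AtrophySite(center=(round(0.35 * (sx - 1)), y, z), radius=radius, delta=0.3),
        AtrophySite(center=(round(0.65 * (sx - 1)), y, z), radius=radius, delta=0.3),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full description of one synthetic cohort; the seed closes determinism."""

    n_subjects: int = 40
    class_fraction_ad: float = 0.5
    volume_shape: tuple[int, int, int] = (121, 145, 121)
    voxel_size_mm: float = 1.5
    atrophy_sites: tuple[AtrophySite, ...] | None = None
    heterogeneity_fraction: float = 0.0
    noise_sd: float = 0.05
    background_smoothness_mm: float = 9.0
    jitter_voxels: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "volume_shape", tuple(int(s) for s in self.volume_shape)
        )
        if self.atrophy_sites is None:
            object.__setattr__(self, "atrophy_sites", _default_sites(self.volume_shape))
        object.__setattr__(self, "atrophy_sites", tuple(self.atrophy_sites))
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if not (0.0 < self.class_fraction_ad < 1.0):
            raise ValueError("class_fraction_ad must be in (0,1)")
        if any(s < 1 for s in self.volume_shape):
            raise ValueError(f"invalid volume shape {self.volume_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.noise_sd < 0 or self.background_smoothness_mm < 0:
            raise ValueError("noise_sd and background_smoothness_mm must be nonnegative")
        if not (0.0 <= self.heterogeneity_fraction <= 1.0):
            raise ValueError("heterogeneity_fraction must be in [0,1]")
        if self.jitter_voxels < 0 or self.jitter_voxels > 1.0:
            raise ValueError("jitter amplitude is limited to <= 1 voxel")
        for i, site in enumerate(self.atrophy_sites):
            # the sphere must intersect the volume box
            gap = 0.0
            for c, extent in zip(site.center, self.volume_shape):
                d = max(-c, c - (extent - 1), 0)
                gap += d * d
            if math.sqrt(gap) > site.radius:
                raise ValueError(
                    f"atrophy site {i} (center {site.center}, radius {site.radius}) "
                    f"lies wholly outside the volume {self.volume_shape}"
                )

    @property
    def n_ad(self) -> int:
        return int(round(self.n_subjects * self.class_fraction_ad))


@dataclass
class SubjectRecord:
    """One subject: id, diagnostic label, volume location, split assignment."""

    subject_id: str
    label: str
    volume_path: str = ""
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")


def build_template(config: CohortConfig) -> np.ndarray:
    """The shared smooth pseudo-anatomy, intensities in [0, 1].

    A broad central ellipsoidal mass plus a handful of low-frequency bumps,
    smoothed with a Gaussian of FWHM ``background_smoothness_mm``. Drawn from
    a fixed internal seed so the "anatomy" is stable across cohorts and
    seeds; per-subject variability enters only through jitter and noise.
    """
    shape = config.volume_shape
    rng = np.random.default_rng(_TEMPLATE_SEED)
    grids = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"
    )
    center = [(s - 1) / 2.0 for s in shape]
    # central mass occupying most of the box
    q = sum(((g - c) / (0.38 * s)) ** 2 for g, c, s in zip(grids, center, shape))
    template = 0.75 * np.exp(-q)
    for _ in range(6):
        frac_center = rng.uniform(0.25, 0.75, size=3)
        widths = rng.uniform(0.10, 0.22, size=3)
        amp = rng.uniform(0.15, 0.4)
        q = sum(
            ((g - fc * s) / (w * s)) ** 2
            for g, fc, w, s in zip(grids, frac_center, widths, shape)
        )
        template += amp * np.exp(-q)
    if config.background_smoothness_mm > 0:
        sigma = fwhm_to_sigma_voxels(config.background_smoothness_mm, config.voxel_size_mm)
        template = ndimage.gaussian_filter(template, sigma=sigma, mode="reflect")
    template /= template.max()
    return template.astype(np.float64)


def _site_weight(shape: Sequence[int], site: AtrophySite) -> np.ndarray:
    """Soft sphere indicator: 1 deep inside, 0 outside, 2-voxel linear edge."""
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, site.center)))
    return np.clip((site.radius + 1.0 - d) / 2.0, 0.0, 1.0)


def generate_cohort_arrays(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], dict[str, Volume]]:
    """Generate the cohort in memory: records plus subject_id → Volume.

    AD volumes have intensity inside each non-spared site sphere reduced by
    the factor (1−δ) relative to the shared template, before noise.
    Deterministic given the config.
    """
    template = build_template(config)
    site_weights = [_site_weight(config.volume_shape, s) for s in config.atrophy_sites]
    n_ad = config.n_ad
    labels = ["AD"] * n_ad + ["CN"] * (config.n_subjects - n_ad)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0F0)))
    n_spared = int(round(config.heterogeneity_fraction * n_ad))
    spared_idx = set(rng.choice(n_ad, size=n_spared, replace=False).tolist()) if n_ad else set()
    upper = 1.0 + 5.0 * config.noise_sd

    records: list[SubjectRecord] = []
    volumes: dict[str, Volume] = {}
    ad_seen = 0
    for i, label in enumerate(labels):
        vol = template
        if config.jitter_voxels > 0:
            shift = rng.uniform(-config.jitter_voxels, config.jitter_voxels, size=3)
            vol = ndimage.shift(vol, shift, order=1, mode="nearest")
        if label == "AD":
            spared_first = ad_seen in spared_idx
            ad_seen += 1
            factor = np.ones_like(vol)
            for j, (site, w) in enumerate(zip(config.atrophy_sites, site_weights)):
                if j == 0 and spared_first:
                    continue
                factor *= 1.0 - site.delta * w
            vol = vol * factor
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, size=vol.shape)
        vol = np.clip(vol, 0.0, upper)
        sid = f"sub{i:04d}"
        records.append(SubjectRecord(subject_id=sid, label=label))
        volumes[sid] = Volume(
            data=vol.astype(np.float32), voxel_size_mm=(config.voxel_size_mm,) * 3
        )
    return records, volumes


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> list[SubjectRecord]:
    """Generate and write the cohort: NIfTI volumes plus ``cohort.csv``.

    Returns the subject records with ``volume_path`` filled in. Byte-identical
    output for identical configurations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, volumes = generate_cohort_arrays(config)
    for rec in records:
        path = out_dir / f"{rec.subject_id}.nii.gz"
        save_volume(volumes[rec.subject_id], path)
        rec.volume_path = str(path)
    write_cohort_table(records, out_dir / "cohort.csv")
    return records


def write_cohort_table(records: Sequence[SubjectRecord], path: str | Path) -> Path:
    """Write records as a headered CSV (subject_id,label,volume_path,split)."""
    if not records:
        raise ValueError("cannot write an empty cohort table")
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate subject_id {dup!r} in cohort")
    df = pd.DataFrame(
        {
            "subject_id": ids,
            "label": [r.label for r in records],
            "volume_path": [r.volume_path for r in records],
            "split": [r.split for r in records],
        }
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_cohort_table(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV back into records; parse errors name the row."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"subject_id", "label", "volume_path", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table {path} missing columns {sorted(missing)}")
    records: list[SubjectRecord] = []
    seen: set[str] = set()
    for row_idx, row in df.iterrows():
        sid = row["subject_id"]
        if not sid:
            raise ValueError(f"row {row_idx}: empty subject_id")
        if sid in seen:
            raise ValueError(f"row {row_idx}: duplicate subject_id {sid!r}")
        seen.add(sid)
        try:
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    label=row["label"],
                    volume_path=row["volume_path"],
                    split=row["split"] or "unassigned",
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {row_idx}: {exc}") from exc
    return records


def load_cohort_volumes(
    records: Sequence[SubjectRecord],
) -> Mapping[str, Volume]:
    """Load each record's NIfTI volume; errors name the subject."""
    from .volume import load_volume

    out = {}
    for rec in records:
        if not rec.volume_path or not Path(rec.volume_path).exists():
            raise FileNotFoundError(
                f"volume file missing for subject {rec.subject_id!r}: {rec.volume_path!r}"
            )
        out[rec.subject_id] = load_volume(rec.volume_path)
    return out
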