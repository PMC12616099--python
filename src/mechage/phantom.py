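"""Synthetic mechanical phantom generator.

Produces age-dependent multi-channel stiffness/damping (and optionally
T1-like) volumes with the statistical structure the modelling pipeline
assumes: a spherical head support, ten disjoint subcortical-analogue
regions plus WM/GM shells, linear percent-per-year global ageing trends,
voxel-level Gaussian noise, a multiplicative between-subject offset, and
disease cohorts realised as regional "effective age" shifts.

Defaults encode the study conditions the pipeline targets: ages uniform on
14-90 years, whole-brain stiffness declining at 0.33 %/yr and damping ratio
rising at 0.34 %/yr.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import write_atlas, write_manifest, write_volume
from .types import (
    Cohort,
    GM_LABEL,
    MechanicalMap,
    Modality,
    MultiChannelVolume,
    RegionAtlas,
    SUBCORTICAL_REGIONS,
    SubjectRecord,
    WM_LABEL,
)

__all__ = ["RegionSpec", "PhantomConfig", "generate_atlas", "generate_cohort",
           "write_phantom_dataset", "WHOLE_BRAIN"]

#: pseudo-region name accepted in ``disease_spec``: the effective-age offset
#: applies to every in-brain voxel.
WHOLE_BRAIN = "whole_brain"


@dataclass
class RegionSpec:
    """One spherical region: centre offset (voxels, from grid centre, at the
    reference 32-voxel grid scale), radius (voxels at that scale), and an
    additional regional ageing slope in % per year on top of the global one."""

    name: str
    centre: tuple[float, float, float]
    radius: float
    extra_slope_pct: float = 0.0


def default_region_spec() -> list[RegionSpec]:
    # Centres/radii are laid out inside a radius-15 spherical head support
    # (reference grid 32^3) so that regions are pairwise disjoint and the
    # voxel counts are ordered like the real anatomy: cerebellum largest,
    # nucleus accumbens smallest.
    geom = {
        "cerebellum": ((0, -6, -6), 5.0),
        "brain_stem": ((0, 6, -7), 4.2),
        "thalamus": ((0, 0, 2), 3.6),
        "putamen": ((8, 0, -1), 3.3),
        "caudate": ((-8, 0, -1), 3.15),
        "hippocampus": ((6, -5, 5), 3.0),
        "ventral_dc": ((0, 4, 9), 2.9),
        "amygdala": ((-6, -5, 5), 2.75),
        "pallidum": ((0, -9, 4), 2.6),
        "accumbens": ((0, 9, 3), 2.4),
    }
    return [RegionSpec(name, *geom[name]) for name in SUBCORTICAL_REGIONS]


def default_disease_spec() -> dict[str, list[tuple[str, float]]]:
    # MCI: early hippocampal involvement; AD: pronounced thalamic effect.
    return {"MCI": [("hippocampus", 15.0)], "AD": [("thalamus", 30.0)]}


@dataclass
class PhantomConfig:
    """Generative parameters of the phantom cohort.

    Slopes are percent of the mid-cohort baseline per year; noise and
    subject-offset scales are fractions of each channel's baseline.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_subjects: int = 100
    age_range: tuple[float, float] = (14.0, 90.0)
    stiffness_baseline: float = 3.0
    stiffness_slope_pct: float = -0.33
    damping_baseline: float = 0.20
    damping_slope_pct: float = +0.34
    t1_baseline: float = 1.0
    t1_slope_pct: float = -0.05
    include_t1: bool = False
    noise_sd_frac: float = 0.05
    subject_offset_sd_frac: float = 0.02
    region_spec: list[RegionSpec] = field(default_factory=default_region_spec)
    disease_spec: dict[str, list[tuple[str, float]]] = field(
        default_factory=default_disease_spec)
    age_ref_years: float | None = None  # default: midpoint of age_range
    seed: int = 0

    @property
    def age_ref(self) -> float:
        if self.age_ref_years is not None:
            return self.age_ref_years
        return 0.5 * (self.age_range[0] + self.age_range[1])

    @property
    def scale(self) -> float:
        """Geometry scale factor relative to the reference 32-voxel grid."""
        return min(self.grid_shape) / 32.0


def _grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    return np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape),
                       indexing="ij")


def _support_mask(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Spherical head support and normalised radius grid."""
    shape = cfg.grid_shape
    centre = [(s - 1) / 2.0 for s in shape]
    xs, ys, zs = _grids(shape)
    r = np.sqrt((xs - centre[0]) ** 2 + (ys - centre[1]) ** 2 + (zs - centre[2]) ** 2)
    radius = 15.0 * cfg.scale
    return r <= radius, r / radius


def generate_atlas(cfg: PhantomConfig) -> RegionAtlas:
    """Build the region atlas for the configured grid.

    Labels 1-10 are the subcortical analogues in :data:`SUBCORTICAL_REGIONS`
    order; the remaining head foreground is split into a deep WM core
    (label 11) and an outer GM shell (label 12) by a radial threshold.
    """
    if not cfg.region_spec:
        raise ValueError("region_spec must be nonempty")
    support, rho = _support_mask(cfg)
    shape = cfg.grid_shape
    centre = [(s - 1) / 2.0 for s in shape]
    xs, ys, zs = _grids(shape)
    labels = np.zeros(shape, dtype=np.int16)
    masks = {}
    for i, spec in enumerate(cfg.region_spec, start=1):
        c = [centre[a] + spec.centre[a] * cfg.scale for a in range(3)]
        d2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2 + (zs - c[2]) ** 2
        m = (d2 <= (spec.radius * cfg.scale) ** 2) & support
        masks[spec.name] = m
    for (na, ma), (nb, mb) in itertools.combinations(masks.items(), 2):
        if np.any(ma & mb):
            raise ValueError(f"overlapping regions: {na} and {nb}")
    for i, spec in enumerate(cfg.region_spec, start=1):
        labels[masks[spec.name]] = i
    rest = support & (labels == 0)
    labels[rest & (rho <= 0.7)] = WM_LABEL
    labels[rest & (rho > 0.7)] = GM_LABEL
    name_map = {i: s.name for i, s in enumerate(cfg.region_spec, start=1)}
    name_map[WM_LABEL] = "white_matter"
    name_map[GM_LABEL] = "grey_matter"
    return RegionAtlas(labels=labels, name_map=name_map)


_CHANNEL_PARAMS = {
    Modality.STIFFNESS: ("stiffness_baseline", "stiffness_slope_pct"),
    Modality.DAMPING: ("damping_baseline", "damping_slope_pct"),
    Modality.T1_LIKE: ("t1_baseline", "t1_slope_pct"),
}

_COHORT_STREAM = {Cohort.HC: 0, Cohort.MCI: 1, Cohort.AD: 2}


def _effective_age_grid(cfg: PhantomConfig, atlas: RegionAtlas, age: float,
                        cohort: Cohort, shape) -> np.ndarray | float:
    if cohort is Cohort.HC:
        return age
    entries = cfg.disease_spec.get(cohort.value, [])
    if not entries:
        return age
    grid = np.full(shape, age, dtype=np.float64)
    for region, offset in entries:
        if region == WHOLE_BRAIN:
            grid += offset
        else:
            grid[atlas.region_mask(atlas.label_of(region))] += offset
    return grid


def generate_cohort(cfg: PhantomConfig, cohort: Cohort | str = Cohort.HC,
                    atlas: RegionAtlas | None = None
                    ) -> tuple[list[MultiChannelVolume], list[SubjectRecord]]:
    """Draw ``cfg.n_subjects`` phantom subjects for one cohort.

    Per subject and channel the in-brain value at a voxel is

        baseline * (1 + slope/100 * (age_eff - age_ref)) * (1 + b)  +  eps

    where ``age_eff`` equals the chronological age except inside regions
    carrying a disease offset, ``b ~ N(0, subject_offset_sd_frac)`` is a
    per-(subject, channel) multiplicative offset, and
    ``eps ~ N(0, noise_sd_frac * baseline)`` i.i.d. per voxel. Regional
    ``extra_slope_pct`` values add to the global slope inside their region.
    Fully deterministic given ``cfg.seed`` and the cohort.
    """
    cohort = Cohort(cohort)
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if atlas is None:
        atlas = generate_atlas(cfg)
    support = atlas.labels > 0
    rng = np.random.default_rng([cfg.seed % (2 ** 31), _COHORT_STREAM[cohort]])
    ages = rng.uniform(*cfg.age_range, size=cfg.n_subjects)
    modalities = [Modality.STIFFNESS, Modality.DAMPING]
    if cfg.include_t1:
        modalities.append(Modality.T1_LIKE)
    extra_slope = np.zeros(cfg.grid_shape)
    for i, spec in enumerate(cfg.region_spec, start=1):
        if spec.extra_slope_pct:
            extra_slope[atlas.region_mask(i)] = spec.extra_slope_pct
    volumes, records = [], []
    for s in range(cfg.n_subjects):
        age = float(ages[s])
        age_eff = _effective_age_grid(cfg, atlas, age, cohort, cfg.grid_shape)
        chans = []
        for mod in modalities:
            bname, sname = _CHANNEL_PARAMS[mod]
            base = getattr(cfg, bname)
            slope = getattr(cfg, sname)
            offset = rng.normal(0.0, cfg.subject_offset_sd_frac)
            trend = 1.0 + (slope + extra_slope) / 100.0 * (age_eff - cfg.age_ref)
            vals = base * trend * (1.0 + offset)
            noise = rng.normal(0.0, cfg.noise_sd_frac * base, size=cfg.grid_shape)
            vals = np.where(support, vals + noise, 0.0)
            m = MechanicalMap.__new__(MechanicalMap)  # phantom values may graze bounds
            m.values = vals
            m.modality = mod
            m.voxel_size = (1.0, 1.0, 1.0)
            m.brain_mask = support.copy()
            chans.append(m)
        sid = f"{cohort.value}{s:04d}"
        volumes.append(MultiChannelVolume(subject_id=sid, channels=chans))
        records.append(SubjectRecord(subject_id=sid, age=age, cohort=cohort,
                                     study_id="phantom"))
    return volumes, records


def write_phantom_dataset(volumes: Sequence[MultiChannelVolume],
                          records: Sequence[SubjectRecord],
                          atlas: RegionAtlas, out_dir: str | Path) -> Path:
    """Write NIfTI channels, the atlas and a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recs = []
    for vol, rec in zip(volumes, records):
        paths = {}
        for ch in vol.channels:
            p = out / f"{vol.subject_id}_{ch.modality.value}.nii.gz"
            write_volume(ch, p)
            paths[ch.modality.value] = str(p)
        recs.append(SubjectRecord(subject_id=rec.subject_id, age=rec.age,
                                  cohort=rec.cohort, study_id=rec.study_id,
                                  channel_paths=paths))
    write_atlas(atlas, out / "atlas.nii.gz")
    manifest = out / "manifest.csv"
    write_manifest(recs, manifest, relative_to=out)
    return manifest
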