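"""Per-region brain-age models, cohort BAG profiles and profile matching.

Each region gets its own encoder + ridge pipeline trained on the region's
voxels only: volumes are masked to the region, cropped to the region's
bounding box and zero-padded to a small cube, which keeps encoder inputs
compact and guarantees that voxels outside the region cannot influence the
regional prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contrastive import KernelConfig, NeighbourhoodSchedule
from .data import extract_region
from .encoder import EncoderConfig, TrainConfig
from .predictor import AgePredictor, train_age_predictor
from .types import MechanicalMap, MultiChannelVolume, RegionAtlas

__all__ = ["BAGProfile", "RegionalPredictor", "train_regional_models",
           "predict_regional", "cohort_profile", "subject_profile",
           "profile_similarity", "WHOLE_BRAIN_REGION"]

WHOLE_BRAIN_REGION = "whole_brain"
MIN_REGION_VOXELS = 50


@dataclass
class BAGProfile:
    """Corrected BAG per region, for one subject or a cohort mean."""

    region_names: list[str]
    values: np.ndarray
    level: str  # "subject" or "cohort_mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.region_names) != self.values.size:
            raise ValueError("region names and values must match")


def _bounding_box(mask: np.ndarray, min_size: int = 8) -> tuple[slice, ...]:
    """Bounding box of a mask, symmetrically grown to at least ``min_size``
    per axis (clipped at the grid edges)."""
    idx = np.nonzero(mask)
    slices = []
    for ax in range(3):
        lo, hi = int(idx[ax].min()), int(idx[ax].max()) + 1
        size = hi - lo
        if size < min_size:
            extra = min_size - size
            lo = max(0, lo - extra // 2)
            hi = min(mask.shape[ax], lo + min_size)
            lo = max(0, hi - min_size)
        slices.append(slice(lo, hi))
    return tuple(slices)


def _crop_volume(vol: MultiChannelVolume, box: tuple[slice, ...]) -> MultiChannelVolume:
    chans = []
    for ch in vol.channels:
        m = MechanicalMap.__new__(MechanicalMap)
        m.values = ch.values[box]
        m.modality = ch.modality
        m.voxel_size = ch.voxel_size
        m.brain_mask = ch.brain_mask[box]
        chans.append(m)
    return MultiChannelVolume(vol.subject_id, chans)


@dataclass
class RegionalPredictor:
    predictor: AgePredictor
    region: str
    label: int | None  # None for whole brain
    box: tuple[slice, ...] | None

    def predict(self, volumes: Sequence[MultiChannelVolume],
                atlas: RegionAtlas | None) -> np.ndarray:
        vols = _region_inputs(volumes, atlas, self.label, self.box)
        return self.predictor.predict(vols)


def _region_inputs(volumes: Sequence[MultiChannelVolume],
                   atlas: RegionAtlas | None, label: int | None,
                   box: tuple[slice, ...] | None) -> list[MultiChannelVolume]:
    if label is None:
        return list(volumes)
    masked = [extract_region(v, atlas, label) for v in volumes]
    return [_crop_volume(v, box) for v in masked]


def train_regional_models(volumes: Sequence[MultiChannelVolume],
                          ages: np.ndarray, atlas: RegionAtlas,
                          regions: Sequence[str],
                          ecfg: EncoderConfig, tcfg: TrainConfig,
                          kcfg: KernelConfig | None = None,
                          schedule: NeighbourhoodSchedule | None = None,
                          lam: float = 1.0,
                          min_voxels: int = MIN_REGION_VOXELS
                          ) -> dict[str, RegionalPredictor]:
    """Train one encoder+ridge pipeline per requested region.

    ``regions`` may contain atlas region names plus ``"whole_brain"``.
    """
    out: dict[str, RegionalPredictor] = {}
    for region in regions:
        if region == WHOLE_BRAIN_REGION:
            label, box = None, None
        else:
            label = atlas.label_of(region)
            count = atlas.voxel_count(label)
            if count < min_voxels:
                raise ValueError(
                    f"region {region} has only {count} voxels (< {min_voxels})")
            box = _bounding_box(atlas.region_mask(label))
        train_vols = _region_inputs(volumes, atlas, label, box)
        pred, _ = train_age_predictor(train_vols, ages, ecfg, tcfg, kcfg,
                                      schedule, lam=lam)
        out[region] = RegionalPredictor(predictor=pred, region=region,
                                        label=label, box=box)
    return out


def predict_regional(models: Mapping[str, RegionalPredictor],
                     volumes: Sequence[MultiChannelVolume],
                     atlas: RegionAtlas | None) -> pd.DataFrame:
    """Long-format table of per-region predictions for each subject."""
    rows = []
    for region, rp in models.items():
        preds = rp.predict(volumes, atlas)
        for v, p in zip(volumes, preds):
            rows.append({"subject_id": v.subject_id, "region": region,
                         "predicted_age": float(p)})
    return pd.DataFrame(rows)


def _profile_table(bag_df: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "cohort", "region", "corrected_bag"}
    missing = required - set(bag_df.columns)
    if missing:
        raise ValueError(f"BAG table missing columns: {sorted(missing)}")
    pivot = bag_df.pivot_table(index="subject_id", columns="region",
                               values="corrected_bag", aggfunc="first")
    if pivot.isna().any().any():
        bad = pivot.columns[pivot.isna().any()].tolist()
        raise ValueError(f"missing region values for some subjects: {bad}")
    return pivot


def cohort_profile(bag_df: pd.DataFrame, cohort: str,
                   region_order: Sequence[str] | None = None) -> BAGProfile:
    """Mean corrected BAG per region over the cohort's members."""
    sub = bag_df[bag_df["cohort"] == cohort]
    if sub.empty:
        raise ValueError(f"no subjects with cohort {cohort!r}")
    pivot = _profile_table(sub)
    regions = list(region_order) if region_order else sorted(pivot.columns)
    return BAGProfile(region_names=regions,
                      values=pivot[regions].mean(axis=0).to_numpy(),
                      level="cohort_mean")


def subject_profile(bag_df: pd.DataFrame, subject_id: str,
                    region_order: Sequence[str] | None = None) -> BAGProfile:
    sub = bag_df[bag_df["subject_id"] == subject_id]
    if sub.empty:
        raise ValueError(f"no rows for subject {subject_id!r}")
    pivot = _profile_table(sub)
    regions = list(region_order) if region_order else sorted(pivot.columns)
    return BAGProfile(region_names=regions,
                      values=pivot[regions].iloc[0].to_numpy(), level="subject")


def profile_similarity(individual: BAGProfile, cohort: BAGProfile,
                       metric: str = "pearson") -> float:
    """Similarity in [-1, 1] between two region-ordered BAG profiles."""
    if individual.region_names != cohort.region_names:
        raise ValueError("profiles must share the same region ordering")
    x, y = individual.values, cohort.values
    if metric == "pearson":
        if x.std() == 0 or y.std() == 0:
            raise ValueError("zero-variance profile under pearson")
        return float(np.corrcoef(x, y)[0, 1])
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise ValueError("zero profile under cosine")
        return float(x @ y / (nx * ny))
    raise ValueError(f"unknown metric {metric!r}")
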