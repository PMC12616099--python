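"""Core domain types: subjects, mechanical maps, atlases and dataset splits.

All volumetric data live in voxel space, axis order (x, y, z) as stored,
0-based indices. Registration to a template is assumed to have happened
upstream (or to be irrelevant, as for phantom data).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Cohort",
    "Modality",
    "SubjectRecord",
    "MechanicalMap",
    "MultiChannelVolume",
    "RegionAtlas",
    "DatasetSplit",
    "SUBCORTICAL_REGIONS",
    "WM_LABEL",
    "GM_LABEL",
]


class Cohort(str, Enum):
    """Clinical group label: healthy control, mild cognitive impairment, Alzheimer's."""

    HC = "HC"
    MCI = "MCI"
    AD = "AD"


class Modality(str, Enum):
    """Channel type of a volumetric map.

    ``stiffness_mu`` and ``damping_xi`` are the two MRE-derived viscoelastic
    properties; ``t1_like`` stands for a conventional anatomical MRI channel.
    """

    STIFFNESS = "stiffness_mu"
    DAMPING = "damping_xi"
    T1_LIKE = "t1_like"


#: Canonical ordering of the ten subcortical structures used for regional
#: modelling, plus white and grey matter. Atlas integer labels are the
#: 1-based positions in this list.
SUBCORTICAL_REGIONS: tuple[str, ...] = (
    "cerebellum",
    "brain_stem",
    "thalamus",
    "putamen",
    "caudate",
    "hippocampus",
    "ventral_dc",
    "amygdala",
    "pallidum",
    "accumbens",
)

WM_LABEL = 11
GM_LABEL = 12


@dataclass
class SubjectRecord:
    """One row of the study manifest."""

    subject_id: str
    age: float
    cohort: Cohort
    study_id: str
    channel_paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(f"age must be a positive real, got {self.age!r}")
        self.cohort = Cohort(self.cohort)


# value ranges enforced inside the brain mask
_DAMPING_RANGE = (0.0, 1.5)


@dataclass
class MechanicalMap:
    """A single 3D channel for one subject.

    Parameters
    ----------
    values
        3D array of property values; zero outside the head by convention.
    modality
        Which physical quantity the grid holds.
    voxel_size
        Edge lengths in mm.
    brain_mask
        Boolean grid of in-brain voxels, same shape as ``values``.
    """

    values: np.ndarray
    modality: Modality
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        self.modality = Modality(self.modality)
        if self.brain_mask is None:
            self.brain_mask = self.values > 0
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        self.validate()

    def validate(self) -> None:
        inside = self.values[self.brain_mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("non-finite values inside brain mask")
        if self.modality is Modality.STIFFNESS and inside.size and inside.min() <= 0:
            raise ValueError("stiffness values must be positive inside mask")
        if self.modality is Modality.DAMPING and inside.size:
            lo, hi = _DAMPING_RANGE
            if inside.min() < lo or inside.max() > hi:
                raise ValueError(f"damping values must lie in [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class MultiChannelVolume:
    """All channels of one subject on a shared grid with a shared mask."""

    subject_id: str
    channels: list[MechanicalMap]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("need at least one channel")
        shape = self.channels[0].shape
        mask = self.channels[0].brain_mask
        for ch in self.channels[1:]:
            if ch.shape != shape:
                raise ValueError("all channels must share one grid")
            if not np.array_equal(ch.brain_mask, mask):
                raise ValueError("all channels must share one brain mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.channels[0].shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.channels[0].brain_mask

    @property
    def modalities(self) -> list[Modality]:
        return [ch.modality for ch in self.channels]

    def stacked(self) -> np.ndarray:
        """Channel-first array of shape (C, X, Y, Z)."""
        return np.stack([ch.values for ch in self.channels])


@dataclass
class RegionAtlas:
    """Integer-labelled parcellation; 0 is background."""

    labels: np.ndarray
    name_map: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.name_map)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        if 0 in self.name_map:
            raise ValueError("label 0 is reserved for background")

    def label_of(self, name: str) -> int:
        for lab, nm in self.name_map.items():
            if nm == name:
                return lab
        raise KeyError(f"region {name!r} not in atlas")

    def region_mask(self, label: int) -> np.ndarray:
        if label == 0:
            raise ValueError("label 0 is background, not a region")
        if label not in self.name_map:
            raise ValueError(f"label {label} absent from atlas")
        return self.labels == label

    def voxel_count(self, label: int) -> int:
        return int(self.region_mask(label).sum())


@dataclass
class DatasetSplit:
    """Disjoint train/test partition of healthy subject ids."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    train_fraction: float = 0.8

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def stack_dataset(volumes: Sequence[MultiChannelVolume]) -> np.ndarray:
    """Stack a list of subjects into an (N, C, X, Y, Z) float32 array."""
    return np.stack([v.stacked() for v in volumes]).astype(np.float32)
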