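"""Dataset splitting, per-image normalisation and region extraction."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import (
    Cohort,
    DatasetSplit,
    MechanicalMap,
    MultiChannelVolume,
    RegionAtlas,
    SubjectRecord,
)

__all__ = ["split_dataset", "normalize_per_image", "extract_region"]


def split_dataset(records: Sequence[SubjectRecord], fraction: float = 0.8,
                  seed: int = 0, stratify_by_age: bool = False,
                  n_strata: int = 5) -> DatasetSplit:
    """Seeded train/test split of healthy subjects.

    The default is a plain shuffle; ``stratify_by_age`` draws the split
    within age-quantile strata instead so both halves cover the age range.
    """
    if any(r.cohort is not Cohort.HC for r in records):
        raise ValueError("split_dataset expects healthy controls only")
    n = len(records)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.array([r.subject_id for r in records])
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    if stratify_by_age:
        ages = np.array([r.age for r in records])
        edges = np.quantile(ages, np.linspace(0, 1, n_strata + 1))
        strata = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, n_strata - 1)
        train_idx: list[int] = []
        for s in range(n_strata):
            idx = np.flatnonzero(strata == s)
            rng.shuffle(idx)
            k = int(round(fraction * idx.size))
            train_idx.extend(idx[:k].tolist())
        # adjust to the global target count deterministically
        rest = [i for i in rng.permutation(n) if i not in set(train_idx)]
        while len(train_idx) < n_train:
            train_idx.append(rest.pop(0))
        while len(train_idx) > n_train:
            train_idx.pop()
        train = set(train_idx)
    else:
        perm = rng.permutation(n)
        train = set(perm[:n_train].tolist())
    train_ids = [str(i) for i in ids[sorted(train)]]
    test_ids = [str(i) for i in ids[sorted(set(range(n)) - train)]]
    return DatasetSplit(train_ids=train_ids, test_ids=test_ids, seed=seed,
                        train_fraction=fraction)


def normalize_per_image(vol: MechanicalMap) -> MechanicalMap:
    """Z-score a map within its brain mask; background stays zero.

    Removes the subject-level global offset (and with it, global ageing
    trends), leaving only the spatial pattern. Idempotent and invariant to
    affine rescaling of the input.
    """
    mask = vol.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    inside = vol.values[mask]
    sd = inside.std()
    if sd == 0:
        raise ValueError("constant image: cannot normalise zero variance")
    out = np.zeros_like(vol.values)
    out[mask] = (inside - inside.mean()) / sd
    # bypass the physical-range validation: normalised values are z-scores
    new = MechanicalMap.__new__(MechanicalMap)
    new.values = out
    new.modality = vol.modality
    new.voxel_size = vol.voxel_size
    new.brain_mask = mask.copy()
    return new


def extract_region(volume: MultiChannelVolume, atlas: RegionAtlas,
                   label: int) -> MultiChannelVolume:
    """Restrict a subject's channels to one atlas region.

    The returned volume's mask is the intersection of the brain mask with
    ``atlas == label``; values outside it are zeroed.
    """
    if atlas.labels.shape != volume.shape:
        raise ValueError("atlas grid does not match volume grid")
    region = atlas.region_mask(label)
    new_mask = volume.brain_mask & region
    chans = []
    for ch in volume.channels:
        vals = np.where(new_mask, ch.values, 0.0)
        new = MechanicalMap.__new__(MechanicalMap)
        new.values = vals
        new.modality = ch.modality
        new.voxel_size = ch.voxel_size
        new.brain_mask = new_mask
        chans.append(new)
    return MultiChannelVolume(subject_id=volume.subject_id, channels=chans)
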