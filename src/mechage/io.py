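"""NIfTI and manifest I/O.

Volumes are stored as NIfTI-1 (via nibabel) in float32; the brain mask is
written to a ``<stem>_mask.nii.gz`` sidecar so that masks that are not simply
``values > 0`` survive a round trip. Manifests are plain CSV with columns
``subject_id, age, cohort, study_id`` plus one ``<modality>_path`` column per
channel.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .types import Cohort, MechanicalMap, Modality, SubjectRecord, RegionAtlas, MultiChannelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "load_manifest",
    "write_manifest",
    "read_atlas",
    "write_atlas",
    "load_subject_volumes",
]

MANIFEST_COLUMNS = ("subject_id", "age", "cohort", "study_id")


def _mask_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + "_mask" + suf)
    raise ValueError(f"not a NIfTI path: {path}")


def read_volume(path: str | os.PathLike, modality: Modality | str) -> MechanicalMap:
    """Load a 3D NIfTI volume as a :class:`MechanicalMap`.

    The brain mask defaults to strictly positive voxels unless a
    ``_mask`` sidecar file sits next to ``path``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D")
    data = np.asarray(data, dtype=np.float64)
    if not np.any(np.isfinite(data)):
        raise ValueError("volume contains no finite voxels")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask_file = _mask_path(path)
    if mask_file.exists():
        mask = np.asanyarray(nib.load(str(mask_file)).dataobj) > 0
    else:
        mask = data > 0
    return MechanicalMap(values=data, modality=Modality(modality),
                         voxel_size=voxel_size, brain_mask=mask)


def write_volume(vol: MechanicalMap, path: str | os.PathLike) -> None:
    """Write a map (and its mask sidecar) as float32 NIfTI-1."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(vol.voxel_size) + [1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))
    mimg = nib.Nifti1Image(vol.brain_mask.astype(np.uint8), affine)
    nib.save(mimg, str(_mask_path(path)))


def write_atlas(atlas: RegionAtlas, path: str | os.PathLike,
                voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), str(path))
    # name map sidecar: "<label>,<name>" lines
    names = Path(str(path).split(".nii")[0] + "_labels.csv")
    pd.DataFrame(sorted(atlas.name_map.items()),
                 columns=["label", "name"]).to_csv(names, index=False)


def read_atlas(path: str | os.PathLike) -> RegionAtlas:
    labels = np.asanyarray(nib.load(str(path)).dataobj).astype(np.int32)
    names = Path(str(path).split(".nii")[0] + "_labels.csv")
    name_map = {}
    if names.exists():
        df = pd.read_csv(names)
        name_map = {int(r.label): str(r.name) for r in df.itertuples()}
    else:
        name_map = {int(l): f"region_{int(l)}" for l in np.unique(labels) if l != 0}
    return RegionAtlas(labels=labels, name_map=name_map)


def load_manifest(path: str | os.PathLike) -> list[SubjectRecord]:
    """Read a manifest CSV into validated subject records."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    path_cols = [c for c in df.columns if c.endswith("_path")]
    records = []
    root = Path(path).parent
    for row in df.itertuples():
        cohort = str(row.cohort)
        if cohort not in Cohort.__members__:
            raise ValueError(f"unknown cohort {cohort!r}")
        paths = {}
        for c in path_cols:
            val = getattr(row, c)
            if isinstance(val, str) and val:
                p = Path(val)
                paths[c[: -len("_path")]] = str(p if p.is_absolute() else root / p)
        records.append(SubjectRecord(subject_id=str(row.subject_id), age=float(row.age),
                                     cohort=Cohort(cohort), study_id=str(row.study_id),
                                     channel_paths=paths))
    return records


def write_manifest(records: Sequence[SubjectRecord], path: str | os.PathLike,
                   relative_to: str | os.PathLike | None = None) -> None:
    modalities: list[str] = []
    for r in records:
        for m in r.channel_paths:
            if m not in modalities:
                modalities.append(m)
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "age": repr(float(r.age)),
               "cohort": r.cohort.value, "study_id": r.study_id}
        for m in modalities:
            p = r.channel_paths.get(m, "")
            if p and relative_to is not None:
                p = os.path.relpath(p, relative_to)
            row[f"{m}_path"] = p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_subject_volumes(records: Sequence[SubjectRecord],
                         modalities: Sequence[Modality | str] | None = None
                         ) -> list[MultiChannelVolume]:
    """Load each record's channels (optionally a subset, in the given order)."""
    out = []
    for r in records:
        names = [Modality(m).value for m in modalities] if modalities else list(r.channel_paths)
        chans = []
        for name in names:
            if name not in r.channel_paths:
                raise KeyError(f"subject {r.subject_id} has no {name} channel")
            chans.append(read_volume(r.channel_paths[name], Modality(name)))
        out.append(MultiChannelVolume(subject_id=r.subject_id, channels=chans))
    return out
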