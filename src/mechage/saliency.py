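"""Occlusion-based saliency: error increase from masking cubic sub-volumes.

For every position of a ``cube_size``-voxel cube on a stride grid, the cube
is filled (all channels) with zero or the channel's training mean, the age
prediction is recomputed, and the change in absolute error relative to the
unoccluded prediction is recorded. Per-subject maps are averaged within
quantile age bins and min-max normalised per bin for group-level display:
regions whose occlusion hurts most are the most influential.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .predictor import AgePredictor
from .types import MechanicalMap, MultiChannelVolume

__all__ = ["SaliencyConfig", "SaliencyMap", "occlusion_saliency",
           "bin_and_normalize", "saliency_table", "write_saliency_niftis"]


@dataclass
class SaliencyConfig:
    cube_size: int = 7
    stride: int | None = None  # default: non-overlapping (= cube_size)
    fill_mode: str = "zero"  # or "training_mean"
    n_age_bins: int = 5

    def __post_init__(self) -> None:
        if self.cube_size % 2 == 0:
            raise ValueError("cube_size must be odd")
        if self.stride is None:
            self.stride = self.cube_size
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.fill_mode not in ("zero", "training_mean"):
            raise ValueError(f"unknown fill_mode {self.fill_mode!r}")


@dataclass
class SaliencyMap:
    """One grid of mean delta-error per age bin, at occlusion-centre resolution."""

    delta_error: np.ndarray  # (n_bins, gx, gy, gz)
    bin_edges: np.ndarray
    normalisation: str
    cube_size: int
    stride: int


def _grid_starts(dim: int, cube: int, stride: int) -> np.ndarray:
    return np.arange(0, dim, stride)


def occlusion_saliency(predictor: AgePredictor,
                       test_volumes: Sequence[MultiChannelVolume],
                       ages: np.ndarray, cfg: SaliencyConfig) -> np.ndarray:
    """Per-subject delta-|error| maps of shape (n_subjects, gx, gy, gz)."""
    ages = np.asarray(ages, dtype=np.float64)
    if len(test_volumes) < 1:
        raise ValueError("need at least one test subject")
    shape = test_volumes[0].shape
    if any(c > d for c, d in zip((cfg.cube_size,) * 3, shape)):
        raise ValueError("occlusion cube larger than volume")
    starts = [_grid_starts(d, cfg.cube_size, cfg.stride) for d in shape]
    base_pred = predictor.predict(test_volumes)
    base_err = np.abs(base_pred - ages)
    fills = {}
    if cfg.fill_mode == "training_mean":
        for c, m in enumerate(predictor.encoder.channel_mean):
            fills[c] = float(m)
    maps = np.zeros((len(test_volumes), len(starts[0]), len(starts[1]), len(starts[2])))
    for si, vol in enumerate(test_volumes):
        occluded: list[MultiChannelVolume] = []
        for ix, x0 in enumerate(starts[0]):
            for iy, y0 in enumerate(starts[1]):
                for iz, z0 in enumerate(starts[2]):
                    chans = []
                    for c, ch in enumerate(vol.channels):
                        vals = ch.values.copy()
                        vals[x0:x0 + cfg.cube_size, y0:y0 + cfg.cube_size,
                             z0:z0 + cfg.cube_size] = fills.get(c, 0.0)
                        m = MechanicalMap.__new__(MechanicalMap)
                        m.values = vals
                        m.modality = ch.modality
                        m.voxel_size = ch.voxel_size
                        m.brain_mask = ch.brain_mask
                        chans.append(m)
                    occluded.append(MultiChannelVolume(vol.subject_id, chans))
        preds = predictor.predict(occluded)
        derr = np.abs(preds - ages[si]) - base_err[si]
        maps[si] = derr.reshape(len(starts[0]), len(starts[1]), len(starts[2]))
    return maps


def bin_and_normalize(raw_maps: np.ndarray, ages: np.ndarray,
                      cfg: SaliencyConfig) -> SaliencyMap:
    """Average per-subject maps within quantile age bins; min-max per bin."""
    ages = np.asarray(ages, dtype=np.float64)
    n = ages.size
    if n < cfg.n_age_bins:
        raise ValueError("need at least n_age_bins subjects")
    edges = np.quantile(ages, np.linspace(0, 1, cfg.n_age_bins + 1))
    assign = np.clip(np.searchsorted(edges, ages, side="right") - 1,
                     0, cfg.n_age_bins - 1)
    out = np.empty((cfg.n_age_bins,) + raw_maps.shape[1:])
    for b in range(cfg.n_age_bins):
        members = raw_maps[assign == b]
        if members.shape[0] == 0:
            raise ValueError(f"empty age bin {b}")
        mean_map = members.mean(axis=0)
        rng_ = np.ptp(mean_map)
        if rng_ == 0:
            raise ValueError(f"constant saliency map in bin {b}: zero range")
        out[b] = (mean_map - mean_map.min()) / rng_
    return SaliencyMap(delta_error=out, bin_edges=edges, normalisation="minmax",
                       cube_size=cfg.cube_size, stride=cfg.stride)


def saliency_table(smap: SaliencyMap) -> "pandas.DataFrame":
    """Long-format table of (centre index, bin, delta) for archiving as CSV."""
    import pandas as pd

    rows = []
    for b in range(smap.delta_error.shape[0]):
        grid = smap.delta_error[b]
        for idx in np.ndindex(grid.shape):
            rows.append({"ix": idx[0], "iy": idx[1], "iz": idx[2],
                         "bin": b, "delta": float(grid[idx])})
    return pd.DataFrame(rows)


def write_saliency_niftis(smap: SaliencyMap, volume_shape: tuple[int, int, int],
                          out_dir: str | Path, prefix: str = "saliency") -> list[Path]:
    """Upsample each bin's grid to the input grid (nearest-neighbour) and save."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for b in range(smap.delta_error.shape[0]):
        grid = smap.delta_error[b]
        up = np.zeros(volume_shape, dtype=np.float32)
        for ix in range(grid.shape[0]):
            for iy in range(grid.shape[1]):
                for iz in range(grid.shape[2]):
                    x0, y0, z0 = ix * smap.stride, iy * smap.stride, iz * smap.stride
                    up[x0:x0 + smap.stride, y0:y0 + smap.stride,
                       z0:z0 + smap.stride] = grid[ix, iy, iz]
        p = out_dir / f"{prefix}_bin{b}.nii.gz"
        nib.save(nib.Nifti1Image(up, np.eye(4)), str(p))
        paths.append(p)
    return paths
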