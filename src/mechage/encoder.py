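"""Contrastive training of the 3D encoder and frozen-embedding extraction.

Stage one of the two-stage framework: the encoder is optimised with the
age-adaptive contrastive loss so that subjects with similar ages end up
close in latent space. Neighbour sets are formed within each mini-batch.
Stage two (the ridge head) lives in :mod:`mechage.age_head`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .contrastive import (EmbeddingMatrix, KernelConfig, NeighbourhoodSchedule,
                          adaptnn_loss_and_grad)
from .data import normalize_per_image
from .types import MultiChannelVolume, stack_dataset

__all__ = ["EncoderConfig", "TrainConfig", "EncoderState", "train_encoder",
           "embed", "save_encoder", "load_encoder", "save_training_log"]

_ARCHITECTURES = {"small3dcnn": nn.build_small_cnn, "resnet18_3d": nn.build_resnet3d}


@dataclass
class EncoderConfig:
    in_channels: int = 2
    embedding_dim: int = 64
    width_multiplier: int = 1
    architecture: str = "small3dcnn"

    def __post_init__(self) -> None:
        if self.architecture not in _ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")

    def build(self, rng: np.random.Generator) -> nn.Sequential:
        return _ARCHITECTURES[self.architecture](
            self.in_channels, self.embedding_dim, self.width_multiplier, rng)


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimiser: str = "adam"
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.batch_size < 4:
            raise ValueError("batch_size must be >= 4 (the loss needs neighbours)")
        if self.optimiser != "adam":
            raise ValueError("only adam is implemented")


@dataclass
class EncoderState:
    """Everything needed to reproduce embeddings: weights + input statistics."""

    config: EncoderConfig
    weights: list[np.ndarray]
    channel_mean: np.ndarray  # per-channel mean over in-mask training voxels
    channel_sd: np.ndarray
    per_image_norm: bool = False


def _standardize(X: np.ndarray, masks: np.ndarray, mean: np.ndarray,
                 sd: np.ndarray) -> np.ndarray:
    """Channel-wise z-score inside the mask; background stays zero."""
    out = np.zeros_like(X)
    m = masks[:, None]  # (N, 1, X, Y, Z)
    out = np.where(m, (X - mean[None, :, None, None, None]) /
                   sd[None, :, None, None, None], 0.0)
    return out.astype(np.float32)


def _prepare(volumes: Sequence[MultiChannelVolume], per_image_norm: bool,
             mean: np.ndarray | None = None, sd: np.ndarray | None = None):
    if per_image_norm:
        volumes = [MultiChannelVolume(v.subject_id,
                                      [normalize_per_image(ch) for ch in v.channels])
                   for v in volumes]
        X = stack_dataset(volumes)
        C = X.shape[1]
        return X, np.zeros(C), np.ones(C)
    X = stack_dataset(volumes)
    masks = np.stack([v.brain_mask for v in volumes])
    if mean is None:
        C = X.shape[1]
        mean = np.empty(C)
        sd = np.empty(C)
        for c in range(C):
            vals = X[:, c][masks]
            mean[c] = vals.mean()
            sd[c] = vals.std() if vals.std() > 0 else 1.0
    return _standardize(X, masks, mean, sd), mean, sd


def train_encoder(train_volumes: Sequence[MultiChannelVolume], ages: np.ndarray,
                  ecfg: EncoderConfig, tcfg: TrainConfig,
                  kcfg: KernelConfig | None = None,
                  schedule: NeighbourhoodSchedule | None = None,
                  per_image_norm: bool = False
                  ) -> tuple[EncoderState, list[float]]:
    """Train the encoder with the adaptive contrastive loss.

    Returns the frozen state and the per-epoch mean batch loss. Deterministic
    given ``tcfg.seed`` (initialisation and batch order).
    """
    ages = np.asarray(ages, dtype=np.float64)
    n = len(train_volumes)
    if ages.size != n:
        raise ValueError("ages must match volumes")
    if tcfg.batch_size > n:
        raise ValueError(f"batch_size {tcfg.batch_size} exceeds n={n}")
    chans = train_volumes[0].stacked().shape[0]
    if any(v.stacked().shape[0] != chans for v in train_volumes):
        raise ValueError("inconsistent channel counts")
    if chans != ecfg.in_channels:
        raise ValueError(f"encoder expects {ecfg.in_channels} channels, data has {chans}")
    kcfg = kcfg or KernelConfig()
    schedule = schedule or NeighbourhoodSchedule(total_epochs=tcfg.epochs)
    if schedule.total_epochs != tcfg.epochs:
        raise ValueError("schedule.total_epochs must equal tcfg.epochs")

    X, mean, sd = _prepare(train_volumes, per_image_norm)
    rng = np.random.default_rng(tcfg.seed)
    net = ecfg.build(rng)
    opt = nn.Adam(net.params(), lr=tcfg.learning_rate)
    loss_log: list[float] = []
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n - tcfg.batch_size + 1, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            emb = net.forward(X[idx].astype(np.float64))
            loss, grad = adaptnn_loss_and_grad(emb, ages[idx], epoch, kcfg, schedule)
            net.zero_grad()
            net.backward(grad)
            opt.step()
            batch_losses.append(loss)
        loss_log.append(float(np.mean(batch_losses)))
    state = EncoderState(config=ecfg, weights=net.get_state(),
                         channel_mean=mean, channel_sd=sd,
                         per_image_norm=per_image_norm)
    return state, loss_log


def embed(state: EncoderState, volumes: Sequence[MultiChannelVolume],
          batch_size: int = 32) -> EmbeddingMatrix:
    """Frozen-encoder embeddings, L2-normalised row-wise.

    A pure function of (state, input): identical inputs give identical rows.
    """
    net = state.config.build(np.random.default_rng(0))
    net.set_state(state.weights)
    if state.per_image_norm:
        X, _, _ = _prepare(volumes, True)
    else:
        X, _, _ = _prepare(volumes, False, state.channel_mean, state.channel_sd)
    if X.shape[1] != state.config.in_channels:
        raise ValueError("channel count does not match trained encoder")
    outs = []
    for start in range(0, X.shape[0], batch_size):
        outs.append(net.forward(X[start:start + batch_size].astype(np.float64)))
    V = nn.l2_normalize(np.vstack(outs))
    return EmbeddingMatrix(vectors=V, subject_ids=[v.subject_id for v in volumes])


def save_training_log(loss_log: list[float], path: str | Path) -> None:
    """Per-epoch mean batch loss as a two-column CSV (epoch, loss)."""
    import pandas as pd

    pd.DataFrame({"epoch": range(len(loss_log)),
                  "loss": loss_log}).to_csv(path, index=False)


def save_encoder(state: EncoderState, path: str | Path) -> None:
    """Single-file .npz checkpoint."""
    arrays = {f"w{i}": w for i, w in enumerate(state.weights)}
    np.savez(path, n_weights=len(state.weights),
             channel_mean=state.channel_mean, channel_sd=state.channel_sd,
             per_image_norm=np.array(state.per_image_norm),
             in_channels=state.config.in_channels,
             embedding_dim=state.config.embedding_dim,
             width_multiplier=state.config.width_multiplier,
             architecture=np.array(state.config.architecture), **arrays)


def load_encoder(path: str | Path) -> EncoderState:
    with np.load(path, allow_pickle=False) as z:
        cfg = EncoderConfig(in_channels=int(z["in_channels"]),
                            embedding_dim=int(z["embedding_dim"]),
                            width_multiplier=int(z["width_multiplier"]),
                            architecture=str(z["architecture"]))
        weights = [z[f"w{i}"] for i in range(int(z["n_weights"]))]
        return EncoderState(config=cfg, weights=weights,
                            channel_mean=z["channel_mean"],
                            channel_sd=z["channel_sd"],
                            per_image_norm=bool(z["per_image_norm"]))
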