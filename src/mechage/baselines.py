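"""Comparator models: PCA + Gaussian-process regression and a supervised CNN.

These are the two baseline families against which the contrastive pipeline
is benchmarked in the three-way comparison harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from . import nn
from .encoder import _prepare
from .types import MultiChannelVolume

__all__ = ["BaselineConfig", "run_pca_gp", "run_supervised_cnn",
           "SupervisedCNN", "train_supervised_cnn"]


@dataclass
class BaselineConfig:
    kind: str = "pca_gp"  # or "supervised_cnn"
    n_components: int = 20
    backbone: str = "small3dcnn"
    width_multiplier: int = 1
    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pca_gp", "supervised_cnn"):
            raise ValueError(f"unknown baseline kind {self.kind!r}")


def _masked_features(volumes: Sequence[MultiChannelVolume],
                     mask: np.ndarray) -> np.ndarray:
    return np.stack([v.stacked()[:, mask].ravel() for v in volumes])


def run_pca_gp(train_volumes: Sequence[MultiChannelVolume],
               train_ages: np.ndarray,
               test_volumes: Sequence[MultiChannelVolume],
               cfg: BaselineConfig) -> np.ndarray:
    """Project flattened in-mask voxels onto principal axes, regress with a GP.

    The GP uses a stationary squared-exponential kernel with variance,
    length-scale and noise level fitted by marginal likelihood.
    """
    n_train = len(train_volumes)
    if cfg.n_components > n_train:
        raise ValueError("n_components exceeds number of training subjects")
    mask = np.logical_and.reduce([v.brain_mask for v in train_volumes])
    Xtr = _masked_features(train_volumes, mask)
    Xte = _masked_features(test_volumes, mask)
    n_comp = min(cfg.n_components, n_train - 1, Xtr.shape[1])
    pca = PCA(n_components=n_comp, random_state=cfg.seed)
    Ztr = pca.fit_transform(Xtr)
    Zte = pca.transform(Xte)
    scale = Ztr.std(axis=0).mean() or 1.0
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=scale, length_scale_bounds=(1e-2 * scale, 1e4 * scale))
              + WhiteKernel(noise_level=1e-2, noise_level_bounds=(1e-8, 1e2)))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                  random_state=cfg.seed)
    gp.fit(Ztr, np.asarray(train_ages, float))
    return gp.predict(Zte)


@dataclass
class SupervisedCNN:
    """Backbone + linear head trained end-to-end on squared-error age loss."""

    weights: list[np.ndarray]
    channel_mean: np.ndarray
    channel_sd: np.ndarray
    target_mean: float
    backbone: str
    width_multiplier: int
    in_channels: int

    def _build(self) -> nn.Sequential:
        builder = {"small3dcnn": nn.build_small_cnn,
                   "resnet18_3d": nn.build_resnet3d}[self.backbone]
        net = builder(self.in_channels, 1, self.width_multiplier,
                      np.random.default_rng(0))
        net.set_state(self.weights)
        return net

    def predict(self, volumes: Sequence[MultiChannelVolume]) -> np.ndarray:
        from .encoder import _standardize
        X = np.stack([v.stacked() for v in volumes]).astype(np.float32)
        masks = np.stack([v.brain_mask for v in volumes])
        X = _standardize(X, masks, self.channel_mean, self.channel_sd)
        net = self._build()
        out = net.forward(X.astype(np.float64))
        return out.ravel() + self.target_mean


def train_supervised_cnn(train_volumes: Sequence[MultiChannelVolume],
                         train_ages: np.ndarray,
                         cfg: BaselineConfig) -> SupervisedCNN:
    """Train the supervised regression CNN; deterministic per seed.

    Targets are mean-centred, so an untrained network predicts approximately
    the training mean age.
    """
    ages = np.asarray(train_ages, dtype=np.float64)
    n = len(train_volumes)
    if cfg.batch_size > n:
        raise ValueError("batch_size exceeds number of training subjects")
    X, mean, sd = _prepare(train_volumes, False)
    tmean = float(ages.mean())
    yc = ages - tmean
    rng = np.random.default_rng(cfg.seed)
    builder = {"small3dcnn": nn.build_small_cnn,
               "resnet18_3d": nn.build_resnet3d}[cfg.backbone]
    in_c = X.shape[1]
    net = builder(in_c, 1, cfg.width_multiplier, rng)
    opt = nn.Adam(net.params(), lr=cfg.learning_rate)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = net.forward(X[idx].astype(np.float64)).ravel()
            resid = pred - yc[idx]
            net.zero_grad()
            net.backward((2.0 * resid / idx.size)[:, None])
            opt.step()
    return SupervisedCNN(weights=net.get_state(), channel_mean=mean,
                         channel_sd=sd, target_mean=tmean,
                         backbone=cfg.backbone,
                         width_multiplier=cfg.width_multiplier, in_channels=in_c)


def run_supervised_cnn(train_volumes: Sequence[MultiChannelVolume],
                       train_ages: np.ndarray,
                       test_volumes: Sequence[MultiChannelVolume],
                       cfg: BaselineConfig) -> np.ndarray:
    model = train_supervised_cnn(train_volumes, train_ages, cfg)
    return model.predict(test_volumes)
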