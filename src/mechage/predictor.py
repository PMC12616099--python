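"""The composed two-stage predictor: frozen encoder + ridge head."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .age_head import RidgeModel, fit_ridge, fit_ridge_cv, predict_age
from .contrastive import KernelConfig, NeighbourhoodSchedule
from .encoder import EncoderConfig, EncoderState, TrainConfig, embed, train_encoder
from .types import MultiChannelVolume

__all__ = ["AgePredictor", "train_age_predictor"]


@dataclass
class AgePredictor:
    """Frozen encoder plus fitted ridge head; maps volumes to predicted ages."""

    encoder: EncoderState
    head: RidgeModel

    def predict(self, volumes: Sequence[MultiChannelVolume]) -> np.ndarray:
        return predict_age(self.head, embed(self.encoder, volumes))


def train_age_predictor(train_volumes: Sequence[MultiChannelVolume],
                        train_ages: np.ndarray,
                        ecfg: EncoderConfig, tcfg: TrainConfig,
                        kcfg: KernelConfig | None = None,
                        schedule: NeighbourhoodSchedule | None = None,
                        lam: float = 1.0, use_cv: bool = False,
                        per_image_norm: bool = False
                        ) -> tuple[AgePredictor, list[float]]:
    """End-to-end stage 1 + stage 2 training; returns predictor and loss log."""
    state, log = train_encoder(train_volumes, train_ages, ecfg, tcfg, kcfg,
                               schedule, per_image_norm=per_image_norm)
    emb_train = embed(state, train_volumes)
    if use_cv:
        head, _ = fit_ridge_cv(emb_train, train_ages, seed=tcfg.seed)
    else:
        head = fit_ridge(emb_train, train_ages, lam)
    return AgePredictor(encoder=state, head=head), log
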