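"""Age-adaptive contrastive loss for regression on continuous labels.

The training signal arranges subjects in latent space so that similar ages
sit close together. For a batch with ages ``y`` and embeddings ``f(x)`` the
loss for sample ``i`` is

    L_i = - sum_{k != i}  w_ik / (sum_{t != i} w_it)
              * log[ exp(s_ik) / sum_{t in NN(i; epoch)} exp(s_it (1 - w_it)) ]

with the age-kernel weight ``w_ik = exp(-(y_i - y_k)^2 / (2 sigma^2))`` and
the embedding similarity ``s_ik`` (temperature-scaled cosine by default).
``NN(i; epoch)`` is the adaptive neighbourhood: the age-nearest fraction
``rho(epoch)`` of the other samples, shrinking linearly over training so
that learning shifts from coarse to fine age distinctions. The positive
index ``k`` is not forced into the neighbourhood, and the loss is reported
exactly as the formula gives it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KernelConfig",
    "NeighbourhoodSchedule",
    "EmbeddingMatrix",
    "age_kernel_matrix",
    "similarity_matrix",
    "select_neighbourhoods",
    "adaptnn_loss",
    "adaptnn_loss_and_grad",
]


@dataclass
class KernelConfig:
    """Age-kernel bandwidth (years), softmax temperature and similarity type."""

    bandwidth_sigma: float = 2.0
    temperature_tau: float = 0.1
    similarity: str = "cosine"  # or "dot"

    def __post_init__(self) -> None:
        if self.bandwidth_sigma <= 0 or self.temperature_tau <= 0:
            raise ValueError("sigma and tau must be positive")
        if self.similarity not in ("cosine", "dot"):
            raise ValueError(f"unknown similarity {self.similarity!r}")


@dataclass
class NeighbourhoodSchedule:
    """Fraction of repelled neighbours kept per epoch, shrinking linearly."""

    total_epochs: int
    rho_start: float = 1.0
    rho_end: float = 0.25
    mode: str = "linear"

    def __post_init__(self) -> None:
        if not (0 < self.rho_end <= self.rho_start <= 1):
            raise ValueError("need 0 < rho_end <= rho_start <= 1")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")

    def rho(self, epoch: int) -> float:
        if not 0 <= epoch < self.total_epochs:
            raise ValueError(f"epoch {epoch} outside [0, {self.total_epochs})")
        if self.total_epochs == 1:
            return self.rho_start
        frac = epoch / (self.total_epochs - 1)
        return self.rho_start + (self.rho_end - self.rho_start) * frac


@dataclass
class EmbeddingMatrix:
    """n x D latent vectors with their subject ids."""

    vectors: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2D (n, D)")
        if len(self.subject_ids) != self.vectors.shape[0]:
            raise ValueError("ids must correspond 1:1 with rows")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding entries")


def age_kernel_matrix(ages: np.ndarray, config: KernelConfig) -> np.ndarray:
    """Gaussian age-similarity weights, K(0) normalised to 1."""
    ages = np.asarray(ages, dtype=np.float64)
    if ages.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(ages)):
        raise ValueError("non-finite ages")
    d = ages[:, None] - ages[None, :]
    return np.exp(-(d ** 2) / (2.0 * config.bandwidth_sigma ** 2))


def similarity_matrix(emb: EmbeddingMatrix | np.ndarray,
                      config: KernelConfig) -> np.ndarray:
    """Pairwise embedding similarities scaled by 1/tau."""
    V = emb.vectors if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)
    if config.similarity == "cosine":
        norms = np.linalg.norm(V, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm embedding under cosine similarity")
        V = V / norms[:, None]
    return (V @ V.T) / config.temperature_tau


def select_neighbourhoods(ages: np.ndarray, epoch: int,
                          schedule: NeighbourhoodSchedule) -> list[np.ndarray]:
    """Per-sample repelled-neighbour index sets for the given epoch.

    Candidates j != i are ranked by |y_i - y_j| ascending (ties broken by
    index); the first ``ceil(rho(epoch) * (n - 1))`` are retained.
    """
    ages = np.asarray(ages, dtype=np.float64)
    n = ages.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    keep = int(np.ceil(schedule.rho(epoch) * (n - 1)))
    keep = max(keep, 1)
    sets = []
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        order = np.lexsort((others, np.abs(ages[others] - ages[i])))
        sets.append(others[order[:keep]])
    return sets


def _loss_pieces(V: np.ndarray, ages: np.ndarray, epoch: int,
                 kcfg: KernelConfig, schedule: NeighbourhoodSchedule):
    W = age_kernel_matrix(ages, kcfg)
    S = similarity_matrix(V, kcfg)
    nn = select_neighbourhoods(ages, epoch, schedule)
    n = ages.size
    off = ~np.eye(n, dtype=bool)
    Wn = W * off
    wsum = Wn.sum(axis=1)
    What = Wn / wsum[:, None]  # rows sum to 1, zero diagonal
    A = S * (1.0 - W)  # denominator exponents
    logZ = np.empty(n)
    soft = np.zeros((n, n))
    for i in range(n):
        idx = nn[i]
        logZ[i] = logsumexp(A[i, idx])
        soft[i, idx] = np.exp(A[i, idx] - logZ[i])
    loss = -np.sum(What * S) + logZ.sum()
    return loss, (W, S, What, soft, nn)


def adaptnn_loss(emb: EmbeddingMatrix | np.ndarray, ages: np.ndarray,
                 epoch: int, kcfg: KernelConfig,
                 schedule: NeighbourhoodSchedule) -> float:
    """Batch value of the adaptive-neighbourhood contrastive loss."""
    V = emb.vectors if isinstance(emb, EmbeddingMatrix) else np.asarray(emb, float)
    ages = np.asarray(ages, dtype=np.float64)
    if V.shape[0] != ages.size:
        raise ValueError("embeddings and ages must have consistent lengths")
    loss, _ = _loss_pieces(V, ages, epoch, kcfg, schedule)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")
    return float(loss)


def adaptnn_loss_and_grad(V: np.ndarray, ages: np.ndarray, epoch: int,
                          kcfg: KernelConfig, schedule: NeighbourhoodSchedule
                          ) -> tuple[float, np.ndarray]:
    """Loss and its analytic gradient with respect to the raw embeddings.

    For the cosine similarity the gradient is propagated through the row
    normalisation ``u_i = v_i / ||v_i||``.
    """
    V = np.asarray(V, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    loss, (W, S, What, soft, _) = _loss_pieces(V, ages, epoch, kcfg, schedule)
    # dL/dS: -What from the alignment term, softmax*(1-w) from each logZ
    G = -What + soft * (1.0 - W)
    np.fill_diagonal(G, 0.0)
    tau = kcfg.temperature_tau
    if kcfg.similarity == "dot":
        grad = (G + G.T) @ V / tau
    else:
        norms = np.linalg.norm(V, axis=1)
        U = V / norms[:, None]
        gU = (G + G.T) @ U / tau
        # project out the radial component of each row's gradient
        grad = (gU - (np.sum(gU * U, axis=1)[:, None]) * U) / norms[:, None]
    return float(loss), grad
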