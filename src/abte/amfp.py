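"""Adjacency matrix factorization with latent-factor propagation (AMFP).

Factorizes the symmetric interaction matrix with one latent vector per drug
shared between rows and columns. The pair score is

    r_hat(i, j) = sigmoid( w . (U'_i * U'_j) + b_i + b_j + b0 )

where * is element-wise multiplication, w a learned weight vector, b_i per-
drug biases, b0 a global bias, and U' the propagated factors

    U'_i = (1 - alpha) U_i + alpha * mean_{j in N(i)} U_j

with N(i) the training partners of drug i; isolated drugs keep U_i
unchanged. The propagation factor alpha in [0, 1] controls how much
neighborhood information flows in; alpha = 0 recovers plain adjacency matrix
factorization (AMF). Propagation is applied once inside every forward pass
over the current factors, so its effect is present in the gradients.
Parameters are fitted with Adam on binary cross-entropy over per-epoch
negative-sampled batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._mlp import Adam, glorot_normal, bce_loss, sigmoid
from .data import InteractionDataset, negative_sample

__all__ = ["AMFPConfig", "AMFPModel", "propagate", "predict_pair_amfp",
           "train_amfp", "train_amf"]


@dataclass
class AMFPConfig:
    """Training hyperparameters for the factorization component."""

    n_factors: int = 16
    alpha: float = 0.5
    lr: float = 0.01
    batch_size: int = 256
    epochs: int = 40
    neg_ratio: float = 1.0

    def validate(self) -> None:
        if self.n_factors <= 0:
            raise ValueError(f"n_factors must be positive, got {self.n_factors}")
        if self.lr <= 0:
            raise ValueError(f"lr must be positive, got {self.lr}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epochs < 0 or self.batch_size <= 0 or self.neg_ratio <= 0:
            raise ValueError("invalid epochs / batch_size / neg_ratio")


def _propagation_operator(R: sp.spmatrix, alpha: float) -> sp.csr_matrix:
    """Sparse linear operator P with U' = P @ U.

    P = (1 - alpha) I + alpha D^-1 A, with rows of zero degree replaced by
    identity rows so isolated drugs are untouched.
    """
    n = R.shape[0]
    deg = np.asarray(R.sum(axis=1)).ravel()
    inv = np.zeros(n)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    M = sp.diags(inv) @ R.tocsr()
    diag = np.where(nz, 1.0 - alpha, 1.0)
    return (sp.diags(diag) + alpha * M).tocsr()


def propagate(U: np.ndarray, R_train: sp.spmatrix, alpha: float) -> np.ndarray:
    """Blend each drug's latent vector with its neighborhood mean."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if alpha == 0.0:
        return U.copy()
    return _propagation_operator(R_train, alpha) @ U


@dataclass
class AMFPModel:
    """Fitted factorization model; holds the training adjacency for propagation."""

    U: np.ndarray            # (n, k) latent factors, rows shared between axes
    w: np.ndarray            # (k,) element-wise multiplication weights
    b_drug: np.ndarray       # (n,) per-drug biases
    b0: float
    alpha: float
    R_train: sp.csr_matrix = field(repr=False)
    loss_trajectory: list[float] = field(default_factory=list, repr=False)

    @property
    def n_factors(self) -> int:
        return self.U.shape[1]

    def propagated_factors(self) -> np.ndarray:
        return propagate(self.U, self.R_train, self.alpha)

    def predict(self, pairs: np.ndarray) -> np.ndarray:
        """Interaction probabilities for an (m, 2) array of index pairs."""
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("cannot score a drug against itself")
        Ut = self.propagated_factors()
        i, j = pairs[:, 0], pairs[:, 1]
        # biases grouped first so the score is bitwise-symmetric in (i, j)
        z = (Ut[i] * Ut[j]) @ self.w + (self.b_drug[i] + self.b_drug[j]) + self.b0
        return sigmoid(z)


def predict_pair_amfp(model: AMFPModel, i: int, j: int) -> float:
    """Score a single pair; symmetric in (i, j) by construction."""
    if i == j:
        raise ValueError("cannot score a drug against itself")
    return float(model.predict(np.array([[i, j]]))[0])


def train_amfp(
    ds: InteractionDataset,
    hp: AMFPConfig | None = None,
    seed: int = 0,
    use_propagation: bool = True,
) -> AMFPModel:
    """Fit the factorization by Adam on BCE over per-epoch resampled batches.

    When ``use_propagation`` is false (or alpha is 0) the propagation step is
    skipped entirely, which is exactly the AMF special case. Deterministic
    given ``seed``.
    """
    hp = hp or AMFPConfig()
    hp.validate()
    alpha = hp.alpha if use_propagation else 0.0
    n, k = ds.n_drugs, hp.n_factors
    rng = np.random.default_rng(seed)
    U = glorot_normal(rng, k, n, shape=(n, k))  # fan: k inputs -> n rows
    w = glorot_normal(rng, k, 1, shape=(k,))
    b_drug = np.zeros(n)
    b0 = np.zeros(1)
    R = ds.R_train.tocsr().astype(np.float64)
    P = _propagation_operator(R, alpha) if alpha > 0.0 else None
    params = [U, w, b_drug, b0]
    opt = Adam(params, lr=hp.lr)
    trajectory: list[float] = []
    for epoch in range(hp.epochs):
        batch = negative_sample(ds, hp.neg_ratio, seed, epoch)
        order = rng.permutation(len(batch))
        pairs, labels = batch.pairs[order], batch.labels[order].astype(np.float64)
        losses = []
        for start in range(0, len(pairs), hp.batch_size):
            mb = slice(start, start + hp.batch_size)
            i, j, y = pairs[mb, 0], pairs[mb, 1], labels[mb]
            m = len(y)
            Ut = P @ U if P is not None else U
            z = (Ut[i] * Ut[j]) @ w + (b_drug[i] + b_drug[j]) + b0[0]
            p = sigmoid(z)
            losses.append(bce_loss(p, y) * m)
            dz = (p - y) / m
            dw = (Ut[i] * Ut[j]).T @ dz
            dUt = np.zeros_like(U)
            np.add.at(dUt, i, dz[:, None] * (w * Ut[j]))
            np.add.at(dUt, j, dz[:, None] * (w * Ut[i]))
            dU = P.T @ dUt if P is not None else dUt
            db = np.zeros(n)
            np.add.at(db, i, dz)
            np.add.at(db, j, dz)
            opt.step(params, [dU, dw, db, np.array([dz.sum()])])
        trajectory.append(sum(losses) / len(pairs))
    return AMFPModel(U=U, w=w, b_drug=b_drug, b0=float(b0[0]), alpha=alpha,
                     R_train=R, loss_trajectory=trajectory)


def train_amf(ds: InteractionDataset, hp: AMFPConfig | None = None, seed: int = 0) -> AMFPModel:
    """Plain adjacency matrix factorization: AMFP with no propagation step."""
    return train_amfp(ds, hp, seed, use_propagation=False)
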