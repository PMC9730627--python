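"""Bio-text pair classifier: a feed-forward network over drug text embeddings.

The input layer a^(0) for a pair (i, j) is built from the pre-trained text
vectors L_i, L_j in one of four variants:

    concat                          [L_i, L_j]
    multiply                        [L_i * L_j, 1]        (bias component)
    concat_feature_combination      [L_i, L_j, E_i * E_j]
    multiply_feature_combination    [L_i * L_j, E_i * E_j]

where E is a per-drug ID embedding trained jointly inside the same network
(the feature-combination variants); the text vectors themselves stay frozen.
Hidden layers apply a^(l+1) = ReLU(W^(l) a^(l) + b^(l)); the last layer feeds
a sigmoid for the interaction probability, trained with binary cross-entropy
over per-epoch negative-sampled batches.

The concat variants are not symmetric in the pair order as written; at
inference both orderings are scored and averaged so the per-pair score of an
undirected interaction is well defined. Multiply variants are exactly
symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mlp import MLP, Adam, bce_loss, glorot_normal
from .data import InteractionDataset, negative_sample
from .embeddings import DrugVectorMap

__all__ = ["VARIANTS", "BioTextConfig", "BioTextModel", "build_pair_features",
           "forward", "bce_loss", "train_biotext"]

VARIANTS = (
    "concat",
    "multiply",
    "concat_feature_combination",
    "multiply_feature_combination",
)


@dataclass
class BioTextConfig:
    variant: str = "concat"
    hidden_widths: tuple[int, ...] = (128, 64)
    dropout: float = 0.5
    lr: float = 0.01
    batch_size: int = 256
    epochs: int = 50
    neg_ratio: float = 1.0
    id_dim: int = 64  # drug-ID embedding size, feature-combination variants only

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("invalid lr / batch_size / epochs")
        if not 0.0 <= self.dropout <= 0.9:
            raise ValueError(f"dropout must be in [0, 0.9], got {self.dropout}")
        if self.neg_ratio <= 0:
            raise ValueError(f"neg_ratio must be positive, got {self.neg_ratio}")
        if "feature_combination" in self.variant and self.id_dim <= 0:
            raise ValueError("feature-combination variants need id_dim > 0")


def _feature_dim(variant: str, e: int, k: int = 0) -> int:
    return {
        "concat": 2 * e,
        "multiply": e + 1,
        "concat_feature_combination": 2 * e + k,
        "multiply_feature_combination": e + k,
    }[variant]


def build_pair_features(L_i, L_j, variant: str,
                        id_i=None, id_j=None) -> np.ndarray:
    """Input-layer feature vector for a single drug pair."""
    L_i, L_j = np.asarray(L_i, float), np.asarray(L_j, float)
    if L_i.shape != L_j.shape:
        raise ValueError(f"embedding length mismatch: {L_i.shape} vs {L_j.shape}")
    needs_id = "feature_combination" in variant
    if needs_id and (id_i is None or id_j is None):
        raise ValueError(f"variant {variant!r} requires id vectors")
    if not needs_id and (id_i is not None or id_j is not None):
        raise ValueError(f"variant {variant!r} takes no id vectors")
    if needs_id:
        id_i, id_j = np.asarray(id_i, float), np.asarray(id_j, float)
        if id_i.shape != id_j.shape:
            raise ValueError("id embedding length mismatch")
    if variant == "concat":
        return np.concatenate([L_i, L_j])
    if variant == "multiply":
        return np.concatenate([L_i * L_j, [1.0]])
    if variant == "concat_feature_combination":
        return np.concatenate([L_i, L_j, id_i * id_j])
    if variant == "multiply_feature_combination":
        return np.concatenate([L_i * L_j, id_i * id_j])
    raise ValueError(f"unknown variant {variant!r}")


def _batch_features(L: np.ndarray, pairs: np.ndarray, variant: str,
                    id_emb: np.ndarray | None, swap: bool = False) -> np.ndarray:
    """Vectorized feature construction for an (m, 2) pair array."""
    i, j = (pairs[:, 1], pairs[:, 0]) if swap else (pairs[:, 0], pairs[:, 1])
    Li, Lj = L[i], L[j]
    if variant == "concat":
        return np.hstack([Li, Lj])
    if variant == "multiply":
        return np.hstack([Li * Lj, np.ones((len(pairs), 1))])
    if variant == "concat_feature_combination":
        return np.hstack([Li, Lj, id_emb[i] * id_emb[j]])
    if variant == "multiply_feature_combination":
        return np.hstack([Li * Lj, id_emb[i] * id_emb[j]])
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class BioTextModel:
    """Trained pair classifier (network weights plus optional ID embedding)."""

    variant: str
    mlp: MLP
    id_embedding: np.ndarray | None = None  # (n, k), feature-combination only
    loss_trajectory: list[float] = field(default_factory=list, repr=False)

    def predict(self, dvm: DrugVectorMap, pairs: np.ndarray,
                chunk: int = 8192) -> np.ndarray:
        """Deterministic inference; concat variants average both pair orders."""
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("cannot score a drug against itself")
        out = np.empty(len(pairs))
        for start in range(0, len(pairs), chunk):
            mb = pairs[start:start + chunk]
            X = _batch_features(dvm.matrix, mb, self.variant, self.id_embedding)
            p, _ = self.mlp.forward(X)
            if self.variant.startswith("concat"):
                Xs = _batch_features(dvm.matrix, mb, self.variant,
                                     self.id_embedding, swap=True)
                ps, _ = self.mlp.forward(Xs)
                p = 0.5 * (p + ps)
            out[start:start + chunk] = p
        return out


def forward(model: BioTextModel, features: np.ndarray) -> np.ndarray:
    """Raw network forward pass on pre-built features (inference mode)."""
    p, _ = model.mlp.forward(features)
    return p if np.ndim(features) > 1 else float(p[0])


def train_biotext(
    ds: InteractionDataset,
    dvm: DrugVectorMap,
    hp: BioTextConfig | None = None,
    seed: int = 0,
) -> BioTextModel:
    """Train the pair classifier with Adam on per-epoch resampled batches.

    Text vectors are frozen; in feature-combination variants the drug-ID
    embedding receives gradients through the element-wise product and is
    updated jointly with the network. Deterministic given ``seed``.
    """
    hp = hp or BioTextConfig()
    hp.validate()
    rng = np.random.default_rng(seed)
    e = dvm.dim
    needs_id = "feature_combination" in hp.variant
    k = hp.id_dim if needs_id else 0
    id_emb = (glorot_normal(rng, k, ds.n_drugs, shape=(ds.n_drugs, k))
              if needs_id else None)
    mlp = MLP([_feature_dim(hp.variant, e, k), *hp.hidden_widths], rng,
              dropout=hp.dropout)
    params = mlp.params() + ([id_emb] if needs_id else [])
    opt = Adam(params, lr=hp.lr)
    id_off = _feature_dim(hp.variant, e, 0)  # id-product slice starts here
    trajectory: list[float] = []
    for epoch in range(hp.epochs):
        batch = negative_sample(ds, hp.neg_ratio, seed, epoch)
        order = rng.permutation(len(batch))
        pairs = batch.pairs[order]
        labels = batch.labels[order].astype(np.float64)
        losses = []
        for start in range(0, len(pairs), hp.batch_size):
            mb = slice(start, start + hp.batch_size)
            pr, y = pairs[mb], labels[mb]
            X = _batch_features(dvm.matrix, pr, hp.variant, id_emb)
            p, cache = mlp.forward(X, training=True, rng=rng)
            losses.append(bce_loss(p, y) * len(y))
            delta = ((p - y) / len(y))[:, None]
            grads, dX = mlp.backward(cache, delta)
            if needs_id:
                d_prod = dX[:, id_off:id_off + k]
                dE = np.zeros_like(id_emb)
                i, j = pr[:, 0], pr[:, 1]
                np.add.at(dE, i, d_prod * id_emb[j])
                np.add.at(dE, j, d_prod * id_emb[i])
                grads = grads + [dE]
            opt.step(params, grads)
        trajectory.append(sum(losses) / len(pairs))
    return BioTextModel(variant=hp.variant, mlp=mlp, id_embedding=id_emb,
                        loss_trajectory=trajectory)
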