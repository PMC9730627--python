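"""ABTE hybrid: stacking combiner plus the cold-start switching rule.

The bio-text and AMFP components are trained separately; a small neural
network (the stacker) then maps their two scalar predictions to a combined
probability. The final hybrid routes each pair (i, j) by the switching rule

    r_hat(i, j) = stacking(i, j)   if I_i >= M and I_j >= M
                  text(i, j)       otherwise

where I are training interaction counts and M a non-negative integer
threshold tuned on validation data (the prose rule "equal or higher than M"
governs, i.e. >=). When either drug has fewer than M training interactions
its factorization latent vector is uninformative, so the text-only score is
used verbatim; otherwise the stacker blends both components.

The stacker is trained on the validation split's component scores rather
than training-set scores, to avoid learning from the components' fit
optimism; M is chosen to maximize validation AUPR (ties -> smallest M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mlp import MLP, Adam, bce_loss
from .amfp import AMFPConfig, AMFPModel, train_amfp
from .biotext import BioTextConfig, BioTextModel, train_biotext
from .data import InteractionDataset, PairBatch, interaction_counts, validation_split
from .embeddings import DrugVectorMap
from .evaluation import aupr

__all__ = ["StackerConfig", "StackingModel", "ABTEModel", "train_stacking",
           "abte_predict", "tune_M", "train_abte"]


@dataclass
class StackerConfig:
    hidden_widths: tuple[int, ...] = (8,)
    lr: float = 0.01
    batch_size: int = 512
    epochs: int = 300

    def validate(self) -> None:
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs < 0:
            raise ValueError("invalid lr / batch_size / epochs")


@dataclass
class StackingModel:
    """2-input sigmoid MLP over (text score, amfp score)."""

    mlp: MLP
    loss_trajectory: list[float] = field(default_factory=list, repr=False)

    def predict(self, text_scores, amfp_scores) -> np.ndarray:
        X = np.column_stack([np.asarray(text_scores, float).ravel(),
                             np.asarray(amfp_scores, float).ravel()])
        p, _ = self.mlp.forward(X)
        return p


def train_stacking(text_scores, amfp_scores, labels,
                   hp: StackerConfig | None = None, seed: int = 0) -> StackingModel:
    """Fit the stacker with Adam on BCE over the two component scores."""
    hp = hp or StackerConfig()
    hp.validate()
    text_scores = np.asarray(text_scores, float).ravel()
    amfp_scores = np.asarray(amfp_scores, float).ravel()
    y_all = np.asarray(labels, float).ravel()
    if not len(text_scores) == len(amfp_scores) == len(y_all):
        raise ValueError("score and label vectors must have equal length")
    rng = np.random.default_rng(seed)
    mlp = MLP([2, *hp.hidden_widths], rng)
    params = mlp.params()
    opt = Adam(params, lr=hp.lr)
    X_all = np.column_stack([text_scores, amfp_scores])
    trajectory: list[float] = []
    for _ in range(hp.epochs):
        order = rng.permutation(len(y_all))
        losses = []
        for start in range(0, len(y_all), hp.batch_size):
            sel = order[start:start + hp.batch_size]
            X, y = X_all[sel], y_all[sel]
            p, cache = mlp.forward(X)
            losses.append(bce_loss(p, y) * len(y))
            grads, _ = mlp.backward(cache, ((p - y) / len(y))[:, None])
            opt.step(params, grads)
        trajectory.append(sum(losses) / len(y_all))
    return StackingModel(mlp=mlp, loss_trajectory=trajectory)


@dataclass
class ABTEModel:
    """Assembled hybrid: components, stacker, switching threshold, counts."""

    biotext: BioTextModel
    amfp: AMFPModel
    stacker: StackingModel
    M: int
    counts: np.ndarray  # training-time interaction counts I

    def __post_init__(self) -> None:
        if self.M < 0:
            raise ValueError("switching threshold M must be non-negative")

    def component_scores(self, dvm: DrugVectorMap, pairs: np.ndarray):
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        text = self.biotext.predict(dvm, pairs)
        am = self.amfp.predict(pairs)
        return text, am

    def predict(self, dvm: DrugVectorMap, pairs: np.ndarray) -> np.ndarray:
        return abte_predict(self, dvm, pairs)


def _routing_mask(counts: np.ndarray, pairs: np.ndarray, M: int) -> np.ndarray:
    """True where both drugs have >= M training interactions (stacking branch)."""
    return (counts[pairs[:, 0]] >= M) & (counts[pairs[:, 1]] >= M)


def abte_predict(model: ABTEModel, dvm: DrugVectorMap, pairs: np.ndarray) -> np.ndarray:
    """Hybrid prediction; the text branch returns the bio-text score verbatim."""
    pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
    if np.any(pairs[:, 0] == pairs[:, 1]):
        raise ValueError("cannot score a drug against itself")
    text, am = model.component_scores(dvm, pairs)
    stacked = model.stacker.predict(text, am)
    mask = _routing_mask(model.counts, pairs, model.M)
    return np.where(mask, stacked, text)


def tune_M(
    biotext: BioTextModel,
    amfp_model: AMFPModel,
    stacker: StackingModel,
    dvm: DrugVectorMap,
    validation: PairBatch,
    counts: np.ndarray,
    candidate_range=range(0, 11),
) -> tuple[int, dict[int, float]]:
    """Pick the switching threshold maximizing validation AUPR.

    Candidates are scanned in ascending order and ties keep the smallest M
    (broader use of the stacking branch). Also returns the per-candidate
    AUPR table.
    """
    candidates = sorted(set(int(m) for m in candidate_range))
    if not candidates:
        raise ValueError("candidate range is empty")
    if any(m < 0 for m in candidates):
        raise ValueError("candidate M values must be non-negative")
    text = biotext.predict(dvm, validation.pairs)
    am = amfp_model.predict(validation.pairs)
    stacked = stacker.predict(text, am)
    table: dict[int, float] = {}
    best_m, best_metric = candidates[0], -np.inf
    for m in candidates:
        routed = np.where(_routing_mask(counts, validation.pairs, m), stacked, text)
        metric = aupr(routed, validation.labels)
        table[m] = metric
        if metric > best_metric:
            best_m, best_metric = m, metric
    return best_m, table


def _balanced_subsample(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of all positives plus an equal-size uniform draw of negatives."""
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    n_neg = min(len(pos), len(neg))
    sel = rng.choice(neg, size=n_neg, replace=False)
    return np.sort(np.concatenate([pos, sel]))


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2 ** 31)) for s in state]


def train_abte(
    ds: InteractionDataset,
    dvm: DrugVectorMap,
    amfp_hp: AMFPConfig | None = None,
    text_hp: BioTextConfig | None = None,
    stacker_hp: StackerConfig | None = None,
    seed: int = 0,
    val_fraction: float = 0.2,
    m_candidates=range(0, 11),
) -> tuple[ABTEModel, dict]:
    """End-to-end pipeline: split, train components, stack, tune M, assemble.

    The components are fitted on the sub-training matrix left after the
    validation split; switching counts are taken from that same matrix so
    routing reflects exactly the interactions the factorization saw.
    Returns the model plus an info dict (validation scores, per-M table).
    """
    s_val, s_amfp, s_text, s_stack, s_bal = _child_seeds(seed, 5)
    sub, val = validation_split(ds, val_fraction, s_val)
    amfp_model = train_amfp(sub, amfp_hp, s_amfp)
    text_model = train_biotext(sub, dvm, text_hp, s_text)
    text_val = text_model.predict(dvm, val.pairs)
    am_val = amfp_model.predict(val.pairs)
    # one negative per positive, the same protocol the components train
    # under, so all three branch outputs share one prior scale and the
    # switching rule mixes comparable scores
    bal = _balanced_subsample(val.labels, np.random.default_rng(s_bal))
    stacker = train_stacking(text_val[bal], am_val[bal], val.labels[bal],
                             stacker_hp, s_stack)
    counts = interaction_counts(sub)
    best_m, table = tune_M(text_model, amfp_model, stacker, dvm, val,
                           counts, m_candidates)
    model = ABTEModel(biotext=text_model, amfp=amfp_model, stacker=stacker,
                      M=best_m, counts=counts)
    info = {
        "validation": val,
        "sub_train": sub,
        "m_table": table,
        "validation_scores": {"text": text_val, "amfp": am_val,
                              "stacked": stacker.predict(text_val, am_val)},
    }
    return model, info
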