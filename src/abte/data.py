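"""Interaction data handling.

Builds the symmetric binary drug-drug interaction matrix R from tab-separated
edge lists, derives the temporal evaluation pair set between two database
releases, splits off a validation set, and performs per-epoch negative
sampling from the non-edge pool (implicit-feedback framing: an absent edge is
"unknown, usable as a negative", not a verified negative).

All unordered pairs are canonicalized as (i, j) with i < j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DrugCatalog",
    "InteractionDataset",
    "PairBatch",
    "load_interactions",
    "write_edge_list",
    "temporal_split",
    "validation_split",
    "negative_sample",
    "interaction_counts",
]


@dataclass(frozen=True)
class DrugCatalog:
    """Ordered set of drug identifiers with a stable integer index.

    Ordering is lexicographic on the identifier so that matrix indices are
    reproducible across runs and machines.
    """

    drugs: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.drugs) < 2:
            raise ValueError("catalog needs at least 2 drugs")
        if len(set(self.drugs)) != len(self.drugs):
            raise ValueError("drug identifiers must be unique")

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "DrugCatalog":
        drugs = tuple(sorted(set(ids)))
        return cls(drugs=drugs, index={d: i for i, d in enumerate(drugs)})

    def __len__(self) -> int:
        return len(self.drugs)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.index


@dataclass
class InteractionDataset:
    """Drug catalog plus symmetric binary interaction matrices.

    ``R_train`` holds interactions known at release time t; ``R_test``
    (optional) holds the matrix of a later release t'. Both are n x n sparse
    symmetric with zero diagonal.
    """

    catalog: DrugCatalog
    R_train: sp.csr_matrix
    R_test: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        n = len(self.catalog)
        for name, R in (("R_train", self.R_train), ("R_test", self.R_test)):
            if R is None:
                continue
            if R.shape != (n, n):
                raise ValueError(f"{name} shape {R.shape} != catalog size {n}")
            if (R != R.T).nnz != 0:
                raise ValueError(f"{name} is not symmetric")
            if R.diagonal().any():
                raise ValueError(f"{name} has nonzero diagonal")

    @property
    def n_drugs(self) -> int:
        return len(self.catalog)

    @property
    def counts(self) -> np.ndarray:
        """Per-drug training interaction counts I_i (row degrees of R_train)."""
        return interaction_counts(self)

    def train_pairs(self) -> np.ndarray:
        """Training positives as an (m, 2) array of canonical (i < j) pairs."""
        coo = sp.triu(self.R_train, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])


@dataclass
class PairBatch:
    """Drug-pair instances Y with binary labels, pairs canonical (i < j)."""

    pairs: np.ndarray  # (m, 2) int
    labels: np.ndarray  # (m,) in {0, 1}

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-pairs are not allowed")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.pairs)


def _pairs_to_matrix(pairs: np.ndarray, n: int) -> sp.csr_matrix:
    """Symmetric binary CSR matrix from an (m, 2) array of index pairs."""
    if len(pairs) == 0:
        return sp.csr_matrix((n, n), dtype=np.int8)
    i, j = pairs[:, 0], pairs[:, 1]
    data = np.ones(2 * len(pairs), dtype=np.int8)
    R = sp.coo_matrix(
        (data, (np.concatenate([i, j]), np.concatenate([j, i]))), shape=(n, n)
    ).tocsr()
    R.data[:] = 1  # collapse duplicates
    return R


def load_interactions(
    edge_list_path: str | Path, catalog: DrugCatalog | None = None
) -> InteractionDataset:
    """Read a tab-separated two-column edge list into an InteractionDataset.

    Lines starting with ``#`` are comments. Duplicate rows and reversed
    duplicates collapse to a single undirected edge. A self-loop row or (when
    a catalog is supplied) an unknown identifier is an error.
    """
    path = Path(edge_list_path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop edge ({a}, {b})")
            edges.append((a, b))
    if catalog is None:
        catalog = DrugCatalog.from_ids(d for e in edges for d in e)
    else:
        for a, b in edges:
            for d in (a, b):
                if d not in catalog:
                    raise KeyError(f"drug ID {d!r} not in supplied catalog")
    idx = catalog.index
    pairs = np.array(
        [sorted((idx[a], idx[b])) for a, b in edges], dtype=np.int64
    ).reshape(-1, 2)
    return InteractionDataset(catalog, _pairs_to_matrix(pairs, len(catalog)))


def write_edge_list(ds: InteractionDataset, path: str | Path, matrix: str = "train") -> None:
    """Write the train (or test) matrix back out as a canonical TSV edge list."""
    R = ds.R_train if matrix == "train" else ds.R_test
    if R is None:
        raise ValueError(f"dataset has no {matrix} matrix")
    coo = sp.triu(R, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with Path(path).open("w") as fh:
        fh.write("# drug_id_a\tdrug_id_b\n")
        for i, j in zip(coo.row[order], coo.col[order]):
            fh.write(f"{ds.catalog.drugs[i]}\t{ds.catalog.drugs[j]}\n")


def _all_pairs(n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def temporal_split(train: InteractionDataset, test: InteractionDataset) -> PairBatch:
    """Evaluation pair set of a retrospective (release-to-release) study.

    Returns every unordered pair (i < j) that is *not* a training positive,
    labelled 1 iff it is an interaction in the later release. Training
    positives are dropped from evaluation entirely: the task is to predict
    interactions absent from R at time t.
    """
    if train.catalog is not test.catalog and train.catalog.drugs != test.catalog.drugs:
        raise ValueError("train and test datasets must share one catalog")
    n = train.n_drugs
    pairs = _all_pairs(n)
    in_train = np.asarray(train.R_train[pairs[:, 0], pairs[:, 1]]).ravel() > 0
    pairs = pairs[~in_train]
    labels = np.asarray(test.R_train[pairs[:, 0], pairs[:, 1]]).ravel() > 0
    return PairBatch(pairs, labels.astype(np.int8))


def validation_split(
    ds: InteractionDataset, fraction: float, seed: int
) -> tuple[InteractionDataset, PairBatch]:
    """Hold out a fraction of existing and of non-existing pairs for validation.

    The selected positives are removed from the returned sub-training matrix;
    the validation PairBatch mixes them with the same fraction of randomly
    selected non-edges. Deterministic under ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    pos = ds.train_pairs()
    all_pairs = _all_pairs(ds.n_drugs)
    is_edge = np.asarray(ds.R_train[all_pairs[:, 0], all_pairs[:, 1]]).ravel() > 0
    neg = all_pairs[~is_edge]
    n_pos = int(round(fraction * len(pos)))
    n_neg = int(round(fraction * len(neg)))
    pos_sel = rng.choice(len(pos), size=n_pos, replace=False)
    neg_sel = rng.choice(len(neg), size=n_neg, replace=False)
    val_pairs = np.concatenate([pos[pos_sel], neg[neg_sel]])
    val_labels = np.concatenate(
        [np.ones(n_pos, dtype=np.int8), np.zeros(n_neg, dtype=np.int8)]
    )
    keep = np.ones(len(pos), dtype=bool)
    keep[pos_sel] = False
    sub = InteractionDataset(
        ds.catalog, _pairs_to_matrix(pos[keep], ds.n_drugs), ds.R_test
    )
    return sub, PairBatch(val_pairs, val_labels)


def negative_sample(
    ds: InteractionDataset, ratio: float, rng_seed: int, epoch: int
) -> PairBatch:
    """Per-epoch training batch: all positives plus freshly sampled negatives.

    Negatives are floor(ratio * #positives) unordered non-edges drawn
    uniformly without replacement. A different draw per epoch, deterministic
    given (rng_seed, epoch).
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    pos = ds.train_pairs()
    if len(pos) == 0:
        raise ValueError("dataset has no training positives")
    all_pairs = _all_pairs(ds.n_drugs)
    is_edge = np.asarray(ds.R_train[all_pairs[:, 0], all_pairs[:, 1]]).ravel() > 0
    neg_pool = all_pairs[~is_edge]
    n_neg = int(ratio * len(pos))
    if n_neg > len(neg_pool):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(neg_pool)} non-edges exist"
        )
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, epoch]))
    sel = rng.choice(len(neg_pool), size=n_neg, replace=False)
    pairs = np.concatenate([pos, neg_pool[sel]])
    labels = np.concatenate(
        [np.ones(len(pos), dtype=np.int8), np.zeros(n_neg, dtype=np.int8)]
    )
    return PairBatch(pairs, labels)


def interaction_counts(ds: InteractionDataset) -> np.ndarray:
    """I_i: number of training partners of each drug (row degree of R_train)."""
    return np.asarray(ds.R_train.sum(axis=1)).ravel().astype(np.int64)


def export_scores(
    ds: InteractionDataset,
    batch: PairBatch,
    scores: Sequence[float],
    path: str | Path,
) -> None:
    """TSV export ``drug_id_a, drug_id_b, label, score`` aligned to a batch."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(batch):
        raise ValueError("scores length does not match batch")
    with Path(path).open("w") as fh:
        fh.write("drug_id_a\tdrug_id_b\tlabel\tscore\n")
        for (i, j), y, s in zip(batch.pairs, batch.labels, scores):
            fh.write(
                f"{ds.catalog.drugs[i]}\t{ds.catalog.drugs[j]}\t{int(y)}\t{s:.6f}\n"
            )
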