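"""Synthetic study generator: planted-partition interactions + correlated embeddings.

Emulates the ingredients of a retrospective DDI study so the whole pipeline
is testable without external downloads:

* drugs are assigned uniformly to clusters; an edge between two drugs is
  Bernoulli(p_within) inside a cluster and Bernoulli(p_between) across —
  a planted-partition (stochastic block model) interaction matrix;
* each drug's text embedding is its cluster centroid (scaled orthogonal
  unit vectors) plus isotropic Gaussian noise, so cluster co-membership
  simultaneously drives interactions and embeddings — the premise that
  literature-derived vectors carry interaction signal;
* a temporal holdout moves a fraction of the drawn edges into the "future"
  test matrix;
* a designated fraction of drugs is forced cold, emulating drugs newly
  approved between the releases: each cold drug keeps a budget of training
  edges drawn uniformly from {0, ..., cold_max_links} (the rest move to
  test), so the cold population mixes genuinely new drugs (no known
  interactions at time t) with barely-known ones, all inside the rare
  stratum (I < 3 at the default).

Everything is reproducible under a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data import DrugCatalog, InteractionDataset, _pairs_to_matrix, write_edge_list
from .embeddings import EmbeddingTable, write_word2vec_text

__all__ = ["SynthConfig", "SynthStudy", "generate", "write_study"]


@dataclass
class SynthConfig:
    n_drugs: int = 300
    n_clusters: int = 6
    embed_dim: int = 100
    edge_prob_within: float = 0.25
    edge_prob_between: float = 0.01
    embed_noise_sd: float = 0.3
    holdout_frac: float = 0.5
    cold_frac: float = 0.15
    cold_max_links: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_drugs < 2 or self.n_clusters < 1:
            raise ValueError("need n_drugs >= 2 and n_clusters >= 1")
        if self.n_clusters > self.embed_dim:
            raise ValueError("embed_dim must be >= n_clusters (orthogonal centroids)")
        for p in (self.edge_prob_within, self.edge_prob_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability {p} outside [0, 1]")
        for f in (self.holdout_frac, self.cold_frac):
            if not 0.0 <= f < 1.0:
                raise ValueError(f"fraction {f} outside [0, 1)")
        if self.cold_max_links < 0:
            raise ValueError("cold_max_links must be non-negative")
        if self.edge_prob_within == 0.0 and self.edge_prob_between == 0.0:
            raise ValueError("edge probabilities imply zero positives")


@dataclass
class SynthStudy:
    dataset: InteractionDataset          # R_train plus temporal R_test
    embeddings: EmbeddingTable
    cluster_labels: np.ndarray           # (n,) ground-truth community ids
    cold_drugs: np.ndarray               # indices of designated cold drugs
    config: SynthConfig


def generate(cfg: SynthConfig | None = None) -> SynthStudy:
    """Draw one synthetic study from the planted-partition model."""
    cfg = cfg or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_drugs
    width = len(str(n - 1))
    catalog = DrugCatalog.from_ids(f"D{i:0{width}d}" for i in range(n))
    labels = rng.integers(cfg.n_clusters, size=n)

    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    prob = np.where(same, cfg.edge_prob_within, cfg.edge_prob_between)
    drawn = rng.random(len(prob)) < prob
    edges = np.column_stack([iu[0][drawn], iu[1][drawn]])
    if len(edges) == 0:
        raise ValueError("drawn interaction set is empty; raise edge probabilities")

    # temporal holdout: a uniform fraction of edges becomes "future" positives
    to_test = np.zeros(len(edges), dtype=bool)
    n_hold = int(round(cfg.holdout_frac * len(edges)))
    to_test[rng.choice(len(edges), size=n_hold, replace=False)] = True

    # cold drugs keep a uniform {0..cold_max_links} budget of training edges
    n_cold = int(round(cfg.cold_frac * n))
    cold = rng.choice(n, size=n_cold, replace=False)
    budget = np.full(n, np.iinfo(np.int64).max)
    budget[cold] = rng.integers(0, cfg.cold_max_links + 1, size=n_cold)
    train_deg = np.zeros(n, dtype=np.int64)
    order = rng.permutation(len(edges))
    for idx in order:
        if to_test[idx]:
            continue
        i, j = edges[idx]
        if train_deg[i] >= budget[i] or train_deg[j] >= budget[j]:
            to_test[idx] = True
        else:
            train_deg[i] += 1
            train_deg[j] += 1

    R_train = _pairs_to_matrix(edges[~to_test], n)
    R_test = _pairs_to_matrix(edges[to_test], n)
    ds = InteractionDataset(catalog, R_train, R_test)

    centroids = np.zeros((cfg.n_clusters, cfg.embed_dim))
    centroids[np.arange(cfg.n_clusters), np.arange(cfg.n_clusters)] = 1.0
    vectors = centroids[labels] + rng.normal(0.0, cfg.embed_noise_sd,
                                             size=(n, cfg.embed_dim))
    table = EmbeddingTable(
        dim=cfg.embed_dim,
        vectors={catalog.drugs[i]: vectors[i] for i in range(n)},
    )
    return SynthStudy(dataset=ds, embeddings=table, cluster_labels=labels,
                      cold_drugs=np.sort(cold), config=cfg)


def write_study(study: SynthStudy, out_dir: str | Path) -> None:
    """Write train/test edge TSVs, the embedding table, and a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(study.dataset, out / "train_edges.tsv", matrix="train")
    write_edge_list(study.dataset, out / "test_edges.tsv", matrix="test")
    write_word2vec_text(study.embeddings, out / "embeddings.txt")
    truth = {
        "config": asdict(study.config),
        "cluster_labels": {
            d: int(c) for d, c in zip(study.dataset.catalog.drugs,
                                      study.cluster_labels)
        },
        "cold_drugs": [study.dataset.catalog.drugs[i] for i in study.cold_drugs],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
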