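import numpy as np
import pytest

from abte.data import DrugCatalog, InteractionDataset
from abte.data import _pairs_to_matrix


def make_dataset(edges, ids=None, test_edges=None):
    """InteractionDataset from (id_a, id_b) tuples, catalog from the union."""
    if ids is None:
        ids = sorted({d for e in edges for d in e} |
                     {d for e in (test_edges or []) for d in e})
    catalog = DrugCatalog.from_ids(ids)
    idx = catalog.index

    def mat(es):
        pairs = np.array([sorted((idx[a], idx[b])) for a, b in es],
                         dtype=np.int64).reshape(-1, 2)
        return _pairs_to_matrix(pairs, len(catalog))

    R_test = mat(test_edges) if test_edges is not None else None
    return InteractionDataset(catalog, mat(edges), R_test)


def brute_force_auroc(scores, labels):
    """O(n_pos * n_neg) pairwise comparison oracle for AUROC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by integration-level tests."""
    from abte.synth import SynthConfig, generate

    return generate(SynthConfig(n_drugs=80, n_clusters=4, embed_dim=20,
                                edge_prob_within=0.3, edge_prob_between=0.02,
                                seed=7))
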