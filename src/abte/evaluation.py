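"""Ranking evaluation: AUROC, AUPR, precision@K / recall@K, rare-drug strata.

AUROC is the Mann-Whitney statistic P(score_pos > score_neg) + 0.5 P(tie);
AUPR is the step-wise (average-precision) sum over ranked thresholds,
sum_k (R_k - R_{k-1}) P_k, which avoids the optimistic bias of trapezoidal
interpolation on PR curves. Under heavy class imbalance — the regime of DDI
prediction, where known interactions are a few percent of all pairs — AUPR
is the more informative of the two.

The rare (cold-start) stratum contains pairs where min(I_i, I_j) < threshold,
I being training interaction counts; per-drug averaged top-K metrics and the
cumulative distribution of drugs / test interactions by training count
support the gain-vs-interaction-count analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["EvalReport", "auroc", "aupr", "precision_recall_at_k",
           "evaluate_scores", "stratified_report"]


def auroc(scores, labels) -> float:
    """Area under the ROC curve (tie-corrected rank statistic)."""
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel()
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, step summation."""
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel()
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if labels.sum() == 0:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


def _ranking(scores: np.ndarray) -> np.ndarray:
    # score descending, original index ascending on ties
    return np.lexsort((np.arange(len(scores)), -scores))


def precision_recall_at_k(scores, labels, k_values) -> tuple[dict, dict]:
    """Top-K precision and recall with a deterministic tie-break.

    precision@K = positives among top K / K; recall@K = positives among
    top K / total positives. Ties broken by (score desc, index asc).
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel()
    order = _ranking(scores)
    ranked = labels[order]
    total_pos = int(labels.sum())
    precision, recall = {}, {}
    for k in k_values:
        if not 0 < k <= len(scores):
            raise ValueError(f"K={k} out of range for {len(scores)} scored pairs")
        hits = int(ranked[:k].sum())
        precision[k] = hits / k
        recall[k] = hits / total_pos if total_pos else 0.0
    return precision, recall


@dataclass
class EvalReport:
    auroc: float | None
    aupr: float | None
    n_pairs: int
    n_positives: int
    precision_at: dict[int, float] = field(default_factory=dict)
    recall_at: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_scores(scores, labels, k_values=(10, 50, 100)) -> EvalReport:
    """Full ranking report; AUROC/AUPR are None when undefined (one class)."""
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel()
    ks = [k for k in k_values if k <= len(scores)]
    precision, recall = precision_recall_at_k(scores, labels, ks) if ks else ({}, {})
    two_class = len(np.unique(labels)) == 2
    return EvalReport(
        auroc=auroc(scores, labels) if two_class else None,
        aupr=aupr(scores, labels) if labels.sum() > 0 else None,
        n_pairs=len(scores),
        n_positives=int(labels.sum()),
        precision_at=precision,
        recall_at=recall,
    )


def stratified_report(
    scores,
    labels,
    pairs,
    counts,
    threshold: int = 3,
    k_values=(10, 50, 100),
    bins=(0, 1, 2, 3, 5, 10, 20, 50),
) -> dict:
    """Pooled and per-drug metrics split by training interaction count.

    ``counts`` are training-matrix degrees I. The rare stratum pools pairs
    with min(I_i, I_j) < threshold; the warm stratum is its complement. An
    empty stratum is reported as absent (None). ``per_drug_rare`` computes
    each rare drug's metrics over its own candidate pairs and averages
    across drugs; ``cumulative`` gives, per count bin b, the fraction of
    drugs with I <= b and the fraction of test positives whose rarer drug
    has I <= b.
    """
    scores = np.asarray(scores, float).ravel()
    labels = np.asarray(labels).ravel()
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    counts = np.asarray(counts, dtype=np.int64)
    min_count = np.minimum(counts[pairs[:, 0]], counts[pairs[:, 1]])
    rare_mask = min_count < threshold

    def _stratum(mask: np.ndarray):
        if not mask.any():
            return None
        return evaluate_scores(scores[mask], labels[mask], k_values).to_dict()

    rare_drugs = np.flatnonzero(counts < threshold)
    per_drug_auc, per_drug_prec, per_drug_rec = [], [], {k: [] for k in k_values}
    prec_acc = {k: [] for k in k_values}
    for d in rare_drugs:
        dmask = (pairs[:, 0] == d) | (pairs[:, 1] == d)
        if not dmask.any():
            continue
        s, y = scores[dmask], labels[dmask]
        if len(np.unique(y)) == 2:
            per_drug_auc.append(auroc(s, y))
        if y.sum() > 0:
            ks = [min(k, len(s)) for k in k_values]
            prec, rec = precision_recall_at_k(s, y, sorted(set(ks)))
            for k_req, k_eff in zip(k_values, ks):
                prec_acc[k_req].append(prec[k_eff])
                per_drug_rec[k_req].append(rec[k_eff])
    per_drug = {
        "n_rare_drugs": int(len(rare_drugs)),
        "auroc_mean": float(np.mean(per_drug_auc)) if per_drug_auc else None,
        "precision_at": {k: (float(np.mean(v)) if v else None)
                         for k, v in prec_acc.items()},
        "recall_at": {k: (float(np.mean(v)) if v else None)
                      for k, v in per_drug_rec.items()},
    }
    pos = labels == 1
    n_pos = int(pos.sum())
    cumulative = {
        int(b): {
            "frac_drugs": float(np.mean(counts <= b)),
            "frac_test_positives": (float(np.mean(min_count[pos] <= b))
                                    if n_pos else None),
        }
        for b in bins
    }
    return {
        "threshold": int(threshold),
        "overall": _stratum(np.ones(len(scores), dtype=bool)),
        "rare": _stratum(rare_mask),
        "warm": _stratum(~rare_mask),
        "per_drug_rare": per_drug,
        "cumulative": cumulative,
    }
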