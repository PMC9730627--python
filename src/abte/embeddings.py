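"""Pre-trained biomedical text embedding I/O and drug resolution.

Embedding tables arrive in word2vec text format: an optional ``count dim``
header, then one ``token v1 ... ve`` row per line. Drugs resolve to vectors
either through an explicit drug-ID -> token mapping (concept mode, the
normalized-entity case) or by using the drug ID itself as the token (word
mode). Unresolved drugs follow a configurable fallback policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import DrugCatalog

__all__ = [
    "EmbeddingTable",
    "DrugVectorMap",
    "load_word2vec_text",
    "write_word2vec_text",
    "load_token_mapping",
    "resolve_drugs",
]


@dataclass
class EmbeddingTable:
    """Map token -> dense vector, all of one dimension e."""

    dim: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")
        for tok, v in self.vectors.items():
            if v.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has length {len(v)} != {self.dim}")

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors


@dataclass
class DrugVectorMap:
    """Resolved per-drug embedding matrix L (n x e) aligned to a catalog."""

    catalog: DrugCatalog
    matrix: np.ndarray
    resolved: np.ndarray  # bool, per drug

    @property
    def coverage(self) -> float:
        """Fraction of catalog drugs that matched a table token directly."""
        return float(self.resolved.mean())

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def load_word2vec_text(path: str | Path) -> EmbeddingTable:
    """Parse a word2vec-text embedding file.

    Accepts the standard ``<count> <dim>`` header; a headerless file has its
    dimension inferred from the first row. Rows of deviating length and
    duplicate tokens are errors (reported with line numbers).
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open() as fh:
        first = fh.readline()
        start_lineno = 2
        parts = first.split()
        if len(parts) == 2 and all(p.lstrip("+-").isdigit() for p in parts):
            dim = int(parts[1])  # header line
        else:
            start_lineno = 1
            fh.seek(0)
        for lineno, line in enumerate(fh, start=start_lineno):
            parts = line.split()
            if not parts:
                continue
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
            if len(values) != dim:
                raise ValueError(
                    f"{path}:{lineno}: row has {len(values)} values, expected {dim}"
                )
            if token in vectors:
                raise ValueError(f"{path}:{lineno}: duplicate token {token!r}")
            vectors[token] = np.array(values, dtype=np.float64)
    if dim is None or not vectors:
        raise ValueError(f"{path}: no embedding rows found")
    return EmbeddingTable(dim=dim, vectors=vectors)


def write_word2vec_text(table: EmbeddingTable, path: str | Path) -> None:
    """Write a table in word2vec text format with a ``count dim`` header."""
    with Path(path).open("w") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for token, vec in table.vectors.items():
            fh.write(token + " " + " ".join(f"{x:.8f}" for x in vec) + "\n")


def load_token_mapping(path: str | Path) -> dict[str, str]:
    """Read a ``drug_id<TAB>embedding_token`` mapping file."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            drug_id, token = line.split("\t")[:2]
            mapping[drug_id.strip()] = token.strip()
    return mapping


def resolve_drugs(
    catalog: DrugCatalog,
    table: EmbeddingTable,
    mapping: dict[str, str] | None = None,
    fallback: str = "mean",
) -> DrugVectorMap:
    """Resolve each catalog drug to an embedding vector.

    A drug resolves through the mapping first (concept mode) and otherwise by
    its own identifier as token (word mode). Unresolved drugs are handled by
    ``fallback``: ``"error"`` raises listing them, ``"zero"`` assigns the zero
    vector, ``"mean"`` (default) assigns the column-wise mean of the resolved
    rows — a neutral prior that keeps every drug scoreable.
    """
    if fallback not in ("error", "zero", "mean"):
        raise ValueError(f"unknown fallback policy {fallback!r}")
    n = len(catalog)
    matrix = np.zeros((n, table.dim), dtype=np.float64)
    resolved = np.zeros(n, dtype=bool)
    for i, drug in enumerate(catalog.drugs):
        token = mapping.get(drug, drug) if mapping else drug
        if token in table:
            matrix[i] = table.vectors[token]
            resolved[i] = True
    if not resolved.all():
        unresolved = [d for d, r in zip(catalog.drugs, resolved) if not r]
        if fallback == "error":
            raise KeyError(f"unresolved drugs: {', '.join(unresolved)}")
        if fallback == "mean" and resolved.any():
            matrix[~resolved] = matrix[resolved].mean(axis=0)
        # fallback == "zero": rows already zero
    return DrugVectorMap(catalog=catalog, matrix=matrix, resolved=resolved)
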