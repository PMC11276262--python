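"""Proteome-scale interaction prediction: candidates, scoring, bins, subnets."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy import sparse

from .classifier import TrainedModel
from .dataset import FeatureSpace, protein_indices_map

__all__ = [
    "EdgeList",
    "ScoreBinTable",
    "candidate_count",
    "generate_candidates",
    "predict_network",
    "bin_scores",
    "extract_subnetwork",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class EdgeList:
    """Scored predicted interactions above a threshold.

    Pairs are unordered and unique; ``edges`` is kept in the deterministic
    order in which candidates were generated (lexicographic).
    """

    edges: list[tuple[str, str, float]]
    n_proteins: int
    threshold: float

    def __len__(self) -> int:
        return len(self.edges)

    def self_pairs(self) -> list[tuple[str, str, float]]:
        return [e for e in self.edges if e[0] == e[1]]


@dataclass
class ScoreBinTable:
    """Cumulative edge counts strictly above each threshold."""

    thresholds: tuple[float, ...]
    counts: tuple[int, ...]

    def as_rows(self) -> list[tuple[str, int]]:
        return [(f">{t:g}", c) for t, c in zip(self.thresholds, self.counts)]


def candidate_count(n: int, include_self: bool = True) -> int:
    """Closed-form number of unordered candidate pairs for ``n`` proteins."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n + 1) // 2 if include_self else n * (n - 1) // 2


def generate_candidates(
    proteins: Sequence[str],
    include_self: bool = True,
) -> Iterator[tuple[str, str]]:
    """Stream all unordered pairs in lexicographic order (never materialized)."""
    ordered = sorted(proteins)
    if len(set(ordered)) != len(ordered):
        raise ValueError("duplicate protein ids in inventory")
    for i, a in enumerate(ordered):
        start = i if include_self else i + 1
        for b in ordered[start:]:
            yield a, b


def _batched(iterator: Iterator, size: int) -> Iterator[list]:
    batch: list = []
    for item in iterator:
        batch.append(item)
        if len(batch) == size:
            yield batch
            batch = []
    if batch:
        yield batch


def _batch_matrix(
    pairs: list[tuple[str, str]],
    pidx: Mapping[str, list[int]],
    D: int,
    reverse: bool = False,
) -> sparse.csr_matrix:
    indices: list[int] = []
    indptr = [0]
    for a, b in pairs:
        first, second = (pidx[b], pidx[a]) if reverse else (pidx[a], pidx[b])
        indices.extend(first)
        indices.extend(j + D for j in second)
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.ones(len(indices), dtype=np.int8), np.array(indices, dtype=np.int64),
         np.array(indptr, dtype=np.int64)),
        shape=(len(pairs), 2 * D),
    )


def predict_network(
    model: TrainedModel,
    proteins: Sequence[str],
    space: FeatureSpace,
    domains: Mapping[str, Iterable[str]],
    go_l: Mapping[str, Iterable[str]],
    threshold: float = 0.5,
    orientation: str = "average",
    batch_size: int = 4096,
    include_self: bool = True,
) -> EdgeList:
    """Score every candidate pair and keep edges with score > threshold.

    Per-pair score defaults to the mean of the forward and reverse
    orientation scores, which makes the result symmetric in the pair order;
    ``orientation="forward"`` scores only the lexicographic concatenation.
    Pairs are scored in fixed-size batches so memory stays O(batch).
    """
    if orientation not in ("average", "forward"):
        raise ValueError(f"unknown orientation mode {orientation!r}")
    if model.space_fingerprint and model.space_fingerprint != space.fingerprint():
        raise ValueError("model fingerprint does not match the feature space")
    if space.pair_dim != model.pair_dim:
        raise ValueError(
            f"space pair_dim {space.pair_dim} != model pair_dim {model.pair_dim}"
        )
    ordered = sorted(proteins)
    pidx = protein_indices_map(ordered, space, domains, go_l, warn_unknown=False)
    D = space.per_protein_dim

    edges: list[tuple[str, str, float]] = []
    n_scored = 0
    for batch in _batched(generate_candidates(ordered, include_self), batch_size):
        fwd = _batch_matrix(batch, pidx, D, reverse=False)
        scores = model.predict_scores(fwd)
        if orientation == "average":
            rev = _batch_matrix(batch, pidx, D, reverse=True)
            scores = (scores + model.predict_scores(rev)) / 2.0
        keep = scores > threshold
        for (a, b), s in zip(
            (batch[i] for i in np.flatnonzero(keep)), scores[keep]
        ):
            edges.append((a, b, float(s)))
        n_scored += len(batch)
        logger.info("scored %d candidate pairs, %d edges kept", n_scored, len(edges))
    return EdgeList(edges=edges, n_proteins=len(ordered), threshold=threshold)


def bin_scores(
    edges: EdgeList,
    thresholds: Sequence[float] = DEFAULT_BINS,
    subset: set[str] | None = None,
) -> ScoreBinTable:
    """Cumulative counts of edges with score strictly above each threshold.

    ``subset`` restricts counting to edges touching at least one subset
    protein.  Thresholds must be sorted ascending.
    """
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    pool = edges.edges
    if subset is not None:
        pool = [e for e in pool if e[0] in subset or e[1] in subset]
    scores = np.array([s for _, _, s in pool], dtype=float)
    counts = tuple(int(np.sum(scores > t)) for t in thresholds)
    return ScoreBinTable(thresholds=thresholds, counts=counts)


def extract_subnetwork(edges: EdgeList, subset: set[str]) -> EdgeList:
    """Edges with at least one endpoint in ``subset``."""
    kept = [e for e in edges.edges if e[0] in subset or e[1] in subset]
    return EdgeList(edges=kept, n_proteins=edges.n_proteins, threshold=edges.threshold)
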