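"""Binary feature spaces, pair vectorization, negative sampling, fold splits.

A protein is encoded as a binary vector over the ordered union of domain
identifiers and level-L GO terms; a pair is the concatenation of its two
protein vectors, optionally emitted in both concatenation orders ("mirrored"
vectors).  Rows are stored sparsely (CSR) since typical densities are well
below 1%.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import io as spio
from scipy import sparse

from .io_sources import PPIRecord, pair_key

__all__ = [
    "FeatureSpace",
    "LabeledPair",
    "VectorizedDataset",
    "FoldSplit",
    "build_feature_space",
    "vectorize_protein",
    "vectorize_pair",
    "sample_negatives",
    "assemble_dataset",
    "expected_row_count",
    "kfold_split",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered binary-feature coordinates: domains first, then GO terms.

    Ordering is lexicographic within each block and fixed at construction.
    """

    domain_features: tuple[str, ...]
    go_features: tuple[str, ...]

    def __post_init__(self):
        overlap = set(self.domain_features) & set(self.go_features)
        if overlap:
            raise ValueError(
                f"feature id(s) present in both domain and GO blocks: {sorted(overlap)[:5]}"
            )
        index = {f: i for i, f in enumerate(self.domain_features + self.go_features)}
        if len(index) != self.per_protein_dim:
            raise ValueError("duplicate feature ids within a block")
        object.__setattr__(self, "_index", index)

    @property
    def per_protein_dim(self) -> int:
        return len(self.domain_features) + len(self.go_features)

    @property
    def pair_dim(self) -> int:
        return 2 * self.per_protein_dim

    @property
    def index(self) -> dict[str, int]:
        return self._index  # type: ignore[attr-defined]

    def fingerprint(self) -> str:
        """Stable content hash used to guard model/space compatibility."""
        h = hashlib.sha256()
        h.update("\n".join(self.domain_features).encode())
        h.update(b"\x00")
        h.update("\n".join(self.go_features).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class LabeledPair:
    protein_a: str
    protein_b: str
    label: int
    orientation: str  # "forward" | "reverse"

    def key(self) -> tuple[str, str]:
        return pair_key(self.protein_a, self.protein_b)


@dataclass
class VectorizedDataset:
    """Sparse binary pair matrix with labels and per-row pair provenance."""

    rows: sparse.csr_matrix
    labels: np.ndarray
    pairs: list[LabeledPair]
    space: FeatureSpace
    mirrored: bool
    shuffle_seed: int

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.rows.todense(), dtype=np.int8)


@dataclass(frozen=True)
class FoldSplit:
    """Row→fold assignment for k-fold cross-validation."""

    k: int
    assignment: np.ndarray
    mode: str  # "row_level" | "pair_group"

    def test_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def build_feature_space(
    domains: Mapping[str, Iterable[str]],
    go_l: Mapping[str, Iterable[str]],
) -> FeatureSpace:
    """Union the distinct domain and GO identifiers into a feature space.

    Per-protein dimension = distinct domains + distinct GO terms; the pair
    dimension doubles it.
    """
    domain_ids = sorted({d for ds in domains.values() for d in ds})
    go_ids = sorted({g for gs in go_l.values() for g in gs})
    if not domain_ids and not go_ids:
        raise ValueError("both annotation tables are empty; no features to build")
    return FeatureSpace(tuple(domain_ids), tuple(go_ids))


def protein_indices(
    protein: str,
    space: FeatureSpace,
    domains: Mapping[str, Iterable[str]],
    go_l: Mapping[str, Iterable[str]],
) -> list[int]:
    """Sorted set-bit coordinates of one protein's per-protein vector."""
    feats: set[str] = set()
    feats.update(domains.get(protein, ()))
    feats.update(go_l.get(protein, ()))
    idx = space.index
    return sorted(idx[f] for f in feats if f in idx)


def protein_indices_map(
    proteins: Iterable[str],
    space: FeatureSpace,
    domains: Mapping[str, Iterable[str]],
    go_l: Mapping[str, Iterable[str]],
    warn_unknown: bool = True,
) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    unknown = 0
    for p in proteins:
        if p not in domains and p not in go_l:
            unknown += 1
        out[p] = protein_indices(p, space, domains, go_l)
    if unknown and warn_unknown:
        warnings.warn(
            f"{unknown} protein(s) absent from both annotation tables; "
            "encoded as all-zero vectors",
            UserWarning,
            stacklevel=2,
        )
    return out


def vectorize_protein(
    protein: str,
    space: FeatureSpace,
    domains: Mapping[str, Iterable[str]],
    go_l: Mapping[str, Iterable[str]],
) -> np.ndarray:
    """Dense binary vector of length ``space.per_protein_dim``."""
    vec = np.zeros(space.per_protein_dim, dtype=np.int8)
    idx = protein_indices(protein, space, domains, go_l)
    if not idx and protein not in domains and protein not in go_l:
        warnings.warn(f"unknown protein {protein!r}: all-zero vector", UserWarning, stacklevel=2)
    vec[idx] = 1
    return vec


def vectorize_pair(
    a: str,
    b: str,
    space: FeatureSpace,
    domains: Mapping[str, Iterable[str]],
    go_l: Mapping[str, Iterable[str]],
    mirrored: bool = True,
) -> list[np.ndarray]:
    """Concatenated pair vector(s): forward = vec(a)+vec(b), reverse swapped.

    With ``mirrored=True`` both concatenation orders are returned (even for a
    self pair, where they coincide).
    """
    va = vectorize_protein(a, space, domains, go_l)
    vb = vectorize_protein(b, space, domains, go_l)
    forward = np.concatenate([va, vb])
    if not mirrored:
        return [forward]
    return [forward, np.concatenate([vb, va])]


def expected_row_count(n_pos: int, n_neg: int, mirrored: bool = True) -> int:
    """Closed-form dataset size: (positives + negatives) x orientations."""
    return (n_pos + n_neg) * (2 if mirrored else 1)


def _as_pairs(records: Iterable) -> list[tuple[str, str]]:
    out = []
    for r in records:
        if isinstance(r, PPIRecord):
            out.append((r.protein_a, r.protein_b))
        else:
            a, b = r[0], r[1]
            out.append((a, b))
    return out


def sample_negatives(
    proteins: Sequence[str],
    all_positives: Iterable,
    n: int,
    seed: int,
    max_draw_factor: int = 200,
) -> list[PPIRecord]:
    """Draw ``n`` distinct unordered non-positive, non-self pairs.

    Candidate pairs are drawn by repeatedly sampling two protein indices at
    random and rejecting self pairs, pairs present in ``all_positives``
    (either orientation) and duplicates.  Reproducible per ``seed``; raises
    if the non-positive pool is smaller than ``n`` or the rejection loop
    exceeds ``max_draw_factor * n`` draws.
    """
    proteins = list(proteins)
    protein_set = set(proteins)
    if len(protein_set) != len(proteins):
        raise ValueError("duplicate protein ids in inventory")
    m = len(proteins)
    positive_keys = {pair_key(a, b) for a, b in _as_pairs(all_positives)}
    in_pool = {
        k for k in positive_keys
        if k[0] != k[1] and k[0] in protein_set and k[1] in protein_set
    }
    pool = m * (m - 1) // 2 - len(in_pool)
    if n > pool:
        raise ValueError(
            f"cannot sample {n} negatives: only {pool} non-positive pairs available"
        )

    rng = np.random.default_rng(seed)
    chosen: dict[tuple[str, str], None] = {}
    draws = 0
    cap = max_draw_factor * max(n, 1)
    while len(chosen) < n:
        if draws >= cap:
            raise RuntimeError(
                f"negative sampling exceeded {cap} draws ({len(chosen)}/{n} found); "
                "pool too saturated"
            )
        i, j = rng.integers(0, m, size=2)
        draws += 1
        if i == j:
            continue
        key = pair_key(proteins[i], proteins[j])
        if key in positive_keys or key in chosen:
            continue
        chosen[key] = None
    return [PPIRecord(a, b, combined_score=None, label="negative") for a, b in chosen]


def assemble_dataset(
    positives: Iterable,
    negatives: Iterable,
    space: FeatureSpace,
    domains: Mapping[str, Iterable[str]],
    go_l: Mapping[str, Iterable[str]],
    mirrored: bool = True,
    shuffle_seed: int = 0,
) -> VectorizedDataset:
    """Vectorize both classes, mirror, and shuffle rows and labels together.

    Raises if the two classes overlap as unordered pairs.
    """
    pos_pairs = _as_pairs(positives)
    neg_pairs = _as_pairs(negatives)
    overlap = {pair_key(*p) for p in pos_pairs} & {pair_key(*p) for p in neg_pairs}
    if overlap:
        raise ValueError(
            f"{len(overlap)} pair(s) present in both classes, e.g. {sorted(overlap)[:5]}"
        )

    all_proteins = {p for a, b in pos_pairs + neg_pairs for p in (a, b)}
    pidx = protein_indices_map(sorted(all_proteins), space, domains, go_l)
    D = space.per_protein_dim

    indices: list[int] = []
    indptr = [0]
    labels: list[int] = []
    pairs: list[LabeledPair] = []

    def emit(a: str, b: str, label: int) -> None:
        ia, ib = pidx[a], pidx[b]
        indices.extend(ia)
        indices.extend(j + D for j in ib)
        indptr.append(len(indices))
        labels.append(label)
        pairs.append(LabeledPair(a, b, label, "forward"))
        if mirrored:
            indices.extend(ib)
            indices.extend(j + D for j in ia)
            indptr.append(len(indices))
            labels.append(label)
            pairs.append(LabeledPair(a, b, label, "reverse"))

    for a, b in pos_pairs:
        emit(a, b, 1)
    for a, b in neg_pairs:
        emit(a, b, 0)

    n_rows = len(labels)
    assert n_rows == expected_row_count(len(pos_pairs), len(neg_pairs), mirrored)
    rows = sparse.csr_matrix(
        (np.ones(len(indices), dtype=np.int8), np.array(indices, dtype=np.int64),
         np.array(indptr, dtype=np.int64)),
        shape=(n_rows, space.pair_dim),
    )

    perm = np.random.default_rng(shuffle_seed).permutation(n_rows)
    rows = rows[perm]
    label_arr = np.array(labels, dtype=np.int8)[perm]
    pair_list = [pairs[i] for i in perm]
    return VectorizedDataset(
        rows=rows,
        labels=label_arr,
        pairs=pair_list,
        space=space,
        mirrored=mirrored,
        shuffle_seed=shuffle_seed,
    )


def kfold_split(
    ds: VectorizedDataset,
    k: int,
    seed: int = 0,
    mode: str = "row_level",
) -> FoldSplit:
    """Assign rows to ``k`` near-equal folds.

    ``row_level`` shuffles individual rows (mirror twins may land in
    different folds, matching a plain row shuffle); ``pair_group`` keeps both
    orientations of a pair in the same fold to prevent twin leakage.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    n = ds.n_rows
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=np.int32)
    if mode == "row_level":
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            assignment[chunk] = fold
    elif mode == "pair_group":
        keys: list[tuple[str, str]] = []
        seen: dict[tuple[str, str], int] = {}
        rows_of: list[list[int]] = []
        for i, pair in enumerate(ds.pairs):
            key = pair.key()
            if key not in seen:
                seen[key] = len(keys)
                keys.append(key)
                rows_of.append([])
            rows_of[seen[key]].append(i)
        order = rng.permutation(len(keys))
        for fold, chunk in enumerate(np.array_split(order, k)):
            for g in chunk:
                assignment[rows_of[g]] = fold
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return FoldSplit(k=k, assignment=assignment, mode=mode)


# ---------------------------------------------------------------------------
# Serialization (MatrixMarket matrix + sidecar TSV/JSON)
# ---------------------------------------------------------------------------


def save_dataset(ds: VectorizedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"), ds.rows.astype(np.int8))
    np.savetxt(outdir / "labels.tsv", ds.labels, fmt="%d")
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("protein_a\tprotein_b\tlabel\torientation\n")
        for p in ds.pairs:
            fh.write(f"{p.protein_a}\t{p.protein_b}\t{p.label}\t{p.orientation}\n")
    with open(outdir / "features.tsv", "w") as fh:
        fh.write("feature\tblock\n")
        for f in ds.space.domain_features:
            fh.write(f"{f}\tdomain\n")
        for f in ds.space.go_features:
            fh.write(f"{f}\tgo\n")
    meta = {
        "mirrored": ds.mirrored,
        "shuffle_seed": ds.shuffle_seed,
        "fingerprint": ds.space.fingerprint(),
        "n_rows": ds.n_rows,
        "pair_dim": ds.space.pair_dim,
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_dataset(indir: str | Path) -> VectorizedDataset:
    indir = Path(indir)
    rows = sparse.csr_matrix(spio.mmread(str(indir / "matrix.mtx")), dtype=np.int8)
    labels = np.loadtxt(indir / "labels.tsv", dtype=np.int8, ndmin=1)
    pairs: list[LabeledPair] = []
    with open(indir / "pairs.tsv") as fh:
        next(fh)
        for line in fh:
            a, b, label, orientation = line.rstrip("\n").split("\t")
            pairs.append(LabeledPair(a, b, int(label), orientation))
    domain_feats: list[str] = []
    go_feats: list[str] = []
    with open(indir / "features.tsv") as fh:
        next(fh)
        for line in fh:
            feat, block = line.rstrip("\n").split("\t")
            (domain_feats if block == "domain" else go_feats).append(feat)
    space = FeatureSpace(tuple(domain_feats), tuple(go_feats))
    meta = json.loads((indir / "meta.json").read_text())
    if meta["fingerprint"] != space.fingerprint():
        raise ValueError("feature table does not match stored fingerprint")
    return VectorizedDataset(
        rows=rows,
        labels=labels,
        pairs=pairs,
        space=space,
        mirrored=bool(meta["mirrored"]),
        shuffle_seed=int(meta["shuffle_seed"]),
    )
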