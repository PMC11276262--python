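import itertools

import numpy as np
import pytest

from ppilearn.dataset import (
    FeatureSpace,
    assemble_dataset,
    build_feature_space,
    expected_row_count,
    kfold_split,
    load_dataset,
    sample_negatives,
    save_dataset,
    vectorize_pair,
    vectorize_protein,
)
from ppilearn.io_sources import PPIRecord, pair_key

DOMAINS = {"P1": {"PF2", "PF1"}, "P2": {"PF3"}, "P3": set()}
GO = {"P1": {"GO:2"}, "P2": {"GO:1"}, "P3": {"GO:1", "GO:2"}}


@pytest.fixture
def space():
    return build_feature_space(DOMAINS, GO)


class TestFeatureSpace:
    def test_small_dims(self):
        space = build_feature_space({"P": {"PF1"}}, {"P": {"GO:1"}})
        assert space.per_protein_dim == 2
        assert space.pair_dim == 4

    def test_ordering_lexicographic_and_blocked(self, space):
        assert space.domain_features == ("PF1", "PF2", "PF3")
        assert space.go_features == ("GO:1", "GO:2")

    def test_id_collision_between_blocks_rejected(self):
        with pytest.raises(ValueError, match="both"):
            FeatureSpace(("X",), ("X",))

    def test_duplicate_within_block_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureSpace(("X", "X"), ())

    def test_fingerprint_tracks_content(self, space):
        other = build_feature_space(DOMAINS, {"P1": {"GO:3"}})
        assert space.fingerprint() != other.fingerprint()
        assert space.fingerprint() == build_feature_space(DOMAINS, GO).fingerprint()


class TestVectorize:
    def test_popcount_matches_annotations(self, space):
        vec = vectorize_protein("P1", space, DOMAINS, GO)
        assert vec.sum() == 3  # PF1, PF2, GO:2

    def test_unknown_protein_zero_vector_with_warning(self, space):
        with pytest.warns(UserWarning, match="unknown protein"):
            vec = vectorize_protein("P404", space, DOMAINS, GO)
        assert vec.sum() == 0

    def test_all_features_present_all_ones(self):
        domains = {"P": {"PF1", "PF2"}}
        go = {"P": {"GO:1"}}
        space = build_feature_space(domains, go)
        assert vectorize_protein("P", space, domains, go).tolist() == [1, 1, 1]

    def test_mirrored_pair_construction(self):
        domains = {"A": {"PF1"}, "B": set()}
        go = {"A": set(), "B": {"GO:1"}}
        space = build_feature_space(domains, go)  # order: PF1, GO:1
        fwd, rev = vectorize_pair("A", "B", space, domains, go, mirrored=True)
        assert fwd.tolist() == [1, 0, 0, 1]
        assert rev.tolist() == [0, 1, 1, 0]

    def test_self_pair_mirrors_coincide(self, space):
        fwd, rev = vectorize_pair("P1", "P1", space, DOMAINS, GO, mirrored=True)
        assert np.array_equal(fwd, rev)

    def test_unmirrored_single_vector(self, space):
        assert len(vectorize_pair("P1", "P2", space, DOMAINS, GO, mirrored=False)) == 1

    def test_vector_reconstructs_supported_annotations(self, space):
        # bijection on the supported feature set
        all_feats = space.domain_features + space.go_features
        for protein in DOMAINS:
            vec = vectorize_protein(protein, space, DOMAINS, GO)
            recovered = {all_feats[i] for i in np.flatnonzero(vec)}
            assert recovered == (DOMAINS[protein] | GO[protein]) & set(all_feats)


class TestSampleNegatives:
    def test_four_protein_enumeration(self):
        proteins = ["P1", "P2", "P3", "P4"]
        positives = [("P1", "P2")]
        negatives = sample_negatives(proteins, positives, 5, seed=0)
        drawn = {r.key() for r in negatives}
        universe = {pair_key(a, b) for a, b in itertools.combinations(proteins, 2)}
        assert drawn == universe - {("P1", "P2")}

    def test_determinism(self):
        proteins = [f"P{i}" for i in range(20)]
        a = sample_negatives(proteins, [("P0", "P1")], 10, seed=42)
        b = sample_negatives(proteins, [("P0", "P1")], 10, seed=42)
        assert [r.key() for r in a] == [r.key() for r in b]

    def test_infeasible_request_reports_pool(self):
        with pytest.raises(ValueError, match="only 2"):
            sample_negatives(["A", "B", "C"], [("A", "B")], 3, seed=0)

    def test_disjointness_exhaustive_small_pools(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            m = int(rng.integers(5, 30))
            proteins = [f"P{i}" for i in range(m)]
            universe = list(itertools.combinations(proteins, 2))
            k = int(rng.integers(0, len(universe) // 2))
            pos_idx = rng.choice(len(universe), size=k, replace=False)
            positives = [universe[i] for i in pos_idx]
            n = min(10, len(universe) - k)
            negatives = sample_negatives(proteins, positives, n, seed=trial)
            drawn = [r.key() for r in negatives]
            assert len(set(drawn)) == n
            assert not set(drawn) & {pair_key(a, b) for a, b in positives}
            assert all(a != b for a, b in drawn)


class TestAssembleDataset:
    def test_tiny_unmirrored(self, space):
        ds = assemble_dataset(
            [("P1", "P2")], [("P1", "P3")], space, DOMAINS, GO, mirrored=False
        )
        assert ds.n_rows == 2
        assert sorted(ds.labels.tolist()) == [0, 1]

    def test_mirrored_row_count_and_balance(self, space):
        pos = [("P1", "P2")]
        neg = [("P2", "P3")]
        ds = assemble_dataset(pos, neg, space, DOMAINS, GO, mirrored=True)
        assert ds.n_rows == expected_row_count(1, 1, True) == 4
        assert int(ds.labels.sum()) == 2
        # exactly half of each pair's rows are forward
        orientations = [p.orientation for p in ds.pairs]
        assert orientations.count("forward") == orientations.count("reverse")

    def test_overlap_between_classes_rejected(self, space):
        with pytest.raises(ValueError, match="both classes"):
            assemble_dataset(
                [("P1", "P2")], [("P2", "P1")], space, DOMAINS, GO
            )

    def test_shuffle_deterministic(self, space):
        pos = [("P1", "P2"), ("P1", "P3")]
        neg = [("P2", "P3")]
        a = assemble_dataset(pos, neg, space, DOMAINS, GO, shuffle_seed=9)
        b = assemble_dataset(pos, neg, space, DOMAINS, GO, shuffle_seed=9)
        assert np.array_equal(a.labels, b.labels)
        assert (a.rows != b.rows).nnz == 0
        assert a.pairs == b.pairs

    def test_rows_match_pair_vectors(self, space):
        ds = assemble_dataset([("P1", "P2")], [], space, DOMAINS, GO, mirrored=True)
        dense = ds.to_dense()
        fwd, rev = vectorize_pair("P1", "P2", space, DOMAINS, GO, mirrored=True)
        by_orientation = {p.orientation: dense[i] for i, p in enumerate(ds.pairs)}
        assert np.array_equal(by_orientation["forward"], fwd)
        assert np.array_equal(by_orientation["reverse"], rev)

    def test_accepts_ppirecords(self, space):
        pos = [PPIRecord("P1", "P2", 950, "positive")]
        neg = [PPIRecord("P1", "P3", None, "negative")]
        ds = assemble_dataset(pos, neg, space, DOMAINS, GO)
        assert ds.n_rows == 4


class TestKFold:
    def _dataset(self, space, n_pairs=5):
        pos = [(f"P1", f"P2")] * 1  # placeholder, rebuilt below
        proteins = list(DOMAINS)
        pairs = [(proteins[i % 3], proteins[(i + 1) % 3]) for i in range(n_pairs)]
        # ensure distinct unordered pairs by generating on a bigger universe
        domains = {f"Q{i}": {"PF1"} for i in range(n_pairs + 1)}
        go = {f"Q{i}": set() for i in range(n_pairs + 1)}
        sp = build_feature_space(domains, {"Q0": {"GO:1"}})
        pos = [(f"Q{i}", f"Q{i + 1}") for i in range(n_pairs)]
        return assemble_dataset(pos, [], sp, domains, go, mirrored=True)

    def test_ten_rows_five_folds(self, space):
        ds = self._dataset(space, n_pairs=5)
        assert ds.n_rows == 10
        split = kfold_split(ds, 5, seed=0)
        sizes = [len(split.test_rows(f)) for f in range(5)]
        assert sizes == [2, 2, 2, 2, 2]

    def test_near_equal_sizes_row_level(self, space):
        ds = self._dataset(space, n_pairs=8)  # 16 rows
        split = kfold_split(ds, 5, seed=1)
        sizes = [len(split.test_rows(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == ds.n_rows

    def test_pair_group_keeps_twins_together(self, space):
        ds = self._dataset(space, n_pairs=7)
        split = kfold_split(ds, 3, seed=2, mode="pair_group")
        fold_of = {}
        for i, pair in enumerate(ds.pairs):
            key = pair.key()
            fold_of.setdefault(key, set()).add(split.assignment[i])
        assert all(len(folds) == 1 for folds in fold_of.values())

    def test_bad_k_rejected(self, space):
        ds = self._dataset(space, n_pairs=3)
        with pytest.raises(ValueError, match="k must be"):
            kfold_split(ds, 1)

    def test_fold_sizes_integer_division_oracle(self, space):
        # n rows into k folds: sizes are ceil or floor of n/k
        ds = self._dataset(space, n_pairs=13)  # 26 rows
        for k in (3, 4, 5):
            split = kfold_split(ds, k, seed=3)
            sizes = sorted(len(split.test_rows(f)) for f in range(k))
            n = ds.n_rows
            expected = sorted([n // k + 1] * (n % k) + [n // k] * (k - n % k))
            assert sizes == expected


class TestSerialization:
    def test_roundtrip(self, space, tmp_path):
        ds = assemble_dataset(
            [("P1", "P2")], [("P1", "P3")], space, DOMAINS, GO, shuffle_seed=4
        )
        save_dataset(ds, tmp_path / "ds")
        again = load_dataset(tmp_path / "ds")
        assert np.array_equal(again.labels, ds.labels)
        assert (again.rows != ds.rows).nnz == 0
        assert again.pairs == ds.pairs
        assert again.space.fingerprint() == ds.space.fingerprint()
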