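import logging
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from quatstack.features import (
    FeatureVector,
    PseASAParams,
    SparseParseError,
    encode_block,
    encode_from_hits,
    encode_pseasa,
    feature_matrix,
    load_precomputed_hits,
    pseaac,
    read_sparse,
    split_accessibility,
    write_sparse,
)
from quatstack.records import AA20, AA_INDEX, ProteinRecord


def pseaac_oracle(seq, lam, w, properties):
    """Straight-line independent evaluation of the encoding formulas."""
    L = len(seq)
    freqs = [seq.count(a) / L for a in AA20]
    thetas = []
    for j in range(1, lam + 1):
        total = 0.0
        for i in range(L - j):
            a, b = AA_INDEX[seq[i]], AA_INDEX[seq[i + j]]
            total += sum((p[a] - p[b]) ** 2 for p in properties) / len(properties)
        thetas.append(total / (L - j))
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


class TestBlockEncoding:
    def test_dimension_always_matches_db(self, tiny_fixture):
        _, block_db, _, records, _ = tiny_fixture
        for r in records[:5]:
            assert encode_block(r, block_db).dimension == len(block_db)

    def test_no_hit_sequence_gives_zero_vector(self, tiny_fixture):
        _, block_db, _, _, _ = tiny_fixture
        rec = ProteinRecord("z", "W" * 60)
        v = encode_block(rec, block_db)
        assert v.entries == {}
        assert (v.to_dense() == 0).all()

    def test_planted_bits_are_set(self, tiny_fixture):
        _, block_db, _, records, truth = tiny_fixture
        checked = 0
        for r in records:
            planted = {m for m in truth.planted_ids(r.id) if m in block_db}
            bits = set(encode_block(r, block_db).entries)
            assert bits >= {block_db.index_of(m) + 1 for m in planted}
            checked += len(planted)
        assert checked > 0

    def test_database_permutation_covariance(self, tiny_fixture):
        from quatstack.motifs import BlockDatabase

        _, block_db, _, records, _ = tiny_fixture
        perm = [3, 0, 4, 1, 5, 2]
        permuted = BlockDatabase([block_db.motifs[i] for i in perm], name="perm")
        for r in records[:6]:
            orig = encode_block(r, block_db)
            new = encode_block(r, permuted)
            remapped = {
                permuted.index_of(block_db.ids[i - 1]) + 1: v
                for i, v in orig.entries.items()
            }
            assert new.entries == remapped


class TestPrecomputedHits:
    def test_round_trip_and_unknown_id_warning(self, tmp_path, tiny_fixture, caplog):
        _, block_db, _, _, _ = tiny_fixture
        p = tmp_path / "hits.tsv"
        known = block_db.ids[1]
        p.write_text(f"p1\t{known}\np1\tNOT_A_BLOCK\n")
        with caplog.at_level(logging.WARNING):
            hits = load_precomputed_hits(p, block_db)
        assert hits == {"p1": {known}}
        assert "ignored 1" in caplog.text
        v = encode_from_hits("p1", hits, block_db)
        assert v.entries == {block_db.index_of(known) + 1: 1.0}
        assert encode_from_hits("absent", hits, block_db).entries == {}

    def test_empty_file_encodes_all_zero(self, tmp_path, tiny_fixture):
        _, block_db, _, _, _ = tiny_fixture
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert load_precomputed_hits(p, block_db) == {}


class TestAccessibilitySplit:
    def test_split_rule(self):
        rec = ProteinRecord("p", "MKTAY", accessibility="EBEBE")
        assert split_accessibility(rec) == ("MTY", "KA")

    def test_all_exposed(self):
        rec = ProteinRecord("p", "MKT", accessibility="EEE")
        assert split_accessibility(rec) == ("MKT", "")

    def test_missing_labels_point_to_sidecar(self):
        with pytest.raises(ValueError, match="sidecar"):
            split_accessibility(ProteinRecord("p", "MKT"))


class TestPseaac:
    def test_lam_zero_is_plain_composition(self):
        params = PseASAParams(lam=0)
        v = pseaac("AAAA", params)
        expected = np.zeros(20)
        expected[AA_INDEX["A"]] = 1.0
        np.testing.assert_allclose(v, expected)

    @given(st.text(alphabet=AA20, min_size=1, max_size=60))
    def test_unit_sum(self, seq):
        v = pseaac(seq, PseASAParams(lam=5))
        assert abs(v.sum() - 1.0) < 1e-9

    def test_acac_matches_direct_formula_oracle(self):
        params = PseASAParams(lam=1, w=0.05)
        got = pseaac("ACAC", params)
        want = pseaac_oracle("ACAC", 1, 0.05, [list(p) for p in params.properties])
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_random_sequences_match_oracle(self):
        rng = np.random.default_rng(13)
        params = PseASAParams(lam=4, w=0.1)
        props = [list(p) for p in params.properties]
        for _ in range(10):
            seq = "".join(AA20[c] for c in rng.integers(20, size=int(rng.integers(6, 40))))
            np.testing.assert_allclose(
                pseaac(seq, params), pseaac_oracle(seq, 4, 0.1, props), atol=1e-9
            )

    def test_unknown_residues_are_dropped(self):
        params = PseASAParams(lam=2)
        np.testing.assert_allclose(
            pseaac("ACXXAC", params), pseaac("ACAC", params), atol=1e-12
        )

    def test_short_sequence_degrades_lam_keeping_dimension(self, caplog):
        params = PseASAParams(lam=10)
        with caplog.at_level(logging.WARNING):
            v = pseaac("ACD", params)
        assert len(v) == 30
        assert (v[20 + 2 :] == 0).all()  # ranks beyond len-1 unreachable
        assert "degrading" in caplog.text


class TestEncodePseasa:
    def test_dimension_is_twice_20_plus_lam(self):
        rec = ProteinRecord("p", "MKTAYMKTAYMK", accessibility="EB" * 6)
        v = encode_pseasa(rec, PseASAParams(lam=10))
        assert v.dimension == 60

    def test_all_buried_zeroes_exposed_block(self):
        rec = ProteinRecord("p", "MKTAY", accessibility="BBBBB")
        dense = encode_pseasa(rec, PseASAParams(lam=0)).to_dense()
        assert (dense[:20] == 0).all()
        assert dense[20:].sum() == pytest.approx(1.0)

    def test_blocks_equal_per_side_composition(self):
        params = PseASAParams(lam=0)
        rec = ProteinRecord("p", "MKTAY", accessibility="EBEBE")
        dense = encode_pseasa(rec, params).to_dense()
        np.testing.assert_allclose(dense[:20], pseaac("MTY", params))
        np.testing.assert_allclose(dense[20:], pseaac("KA", params))


class TestSparseFormat:
    def test_single_entry_line(self, tmp_path):
        p = tmp_path / "v.sparse"
        write_sparse(p, [FeatureVector("block", 3, {2: 1.0})], ["+1"])
        assert p.read_text() == "+1 2:1\n"

    def test_round_trip_of_random_vectors(self, tmp_path):
        rng = np.random.default_rng(7)
        vecs, labels = [], []
        for i in range(100):
            entries = {
                int(j) + 1: 1.0 for j in np.flatnonzero(rng.random(15) < 0.3)
            }
            vecs.append(FeatureVector("block", 15, entries))
            labels.append(f"homo:{rng.choice([2, 3, 4])}")
        p = tmp_path / "v.sparse"
        write_sparse(p, vecs, labels)
        labels2, vecs2 = read_sparse(p, "block", dimension=15)
        assert labels2 == labels
        assert [v.entries for v in vecs2] == [v.entries for v in vecs]

    def test_non_ascending_indices_rejected_with_line(self, tmp_path):
        p = tmp_path / "bad.sparse"
        p.write_text("+1 1:1\n1 3:1 2:1\n")
        with pytest.raises(SparseParseError, match="line 2"):
            read_sparse(p)


class TestFeatureMatrix:
    def test_stack_and_dimension_check(self):
        vs = [FeatureVector("block", 4, {1: 1.0}), FeatureVector("block", 4, {4: 1.0})]
        m = feature_matrix(vs)
        assert m.shape == (2, 4)
        with pytest.raises(ValueError, match="inconsistent"):
            feature_matrix(vs + [FeatureVector("block", 5, {})])
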