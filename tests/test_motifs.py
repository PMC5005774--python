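import math

import numpy as np
import pytest

from quatstack.motifs import (
    NO_HIT_SCORE,
    SCORE_FLOOR,
    BlockDatabase,
    BlockMotif,
    BlockParseError,
    build_pssm,
    calibrate_threshold,
    find_hits,
    parse_block_db,
    scan,
    write_block_db,
)
from quatstack.records import AA20, AA_INDEX


def brute_force_scan(sequence, motif):
    """Oracle: score every window position-by-position in pure Python."""
    w = motif.width
    best_score, best_off = NO_HIT_SCORE, -1
    for o in range(len(sequence) - w + 1):
        s = 0.0
        for j in range(w):
            ch = sequence[o + j]
            if ch in AA_INDEX:
                s += motif.pssm[j, AA_INDEX[ch]]
        if s > best_score:
            best_score, best_off = s, o
    return best_score, best_off


def _random_seq(rng, n):
    return "".join(AA20[c] for c in rng.integers(20, size=n))


class TestBuildPssm:
    def test_direct_formula_two_segments(self):
        pssm = build_pssm(["AC", "AD"], pseudocount=1.0)
        q = 1 / 20
        # position 0: A seen twice of n=2
        assert pssm[0, AA_INDEX["A"]] == pytest.approx(math.log2(((2 + q) / 3) / q))
        assert pssm[0, AA_INDEX["W"]] == pytest.approx(math.log2(((0 + q) / 3) / q))
        # position 1: C and D once each
        for ch in "CD":
            assert pssm[1, AA_INDEX[ch]] == pytest.approx(math.log2(((1 + q) / 3) / q))

    def test_zero_pseudocount_limits(self):
        pssm = build_pssm(["AA"], pseudocount=0.0)
        assert pssm[0, AA_INDEX["A"]] == pytest.approx(math.log2(20))
        assert (pssm[0, np.arange(20) != AA_INDEX["A"]] == SCORE_FLOOR).all()
        assert np.isfinite(build_pssm(["AA"], pseudocount=1.0)).all()

    def test_equal_frequency_symmetry(self):
        pssm = build_pssm(["AA", "CC"])
        assert pssm[0, AA_INDEX["A"]] == pytest.approx(pssm[0, AA_INDEX["C"]])
        assert pssm[1, AA_INDEX["A"]] == pytest.approx(pssm[1, AA_INDEX["C"]])

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="conserved"):
            build_pssm(["AX"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            build_pssm(["ACD", "AC"])


class TestScan:
    def test_consensus_scores_sum_of_row_maxima(self):
        motif = BlockMotif.from_segments("m", ["ACD", "ACD"])
        score, offset = scan("ACD", motif)
        assert offset == 0
        assert score == pytest.approx(float(motif.pssm.max(axis=1).sum()))

    def test_embedded_motif_offset(self):
        motif = BlockMotif.from_segments("m", ["ACD", "ACD"])
        score, offset = scan("WWWACDWW", motif)
        assert offset == 3
        assert (score, offset) == pytest.approx(brute_force_scan("WWWACDWW", motif))

    def test_too_short_sequence_gives_sentinel(self):
        motif = BlockMotif.from_segments("m", ["ACDE"])
        assert scan("AC", motif) == (NO_HIT_SCORE, -1)

    def test_unknown_residues_score_zero(self):
        motif = BlockMotif.from_segments("m", ["AC", "AC"])
        score, _ = scan("XX", motif)
        assert score == 0.0

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            w = int(rng.integers(2, 8))
            motif = BlockMotif.from_segments(
                "m", [_random_seq(rng, w) for _ in range(3)]
            )
            seq = list(_random_seq(rng, int(rng.integers(w, 50))))
            for i in range(len(seq)):
                if rng.random() < 0.05:
                    seq[i] = "X"
            seq = "".join(seq)
            assert scan(seq, motif) == pytest.approx(brute_force_scan(seq, motif))

    def test_appending_residues_never_decreases_best_score(self):
        rng = np.random.default_rng(23)
        motif = BlockMotif.from_segments("m", [_random_seq(rng, 5) for _ in range(4)])
        seq = _random_seq(rng, 5)
        prev = scan(seq, motif)[0]
        for _ in range(30):
            seq += AA20[rng.integers(20)]
            cur = scan(seq, motif)[0]
            assert cur >= prev
            prev = cur


@pytest.fixture(scope="module")
def motif():
    rng = np.random.default_rng(31)
    consensus = _random_seq(rng, 10)
    segments = []
    for _ in range(5):
        seg = list(consensus)
        for j in range(10):
            if rng.random() < 0.1:
                seg[j] = AA20[rng.integers(20)]
        segments.append("".join(seg))
    return BlockMotif.from_segments("fix", segments)


@pytest.fixture(scope="module")
def db():
    rng = np.random.default_rng(41)
    motifs = []
    for i in range(3):
        consensus = _random_seq(rng, 8)
        segs = []
        for _ in range(5):
            seg = list(consensus)
            for j in range(8):
                if rng.random() < 0.1:
                    seg[j] = AA20[rng.integers(20)]
            segs.append("".join(seg))
        m = BlockMotif.from_segments(f"m{i}", segs)
        m.hit_threshold = calibrate_threshold(m, seed=100 + i)
        motifs.append(m)
    return BlockDatabase(motifs, name="fixture")


class TestCalibration:
    def test_deterministic_and_monotone_in_quantile(self, motif):
        t1 = calibrate_threshold(motif, seed=5)
        t2 = calibrate_threshold(motif, seed=5)
        tmax = calibrate_threshold(motif, quantile=1.0, seed=5)
        assert t1 == t2
        assert tmax >= t1

    def test_planted_consensus_detected_in_95_percent_of_trials(self, motif):
        threshold = calibrate_threshold(motif, seed=5)
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(200):
            seq = list(_random_seq(rng, 50))
            pos = int(rng.integers(0, 41))
            seq[pos : pos + 10] = motif.consensus
            if scan("".join(seq), motif)[0] >= threshold:
                hits += 1
        assert hits >= 190

    def test_too_few_decoys_rejected(self, motif):
        with pytest.raises(ValueError):
            calibrate_threshold(motif, n_decoys=10)


class TestFindHits:
    def test_random_sequences_rarely_hit(self, db):
        rng = np.random.default_rng(53)
        total = sum(len(find_hits(_random_seq(rng, 50), db)) for _ in range(100))
        assert total <= 1

    def test_embedded_consensus_is_found(self, db):
        rng = np.random.default_rng(59)
        target = db.motifs[1]
        seq = list(_random_seq(rng, 60))
        seq[20 : 20 + target.width] = target.consensus
        assert target.block_id in find_hits("".join(seq), db)

    def test_disjoint_alphabet_never_hits(self):
        m = BlockMotif.from_segments("polyA", ["AAAAA"])
        m.hit_threshold = 0.0
        db = BlockDatabase([m])
        assert find_hits("W" * 30, db) == set()


class TestBlockDbFormat:
    def test_parse_single_block(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("ID b1\nACD\nACD\nTH 1.5\n//\n")
        db = parse_block_db(p)
        assert len(db) == 1
        assert db.motifs[0].width == 3
        assert db.motifs[0].hit_threshold == 1.5

    def test_feature_indices_follow_file_order(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("ID b1\nACD\nTH 0\n//\nID b2\nWYW\nTH 0\n//\n")
        db = parse_block_db(p)
        assert db.ids == ["b1", "b2"]
        assert db.index_of("b2") == 1

    def test_unequal_segments_name_the_block(self, tmp_path):
        p = tmp_path / "db.txt"
        p.write_text("ID badblock\nACD\nAC\n//\n")
        with pytest.raises(BlockParseError, match="badblock"):
            parse_block_db(p)

    def test_write_parse_round_trip(self, tmp_path, tiny_fixture):
        _, block_db, _, _, _ = tiny_fixture
        p = tmp_path / "rt.txt"
        write_block_db(block_db, p)
        back = parse_block_db(p)
        assert back.ids == block_db.ids
        assert back.digest() == block_db.digest()

    def test_duplicate_ids_rejected(self):
        m1 = BlockMotif.from_segments("dup", ["ACD"])
        m2 = BlockMotif.from_segments("dup", ["WYW"])
        with pytest.raises(ValueError, match="duplicate"):
            BlockDatabase([m1, m2])
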