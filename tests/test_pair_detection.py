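import numpy as np
import pytest
from hypothesis import given, strategies as st

from paraloc.pair_detection import (
    AlignmentResult,
    IdentityThresholdParams,
    ProteinPair,
    ScoringScheme,
    candidate_filter,
    compute_bsr,
    local_align,
    local_align_raw_score,
    localization_subset_filter,
    min_identity_threshold,
    read_tabular_alignments,
    reciprocal_filter,
)
from paraloc.sequence_model import ProteinSequence

from oracles import blosum62, gotoh_local_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _pair(pident, L, cov_a, cov_b, evalue=1e-9, bits=100.0, bsr=0.9):
    aln = AlignmentResult(
        id_a="A", id_b="B", bit_score=bits, e_value=evalue,
        percent_identity=pident, alignment_length=L,
        coverage_a=cov_a, coverage_b=cov_b,
    )
    return ProteinPair(alignment=aln, bsr=bsr)


class TestLocalAlign:
    def test_identical_sequences_full_identity_and_coverage(self):
        seq = ProteinSequence("p", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3)
        r = local_align(seq, ProteinSequence("q", seq.residues))
        assert r.percent_identity == 100.0
        assert r.coverage_a == 1.0 and r.coverage_b == 1.0

    def test_symmetric_in_argument_order(self):
        a = ProteinSequence("a", "MKTAYIAKQRQISFVKSHFSRQ")
        b = ProteinSequence("b", "MKTWYIAKQRQISFVKKK")
        r_ab = local_align(a, b)
        r_ba = local_align(b, a)
        assert r_ab.bit_score == pytest.approx(r_ba.bit_score)
        assert r_ab.percent_identity == pytest.approx(r_ba.percent_identity)
        assert (r_ab.coverage_a, r_ab.coverage_b) == (r_ba.coverage_b, r_ba.coverage_a)

    def test_shared_block_scores_sum_of_diagonal_entries(self):
        # the only positive-scoring region is an exact 10-residue block;
        # flanks are low-complexity mismatches that cannot extend it
        block = "WCHKRNDEQY"
        a = "PPPP" + block + "GGGG"
        b = "LLLL" + block + "SSSS"
        expected = sum(blosum62(c, c) for c in block)
        assert local_align_raw_score(a, b) == pytest.approx(expected)

    def test_matches_gotoh_oracle_on_random_short_peptides(self, rng):
        for _ in range(60):
            la, lb = rng.integers(3, 13, size=2)
            a = "".join(AA[i] for i in rng.integers(0, 20, la))
            b = "".join(AA[i] for i in rng.integers(0, 20, lb))
            assert local_align_raw_score(a, b) == pytest.approx(
                gotoh_local_score(a, b)
            ), (a, b)


class TestBSR:
    @pytest.mark.parametrize(
        "score,sa,sb,expected",
        [(100, 100, 100, 1.0), (60, 100, 150, 0.4), (33, 100, 100, 0.33)],
    )
    def test_examples(self, score, sa, sb, expected):
        assert compute_bsr(score, sa, sb) == pytest.approx(expected)

    def test_threshold_gate_is_inclusive(self):
        p = _pair(50, 200, 0.9, 0.9, evalue=1e-3, bsr=compute_bsr(33, 100, 100))
        assert candidate_filter(p)

    def test_nonpositive_self_score_rejected(self):
        with pytest.raises(ValueError):
            compute_bsr(10, 0, 100)

    @given(
        st.floats(1, 1e4), st.floats(1, 1e4), st.floats(1, 1e4),
        st.floats(0.01, 100),
    )
    def test_symmetry_and_scale_invariance(self, s, a, b, c):
        assert compute_bsr(s, a, b) == pytest.approx(compute_bsr(s, b, a))
        assert compute_bsr(s, a, b) == pytest.approx(compute_bsr(c * s, c * a, c * b))


class TestIdentityThreshold:
    @pytest.mark.parametrize("L,expected", [(150, 30.0), (400, 30.0), (1000, 30.0)])
    def test_flat_above_cutoff(self, L, expected):
        assert min_identity_threshold(L) == expected

    def test_short_peptides_require_more_identity(self):
        assert min_identity_threshold(50) > 30.0

    def test_nonincreasing_and_continuous(self):
        p = IdentityThresholdParams()
        values = [min_identity_threshold(L, p) for L in range(1, 1001)]
        assert all(x >= y for x, y in zip(values, values[1:]))
        # calibrated offset makes the curve meet the flat branch at 150
        assert p.offset + p._raw_curve(150) == pytest.approx(30.0)


class TestFilters:
    @pytest.mark.parametrize(
        "evalue,bsr,expected",
        [(1e-3, 0.33, True), (1e-2, 0.9, False), (1e-10, 0.32, False)],
    )
    def test_candidate(self, evalue, bsr, expected):
        assert candidate_filter(_pair(50, 200, 0.9, 0.9, evalue=evalue, bsr=bsr)) is expected

    @pytest.mark.parametrize(
        "pident,L,cov,expected",
        [
            (35.0, 200, (0.9, 0.85), True),
            (35.0, 200, (0.9, 0.79), False),
            (29.9, 151, (1.0, 1.0), False),
        ],
    )
    def test_reciprocal(self, pident, L, cov, expected):
        assert reciprocal_filter(_pair(pident, L, *cov)) is expected

    @pytest.mark.parametrize(
        "pident,cov,expected",
        [(50.0, (0.8, 0.8), True), (49.0, (1.0, 1.0), False), (100.0, (1.0, 1.0), True)],
    )
    def test_localization_subset(self, pident, cov, expected):
        assert localization_subset_filter(_pair(pident, 100, *cov)) is expected

    def test_reciprocal_passers_subset_of_candidate_passers(self, rng):
        from paraloc.pair_detection import _apply_filters

        pairs = [
            _pair(
                float(rng.uniform(10, 100)), int(rng.integers(30, 400)),
                float(rng.uniform(0.3, 1.0)), float(rng.uniform(0.3, 1.0)),
                evalue=float(10 ** rng.uniform(-12, 0)),
                bsr=float(rng.uniform(0.05, 1.0)),
            )
            for _ in range(300)
        ]
        flagged = _apply_filters(pairs, 1e-3, 0.33, None, 0.8)
        for p in flagged:
            if p.passed_reciprocal:
                assert p.passed_candidate
            if p.passed_localization_subset:
                assert p.passed_reciprocal


class TestTabularReader:
    ROW = "{q}\t{s}\t{pid}\t{L}\t0\t0\t1\t{qe}\t1\t{se}\t{ev}\t{bits}\n"

    def _write(self, tmp_path, rows, lengths):
        aln = tmp_path / "hits.tsv"
        aln.write_text("".join(rows))
        lens = tmp_path / "lens.tsv"
        lens.write_text("".join(f"{p}\t{n}\n" for p, n in lengths.items()))
        return aln, lens

    def test_self_hits_feed_bsr(self, tmp_path):
        rows = [
            self.ROW.format(q="A", s="A", pid=100, L=100, qe=100, se=100, ev=0, bits=200),
            self.ROW.format(q="B", s="B", pid=100, L=100, qe=100, se=100, ev=0, bits=180),
            self.ROW.format(q="A", s="B", pid=60, L=100, qe=100, se=100, ev=1e-30, bits=90),
        ]
        aln, lens = self._write(tmp_path, rows, {"A": 100, "B": 100})
        pairs = read_tabular_alignments(aln, lens)
        assert len(pairs) == 1
        assert pairs[0].bsr == pytest.approx(90 / 200)

    def test_duplicate_unordered_pairs_keep_best_bits(self, tmp_path):
        rows = [
            self.ROW.format(q="A", s="A", pid=100, L=100, qe=100, se=100, ev=0, bits=200),
            self.ROW.format(q="B", s="B", pid=100, L=100, qe=100, se=100, ev=0, bits=200),
            self.ROW.format(q="A", s="B", pid=60, L=100, qe=100, se=100, ev=1e-20, bits=50),
            self.ROW.format(q="B", s="A", pid=60, L=100, qe=100, se=100, ev=1e-25, bits=60),
        ]
        aln, lens = self._write(tmp_path, rows, {"A": 100, "B": 100})
        pairs = read_tabular_alignments(aln, lens)
        assert len(pairs) == 1
        assert pairs[0].alignment.bit_score == 60

    def test_pair_without_self_hit_dropped(self, tmp_path, caplog):
        rows = [
            self.ROW.format(q="A", s="A", pid=100, L=100, qe=100, se=100, ev=0, bits=200),
            self.ROW.format(q="A", s="B", pid=60, L=100, qe=100, se=100, ev=1e-30, bits=90),
        ]
        aln, lens = self._write(tmp_path, rows, {"A": 100, "B": 100})
        with caplog.at_level("WARNING"):
            pairs = read_tabular_alignments(aln, lens)
        assert pairs == []
        assert "missing self-hit" in caplog.text


def test_karlin_altschul_bits_and_evalue_are_consistent():
    s = ScoringScheme()
    bits = s.bit_score(100.0)
    assert s.e_value(100.0, 300, 300) == pytest.approx(300 * 300 * 2.0 ** (-bits))
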