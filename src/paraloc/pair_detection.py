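"""Paralogous-pair detection from all-vs-all local protein alignment.

Candidate pairs must align with e-value <= 1e-3 and a BLAST score ratio
(BSR) >= 0.33; the BSR normalises the pair's bit score by the larger of
the two self-alignment bit scores, so it is symmetric and lies in (0, 1].
Reciprocal filters then require >= 80% coverage of BOTH proteins' full
lengths and a length-dependent minimum percent identity: a flat 30% for
alignments of >= 150 columns and, below that, an empirical "twilight
zone" curve that rises steeply for short peptides.  A stricter subset
(identity >= 50%, coverage >= 80%) feeds the subcellular-localization
comparison.

Alignment is Smith-Waterman (affine gaps, BLOSUM62 by default) via
Bio.Align.PairwiseAligner; bit scores and e-values come from a
Karlin-Altschul conversion with configurable (lambda, K).  Precomputed
BLAST tabular output can be read instead, in which case its e-values and
bit scores are taken verbatim.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from paraloc.sequence_model import ProteinSequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring and Karlin-Altschul statistics.

    Gap penalties follow the aligner's convention: a gap of length k
    scores ``gap_open + (k - 1) * gap_extend`` (both are scores, hence
    <= 0).  ``ka_lambda`` and ``ka_k`` are the gapped Karlin-Altschul
    parameters used to convert raw scores to bit scores and e-values;
    the defaults are the standard gapped BLOSUM62 values.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    database_count: int = 1

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties are scores and must be <= 0")

    def bit_score(self, raw: float) -> float:
        return (self.ka_lambda * raw - math.log(self.ka_k)) / math.log(2)

    def e_value(self, raw: float, len_a: int, len_b: int) -> float:
        space = len_a * len_b * self.database_count
        return space * 2.0 ** (-self.bit_score(raw))


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise local alignment with the statistics the filters need."""

    id_a: str
    id_b: str
    bit_score: float
    e_value: float
    percent_identity: float
    alignment_length: int
    coverage_a: float
    coverage_b: float
    aligned_a: Optional[str] = None
    aligned_b: Optional[str] = None

    @property
    def pair_key(self) -> frozenset[str]:
        return frozenset((self.id_a, self.id_b))

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")


@dataclass
class ProteinPair:
    """A candidate paralog pair: alignment statistics plus BSR and the
    three filter flags (candidate, reciprocal, localization subset)."""

    alignment: AlignmentResult
    bsr: float
    passed_candidate: bool = False
    passed_reciprocal: bool = False
    passed_localization_subset: bool = False

    @property
    def ids(self) -> frozenset[str]:
        return self.alignment.pair_key


@dataclass(frozen=True)
class IdentityThresholdParams:
    """Length-dependent minimum-identity rule.

    For alignment lengths >= ``long_cutoff_length`` the threshold is the
    flat ``long_cutoff_identity``.  Below it, the threshold follows
    ``offset + scale * L ** (-exponent * (1 + exp(-L / damping)))``, with
    ``offset`` calibrated so the curve meets the flat part continuously
    at the cutoff.
    """

    long_cutoff_length: int = 150
    long_cutoff_identity: float = 30.0
    curve_scale: float = 480.0
    curve_exponent: float = 0.32
    curve_damping: float = 1000.0
    curve_offset: Optional[float] = None  # None -> calibrated for continuity

    def _raw_curve(self, L: float) -> float:
        expo = -self.curve_exponent * (1.0 + math.exp(-L / self.curve_damping))
        return self.curve_scale * L**expo

    @property
    def offset(self) -> float:
        if self.curve_offset is not None:
            return self.curve_offset
        return self.long_cutoff_identity - self._raw_curve(self.long_cutoff_length)


def min_identity_threshold(L: int, p: IdentityThresholdParams | None = None) -> float:
    """Minimum percent identity required for an alignment of length L."""
    if p is None:
        p = IdentityThresholdParams()
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if L >= p.long_cutoff_length:
        return p.long_cutoff_identity
    return p.offset + p._raw_curve(L)


_MATRIX_CACHE: dict[str, object] = {}


def _matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def _make_aligner(s: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix(s.matrix_name)
    aligner.open_gap_score = s.gap_open
    aligner.extend_gap_score = s.gap_extend
    return aligner


def local_align(
    a: ProteinSequence, b: ProteinSequence, s: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal Smith-Waterman alignment of two proteins.

    Percent identity is counted over all alignment columns (gaps included
    in the denominator, BLAST-style); coverage is the number of aligned
    residues of each protein divided by its FULL length.
    """
    if s is None:
        s = ScoringScheme()
    aligner = _make_aligner(s)
    aln = aligner.align(a.residues, b.residues)[0]
    raw = aln.score
    gapped_a, gapped_b = str(aln[0]), str(aln[1])
    length = len(gapped_a)
    matches = sum(
        1 for x, y in zip(gapped_a, gapped_b) if x == y and x != "-"
    )
    aligned_res_a = sum(1 for x in gapped_a if x != "-")
    aligned_res_b = sum(1 for x in gapped_b if x != "-")
    return AlignmentResult(
        id_a=a.protein_id,
        id_b=b.protein_id,
        bit_score=s.bit_score(raw),
        e_value=s.e_value(raw, a.length, b.length),
        percent_identity=100.0 * matches / length,
        alignment_length=length,
        coverage_a=aligned_res_a / a.length,
        coverage_b=aligned_res_b / b.length,
        aligned_a=gapped_a,
        aligned_b=gapped_b,
    )


def local_align_raw_score(
    a: str, b: str, s: ScoringScheme | None = None
) -> float:
    """Raw (un-normalised) optimal local alignment score of two residue
    strings; convenience for oracle comparisons."""
    if s is None:
        s = ScoringScheme()
    return _make_aligner(s).score(a, b)


def compute_bsr(score_ab: float, self_a: float, self_b: float) -> float:
    """BLAST score ratio: pair bit score over the larger self bit score.

    Symmetric in the two proteins and scale-invariant; lies in (0, 1]
    because no pair can out-score the better self-alignment.
    """
    if self_a <= 0 or self_b <= 0:
        raise ValueError("self-scores must be positive (degenerate protein?)")
    return score_ab / max(self_a, self_b)


def candidate_filter(
    p: ProteinPair, max_e: float = 1e-3, min_bsr: float = 0.33
) -> bool:
    """Initial candidate gate: e-value <= max_e and BSR >= min_bsr, both
    thresholds inclusive."""
    return p.alignment.e_value <= max_e and p.bsr >= min_bsr


def reciprocal_filter(
    p: ProteinPair,
    t: IdentityThresholdParams | None = None,
    min_coverage: float = 0.8,
) -> bool:
    """Stringent reciprocal gate: both coverages >= min_coverage against
    full protein lengths, and identity >= the length-dependent minimum."""
    a = p.alignment
    return (
        a.coverage_a >= min_coverage
        and a.coverage_b >= min_coverage
        and a.percent_identity >= min_identity_threshold(a.alignment_length, t)
    )


def localization_subset_filter(
    p: ProteinPair, min_identity: float = 50.0, min_coverage: float = 0.8
) -> bool:
    """Stricter subset used for subcellular-localization comparison."""
    a = p.alignment
    return (
        a.percent_identity >= min_identity
        and a.coverage_a >= min_coverage
        and a.coverage_b >= min_coverage
    )


def _apply_filters(
    pairs: Iterable[ProteinPair],
    max_e: float,
    min_bsr: float,
    t: IdentityThresholdParams | None,
    min_coverage: float,
) -> list[ProteinPair]:
    out = []
    for p in pairs:
        p.passed_candidate = candidate_filter(p, max_e=max_e, min_bsr=min_bsr)
        p.passed_reciprocal = p.passed_candidate and reciprocal_filter(
            p, t, min_coverage=min_coverage
        )
        p.passed_localization_subset = (
            p.passed_reciprocal and localization_subset_filter(p)
        )
        out.append(p)
    return out


def detect_pairs(
    proteins: dict[str, ProteinSequence],
    scheme: ScoringScheme | None = None,
    max_e: float = 1e-3,
    min_bsr: float = 0.33,
    identity_params: IdentityThresholdParams | None = None,
    min_coverage: float = 0.8,
) -> list[ProteinPair]:
    """All-vs-all intraspecific pair detection.

    Aligns every unordered protein pair, computes the BSR against
    self-alignment bit scores, and sets the three filter flags.  Invalid
    proteins must already have been excluded.
    """
    if scheme is None:
        scheme = ScoringScheme()
    ids = sorted(proteins)
    self_bits = {
        pid: local_align(proteins[pid], proteins[pid], scheme).bit_score
        for pid in ids
    }
    pairs: list[ProteinPair] = []
    for ia, ib in combinations(ids, 2):
        aln = local_align(proteins[ia], proteins[ib], scheme)
        bsr = compute_bsr(aln.bit_score, self_bits[ia], self_bits[ib])
        pairs.append(ProteinPair(alignment=aln, bsr=bsr))
    return _apply_filters(pairs, max_e, min_bsr, identity_params, min_coverage)


def read_tabular_alignments(
    path: str | Path,
    lengths_path: str | Path,
    max_e: float = 1e-3,
    min_bsr: float = 0.33,
    identity_params: IdentityThresholdParams | None = None,
    min_coverage: float = 0.8,
) -> list[ProteinPair]:
    """Read 12-column BLAST tabular output (outfmt 6) into filtered pairs.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  ``lengths_path`` is a 2-column TSV
    ``protein_id<TAB>length`` needed for coverage.  Self-hits supply the
    BSR denominators; duplicate unordered pairs collapse to the highest
    bit score; pairs lacking a self-hit for either member are dropped
    with a warning.
    """
    lengths: dict[str, int] = {}
    with open(lengths_path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, ln = line.split("\t")[:2]
            lengths[pid] = int(ln)

    self_bits: dict[str, float] = {}
    best: dict[frozenset[str], dict] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            q, s_ = cols[0], cols[1]
            pident = float(cols[2])
            length = int(cols[3])
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
            evalue = float(cols[10])
            bits = float(cols[11])
            if q == s_:
                self_bits[q] = max(self_bits.get(q, 0.0), bits)
                continue
            key = frozenset((q, s_))
            row = {
                "q": q, "s": s_, "pident": pident, "length": length,
                "qspan": abs(qend - qstart) + 1, "sspan": abs(send - sstart) + 1,
                "evalue": evalue, "bits": bits,
            }
            if key not in best or bits > best[key]["bits"]:
                best[key] = row

    pairs: list[ProteinPair] = []
    for key, row in sorted(best.items(), key=lambda kv: sorted(kv[0])):
        q, s_ = row["q"], row["s"]
        if q not in self_bits or s_ not in self_bits:
            log.warning("pair %s-%s dropped: missing self-hit", q, s_)
            continue
        aln = AlignmentResult(
            id_a=q,
            id_b=s_,
            bit_score=row["bits"],
            e_value=row["evalue"],
            percent_identity=row["pident"],
            alignment_length=row["length"],
            coverage_a=min(1.0, row["qspan"] / lengths[q]),
            coverage_b=min(1.0, row["sspan"] / lengths[s_]),
        )
        bsr = compute_bsr(row["bits"], self_bits[q], self_bits[s_])
        pairs.append(ProteinPair(alignment=aln, bsr=bsr))
    return _apply_filters(pairs, max_e, min_bsr, identity_params, min_coverage)


def write_pairs_tsv(path: str | Path, pairs: Iterable[ProteinPair]) -> None:
    header = (
        "id_a\tid_b\tpident\tL\tcov_a\tcov_b\tevalue\tbitscore\tbsr\t"
        "candidate\treciprocal\tlocalization_subset\n"
    )
    with open(path, "w", encoding="utf-8") as out:
        out.write(header)
        for p in pairs:
            a = p.alignment
            out.write(
                f"{a.id_a}\t{a.id_b}\t{a.percent_identity:.2f}\t"
                f"{a.alignment_length}\t{a.coverage_a:.4f}\t{a.coverage_b:.4f}\t"
                f"{a.e_value:.3g}\t{a.bit_score:.2f}\t{p.bsr:.4f}\t"
                f"{int(p.passed_candidate)}\t{int(p.passed_reciprocal)}\t"
                f"{int(p.passed_localization_subset)}\n"
            )
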