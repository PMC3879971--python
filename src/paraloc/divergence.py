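"""Codon alignments and synonymous/nonsynonymous divergence (Ks, Ka).

Protein alignments are back-translated onto their coding sequences to
give codon alignments; divergence is then estimated with the
Nei-Gojobori (1986) pathway-counting method: synonymous and
nonsynonymous site counts from per-codon mutation fractions (averaged
over the two sequences), difference counts averaged over all minimal
mutation pathways between differing codons (pathways through stop
codons excluded), and a Jukes-Cantor multiple-hit correction of the
per-site proportions.  Ks doubles as the survival time of a duplicate
pair, so only relative values matter downstream; estimates whose
corrected proportion saturates (p >= 3/4) are flagged invalid.

An external-estimate reader (yn00 result tables) lets real-data runs
substitute a transition/transversion- and codon-usage-aware estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, Optional

from scipy import stats

from Bio.Data import CodonTable

from paraloc.sequence_model import CodingSequence

GAP_CODON = "---"
_BASES = "ACGT"


def _codon_maps(table: int | str = 1):
    tbl = CodonTable.unambiguous_dna_by_id[int(table)] if str(table).isdigit() \
        else CodonTable.unambiguous_dna_by_name[str(table)]
    aa = dict(tbl.forward_table)
    stops = set(tbl.stop_codons)
    return aa, stops


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon columns for one pair; ``---`` marks a gap codon."""

    id_a: str
    id_b: str
    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for ca, cb in self.columns:
            for c in (ca, cb):
                if c != GAP_CODON and (
                    len(c) != 3 or any(b not in "ACGTN" for b in c)
                ):
                    raise ValueError(f"bad codon {c!r}")

    @property
    def n_complete_columns(self) -> int:
        return sum(
            1
            for ca, cb in self.columns
            if GAP_CODON not in (ca, cb) and "N" not in ca and "N" not in cb
        )

    def complete_columns(self) -> list[tuple[str, str]]:
        return [
            (ca, cb)
            for ca, cb in self.columns
            if GAP_CODON not in (ca, cb) and "N" not in ca and "N" not in cb
        ]


@dataclass(frozen=True)
class DivergenceEstimate:
    """Ks/Ka/omega for one pair; ``valid`` is False on saturation."""

    id_a: str
    id_b: str
    ks: float
    ka: float
    omega: Optional[float]  # None when Ks == 0 (undefined ratio)
    method: str = "NG86"
    valid: bool = True


class BacktranslationError(ValueError):
    """Protein alignment and CDS disagree."""


def codon_backtranslate(
    prot_aln: tuple[str, str],
    cds_a: CodingSequence,
    cds_b: CodingSequence,
    table: int | str = 1,
) -> CodonAlignment:
    """Thread the two coding sequences through a gapped protein
    alignment, column by column.

    The ungapped protein strings must translate exactly from the CDSs
    (trailing stop codons in the CDS are tolerated); a mismatch raises an
    error naming the first discordant residue.
    """
    aa_map, stops = _codon_maps(table)
    aligned_a, aligned_b = prot_aln
    if len(aligned_a) != len(aligned_b):
        raise BacktranslationError("aligned strings differ in length")

    def codons_of(cds: CodingSequence) -> list[str]:
        nt = cds.nucleotides[: len(cds.nucleotides) - len(cds.nucleotides) % 3]
        cods = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        if cods and cods[-1] in stops:
            cods = cods[:-1]
        return cods

    def check(aligned: str, cods: list[str], label: str) -> None:
        residues = [r for r in aligned if r != "-"]
        if len(residues) != len(cods):
            raise BacktranslationError(
                f"{label}: {len(residues)} aligned residues vs "
                f"{len(cods)} codons"
            )
        for i, (r, c) in enumerate(zip(residues, cods), 1):
            trans = aa_map.get(c, "X") if "N" not in c else "X"
            if trans != r and trans != "X" and r != "X":
                raise BacktranslationError(
                    f"{label}: residue {i} is {r!r} but codon {c!r} "
                    f"translates to {trans!r}"
                )

    cods_a, cods_b = codons_of(cds_a), codons_of(cds_b)
    check(aligned_a, cods_a, cds_a.transcript_id)
    check(aligned_b, cods_b, cds_b.transcript_id)

    columns = []
    ia = ib = 0
    for ra, rb in zip(aligned_a, aligned_b):
        if ra == "-":
            ca = GAP_CODON
        else:
            ca = cods_a[ia]
            ia += 1
        if rb == "-":
            cb = GAP_CODON
        else:
            cb = cods_b[ib]
            ib += 1
        columns.append((ca, cb))
    return CodonAlignment(
        id_a=cds_a.transcript_id, id_b=cds_b.transcript_id, columns=tuple(columns)
    )


def _syn_sites(codon: str, aa_map: dict, stops: set) -> float:
    """Synonymous site count of one codon: at each position, the fraction
    of single-base changes (changes to stop codons excluded) that
    preserve the amino acid."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in stops:
                continue
            valid += 1
            if aa_map[mut] == aa_map[codon]:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _path_differences(
    ca: str, cb: str, aa_map: dict, stops: set
) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons,
    averaged over all minimal mutation pathways.  Pathways visiting a
    stop codon are excluded; if every pathway is blocked, all are used."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> Optional[tuple[float, float]]:
        sd = nd = 0.0
        cur = ca
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in stops:
                return None
            if aa_map[cur] == aa_map[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [walk(order) for order in permutations(diff_pos)]
    ok = [r for r in results if r is not None]
    if not ok:  # all pathways pass a stop; fall back to unweighted
        ok = []
        for order in permutations(diff_pos):
            sd = nd = 0.0
            cur = ca
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt not in stops and cur not in stops and \
                        aa_map.get(cur) == aa_map.get(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            ok.append((sd, nd))
    sd = sum(r[0] for r in ok) / len(ok)
    nd = sum(r[1] for r in ok) / len(ok)
    return sd, nd


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes-Cantor multiple-hit correction; invalid when p >= 3/4."""
    if p >= 0.75:
        return math.nan, False
    if p == 0.0:
        return 0.0, True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), True


def estimate_ks_ka(aln: CodonAlignment, table: int | str = 1) -> DivergenceEstimate:
    """Nei-Gojobori (1986) estimate of Ks and Ka for a codon alignment.

    Gapped and ambiguous columns are excluded.  Stop codons appearing in
    a column exclude that column.  Saturation of either corrected
    proportion flags the estimate invalid.
    """
    aa_map, stops = _codon_maps(table)
    cols = [
        (ca, cb)
        for ca, cb in aln.complete_columns()
        if ca not in stops and cb not in stops
    ]
    if not cols:
        raise ValueError("no complete codon columns to estimate from")

    S = N = Sd = Nd = 0.0
    for ca, cb in cols:
        s = 0.5 * (_syn_sites(ca, aa_map, stops) + _syn_sites(cb, aa_map, stops))
        S += s
        N += 3.0 - s
        sd, nd = _path_differences(ca, cb, aa_map, stops)
        Sd += sd
        Nd += nd

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks, ok_s = _jc_correct(pS)
    ka, ok_n = _jc_correct(pN)
    valid = ok_s and ok_n
    omega: Optional[float]
    if not valid:
        omega = None
    elif ks == 0.0:
        omega = None
    else:
        omega = ka / ks
    return DivergenceEstimate(
        id_a=aln.id_a, id_b=aln.id_b, ks=ks, ka=ka, omega=omega, valid=valid
    )


def ks_window_filter(
    estimates: Iterable[DivergenceEstimate], lo: float, hi: float
) -> list[DivergenceEstimate]:
    """Keep valid estimates with lo < Ks < hi (both bounds strict);
    invalid estimates are always excluded."""
    if not lo < hi:
        raise ValueError("window requires lo < hi")
    return [e for e in estimates if e.valid and lo < e.ks < hi]


def positive_selection_fraction(
    groups: dict[str, list[DivergenceEstimate]],
    omega_threshold: float = 1.5,
) -> tuple[dict[str, float], float]:
    """Per-group fraction of valid pairs with Ka/Ks strictly above the
    threshold, and a two-sided two-proportion test p-value.

    A normal-approximation z-test is used unless any contingency cell is
    below 5, in which case Fisher's exact test takes over.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (name0, g0), (name1, g1) = sorted(groups.items())
    if not g0 or not g1:
        raise ValueError("both groups must be nonempty")

    def count(g: list[DivergenceEstimate]) -> tuple[int, int]:
        valid = [e for e in g if e.valid and e.omega is not None]
        hits = sum(1 for e in valid if e.omega > omega_threshold)
        return hits, len(valid)

    x0, n0 = count(g0)
    x1, n1 = count(g1)
    if n0 == 0 or n1 == 0:
        raise ValueError("a group has no valid omega estimates")
    fractions = {name0: x0 / n0, name1: x1 / n1}
    cells = (x0, n0 - x0, x1, n1 - x1)
    if min(cells) < 5:
        _, p = stats.fisher_exact([[x0, n0 - x0], [x1, n1 - x1]])
    else:
        pooled = (x0 + x1) / (n0 + n1)
        se = math.sqrt(pooled * (1 - pooled) * (1 / n0 + 1 / n1))
        if se == 0:
            p = 1.0
        else:
            z = (x0 / n0 - x1 / n1) / se
            p = 2.0 * stats.norm.sf(abs(z))
    return fractions, float(p)


def read_yn00_estimates(path: str | Path) -> list[DivergenceEstimate]:
    """Read externally computed pairwise estimates from a simple TSV
    ``id_a<TAB>id_b<TAB>ks<TAB>ka`` (as exported from yn00 result blocks);
    omega is recomputed and the method tagged ``external``."""
    out: list[DivergenceEstimate] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("id_a"):
                continue
            id_a, id_b, ks_s, ka_s = line.split("\t")[:4]
            ks, ka = float(ks_s), float(ka_s)
            omega = ka / ks if ks > 0 else None
            out.append(
                DivergenceEstimate(
                    id_a=id_a, id_b=id_b, ks=ks, ka=ka, omega=omega,
                    method="external", valid=ks >= 0 and ka >= 0,
                )
            )
    return out


def write_divergence_tsv(path, estimates: Iterable[DivergenceEstimate]) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write("id_a\tid_b\tks\tka\tomega\tmethod\tvalid\n")
        for e in estimates:
            om = f"{e.omega:.6f}" if e.omega is not None else "NA"
            ks = f"{e.ks:.6f}" if not math.isnan(e.ks) else "NA"
            ka = f"{e.ka:.6f}" if not math.isnan(e.ka) else "NA"
            out.write(
                f"{e.id_a}\t{e.id_b}\t{ks}\t{ka}\t{om}\t{e.method}\t"
                f"{int(e.valid)}\n"
            )
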