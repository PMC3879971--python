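"""N-terminal-peptide (NTP) mutation classification.

The NTP — roughly the first 13-85 residues — targets a protein to its
subcellular destination, so indels there are a plausible route to
relocalization.  Each duplicate pair's N-terminal window is classified
into one of four mutually exclusive categories:

* ``COMPLETE`` — a single gap run of >= 30 residues inside the window
  (gain/loss of the whole targeting peptide);
* ``TERMINAL`` — a gap run touching the very first alignment column;
* ``PARTIAL``  — any other (internal) gap within the window;
* ``NONE``     — substitutions only (including identical windows).

Pairs are re-aligned end-to-end (global, end gaps penalised) before the
window is cut, because local alignments clip termini and would hide
terminal events.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import pandas as pd
from Bio import Align

from paraloc.pair_detection import ScoringScheme, _matrix
from paraloc.localization import RelocalizationStatus, Status

log = logging.getLogger(__name__)


class NTPClass(str, Enum):
    NONE = "NONE"
    PARTIAL = "PARTIAL"
    TERMINAL = "TERMINAL"
    COMPLETE = "COMPLETE"


@dataclass(frozen=True)
class NTPRegion:
    """Window from the first residue; default 60 (midpoint of the
    13-85-residue range seen across targeting peptides)."""

    length: int = 60
    source: str = "fixed_config"  # or "per_protein"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("NTP window length must be >= 1")
        if self.source == "per_protein" and not (13 <= self.length <= 85):
            raise ValueError("per-protein NTP length must lie in [13, 85]")


def global_align_pair(
    res_a: str, res_b: str, s: ScoringScheme | None = None
) -> tuple[str, str]:
    """End-to-end global alignment (Needleman-Wunsch, end gaps penalised)
    of two residue strings, so gaps at the N-terminus stay observable."""
    if s is None:
        s = ScoringScheme()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(s.matrix_name)
    aligner.open_gap_score = s.gap_open
    aligner.extend_gap_score = s.gap_extend
    aln = aligner.align(res_a, res_b)[0]
    return str(aln[0]), str(aln[1])


def extract_ntp_window(
    aln: tuple[str, str], region: NTPRegion | None = None
) -> tuple[str, str]:
    """Leading alignment columns containing the first ``region.length``
    residues of the longer member, gaps included.  When the alignment is
    shorter than the window, the whole alignment is returned with a
    warning."""
    if region is None:
        region = NTPRegion()
    sub_a, sub_b = aln
    if len(sub_a) != len(sub_b):
        raise ValueError("aligned strings differ in length")
    # pick the member with more residues; count its residues column-wise
    n_res_a = sum(1 for c in sub_a if c != "-")
    n_res_b = sum(1 for c in sub_b if c != "-")
    longer = sub_a if n_res_a >= n_res_b else sub_b
    seen = 0
    for col, c in enumerate(longer):
        if c != "-":
            seen += 1
        if seen == region.length:
            return sub_a[: col + 1], sub_b[: col + 1]
    log.warning(
        "alignment holds %d residues of the longer member, shorter than "
        "the %d-residue NTP window; using the whole alignment",
        max(n_res_a, n_res_b), region.length,
    )
    return sub_a, sub_b


def _gap_runs(s: str) -> list[tuple[int, int]]:
    """(start, length) of maximal gap runs."""
    runs = []
    start = None
    for i, c in enumerate(s):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(s) - start))
    return runs


def classify_ntp_mutation(
    sub_a: str, sub_b: str, complete_min_gap: int = 30
) -> NTPClass:
    """Classify the windowed alignment of a duplicate pair.

    Precedence: COMPLETE (a maximal gap run of >= ``complete_min_gap``
    columns, or a gap covering an entire member's window) beats TERMINAL
    (a run starting at column 1), which beats PARTIAL (any other gap);
    otherwise NONE.  Symmetric in the two strings.
    """
    if len(sub_a) != len(sub_b):
        raise ValueError("windowed strings must have equal length")
    runs = _gap_runs(sub_a) + _gap_runs(sub_b)
    if not runs:
        return NTPClass.NONE
    window = len(sub_a)
    if any(length >= complete_min_gap or length == window for _, length in runs):
        return NTPClass.COMPLETE
    if any(start == 0 for start, _ in runs):
        return NTPClass.TERMINAL
    return NTPClass.PARTIAL


def category_frequencies(
    classes: Iterable[tuple[NTPClass, Optional[RelocalizationStatus]]],
) -> pd.DataFrame:
    """Tabulate NTP categories.

    Columns per category: ``count``; ``fraction`` of all pairs; the
    within-category PSR rate ``psr_rate`` (relocalized in category /
    total in category); and ``share_of_relocalized`` (relocalized in
    category / all relocalized pairs) — both denominators are reported
    because either reading of "frequency of PSR per category" is useful.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("no classified pairs")
    total = len(classes)
    counts: Counter[NTPClass] = Counter(c for c, _ in classes)
    reloc: Counter[NTPClass] = Counter(
        c
        for c, st in classes
        if st is not None and st.status is Status.RELOCALIZED
    )
    total_reloc = sum(reloc.values())
    rows = []
    for cat in NTPClass:
        n = counts.get(cat, 0)
        r = reloc.get(cat, 0)
        rows.append(
            {
                "category": cat.value,
                "count": n,
                "fraction": n / total,
                "psr_rate": r / n if n else float("nan"),
                "share_of_relocalized": r / total_reloc if total_reloc else float("nan"),
            }
        )
    return pd.DataFrame(rows)
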