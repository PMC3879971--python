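"""Coding-sequence collections, representative-transcript selection, and
conceptual translation to a species proteome.

Each gene may be annotated with several transcripts; the longest CDS
represents the gene (ties broken by lexicographically smallest transcript
id).  Translation uses the standard genetic code by default with a
per-species override; CDSs with internal stop codons are flagged invalid
and excluded from downstream pairing rather than raising.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

#: Bases accepted in a coding sequence.
CDS_ALPHABET = frozenset("ACGTN")

GROUP_LABELS = ("fungi", "metazoan", "plant", "algae", "basal_eukaryote")


@dataclass(frozen=True)
class GeneRecord:
    """Identity of one annotated transcript of a gene."""

    gene_id: str
    transcript_id: str
    protein_id: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")


@dataclass(frozen=True)
class CodingSequence:
    """A nucleotide coding sequence keyed by transcript id."""

    transcript_id: str
    nucleotides: str

    @property
    def length(self) -> int:
        return len(self.nucleotides)

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError(
                f"CDS {self.transcript_id!r} shorter than one codon "
                f"({self.length} bases)"
            )
        bad = set(self.nucleotides) - CDS_ALPHABET
        if bad:
            raise ValueError(
                f"CDS {self.transcript_id!r} contains non-IUPAC-DNA "
                f"characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """A translated protein; ``valid`` is False when the source CDS
    contained an internal stop codon."""

    protein_id: str
    residues: str
    valid: bool = True

    @property
    def length(self) -> int:
        return len(self.residues)


class FastaParseError(ValueError):
    """Raised on malformed FASTA input."""


def _read_id_map(path: Path) -> dict[str, GeneRecord]:
    """Read a 3-column TSV ``gene_id<TAB>transcript_id<TAB>protein_id``
    keyed by transcript id."""
    mapping: dict[str, GeneRecord] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FastaParseError(
                    f"{path}:{lineno}: id map needs 3 tab-separated columns"
                )
            gene_id, transcript_id, protein_id = parts[:3]
            mapping[transcript_id] = GeneRecord(
                gene_id=gene_id, transcript_id=transcript_id, protein_id=protein_id
            )
    return mapping


def load_cds_fasta(
    path: str | Path, id_map: Optional[str | Path] = None
) -> list[tuple[GeneRecord, CodingSequence]]:
    """Load a CDS FASTA, optionally resolving gene/transcript/protein ids
    through a 3-column TSV map.

    FASTA headers carry transcript ids (first whitespace-delimited token).
    Sequences are upper-cased; ``N`` is allowed; any other non-ACGT
    character rejects the entry with an error naming it.  A transcript
    absent from the id map gets its gene_id defaulted to the transcript id
    with a warning.
    """
    path = Path(path)
    mapping = _read_id_map(Path(id_map)) if id_map is not None else {}
    out: list[tuple[GeneRecord, CodingSequence]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        transcript_id = rec.id
        seq = str(rec.seq).upper()
        bad = set(seq) - CDS_ALPHABET
        if bad:
            raise FastaParseError(
                f"entry {transcript_id!r} in {path} contains invalid "
                f"characters {sorted(bad)}"
            )
        if transcript_id in mapping:
            gene = mapping[transcript_id]
        else:
            if mapping:
                log.warning(
                    "transcript %s absent from id map; defaulting gene_id",
                    transcript_id,
                )
            gene = GeneRecord(
                gene_id=transcript_id,
                transcript_id=transcript_id,
                protein_id=transcript_id,
                description=rec.description,
            )
        out.append((gene, CodingSequence(transcript_id=transcript_id, nucleotides=seq)))
    return out


def select_representatives(
    records: Iterable[tuple[GeneRecord, CodingSequence]]
) -> dict[str, CodingSequence]:
    """Pick one representative CDS per gene: the longest, ties broken by
    lexicographically smallest transcript id."""
    best: dict[str, tuple[GeneRecord, CodingSequence]] = {}
    for gene, cds in records:
        cur = best.get(gene.gene_id)
        if cur is None:
            best[gene.gene_id] = (gene, cds)
            continue
        _, cur_cds = cur
        if (-cds.length, cds.transcript_id) < (-cur_cds.length, cur_cds.transcript_id):
            best[gene.gene_id] = (gene, cds)
    return {gid: cds for gid, (_, cds) in best.items()}


def translate_cds(
    cds: CodingSequence, table: int | str = 1, protein_id: str | None = None
) -> ProteinSequence:
    """Conceptually translate a CDS.

    Incomplete trailing codons are trimmed with a warning; one trailing
    stop codon is stripped; an internal stop flags the result invalid
    (``valid=False``) instead of raising, so the gene can be excluded from
    pairing with a logged warning.
    """
    nt = cds.nucleotides
    trailing = len(nt) % 3
    if trailing:
        warnings.warn(
            f"CDS {cds.transcript_id!r}: trimming {trailing} trailing base(s) "
            "to a whole codon",
            stacklevel=2,
        )
        nt = nt[: len(nt) - trailing]
    aa = str(Seq(nt).translate(table=table))
    if aa.endswith("*"):
        aa = aa[:-1]
    pid = protein_id if protein_id is not None else cds.transcript_id
    if "*" in aa:
        log.warning(
            "CDS %s translates with an internal stop codon; flagged invalid",
            cds.transcript_id,
        )
        return ProteinSequence(protein_id=pid, residues=aa, valid=False)
    return ProteinSequence(protein_id=pid, residues=aa)


@dataclass
class SpeciesProteome:
    """One species' genes with a single representative CDS and translated
    protein per gene."""

    species_id: str
    group_label: str
    genes: list[GeneRecord] = field(default_factory=list)
    representatives: dict[str, tuple[CodingSequence, ProteinSequence]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"group_label must be one of {GROUP_LABELS}, got "
                f"{self.group_label!r}"
            )

    @classmethod
    def from_records(
        cls,
        species_id: str,
        group_label: str,
        records: list[tuple[GeneRecord, CodingSequence]],
        table: int | str = 1,
    ) -> "SpeciesProteome":
        """Build a proteome: pick representatives, translate, and drop
        genes whose representative CDS has an internal stop codon."""
        reps = select_representatives(records)
        by_tid = {gene.transcript_id: gene for gene, _ in records}
        proteome = cls(species_id=species_id, group_label=group_label)
        for gid, cds in sorted(reps.items()):
            gene = by_tid[cds.transcript_id]
            prot = translate_cds(cds, table=table, protein_id=gene.protein_id or gid)
            if not prot.valid:
                log.warning(
                    "species %s: gene %s excluded (internal stop)", species_id, gid
                )
                continue
            proteome.genes.append(gene)
            proteome.representatives[gid] = (cds, prot)
        return proteome

    @property
    def proteins(self) -> dict[str, ProteinSequence]:
        """Map protein_id -> ProteinSequence for all valid genes."""
        return {prot.protein_id: prot for _, prot in self.representatives.values()}

    def cds_for_protein(self, protein_id: str) -> CodingSequence:
        for cds, prot in self.representatives.values():
            if prot.protein_id == protein_id:
                return cds
        raise KeyError(protein_id)


def write_cds_fasta(
    path: str | Path, records: Iterable[tuple[GeneRecord, CodingSequence]], width: int = 60
) -> None:
    """Write CDS records as wrapped FASTA (round-trips through
    :func:`load_cds_fasta`)."""
    with open(path, "w", encoding="utf-8") as out:
        for _, cds in records:
            out.write(f">{cds.transcript_id}\n")
            for i in range(0, cds.length, width):
                out.write(cds.nucleotides[i : i + width] + "\n")


def write_id_map(
    path: str | Path, records: Iterable[tuple[GeneRecord, CodingSequence]]
) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for gene, _ in records:
            out.write(f"{gene.gene_id}\t{gene.transcript_id}\t{gene.protein_id}\n")
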