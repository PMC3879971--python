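"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators:

* a retention simulator drawing duplicate-pair "lifetimes" (Ks) from
  group-specific constant-hazard (exponential) survival processes — the
  simplest realisation of proportional hazards, so the Cox hazard ratio
  has the closed-form target delta_N / delta_R — restricted to a Ks
  window by rejection sampling (which mirrors the analysis filter
  exactly), with Bernoulli relocalization status;

* a sequence simulator producing small duplicated CDS sets: per family
  one random ancestral CDS with a designated NTP region, duplicated and
  mutated by point substitutions, an optional background indel, and one
  NTP event per pair (none / partial / terminal / complete deletion),
  with compartments assigned so that relocalization probability depends
  on the NTP event.  Families, statuses and NTP classes are recorded as
  ground truth.

Both are deterministic given their seed.  The sequence model has no
codon-usage bias or realistic indel-length spectrum; it exercises the
pipeline's logic, not the realism of real proteomes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from paraloc.sequence_model import (
    CodingSequence,
    GeneRecord,
    SpeciesProteome,
    write_cds_fasta,
    write_id_map,
)
from paraloc.survival import SurvivalRecord
from paraloc.ntp_mutation import NTPClass
from paraloc.localization import Status

#: Fixture compartment vocabulary (deterministic, taxon-neutral).
FIXTURE_COMPARTMENTS = ("cytoplasm", "nucleus", "mitochondrion", "secreted")

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOPS = frozenset(("TAA", "TAG", "TGA"))


@dataclass(frozen=True)
class RetentionSimParams:
    """Two-rate retention process: relocalized pairs die at
    ``death_rate_reloc`` per Ks unit, nonrelocalized at
    ``death_rate_nonreloc``; ground-truth HR = nonreloc / reloc."""

    n_pairs: int = 5000
    p_relocalized: float = 0.5
    death_rate_reloc: float = 1.0
    death_rate_nonreloc: float = 1.5
    ks_window: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.death_rate_reloc <= 0 or self.death_rate_nonreloc <= 0:
            raise ValueError("death rates must be positive")
        if not 0.0 <= self.p_relocalized <= 1.0:
            raise ValueError("p_relocalized must lie in [0, 1]")

    @property
    def true_hr(self) -> float:
        return self.death_rate_nonreloc / self.death_rate_reloc


@dataclass(frozen=True)
class SequenceSimParams:
    """Duplicated-CDS fixture parameters.

    Defaults give 250-codon genes with a 60-codon NTP, a 2% per-site
    substitution probability per round (one round), one background indel
    in 10% of pairs, and an NTP-event mix dominated by substitutions —
    ``complete`` events delete >= 30 NTP codons and carry the highest
    relocalization probability.
    """

    n_families: int = 50
    codons_per_gene: int = 250
    ntp_codons: int = 60
    substitution_rate: float = 0.02
    substitution_rounds: int = 1
    indel_rate: float = 0.1
    ntp_event_probs: dict = field(
        default_factory=lambda: {
            "none": 0.55, "partial": 0.20, "terminal": 0.15, "complete": 0.10
        }
    )
    reloc_prob_given_event: dict = field(
        default_factory=lambda: {
            "none": 0.10, "partial": 0.30, "terminal": 0.40, "complete": 0.70
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self.ntp_event_probs
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("ntp_event_probs must sum to 1")
        if any(not 0 <= v <= 1 for v in probs.values()):
            raise ValueError("event probabilities must lie in [0, 1]")
        if any(
            not 0 <= v <= 1 for v in self.reloc_prob_given_event.values()
        ):
            raise ValueError("relocalization probabilities must lie in [0, 1]")
        if self.ntp_codons < 30 and probs.get("complete", 0) > 0:
            raise ValueError(
                "ntp_codons < 30 cannot realise a complete (>= 30 codon) "
                "deletion; set complete probability to 0 or enlarge the NTP"
            )
        if self.ntp_codons >= self.codons_per_gene:
            raise ValueError("NTP must be shorter than the gene")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery checks."""

    true_families: list[tuple[str, str]] = field(default_factory=list)
    true_status: dict[tuple[str, str], Status] = field(default_factory=dict)
    true_ntp_class: dict[tuple[str, str], NTPClass] = field(default_factory=dict)
    true_hr: Optional[float] = None
    compartments: dict[str, str] = field(default_factory=dict)


def simulate_retention_dataset(
    p: RetentionSimParams,
) -> tuple[list[SurvivalRecord], GroundTruth]:
    """Draw ``n_pairs`` observed (Ks, DP) records by rejection sampling
    exponential lifetimes into the Ks window; deterministic given seed."""
    lo, hi = p.ks_window
    for rate in (p.death_rate_reloc, p.death_rate_nonreloc):
        accept = math.exp(-rate * lo) - math.exp(-rate * hi)
        if accept < 1e-6:
            raise ValueError(
                f"window {p.ks_window} has acceptance probability "
                f"{accept:.2e} < 1e-6 at rate {rate}"
            )
    rng = np.random.default_rng(p.seed)
    records: list[SurvivalRecord] = []
    while len(records) < p.n_pairs:
        relocalized = rng.random() < p.p_relocalized
        rate = p.death_rate_reloc if relocalized else p.death_rate_nonreloc
        lifetime = rng.exponential(1.0 / rate)
        if lo < lifetime < hi:
            records.append(SurvivalRecord(time=lifetime, dp=0 if relocalized else 1))
    truth = GroundTruth(true_hr=p.true_hr)
    return records, truth


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"] + [
        _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for _ in range(n_codons - 1)
    ]
    return "".join(codons)


def mutate_sequence(
    cds: CodingSequence,
    rounds: int,
    rate: float,
    rng_seed: int | np.random.Generator,
) -> CodingSequence:
    """Point-substitute each site with probability ``rate`` per round;
    substitutions creating stop codons are redrawn (at most two of the
    three alternative bases can yield a stop, so a substituted site
    always ends up different from its input)."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    seq = list(cds.nucleotides)
    n = len(seq)
    for _ in range(rounds):
        for i in range(n):
            if rng.random() >= rate:
                continue
            codon_start = (i // 3) * 3
            original = seq[i]
            valid = []
            for b in "ACGT":
                if b == original:
                    continue
                seq[i] = b
                if "".join(seq[codon_start : codon_start + 3]) not in _STOPS:
                    valid.append(b)
            seq[i] = valid[rng.integers(len(valid))]
    return CodingSequence(transcript_id=cds.transcript_id, nucleotides="".join(seq))


def _delete_codons(nt: str, start_codon: int, n_codons: int) -> str:
    """In-frame deletion of ``n_codons`` codons starting at 0-based codon
    index ``start_codon``."""
    a = start_codon * 3
    b = a + n_codons * 3
    return nt[:a] + nt[b:]


def simulate_duplicate_sequences(
    p: SequenceSimParams,
) -> tuple[SpeciesProteome, dict[str, str], GroundTruth]:
    """Generate a synthetic species proteome of duplicate pairs.

    Returns the proteome, a map protein_id -> compartment (the
    "prediction file" content), and the ground truth.  Per family, the
    ancestor is duplicated; both copies accumulate substitutions; copy B
    additionally receives one NTP event and, with ``indel_rate``
    probability, a small background indel outside the NTP.
    """
    rng = np.random.default_rng(p.seed)
    events = sorted(p.ntp_event_probs)
    event_probs = np.array([p.ntp_event_probs[e] for e in events])
    records: list[tuple[GeneRecord, CodingSequence]] = []
    compartments: dict[str, str] = {}
    truth = GroundTruth()

    for fam in range(1, p.n_families + 1):
        ancestral = _random_cds(rng, p.codons_per_gene)
        ids = {}
        for member in ("A", "B"):
            gid = f"F{fam:04d}{member}"
            pid = f"P_{gid}"
            ids[member] = pid
            nt = ancestral
            cds = CodingSequence(transcript_id=f"T_{gid}", nucleotides=nt)
            cds = mutate_sequence(
                cds, p.substitution_rounds, p.substitution_rate, rng
            )
            nt = cds.nucleotides
            if member == "B":
                event = events[rng.choice(len(events), p=event_probs)]
                if event == "partial":
                    length = int(rng.integers(1, 6))
                    start = int(rng.integers(2, p.ntp_codons - length - 1))
                    nt = _delete_codons(nt, start, length)
                elif event == "terminal":
                    length = int(rng.integers(1, 6))
                    nt = _delete_codons(nt, 0, length)
                elif event == "complete":
                    length = int(rng.integers(30, p.ntp_codons + 1))
                    nt = _delete_codons(nt, 0, length)
                if rng.random() < p.indel_rate:
                    # background indel well clear of the NTP window
                    length = int(rng.integers(1, 4))
                    start = int(
                        rng.integers(
                            p.ntp_codons + 10, p.codons_per_gene - length - 40
                        )
                    )
                    nt = _delete_codons(nt, start, length)
                cds = CodingSequence(transcript_id=f"T_{gid}", nucleotides=nt)
            records.append(
                (
                    GeneRecord(
                        gene_id=gid, transcript_id=f"T_{gid}", protein_id=pid
                    ),
                    cds,
                )
            )
        # compartments: ancestor state for A; B relocates with the
        # event-conditional probability
        comp_a = FIXTURE_COMPARTMENTS[rng.integers(len(FIXTURE_COMPARTMENTS))]
        relocate = rng.random() < p.reloc_prob_given_event[event]
        if relocate:
            others = [c for c in FIXTURE_COMPARTMENTS if c != comp_a]
            comp_b = others[rng.integers(len(others))]
        else:
            comp_b = comp_a
        compartments[ids["A"]] = comp_a
        compartments[ids["B"]] = comp_b

        key = (ids["A"], ids["B"])
        truth.true_families.append(key)
        truth.true_status[key] = (
            Status.RELOCALIZED if relocate else Status.NONRELOCALIZED
        )
        truth.true_ntp_class[key] = NTPClass[event.upper()]
    truth.compartments = dict(compartments)

    proteome = SpeciesProteome.from_records(
        species_id=f"synthetic_seed{p.seed}", group_label="fungi", records=records
    )
    return proteome, compartments, truth


def write_sequence_fixture(
    outdir: str | Path,
    proteome: SpeciesProteome,
    compartments: dict[str, str],
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write the fixture as FASTA + id-map TSV + simple-dialect prediction
    TSV + truth JSON-lines; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_by_id = {g.gene_id: g for g in proteome.genes}
    records = [
        (gene_by_id[gid], cds)
        for gid, (cds, _) in sorted(proteome.representatives.items())
    ]
    paths = {
        "fasta": outdir / "cds.fasta",
        "id_map": outdir / "id_map.tsv",
        "predictions": outdir / "predictions.tsv",
        "truth": outdir / "truth.jsonl",
    }
    write_cds_fasta(paths["fasta"], records)
    write_id_map(paths["id_map"], records)
    with open(paths["predictions"], "w", encoding="utf-8") as out:
        for pid, comp in sorted(compartments.items()):
            out.write(f"{pid}\t{comp}\n")
    with open(paths["truth"], "w", encoding="utf-8") as out:
        for id_a, id_b in truth.true_families:
            key = (id_a, id_b)
            out.write(
                json.dumps(
                    {
                        "id_a": id_a,
                        "id_b": id_b,
                        "status": truth.true_status[key].value,
                        "ntp_class": truth.true_ntp_class[key].value,
                    }
                )
                + "\n"
            )
    return paths
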