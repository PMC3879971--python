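"""Subcellular-localization calls and relocalization classification.

Predictions are consumed from files (the pipeline never runs a
predictor itself): either a simple TSV of top compartments or a
per-protein line format of ``compartment: score`` fields where the top
score wins.  Only whether the two members of a duplicate pair share a
compartment matters — a pair is RELOCALIZED when the top compartments
differ — so cross-species pooling never compares compartment labels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from paraloc.pair_detection import ProteinPair

log = logging.getLogger(__name__)

#: Default compartment vocabulary (per-species configurable; fixture set).
DEFAULT_VOCABULARY = (
    "cytoplasm",
    "nucleus",
    "mitochondrion",
    "secreted",
    "chloroplast",
    "endoplasmic_reticulum",
    "golgi_apparatus",
    "peroxisome",
    "plasma_membrane",
    "vacuole",
    "lysosome",
)


class Status(str, Enum):
    RELOCALIZED = "RELOCALIZED"
    NONRELOCALIZED = "NONRELOCALIZED"


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    compartment: str
    confidence: Optional[float] = None


@dataclass(frozen=True)
class RelocalizationStatus:
    id_a: str
    id_b: str
    status: Status


class UnknownCompartmentError(ValueError):
    pass


def _check_compartment(label: str, vocabulary: tuple[str, ...]) -> None:
    if label not in vocabulary:
        raise UnknownCompartmentError(
            f"unknown compartment {label!r}; vocabulary: {list(vocabulary)}"
        )


def parse_predictions(
    path: str | Path,
    dialect: str = "simple",
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
) -> dict[str, LocalizationCall]:
    """Parse localization predictions into one top call per protein.

    ``simple``: TSV ``protein_id<TAB>compartment[<TAB>confidence]``.
    ``multiloc2``: one line per protein, ``protein_id`` followed by
    ``compartment: score`` fields; the top-scoring compartment wins, ties
    broken by vocabulary order with a warning.
    """
    calls: dict[str, LocalizationCall] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "simple":
                parts = line.split("\t")
                pid, comp = parts[0], parts[1]
                conf = float(parts[2]) if len(parts) > 2 else None
                _check_compartment(comp, vocabulary)
                calls[pid] = LocalizationCall(pid, comp, conf)
            elif dialect == "multiloc2":
                fields = re.split(r"[\t ]+", line)
                pid = fields[0]
                scores: dict[str, float] = {}
                for chunk in re.findall(r"(\S+):\s*([0-9.eE+-]+)", line):
                    comp, score = chunk[0].rstrip(":"), float(chunk[1])
                    _check_compartment(comp, vocabulary)
                    scores[comp] = score
                if not scores:
                    raise ValueError(f"no compartment scores on line: {line!r}")
                top = max(scores.values())
                tied = [c for c, s in scores.items() if s == top]
                if len(tied) > 1:
                    tied.sort(key=vocabulary.index)
                    log.warning(
                        "protein %s: tie at %.3f between %s; taking %s",
                        pid, top, tied, tied[0],
                    )
                calls[pid] = LocalizationCall(pid, tied[0], top)
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    return calls


def classify_relocalization(
    pair: ProteinPair, calls: dict[str, LocalizationCall]
) -> Optional[RelocalizationStatus]:
    """RELOCALIZED iff the two members' top compartments differ.

    Returns None (with a warning) when either member lacks a call, so the
    pair drops out of localization statistics rather than raising.
    """
    id_a, id_b = sorted(pair.ids)
    if id_a not in calls or id_b not in calls:
        log.warning("pair %s-%s missing a localization call; excluded", id_a, id_b)
        return None
    same = calls[id_a].compartment == calls[id_b].compartment
    return RelocalizationStatus(
        id_a=id_a,
        id_b=id_b,
        status=Status.NONRELOCALIZED if same else Status.RELOCALIZED,
    )


def relocalization_frequency(
    statuses: Iterable[RelocalizationStatus],
) -> tuple[int, int, float]:
    """(RD, TND, FR): relocalized count, total duplicates, and their
    ratio.  Rounding is left to report writers."""
    statuses = list(statuses)
    if not statuses:
        raise ValueError("no relocalization statuses given")
    rd = sum(1 for s in statuses if s.status is Status.RELOCALIZED)
    tnd = len(statuses)
    return rd, tnd, rd / tnd


def group_summary(
    per_species: dict[str, tuple[int, int]], groups: dict[str, str]
) -> pd.DataFrame:
    """Pool per-species (RD, TND) counts into per-group rows with pooled
    frequency FR = sum(RD) / sum(TND).  Empty groups are omitted."""
    rows = []
    for species, (rd, tnd) in per_species.items():
        if species not in groups:
            raise KeyError(f"species {species!r} has no group assignment")
        rows.append({"group": groups[species], "rd": rd, "tnd": tnd})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["group", "rd", "tnd", "fr"])
    out = df.groupby("group", as_index=False)[["rd", "tnd"]].sum()
    out["fr"] = out["rd"] / out["tnd"]
    return out
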