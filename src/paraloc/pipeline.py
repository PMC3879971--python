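"""End-to-end orchestration: proteome -> pairs -> families -> divergence
-> relocalization -> NTP classes -> hazard tables, with TSV reports and
a JSON-lines run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from paraloc import (
    divergence as dv,
    family_clustering as fc,
    localization as lc,
    ntp_mutation as ntp,
    pair_detection as pd_,
    sequence_model as sm,
    survival as sv,
)
from paraloc.config import PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    proteome: sm.SpeciesProteome
    pairs: list
    families: set
    estimates: dict        # pair key -> DivergenceEstimate
    statuses: dict         # pair key -> RelocalizationStatus
    ntp_classes: dict      # pair key -> NTPClass
    hazard_rows: list
    counts: dict = field(default_factory=dict)


def _stage(name: str, counts: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - self.t0)

    return _Timer()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on the configured inputs.

    Stage errors propagate with the stage name prefixed so failures are
    attributable; counts per stage land in the manifest.
    """
    cfg.validate()
    counts: dict = {}

    try:
        with _stage("sequence_model", counts):
            records = sm.load_cds_fasta(cfg.fasta, cfg.id_map)
            proteome = sm.SpeciesProteome.from_records(
                cfg.species_id, cfg.group_label, records, table=cfg.genetic_code
            )
        counts["genes"] = len(proteome.genes)
    except Exception as exc:
        raise RuntimeError(f"sequence_model: {exc}") from exc

    idp = pd_.IdentityThresholdParams(
        long_cutoff_length=cfg.long_cutoff_length,
        long_cutoff_identity=cfg.long_cutoff_identity,
    )
    try:
        with _stage("pair_detection", counts):
            if cfg.alignments:
                pairs = pd_.read_tabular_alignments(
                    cfg.alignments,
                    cfg.alignment_lengths,
                    max_e=cfg.max_e_value,
                    min_bsr=cfg.min_bsr,
                    identity_params=idp,
                    min_coverage=cfg.min_coverage,
                )
            else:
                pairs = pd_.detect_pairs(
                    proteome.proteins,
                    max_e=cfg.max_e_value,
                    min_bsr=cfg.min_bsr,
                    identity_params=idp,
                    min_coverage=cfg.min_coverage,
                )
        counts["pairs_aligned"] = len(pairs)
        counts["pairs_candidate"] = sum(p.passed_candidate for p in pairs)
        counts["pairs_reciprocal"] = sum(p.passed_reciprocal for p in pairs)
    except Exception as exc:
        raise RuntimeError(f"pair_detection: {exc}") from exc

    try:
        with _stage("family_clustering", counts):
            graph = fc.PairGraph.from_pairs(pairs)
            if cfg.apply_gene_conversion_filter:
                graph = fc.gene_conversion_filter(
                    graph, cfg.gene_conversion_max_matches
                )
            families = fc.build_families(graph)
        counts["families"] = len(families)
    except Exception as exc:
        raise RuntimeError(f"family_clustering: {exc}") from exc

    reciprocal = [p for p in pairs if p.passed_reciprocal]
    if cfg.apply_gene_conversion_filter:
        kept = graph.nodes
        reciprocal = [p for p in reciprocal if p.ids <= kept]

    prot_by_id = proteome.proteins
    cds_by_pid = {
        prot.protein_id: cds for cds, prot in proteome.representatives.values()
    }

    estimates: dict = {}
    ntp_classes: dict = {}
    try:
        with _stage("divergence+ntp", counts):
            region = ntp.NTPRegion(length=cfg.ntp_window_length)
            for p in reciprocal:
                id_a, id_b = sorted(p.ids)
                aln = ntp.global_align_pair(
                    prot_by_id[id_a].residues, prot_by_id[id_b].residues
                )
                codon_aln = dv.codon_backtranslate(
                    aln, cds_by_pid[id_a], cds_by_pid[id_b], table=cfg.genetic_code
                )
                est = dv.estimate_ks_ka(codon_aln, table=cfg.genetic_code)
                estimates[(id_a, id_b)] = dv.DivergenceEstimate(
                    id_a=id_a, id_b=id_b, ks=est.ks, ka=est.ka,
                    omega=est.omega, method=est.method, valid=est.valid,
                )
                window = ntp.extract_ntp_window(aln, region)
                ntp_classes[(id_a, id_b)] = ntp.classify_ntp_mutation(
                    *window, complete_min_gap=cfg.complete_min_gap
                )
        counts["divergence_estimates"] = len(estimates)
    except Exception as exc:
        raise RuntimeError(f"divergence: {exc}") from exc

    statuses: dict = {}
    try:
        with _stage("localization", counts):
            if cfg.predictions:
                calls = lc.parse_predictions(
                    cfg.predictions, dialect=cfg.predictions_dialect
                )
                for p in reciprocal:
                    if not p.passed_localization_subset:
                        continue
                    st = lc.classify_relocalization(p, calls)
                    if st is not None:
                        statuses[(st.id_a, st.id_b)] = st
        counts["localized_pairs"] = len(statuses)
    except Exception as exc:
        raise RuntimeError(f"localization: {exc}") from exc

    hazard_rows: list = []
    try:
        with _stage("survival", counts):
            joint = [
                (estimates[k], statuses[k])
                for k in estimates
                if k in statuses and estimates[k].valid
                and estimates[k].ks > cfg.ks_min
            ]
            if joint:
                hazard_rows = sv.ks_window_hazard_table(
                    joint,
                    windows=[tuple(w) for w in cfg.ks_windows],
                    ties=cfg.ties_method,
                )
        counts["survival_pairs"] = len(joint)
    except Exception as exc:
        raise RuntimeError(f"survival: {exc}") from exc

    return PipelineResult(
        proteome=proteome,
        pairs=pairs,
        families=families,
        estimates=estimates,
        statuses=statuses,
        ntp_classes=ntp_classes,
        hazard_rows=hazard_rows,
        counts=counts,
    )


def _fmt2(x: float) -> str:
    return f"{x:.2f}"


def write_tables(result: PipelineResult, cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Write the report bundle: per-stage TSVs, the three summary tables
    (duplication proportions, relocalization frequencies, hazard ratios),
    NTP category frequencies, and a JSON-lines manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["pairs"] = outdir / "pairs.tsv"
    pd_.write_pairs_tsv(files["pairs"], result.pairs)

    files["families"] = outdir / "families.tsv"
    fc.write_families_tsv(files["families"], result.families)

    files["divergence"] = outdir / "divergence.tsv"
    dv.write_divergence_tsv(files["divergence"], result.estimates.values())

    # table 1 analog: proportion of the genome duplicated
    files["table1"] = outdir / "table1.tsv"
    with open(files["table1"], "w", encoding="utf-8") as out:
        out.write("species\tgroup\tduplicated_genes\ttotal_genes\tproportion\n")
        total = len(result.proteome.genes)
        if total and result.families:
            prop = fc.duplication_proportion(result.families, total)
            members = len(set().union(*(f.members for f in result.families)))
        else:
            prop, members = 0.0, 0
        out.write(
            f"{result.proteome.species_id}\t{result.proteome.group_label}\t"
            f"{members}\t{total}\t{_fmt2(prop)}\n"
        )

    # table 2 analog: relocalization frequency
    files["table2"] = outdir / "table2.tsv"
    with open(files["table2"], "w", encoding="utf-8") as out:
        out.write("species\tgroup\trd\ttnd\tfr\n")
        if result.statuses:
            rd, tnd, fr = lc.relocalization_frequency(result.statuses.values())
            out.write(
                f"{result.proteome.species_id}\t{result.proteome.group_label}\t"
                f"{rd}\t{tnd}\t{_fmt2(fr)}\n"
            )

    # table 3 analog: hazard ratios over Ks windows
    files["table3"] = outdir / "table3.tsv"
    sv.write_hazard_table_tsv(
        files["table3"], result.proteome.species_id, result.hazard_rows
    )

    # fig 1 analog: NTP categories x relocalization
    files["fig1"] = outdir / "fig1.tsv"
    if result.ntp_classes:
        joint = [
            (cls, result.statuses.get(key))
            for key, cls in result.ntp_classes.items()
        ]
        table = ntp.category_frequencies(joint)
        table.to_csv(files["fig1"], sep="\t", index=False, float_format="%.4f")
    else:
        files["fig1"].write_text(
            "category\tcount\tfraction\tpsr_rate\tshare_of_relocalized\n"
        )

    files["manifest"] = outdir / "manifest.jsonl"
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(files["manifest"], "w", encoding="utf-8") as out:
        out.write(json.dumps({"config_sha256_16": cfg_hash}) + "\n")
        out.write(json.dumps({"counts": result.counts}) + "\n")
    return files
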