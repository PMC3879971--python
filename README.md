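# paraloc

Does protein subcellular relocalization (PSR) help eukaryotic duplicate
genes survive?  `paraloc` is an analysis pipeline for that question: it
detects paralogous protein pairs within a genome, groups them into gene
families, measures each pair's age by synonymous divergence (Ks),
classifies pairs as *relocalized* (the two proteins are predicted to
reside in different subcellular compartments) or *nonrelocalized*, and
compares the two groups' death rates with a Cox proportional-hazards
model over nested Ks windows.  It is written for molecular
evolutionists who have per-species CDS FASTA files (plus optional BLAST
tabular output and subcellular-localization predictions) and want the
whole chain — filtering, clustering, divergence, survival — reproducible
and testable, including on synthetic data with known ground truth.

## The model

Each duplicate pair contributes an observation (t, DP), where t is the
pair's Ks and DP is 0 for relocalized and 1 for nonrelocalized pairs.
The hazard of "death" (loss of one duplicate) is modelled as

    h(t | DP) = h0(t) · exp(β · DP)

with unspecified baseline h0(t).  β is estimated by maximizing the Cox
partial likelihood (Newton–Raphson, Efron tie correction by default).
The hazard ratio e^β is the death rate of nonrelocalized pairs relative
to relocalized ones: e^β > 1 means relocalized duplicates are
preferentially retained.  For example, e^β = 1.58 reads as a 58% higher
death rate for pairs that did not relocalize.  Model adequacy is checked
through Cox–Snell residuals (Kolmogorov–Smirnov distance from a unit
exponential).

Upstream, pairs are called from all-vs-all Smith–Waterman alignment
with an e-value ≤ 1e−3 and a BLAST score ratio (bit score over the
larger self-alignment bit score) ≥ 0.33, then filtered reciprocally:
≥ 80% coverage of both proteins and percent identity above a
length-dependent threshold (flat 30% for alignments of ≥ 150 columns,
rising for shorter ones).  Families are maximal cliques of the filtered
pair graph ("double linkage": A–B, B–C and A–C must all pass) merged
into superclusters until every protein sits in one family.  Ks and Ka
come from a Nei–Gojobori (1986) codon-pathway estimate with
Jukes–Cantor correction on the back-translated codon alignment.
N-terminal-peptide (NTP) mutations between pair members are classified
from an end-to-end realignment as NONE (substitutions only), PARTIAL
(internal indel), TERMINAL (indel at the first column), or COMPLETE
(gap run of ≥ 30 residues).

## Worked example

Simulate duplicate pairs whose lifetimes follow two constant hazards
(nonrelocalized pairs dying twice as fast) and refit the model:

```sh
psr simulate retention --n-pairs 5000 --rate-reloc 1.0 \
    --rate-nonreloc 2.0 --ks-hi 10 --seed 1 --out retention.tsv
```

prints

```
wrote 5000 records to retention.tsv; true HR 2.000, fitted HR 1.968 (95% CI 1.856-2.086, p=7.43e-114)
```

The fitted hazard ratio 1.968 recovers the simulated rate ratio 2.0
within its confidence interval; the tiny p-value says the two groups'
death rates differ decisively at this sample size.  The sequence-level
pipeline runs the same way from files:

```sh
psr simulate sequences --n-families 50 --seed 7 --out fixture/
psr run --config config.yaml          # points at fixture/ paths
```

writing `pairs.tsv`, `families.tsv`, `divergence.tsv`, a hazard-ratio
table over the default nested Ks windows (`table3.tsv`, starred at
p < 0.05 and p < 0.001), relocalization frequencies (`table2.tsv`), NTP
category frequencies (`fig1.tsv`), and a run manifest.

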