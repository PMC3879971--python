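# Methods

## The survival framing

A duplicate pair's Ks — synonymous substitutions per synonymous site —
is treated as the pair's realised lifetime: pairs observed at higher Ks
have survived longer since duplication.  Every observation is an event;
no censoring mechanism enters the model, because the input is a
cross-sectional census of surviving pairs rather than a followed
cohort.  The one-covariate Cox model h(t|DP) = h0(t)·exp(β·DP)
(DP = 1 for nonrelocalized pairs) assumes only that the two groups'
hazards are proportional; the baseline h0(t) — the overall
age-dependent death rate of duplicates, shaped by the genome's
duplication history — is never estimated.

The partial likelihood is maximised by Newton–Raphson from β = 0 with
convergence at |Δβ| < 1e−9 (≤ 100 iterations, steps damped to |Δβ| ≤ 5
and |β| > 50 treated as monotone-likelihood divergence, which happens
exactly when one group's event times completely precede the other's).
Ties use Efron's correction by default; Breslow is available and the
two agree to 1e−9 on tie-free data.  The standard error is the inverse
square root of the observed information, significance a Wald test, and
the 95% CI exp(β ± 1.96·se).  Analyses run on nested Ks windows
(0, 0.05) … (0, 1) with strict bounds, matching the convention of
reading "0 < Ks < 1" literally; an upper bound of 1 limits multiple-hit
saturation and repeated relocalizations, and an optional floor
Ks > 0.01 removes near-identical pairs whose localization predictions
are least trustworthy for homology-based predictors.

Cox–Snell residuals r_i = Λ̂0(t_i)·exp(β·DP_i), with the Breslow
baseline cumulative hazard, are unit-exponential when the model is
well specified; the package reports their Kolmogorov–Smirnov distance
from Exp(1) as a single adequacy number (≈ 0.004 at n = 5,000 on
well-specified simulations).  With all-events data the residuals sum
exactly to the number of records, which the tests assert.

## Pair detection

All-vs-all intraspecific Smith–Waterman (BLOSUM62, gap open −11,
extend −1, where a length-k gap scores open + (k−1)·extend) stands in
for a BLAST search; raw scores convert to bits and e-values through
Karlin–Altschul statistics (λ = 0.267, K = 0.041, search space
len(a)·len(b)·database_count).  When precomputed BLAST tabular output
is supplied, its bits and e-values are used verbatim and duplicate
unordered pairs collapse to the best bit score.

The BLAST score ratio is bits(A,B)/max(selfbits(A), selfbits(B)) —
symmetric, scale-invariant, and in (0, 1].  Candidate pairs need
e ≤ 1e−3 and BSR ≥ 0.33 (both inclusive).  The reciprocal filter then
requires ≥ 80% coverage of both proteins' full lengths and identity at
or above a length-dependent minimum: 30% for alignments of ≥ 150
columns, and below that the twilight-zone-style curve
n0 + 480·L^(−0.32·(1 + e^(−L/1000))), with n0 fixed so the curve meets
30% continuously at L = 150.  The curve is monotonically nonincreasing
over [1, 1000] (grid-checked in tests) and fully configurable.  A
stricter subset (identity ≥ 50%, coverage ≥ 80%) feeds the
localization comparison, where misassigned compartments on marginal
homologs would be most damaging.

## Families and gene conversion

Double-linkage families are the maximal cliques of the filtered pair
graph (Bron–Kerbosch with pivoting); an edge belonging to no triangle
is a two-member family.  Because cliques overlap, overlapping clusters
are merged by single linkage to a fixpoint ("superclusters"), making
the final families a partition.  On all graphs with ≤ 5 nodes
(exhaustive) and hundreds of random 6–7-node graphs, this equals a
brute-force subset-enumeration oracle.

Gene conversion homogenises members of large families and deflates
their apparent Ks.  The guard removes every protein with more than 5
pair-graph matches, degrees computed once on the original graph
(single pass).  Survivors keep original degree ≤ 5 and removals only
lower degrees, so the pass is idempotent — also asserted.

## Divergence

Protein pairs are realigned end-to-end and back-translated to codon
alignments (gap residue → `---`; the ungapped protein must translate
exactly from its CDS).  Ks/Ka uses Nei–Gojobori (1986): per-codon
synonymous site fractions averaged over the two sequences (mutations
to stop codons excluded from each position's denominator), differences
averaged over all minimal mutation pathways with stop-crossing
pathways excluded, and Jukes–Cantor correction of pS and pN.  The
correction saturates at p ≥ 3/4, which flags the estimate invalid
rather than producing a number; gapped, ambiguous (N), and stop-codon
columns are excluded.  The estimator is desk-verifiable — the test
battery pins hand-computed cases to 1e−9 — and symmetric,
concatenation-invariant and monotone on substitution ladders by
property test.  A transition/transversion- and codon-usage-aware
external estimator (e.g. yn00 output) can be substituted through a
simple TSV reader; the survival analysis consumes only relative Ks, so
the choice shifts the Ks scale more than the group contrast.

Positive-selection screening uses the strict cut ω = Ka/Ks > 1.5 and a
two-proportion z-test (Fisher's exact when any cell < 5).

## NTP classification

The N-terminal peptide (~13–85 residues) is approximated by a fixed
window: the leading alignment columns spanning the first 60 residues
(configurable; 60 is the midpoint of the plausible range) of the
longer member.  Classification looks only at gap runs inside that
window: a maximal run ≥ 30 residues (or a gap covering a member's
whole window) is COMPLETE, a run touching column 1 is TERMINAL, any
other gap is PARTIAL, and a gap-free window is NONE.  Precedence
COMPLETE > TERMINAL > PARTIAL makes the four classes exclusive and
exhaustive (property-tested on random gapped strings).  Pairs are
re-aligned globally with end gaps penalised before windowing, because
a local alignment clips unmatched termini and would silently convert
TERMINAL/COMPLETE events into NONE.  Both readings of "PSR frequency
per category" are reported: the within-category relocalization rate
and each category's share among all relocalized pairs.

## Synthetic data

The retention simulator draws status ~ Bernoulli(p_relocalized) and a
lifetime ~ Exponential(δ of the group), keeping lifetimes inside the
Ks window by rejection sampling — the transparent counterpart of the
analysis-side window filter.  Constant hazards are the simplest
proportional-hazards truth, giving the closed-form target
HR = δ_N/δ_R.  Defaults: 5,000 pairs, p = 0.5, δ_R = 1, δ_N = 1.5 per
Ks unit, window (0, 1), fixed integer-seeded RNG (bit-identical
reruns).

A caveat the package measures rather than hides: conditioning on a
window that truncates an appreciable tail makes the *observed* two
groups' hazards non-proportional (the truncated hazard ratio drifts
toward and past 1 near the window's edge), biasing the fitted HR
toward 1.  With δ_R = 1 and window (0, 1) the attenuation is large, so
point-recovery checks use an effectively untruncating window (0, 10),
and the confidence-interval coverage experiment uses a fast clock
(δ_R = 6, < 0.25% of mass beyond Ks = 1), where coverage of the true
ratio is ≥ 94% across ratios 1–2 at n = 1,000 over 200 replicates.
This mirrors real data only to the extent that most duplicate loss
happens well inside the analysed Ks range.

The sequence simulator builds each family from one random ancestral
CDS (uniform sense codons, no stops), duplicates it, applies per-site
substitutions (2% default; stop-creating draws redrawn), an optional
background in-frame indel outside the NTP (10% of pairs), and one NTP
event per pair — none 0.55 / partial 0.20 / terminal 0.15 / complete
0.10 — with relocalization probability increasing with event severity
(0.10 / 0.30 / 0.40 / 0.70), echoing the observation that complete NTP
gain/loss relocalizes most.  Complete events delete ≥ 30 NTP codons,
so parameter validation rejects NTPs shorter than 30 codons when their
probability is nonzero.  Genes default to 250 codons with a 60-codon
NTP.  The generator emulates duplication, divergence and NTP mutation
logic — not codon-usage bias, realistic indel-length spectra,
transcript structure or true birth–death family dynamics — so passing
recovery tests demonstrates the pipeline's correctness on clean
signals, not predictor accuracy on real proteomes.  Note that a
complete NTP deletion removes up to a quarter of a 250-codon gene, so
such pairs can legitimately fail the 80% coverage filter; family
recovery is therefore asserted exactly only on noiseless fixtures,
while NTP-class recovery (≥ 90% on mixed fixtures, measured on
ground-truth pairs) is the classifier's own benchmark.

## Numerical and degenerate-input choices

* Representative transcript: longest CDS per gene, ties to the
  lexicographically smallest transcript id.
* Translation: standard code (per-species override); trailing partial
  codons trimmed with a warning; one trailing stop stripped; internal
  stops flag the gene invalid and exclude it from pairing instead of
  aborting a whole-species run.
* Localization ties at the top score break by configured vocabulary
  order, with a warning; missing predictions exclude the pair, not the
  run.  Only same/different status crosses species boundaries, never
  compartment labels, since vocabularies are taxon-specific.
* Ks windows with an empty group produce an NA hazard row with a
  recorded reason rather than an exception.
* Problem sizes in tests and the acceptance script (dozens of
  families, 120–250-codon genes, 1,000–5,000 survival records, 200
  replicates) are chosen to make every stochastic check decisive at
  desk scale while the whole suite stays fast.

## Known limitations

Smith–Waterman with Karlin–Altschul constants approximates but does
not reproduce BLAST's HSP heuristics; NG86 ignores
transition/transversion bias and codon usage; the fixed NTP window is
a blunt proxy for cleavage-site prediction; localization predictions
are consumed, never produced, so their error structure is outside the
model; and all observations are uncensored by design, which is only
as valid as the census interpretation of Ks.
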