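# Methods

## The quantity being estimated

For a cassette exon with flanking introns, three junctions carry the
splicing evidence: the two inclusion junctions (upstream exon → cassette,
cassette → downstream exon) and the skip junction (upstream exon →
downstream exon).  The inclusion isoform contributes two junction reads per
molecule and the skipping isoform one, so the percent-spliced-in estimator
weights the skip count twice:

    ψ = (j_up + j_down) / (j_up + j_down + 2·j_skip)

ψ is undefined when all three counts are zero; the undefined value
propagates as missing and is never coerced to 0, so "no expression" stays
distinct from "fully skipped".  Δψ = ψ_treated − ψ_control is computed per
replicate; the between-replicate statistic
((ψ_ctrl.1 − ψ_ctrl.2) + (ψ_treat.1 − ψ_treat.2)) / 2 serves as the
baseline fluctuation reference for the Δψ distribution.

Only junction reads whose alignment extends at least 8 nt (configurable)
into both flanking exons are counted; expression is normalised as RPK30M
(reads per kilobase per 30 million mapped reads).  An event is dropped when
its gene is below 16 RPK30M in every sample, or when the three-junction
total is below 4 RPK30M in any single sample — the strictest grammatical
reading of the filter, chosen deliberately and configurable.  Because this
pipeline counts only junction reads, gene expression is proxied by the
gene's total junction reads over its exonic-union length, and a junction's
feature length is fixed at 100 nt (two 50-nt anchor windows); both
conventions are configurable and documented here because they set the
absolute scale of the RPK30M cutoffs.

## Response classes and the strict call

Per-replicate classes follow fixed thresholds: skip (Δψ ≤ −0.05 in either
replicate, < 0 in the other), inclusion (mirror image), no change (both
within ±0.05), and the "others" bucket (no expression; inconsistent
replicates; all ψ < 0.05).  The rules are evaluated in a fixed order so the
classification is total — every input lands in exactly one class, which is
property-tested.

The strict skip call requires mean Δψ ≤ −0.25 *and* a pooled-variance
two-sample t-test p < 0.05 on the replicate ψ values.  With two replicates
per condition (df = 2) the pooled-variance Student test is the only stable
choice.  When both conditions have zero variance the t statistic is
undefined; a perfectly reproduced nonzero shift is treated as p = 0 and an
identical pair as p = 1.

## Homologous-exon pairing

Cassette exons of species A are aligned against internal exons of the
homologous species-B gene (homology supplied as a two-column table) with a
Smith–Waterman local aligner using blastn-like scores (match +2, mismatch
−3, gap open −5, gap extend −2; configurable), replacing an external BLAST
dependency while preserving local-alignment semantics.  Percent identity is
matches over aligned columns with gap columns as mismatches; coverage is
the aligned span over the full exon length per species.  Acceptance
requires identity > 70 % (strict) and coverage > 0.9 on both sides; among
acceptable candidates the winner maximises (identity, coverage sum)
lexicographically, with genomic coordinate as a final deterministic
tie-break.  One B-side exon may serve several A-side exons.  When a B-side
exon has several annotated flanking-exon pairs, the pair with the highest
total junction reads across all samples defines its event.

## Sequence features

All windows are extracted in transcript sense (reverse-complemented for
minus-strand events); windows clipped by a short intron or contig end are
truncated, never padded, and flagged.

- Donor site: 3 exonic + 6 intronic nt (9-mer); acceptor site: 20 intronic
  + 3 exonic nt (23-mer).  Both are scored by first-order position-weight
  models (log2 odds against uniform background).  The scorer is pluggable —
  models round-trip through plain-text TSV, and `train_pwm` fits one from
  aligned sequences — but the shipped defaults are consensus-frequency
  matrices.  Scores are only comparable within one model, so analyses apply
  the same model to both species.
- ESE/ESS counts: occurrences (overlaps counted) of positive-score and
  negative-score motifs from a SpliceAid-style table.
- Branch point: within the last ≤100 intronic nt before the acceptor,
  every heptamer with an adenosine at position 6 is scored against a
  yUnAy-type consensus PWM; the best-scoring candidate wins, ties going to
  the 3′-most.  This deterministic heuristic replaces an SVM predictor with
  an identical interface; events with no candidate adenosine carry no
  branch or PPT score and are excluded from PPT analyses.
- PPT score: pyrimidine count plus longest uninterrupted pyrimidine run,
  over the bases strictly between the branch adenosine and the final 3 nt
  of the intron.  The scale is a stand-in commensurate with the decile-style
  bins used downstream (0–9 / 10–19 / 20–29 / ≥30); the synthetic generator
  is calibrated on this same scale, and bin edges are configurable rather
  than assumed transferable to any other scorer's scale.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when the smaller group has ≤8 values and no ties, otherwise the
normal approximation with tie correction.  Raw p-values are starred at
0.05/0.01/0.001; Benjamini–Hochberg-adjusted values are emitted in a
separate column for transparency but do not drive the stars.  The four-way
design compares (A) skip-enhanced A-side exons vs their paired insensitive
B-side homologs, (B) A-side vs B-side of the control pairs, (C) A-side
skip-enhanced vs A-side controls, (D) paired B-side insensitive vs B-side
controls.  "Insensitive" for the paired group means class = no change;
the control set comprises homolog pairs with Δψ exactly 0 in both
replicates on both sides.  A paired signed-rank variant of comparison A is
available behind a flag but rank-sum is the default.

The nine-category table cross-tabulates the per-species classes
(skip / no effect / inclusion) of homologous pairs; expected counts come
from the product of marginals and the Pearson chi-square (df 4, no
continuity correction) tests conservation of the response against
independence.  The set-overlap test compares an observed overlap with
|A|·|B|/N on the 2×2 membership table (df 1, no continuity correction).

Enrichment stratifies events into 48 bins — exon length (0–64 / ≥65 nt),
ESE (0–4 / 5–15 / ≥16), ESS (0–19 / ≥20), PPT (0–9 / 10–19 / 20–29 / ≥30).
The lower ESS bin starts at 0 and the third PPT bin at 20 so the axes
partition; both are configurable.  Per bin, enrichment is the hit fraction
over the dataset baseline (total hits / total events) and the p-value is
the upper-tail hypergeometric probability (enrichment direction only); bins
with fewer than 3 hits are marked non-reportable.  By construction the
size-weighted mean enrichment over bins equals 1, which is asserted in
tests.

## The synthetic generator

The generator emulates the study conditions the analysis assumes: two
species, two conditions, two replicates each.  Defaults: 200 genes (the
acceptance run uses 500), one cassette per gene, 5 % sensitive exons,
homolog identity 0.936 (typical human–mouse exonic similarity), Δψ effect
−0.3, logit-scale replicate noise 0.1, 2×10⁶ junction reads per sample.
The replicate noise default was chosen so the between-replicate baseline
|Δψ| stays almost entirely within ±0.05, the regime a well-behaved
replicate pair exhibits; the library size keeps per-event counting error
well below the class thresholds at a few hundred genes.

Sensitivity is generated from features: sensitive exons are short
(40–64 nt) with <4 planted ESEs/ESSs and an engineered weak tract (PPT
score 11–19); their B-side homologs and all insensitive exons get strong
tracts (score ≥ 31).  Exons are built from planted motifs in a C-only
filler (every shipped motif contains G, so realised counts equal planted
counts exactly); intron tails place a single consensus branch heptamer
followed by a controlled pyrimidine run, so the realised branch point and
PPT score are deterministic.  Realised values — recomputed with the same
scorers the pipeline uses — are what the truth table records.

Per sample, reads are allocated to genes by a lognormal expression profile
and to an event's three junctions multinomially with weights (ψ, ψ, 1−ψ),
matching the estimator's weighting, so junction totals per gene and sample
are conserved exactly.  A configurable fraction of genes (default 0.4) is
constitutively included: ψ = 1 with no noise, hence measured Δψ exactly 0
in every replicate.  This is the device that populates the Δψ = 0 control
set, which under multinomial noise would otherwise be empty; it stands in
for real exons whose inclusion measurement is saturated and perfectly
reproducible.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: read-level alignment artefacts, intron-retention and
other non-cassette event types, correlated noise between events of one
gene, motif co-occurrence structure, PPT scales of external predictors, and
genuinely continuous feature–sensitivity relationships (the planted classes
are well separated by design).  Recovery rates measured here are upper
bounds for real data.

## Numerical and degenerate-input conventions

ψ of (0,0,0) is missing; classification demands exactly two replicate Δψ
values; enrichment with zero total hits reports undefined ratios and flags
them; chi-square tables with a zero expected cell are flagged unreliable;
alignment below the minimum score (default 10) is "no hit"; stage reruns
overwrite deterministically; all RNG flows from a single integer seed, and
rerunning any stage or the generator with the same seed reproduces outputs
byte for byte.

## Known limitations

- The splice-site and branch-point scorers are position-weight models, not
  maximum-entropy or SVM re-implementations; absolute scores are not
  comparable to external tools, only within-model contrasts are meaningful.
- Gene expression from junction reads under-weights single-exon or
  junction-poor genes; supplying precomputed gene expression is the
  supported alternative.
- With two replicates the t-test has df = 2, so the strict call's power is
  limited and a few percent of true shifts are missed when replicate
  variance is unluckily high; this is inherent to the design, not to the
  implementation.
- The nine-category and four-way analyses require non-empty groups; very
  small synthetic runs can leave groups empty, in which case the stage logs
  and skips the comparison rather than fabricating output.
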