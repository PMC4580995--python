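# splicesense

Comparative transcriptomics of splicing-modulator targets: which cassette
exons does a skip-enhancing compound act on, and what sequence features make
them sensitive?

Small chemical compounds that inhibit splicing-regulatory kinases (the
motivating case is a CLK-family inhibitor) shift the splicing of some — but
not all — cassette exons toward skipping. `splicesense` implements a
pipeline for deciphering the targeting rules of such a compound from
two-species RNA-seq junction counts, for computational biologists studying
splicing-modulation therapy:

1. **Event extraction** — annotated exon-skipping events are pulled from a
   GTF by the four-coordinate rule: an internal exon of one transcript is a
   cassette event iff another transcript of the same gene has an intron
   spanning exactly the 5′ end of the upstream intron to the 3′ end of the
   downstream intron.
2. **ψ/Δψ quantification** — inclusion levels from junction reads
   (8-nt anchor filter, RPK30M expression normalisation and filters):

   ψ = (j_up + j_down) / (j_up + j_down + 2·j_skip),  Δψ = ψ_treated − ψ_control

   with per-replicate response classes (skip / inclusion / no change /
   others) and a strict skip call (mean Δψ ≤ −0.25 and two-sample t-test
   p < 0.05).
3. **Homologous-exon pairing** — Smith–Waterman local alignment
   (blastn-like scoring) of each species-A cassette exon against the
   internal exons of the homologous species-B gene; accepted at identity
   > 70 % and coverage > 0.9 on both sides; flanking exons resolved by
   junction support.
4. **Sequence features** — exon length, ESE/ESS motif counts, donor
   (9-mer) and acceptor (23-mer) position-weight splice-site scores,
   branch-point prediction and a polypyrimidine-tract (PPT) score
   (pyrimidine count + longest run between the branch adenosine and the
   3′ AG) over the 100-nt upstream-intron window.
5. **Statistics** — four-way Wilcoxon feature comparisons (skip-enhanced vs
   paired insensitive homologs vs control pairs), the nine-category
   cross-species conservation table with chi-square against independence,
   a set-overlap independence test, and a 48-bin
   (length × ESE × ESS × PPT) hypergeometric enrichment analysis rendered
   as a decision-tree report.

A first-class synthetic-data module generates two homologous toy genomes
whose ground-truth compound sensitivity is a function of PPT strength, exon
length and motif counts, so the whole cascade is testable end to end
without any downloads.

## Worked example

```sh
splicesense simulate --n-genes 200 --seed 5 --outdir demo_ds
splicesense run-all --data-dir demo_ds --outdir demo_out
```

prints the filtering cascade (events surviving each stage):

```
events_annotated        200
events_expressed        200
events_strict_skip      10
events_with_homolog     10
pairs_b_insensitive     7
```

Of 200 annotated cassette events, all pass the expression filters, 10 are
strictly skip-enhanced (Δψ ≤ −0.25, t-test p < 0.05), all 10 find a
homologous exon in species B, and 7 of those homologs are insensitive —
the differential pairs the feature comparison is built on.  The top of
`demo_out/enrichment.tsv` (reportable bins, sorted):

```
bin_id                           size  hits  enrichment  p_value
len0-64|ese0-4|ess0-19|ppt10-19    11    10       18.18  4.9e-16
```

i.e. short exons with few splicing-factor motifs and a weak polypyrimidine
tract (score 10–19) are strongly enriched for skip-enhanced events — the
signature the generator planted, recovered from the sequence and the reads
alone.  `demo_out/` also holds the per-event ψ/class table, the homolog
pairs with percent identity, the per-feature four-way comparison TSV, the
nine-category table and the decision-tree JSON.

The same steps are available as library calls (`generate_dataset`,
`run_full`) and as per-stage commands (`splicesense stage events ...`),
with every threshold overridable by flag or YAML config.

## Layout

- `src/splicesense/annotation.py` — GTF gene models, event extraction
- `src/splicesense/quantify.py` — junction counting, ψ/Δψ, classification
- `src/splicesense/homology.py` — local alignment, homolog selection
- `src/splicesense/features.py`, `models.py` — feature vectors, PWM scorers
- `src/splicesense/stats.py`, `enrichment.py` — inferential layer
- `src/splicesense/simulate.py` — synthetic dataset generator
- `src/splicesense/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
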