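"""Cross-species homologous-exon pairing.

Cassette exons of species A are matched to internal exons of the homologous
gene in species B by Smith-Waterman local alignment with blastn-like scoring
(match +2, mismatch -3, gap open -5, gap extend -2).  A candidate is accepted
when percent identity over the aligned columns (gaps count as mismatches)
exceeds 70 and the aligned span covers more than 0.9 of the exon length on
both sides; among accepted candidates the pair maximising
(percent identity, coverage_A + coverage_B) lexicographically is selected,
with genomic coordinate as the final deterministic tie-break.  The same
B-side exon may be selected by multiple A-side exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align

from .annotation import Gene
from .quantify import JunctionCounts

logger = logging.getLogger(__name__)

__all__ = ["AlignmentResult", "HomologPair", "local_align", "select_homolog",
           "resolve_flanking"]


@dataclass
class AlignmentResult:
    score: float
    matches: int
    aligned_columns: int   # including gap columns within the local region
    percent_identity: float
    coverage_a: float      # aligned span on A / len(A)
    coverage_b: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]


@dataclass
class HomologPair:
    event_id_a: str
    gene_id_b: str
    exon_b: tuple[int, int]
    percent_identity: float
    coverage_a: float
    coverage_b: float


def _aligner(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_align(
    seq_a: str,
    seq_b: str,
    min_score: float = 10.0,
    scoring: Optional[dict] = None,
) -> Optional[AlignmentResult]:
    """Best local alignment of two nucleotide sequences, or ``None``.

    Returns ``None`` when the optimal local alignment scores below
    ``min_score`` (no meaningful similarity).  Percent identity is
    matches / aligned columns x 100 with gap columns counted as mismatches;
    coverage is the aligned span divided by the full sequence length.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(**(scoring or {}))
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    if len(alignments) == 0:
        return None
    best = alignments[0]
    if best.score < min_score:
        return None
    counts = best.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    blocks_a, blocks_b = best.aligned
    span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    return AlignmentResult(
        score=float(best.score),
        matches=int(counts.identities),
        aligned_columns=int(columns),
        percent_identity=100.0 * counts.identities / columns if columns else 0.0,
        coverage_a=(span_a[1] - span_a[0]) / len(seq_a),
        coverage_b=(span_b[1] - span_b[0]) / len(seq_b),
        span_a=span_a,
        span_b=span_b,
    )


def select_homolog(
    event_id_a: str,
    exon_seq_a: str,
    candidates: Sequence[tuple[str, tuple[int, int], str]],
    min_identity: float = 70.0,
    min_coverage: float = 0.9,
    min_score: float = 10.0,
) -> Optional[HomologPair]:
    """Pick the best homologous exon among B-side candidates.

    ``candidates`` are ``(gene_id_b, (start, end), sequence)`` tuples,
    normally the internal exons of the genes linked to the A-side gene in the
    homology table.  Candidate order does not affect the result.
    """
    best_key = None
    best_pair: Optional[HomologPair] = None
    for gene_id_b, exon_b, seq_b in candidates:
        aln = local_align(exon_seq_a, seq_b, min_score=min_score)
        if aln is None:
            continue
        if aln.percent_identity <= min_identity:
            continue
        if aln.coverage_a <= min_coverage or aln.coverage_b <= min_coverage:
            continue
        # maximise identity, then coverage sum; final tie-break on coordinates
        key = (
            aln.percent_identity,
            aln.coverage_a + aln.coverage_b,
            -exon_b[0],
            -exon_b[1],
        )
        if best_key is None or key > best_key:
            best_key = key
            best_pair = HomologPair(
                event_id_a=event_id_a,
                gene_id_b=gene_id_b,
                exon_b=exon_b,
                percent_identity=aln.percent_identity,
                coverage_a=aln.coverage_a,
                coverage_b=aln.coverage_b,
            )
    if best_pair is None:
        logger.debug("no homolog passing thresholds for %s", event_id_a)
    return best_pair


def resolve_flanking(
    exon_b: tuple[int, int],
    gene_b: Gene,
    junction_counts: JunctionCounts,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Choose the flanking-exon pair of a B-side exon.

    Among all annotated (genomic-left, genomic-right) neighbour pairs across
    the gene's transcripts, returns the pair whose three event junctions have
    the highest total read count summed over all samples; ties break on
    genomic coordinates.  Raises if the exon is not internal in any
    transcript.
    """
    pairs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    for tx in gene_b.transcripts:
        exons = tx.exons
        for i in range(1, len(exons) - 1):
            if exons[i] == exon_b:
                pairs.add((exons[i - 1], exons[i + 1]))
    if not pairs:
        raise ValueError(
            f"exon {exon_b} is not internal in any transcript of {gene_b.gene_id}"
        )

    def total_reads(pair: tuple[tuple[int, int], tuple[int, int]]) -> int:
        left, right = pair
        keys = [
            (gene_b.chrom, left[1], exon_b[0], gene_b.strand),
            (gene_b.chrom, exon_b[1], right[0], gene_b.strand),
            (gene_b.chrom, left[1], right[0], gene_b.strand),
        ]
        return sum(
            junction_counts.get(sample, key)
            for sample in junction_counts.counts
            for key in keys
        )

    return max(sorted(pairs), key=total_reads)
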