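"""Gene models and annotated exon-skipping (cassette exon) events.

A cassette-exon event is described by four genomic coordinates: the 5' end of
the upstream intron (coord1), the cassette exon boundaries (coord2, coord3)
and the 3' end of the downstream intron (coord4).  An internal exon of one
transcript is an annotated skipping event iff another transcript of the same
gene carries an intron spanning exactly coord1..coord4 (the exon-less
"skip" intron).

All coordinates are internal 0-based half-open; GTF input (1-based inclusive)
is converted on parsing.  Minus-strand genes keep genomic coordinates;
transcript-sense orientation is resolved only at feature-extraction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils

__all__ = [
    "Transcript",
    "Gene",
    "GeneModels",
    "SkippingEvent",
    "parse_gtf",
    "extract_skipping_events",
]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent gene annotation."""


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # sorted, 0-based half-open

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]


@dataclass
class GeneModels:
    genes: dict[str, Gene] = field(default_factory=dict)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SkippingEvent:
    """A cassette exon plus its two flanking introns (4 genomic coordinates).

    ``coord1 < coord2 < coord3 < coord4`` on the genomic axis; the cassette
    exon is ``[coord2, coord3)`` and the skip intron is ``[coord1, coord4)``.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    coord1: int
    coord2: int
    coord3: int
    coord4: int

    def __post_init__(self) -> None:
        if not (self.coord1 < self.coord2 < self.coord3 < self.coord4):
            raise AnnotationError(
                f"event {self.event_id}: coordinates must satisfy "
                f"coord1 < coord2 < coord3 < coord4, got "
                f"{(self.coord1, self.coord2, self.coord3, self.coord4)}"
            )

    @property
    def cassette_length(self) -> int:
        return self.coord3 - self.coord2

    @property
    def upstream_intron(self) -> tuple[int, int]:
        """Genomic-left intron (transcript-upstream on the plus strand)."""
        return (self.coord1, self.coord2)

    @property
    def downstream_intron(self) -> tuple[int, int]:
        return (self.coord3, self.coord4)

    @property
    def skip_intron(self) -> tuple[int, int]:
        return (self.coord1, self.coord4)


def _validate_exons(transcript_id: str, exons: list[tuple[int, int]]) -> None:
    for start, end in exons:
        if start >= end:
            raise AnnotationError(
                f"transcript {transcript_id}: empty exon ({start}, {end})"
            )
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise AnnotationError(
                f"transcript {transcript_id}: overlapping or unsorted exons "
                f"({s1},{e1}) and ({s2},{e2})"
            )


def parse_gtf(path: str | Path) -> GeneModels:
    """Parse exon features of a GTF file into :class:`GeneModels`.

    Coordinates are converted from the GTF 1-based inclusive convention to
    0-based half-open.  Exons must carry ``gene_id`` and ``transcript_id``
    attributes; overlapping exons within a transcript raise
    :class:`AnnotationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return GeneModels()
    per_tx: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks "
                f"attribute {exc}"
            ) from None
        rec = per_tx.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
             "exons": []},
        )
        rec["exons"].append((feat.start - 1, feat.end))

    genes: dict[str, dict] = {}
    for tx_id, rec in per_tx.items():
        exons = sorted(rec["exons"])
        _validate_exons(tx_id, exons)
        gene = genes.setdefault(
            rec["gene_id"],
            {"chrom": rec["chrom"], "strand": rec["strand"], "txs": []},
        )
        gene["txs"].append(Transcript(tx_id, tuple(exons)))

    models = GeneModels()
    for gene_id, rec in genes.items():
        txs = tuple(sorted(rec["txs"], key=lambda t: t.transcript_id))
        models.genes[gene_id] = Gene(gene_id, rec["chrom"], rec["strand"], txs)
    return models


def extract_skipping_events(models: GeneModels) -> list[SkippingEvent]:
    """Extract annotated cassette-exon events from gene models.

    For every internal exon of every transcript, an event is emitted iff some
    *other* transcript of the same gene contains an intron spanning exactly
    the upstream-intron 5' end to the downstream-intron 3' end.  Events are
    deduplicated on the (gene_id, coord1..coord4) tuple; transcript input
    order does not affect the result.
    """
    events: list[SkippingEvent] = []
    seen: set[tuple] = set()
    for gene in sorted(models, key=lambda g: g.gene_id):
        intron_sets = {tx.transcript_id: set(tx.introns()) for tx in gene.transcripts}
        candidates: set[tuple[int, int, int, int]] = set()
        for tx in gene.transcripts:
            exons = tx.exons
            for i in range(1, len(exons) - 1):
                c1 = exons[i - 1][1]
                c2, c3 = exons[i]
                c4 = exons[i + 1][0]
                for other in gene.transcripts:
                    if other.transcript_id == tx.transcript_id:
                        continue
                    if (c1, c4) in intron_sets[other.transcript_id]:
                        candidates.add((c1, c2, c3, c4))
                        break
        for c1, c2, c3, c4 in sorted(candidates):
            key = (gene.gene_id, c1, c2, c3, c4)
            if key in seen:
                continue
            seen.add(key)
            events.append(
                SkippingEvent(
                    event_id=f"{gene.gene_id}:{c1}-{c2}-{c3}-{c4}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    coord1=c1,
                    coord2=c2,
                    coord3=c3,
                    coord4=c4,
                )
            )
    return events


def internal_exons(gene: Gene) -> set[tuple[int, int]]:
    """All distinct internal exons of a gene across its transcripts."""
    out: set[tuple[int, int]] = set()
    for tx in gene.transcripts:
        for exon in tx.exons[1:-1]:
            out.add(exon)
    return out
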