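"""Per-event sequence features of cassette exons.

For every skipping event the feature vector collects: exon length, counts of
exonic splicing enhancer/silencer motifs, donor (9-mer) and acceptor (23-mer)
splice-site scores for the cassette's own sites and for the outer sites of
the flanking introns, intron lengths, the predicted branch point and the
polypyrimidine-tract (PPT) score of the 100-nt window at the 3' end of the
upstream intron.

Strand handling: event coordinates are genomic; all extracted sequences are
returned in transcript sense (reverse-complemented for minus-strand events),
so "upstream" always means transcript-upstream.

The PPT score is ``(number of pyrimidines) + (longest uninterrupted
pyrimidine run)`` over the bases strictly between the branch adenosine and
the final 3 nt of the intron.  It is a deterministic stand-in on a scale
commensurate with decile-style binning (0-9 / 10-19 / 20-29 / >=30); events
with no predictable branch point carry no PPT or branch score and are
excluded from PPT analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .annotation import SkippingEvent
from .models import (
    PositionWeightModel,
    default_acceptor_model,
    default_branch_model,
    default_donor_model,
)

__all__ = [
    "MotifTable",
    "FeatureVector",
    "SpliceSiteSequences",
    "splice_site_sequences",
    "score_splice_site",
    "count_motifs",
    "predict_branch_point",
    "ppt_score",
    "feature_vector",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
PYRIMIDINES = frozenset("CT")

DONOR_EXONIC = 3     # exonic nt in the donor 9-mer
DONOR_INTRONIC = 6
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
PPT_WINDOW = 100


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifTable:
    """Splicing-factor binding motifs with signed scores.

    Positive-score entries act as exonic splicing enhancers (ESE),
    negative-score entries as silencers (ESS).
    """

    entries: list[tuple[str, str, float]]  # (factor, motif, score)

    def __post_init__(self) -> None:
        for factor, motif, score in self.entries:
            if not motif:
                raise ValueError(f"empty motif for factor {factor}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotifTable":
        return cls([(r.factor, r.motif.upper(), float(r.score))
                    for r in df.itertuples(index=False)])

    @property
    def ese_motifs(self) -> list[str]:
        return [m for _, m, s in self.entries if s > 0]

    @property
    def ess_motifs(self) -> list[str]:
        return [m for _, m, s in self.entries if s < 0]


@dataclass
class SpliceSiteSequences:
    donor: str                    # cassette 5'ss: 3 exonic + 6 intronic nt
    acceptor: str                 # cassette 3'ss: 20 intronic + 3 exonic nt
    ppt_window: str               # <=100 intronic nt preceding the acceptor
    donor_upstream_intron: str    # 5'ss of the upstream intron (flank donor)
    acceptor_downstream_intron: str  # 3'ss of the downstream intron
    exon: str                     # cassette exon, transcript sense
    truncated: bool               # any window clipped by a short intron/contig


def _slice(genome, chrom: str, start: int, end: int) -> tuple[str, bool]:
    """Contig-clipped slice; the flag reports whether clipping occurred."""
    length = len(genome[chrom])
    cstart, cend = max(0, start), min(length, end)
    truncated = (cstart, cend) != (start, end)
    return str(genome[chrom][cstart:cend]), truncated


def splice_site_sequences(event: SkippingEvent, genome) -> SpliceSiteSequences:
    """Extract the scoring windows of an event, in transcript sense.

    ``genome`` is any mapping of chromosome name to a sliceable sequence
    (e.g. a :class:`pyfaidx.Fasta`).  Windows that would extend past a contig
    end or into a flanking exon (intron shorter than the nominal window) are
    truncated, never padded, and flagged.
    """
    c1, c2, c3, c4 = event.coord1, event.coord2, event.coord3, event.coord4
    chrom = event.chrom
    truncated = False

    def grab(start: int, end: int) -> str:
        nonlocal truncated
        seq, trunc = _slice(genome, chrom, start, end)
        truncated = truncated or trunc
        return seq

    if event.strand == "+":
        up_intron = (c1, c2)
        donor = grab(c3 - DONOR_EXONIC, c3 + DONOR_INTRONIC)
        acceptor = grab(c2 - ACCEPTOR_INTRONIC, c2 + ACCEPTOR_EXONIC)
        win_start = max(c2 - PPT_WINDOW, up_intron[0])
        if c2 - PPT_WINDOW < up_intron[0]:
            truncated = True
        window = grab(win_start, c2)
        donor_up = grab(c1 - DONOR_EXONIC, c1 + DONOR_INTRONIC)
        acceptor_down = grab(c4 - ACCEPTOR_INTRONIC, c4 + ACCEPTOR_EXONIC)
        exon = grab(c2, c3)
    elif event.strand == "-":
        up_intron = (c3, c4)  # transcript-upstream intron is genomic-right
        donor = revcomp(grab(c2 - DONOR_INTRONIC, c2 + DONOR_EXONIC))
        acceptor = revcomp(grab(c3 - ACCEPTOR_EXONIC, c3 + ACCEPTOR_INTRONIC))
        win_end = min(c3 + PPT_WINDOW, up_intron[1])
        if c3 + PPT_WINDOW > up_intron[1]:
            truncated = True
        window = revcomp(grab(c3, win_end))
        donor_up = revcomp(grab(c4 - DONOR_INTRONIC, c4 + DONOR_EXONIC))
        acceptor_down = revcomp(grab(c1 - ACCEPTOR_EXONIC, c1 + ACCEPTOR_INTRONIC))
        exon = revcomp(grab(c2, c3))
    else:
        raise ValueError(f"invalid strand {event.strand!r}")
    return SpliceSiteSequences(
        donor=donor,
        acceptor=acceptor,
        ppt_window=window,
        donor_upstream_intron=donor_up,
        acceptor_downstream_intron=acceptor_down,
        exon=exon,
        truncated=truncated,
    )


def score_splice_site(kmer: str, model: PositionWeightModel) -> float:
    """Log2-odds splice-site score of a k-mer under a position-weight model."""
    return model.score(kmer)


def count_motifs(exon_seq: str, motif_table: MotifTable) -> tuple[int, int]:
    """Counts of ESE and ESS occurrences in an exon (overlaps counted)."""
    if not exon_seq:
        raise ValueError("exon sequence must be non-empty")
    seq = exon_seq.upper()

    def occurrences(motif: str) -> int:
        n, start = 0, 0
        while True:
            idx = seq.find(motif, start)
            if idx < 0:
                return n
            n += 1
            start = idx + 1

    n_ese = sum(occurrences(m) for m in motif_table.ese_motifs)
    n_ess = sum(occurrences(m) for m in motif_table.ess_motifs)
    return n_ese, n_ess


def predict_branch_point(
    intron_window: str,
    model: Optional[PositionWeightModel] = None,
) -> Optional[tuple[int, float]]:
    """Best branch-point candidate in the upstream-intron window.

    Scans every heptamer whose position 6 is an adenosine against the branch
    consensus model and returns ``(bp_position, score)`` where
    ``bp_position`` is the 0-based index of the branch adenosine within the
    window.  Ties go to the candidate closest to the 3' end.  Returns
    ``None`` for windows shorter than 7 nt or without a candidate adenosine.
    """
    if model is None:
        model = default_branch_model()
    window = intron_window.upper()
    if len(window) < 7:
        return None
    best: Optional[tuple[float, int]] = None
    for i in range(len(window) - 6):
        if window[i + 5] != "A":
            continue
        heptamer = window[i:i + 7]
        if any(b not in "ACGT" for b in heptamer):
            continue
        score = model.score(heptamer)
        if best is None or (score, i) >= best:
            best = (score, i)
    if best is None:
        return None
    score, i = best
    return i + 5, score


def ppt_score(intron_window: str, bp_position: int) -> int:
    """Polypyrimidine-tract score downstream of the branch point.

    The scored region is strictly between the branch adenosine and the final
    3 nt of the intron (which contain the AG);
    score = pyrimidine count + longest uninterrupted pyrimidine run.
    """
    if not (0 <= bp_position < len(intron_window)):
        raise ValueError("branch position outside the window")
    region = intron_window.upper()[bp_position + 1:len(intron_window) - 3]
    if not region:
        return 0
    n_py = sum(1 for b in region if b in PYRIMIDINES)
    longest = run = 0
    for b in region:
        run = run + 1 if b in PYRIMIDINES else 0
        longest = max(longest, run)
    return n_py + longest


@dataclass
class FeatureVector:
    event_id: str
    exon_length: int
    n_ese: int
    n_ess: int
    score_5ss: float
    score_3ss: float
    branch_score: Optional[float]
    ppt_score: Optional[int]
    bp_position: Optional[int]
    upstream_intron_length: int
    downstream_intron_length: int
    score_5ss_upstream_intron: float
    score_3ss_downstream_intron: float
    window_truncated: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def feature_vector(
    event: SkippingEvent,
    genome,
    motif_table: MotifTable,
    donor_model: Optional[PositionWeightModel] = None,
    acceptor_model: Optional[PositionWeightModel] = None,
    branch_model: Optional[PositionWeightModel] = None,
) -> FeatureVector:
    """Assemble the full feature vector for one event."""
    donor_model = donor_model or default_donor_model()
    acceptor_model = acceptor_model or default_acceptor_model()
    branch_model = branch_model or default_branch_model()
    seqs = splice_site_sequences(event, genome)
    n_ese, n_ess = count_motifs(seqs.exon, motif_table)
    bp = predict_branch_point(seqs.ppt_window, branch_model)
    if bp is None:
        bp_position, branch_score, ppt = None, None, None
    else:
        bp_position, branch_score = bp
        ppt = ppt_score(seqs.ppt_window, bp_position)
    if event.strand == "+":
        up_len = event.coord2 - event.coord1
        down_len = event.coord4 - event.coord3
    else:
        up_len = event.coord4 - event.coord3
        down_len = event.coord2 - event.coord1
    return FeatureVector(
        event_id=event.event_id,
        exon_length=event.cassette_length,
        n_ese=n_ese,
        n_ess=n_ess,
        score_5ss=score_splice_site(seqs.donor, donor_model),
        score_3ss=score_splice_site(seqs.acceptor, acceptor_model),
        branch_score=branch_score,
        ppt_score=ppt,
        bp_position=bp_position,
        upstream_intron_length=up_len,
        downstream_intron_length=down_len,
        score_5ss_upstream_intron=score_splice_site(
            seqs.donor_upstream_intron, donor_model
        ),
        score_3ss_downstream_intron=score_splice_site(
            seqs.acceptor_downstream_intron, acceptor_model
        ),
        window_truncated=seqs.truncated,
    )
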