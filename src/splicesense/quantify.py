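"""Junction-read quantification: ψ, Δψ, expression filters, response classes.

The inclusion level of a cassette exon is estimated from the reads on its
three splice junctions (upstream-inclusion, downstream-inclusion, skip):

    ψ = (j_up + j_down) / (j_up + j_down + 2 * j_skip)

The inclusion isoform contributes two junctions and the skipping isoform one,
hence the factor 2 on the skip count.  ψ is undefined (``None``) when all
three counts are zero; the undefined value propagates as missing — "no
expression" is distinct from "fully skipped".

Δψ is the treated-minus-control difference per replicate.  Response classes
follow fixed per-replicate thresholds (see :func:`classify_response`); a
stricter call (:func:`strict_skip_call`) additionally requires a mean shift
of at least −0.25 and a two-sample t-test at p < 0.05.

Expression is measured in RPK30M: reads per kilobase of feature per 30
million mapped reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import SkippingEvent

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionCounts",
    "PsiRecord",
    "extract_junctions",
    "rpk30m",
    "compute_psi",
    "passes_expression_filter",
    "classify_response",
    "strict_skip_call",
    "delta_psi_distribution",
    "event_psi_record",
]

RESPONSE_CLASSES = (
    "skip",
    "inclusion",
    "no_change",
    "others:no_expression",
    "others:inconsistent",
    "others:psi_too_low",
)

JunctionKey = tuple[str, int, int, str]  # chrom, intron_start, intron_end, strand


@dataclass
class JunctionCounts:
    """Per-sample junction read counts plus per-sample library sizes."""

    counts: dict[str, dict[JunctionKey, int]] = field(default_factory=dict)
    library_sizes: dict[str, int] = field(default_factory=dict)

    def get(self, sample: str, key: JunctionKey) -> int:
        n = self.counts.get(sample, {}).get(key, 0)
        if n < 0:
            raise ValueError(f"negative junction count for {key} in {sample}")
        return n

    @classmethod
    def from_table(
        cls, table: pd.DataFrame, library_sizes: Optional[dict[str, int]] = None
    ) -> "JunctionCounts":
        """Build from a long-format junction table.

        When no library sizes are given, the per-sample total junction count
        is used.
        """
        jc = cls()
        for row in table.itertuples(index=False):
            if row.intron_start >= row.intron_end:
                raise ValueError(
                    f"intron_start >= intron_end at {row.chrom}:"
                    f"{row.intron_start}-{row.intron_end}"
                )
            key = (row.chrom, int(row.intron_start), int(row.intron_end), row.strand)
            jc.counts.setdefault(row.sample, {})[key] = int(row.count)
        if library_sizes is None:
            library_sizes = {
                s: int(sum(d.values())) for s, d in jc.counts.items()
            }
        jc.library_sizes = dict(library_sizes)
        return jc


@dataclass
class PsiRecord:
    event_id: str
    psi: dict[str, Optional[float]]             # per sample
    delta_psi: tuple[Optional[float], ...]      # per replicate, treated - control
    delta_psi_avg: Optional[float]
    response_class: str
    strict_skip: bool


def extract_junctions(alignments, min_anchor: int = 8) -> JunctionCounts:
    """Count junction reads from SAM/BAM alignments with an anchor filter.

    ``alignments`` is a path to a SAM/BAM file or an open
    :class:`pysam.AlignmentFile`.  Each N operation of a spliced read
    contributes one count to its junction iff the aligned reference block on
    each side of that N is at least ``min_anchor`` nt — reads that do not
    extend ``min_anchor`` nt into both flanking exons are discarded for that
    junction.  The library size is the number of retained mapped reads.
    """
    import pysam

    close = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True
    jc = JunctionCounts()
    sample = "sample"
    counts: dict[JunctionKey, int] = {}
    n_reads = 0
    try:
        for read in alignments.fetch(until_eof=True):
            try:
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                cigar = read.cigartuples
                if cigar is None:
                    continue
                n_reads += 1
                # Segment the alignment into ref-consuming blocks split on N.
                blocks: list[int] = [0]
                introns: list[tuple[int, int]] = []
                pos = read.reference_start
                for op, length in cigar:
                    if op == 3:  # N: splice junction
                        introns.append((pos, pos + length))
                        pos += length
                        blocks.append(0)
                    elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
                        blocks[-1] += length
                        pos += length
                    # I, S, H, P do not consume reference
                for i, intron in enumerate(introns):
                    if blocks[i] >= min_anchor and blocks[i + 1] >= min_anchor:
                        key = (read.reference_name, intron[0], intron[1],
                               "-" if read.is_reverse else "+")
                        counts[key] = counts.get(key, 0) + 1
            except (ValueError, TypeError) as exc:
                logger.warning("skipping malformed alignment record: %s", exc)
    finally:
        if close:
            alignments.close()
    jc.counts[sample] = counts
    jc.library_sizes[sample] = n_reads
    return jc


def rpk30m(count: float, feature_length: int, library_size: int) -> float:
    """Reads per kilobase of feature per 30 million mapped reads."""
    if feature_length <= 0:
        raise ValueError("feature_length must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / ((feature_length / 1000.0) * (library_size / 3.0e7))


def compute_psi(j_up: int, j_down: int, j_skip: int) -> Optional[float]:
    """Percent-spliced-in from the three junction counts of a cassette event.

    Returns ``None`` when all three counts are zero (no evidence either way).
    """
    if min(j_up, j_down, j_skip) < 0:
        raise ValueError("junction counts must be non-negative")
    total = j_up + j_down + 2 * j_skip
    if total == 0:
        return None
    return (j_up + j_down) / total


def passes_expression_filter(
    gene_rpk30m: dict[str, float],
    junction_rpk30m: dict[str, float],
    gene_cutoff: float = 16.0,
    junction_cutoff: float = 4.0,
) -> bool:
    """Expression filter for one event.

    Fails iff the gene is below ``gene_cutoff`` RPK30M in *all* samples, or
    the total of the event's three junctions is below ``junction_cutoff``
    RPK30M in *any* single sample (strictest reading of "any of the
    replicates in at least one of the conditions").
    """
    if not gene_rpk30m or not junction_rpk30m:
        raise ValueError("expression values required for all samples")
    if set(gene_rpk30m) != set(junction_rpk30m):
        raise ValueError("gene and junction expression cover different samples")
    if all(v < gene_cutoff for v in gene_rpk30m.values()):
        return False
    if any(v < junction_cutoff for v in junction_rpk30m.values()):
        return False
    return True


def classify_response(
    delta_psi: Sequence[Optional[float]],
    psi: Sequence[Optional[float]],
    threshold: float = 0.05,
    psi_floor: float = 0.05,
) -> str:
    """Classify a cassette event's response from two replicate Δψ values.

    Rules, evaluated in order:

    - ``others:no_expression`` — any required ψ (hence Δψ) is undefined;
    - ``others:psi_too_low`` — every ψ is below ``psi_floor``;
    - ``others:inconsistent`` — one replicate reaches a threshold while the
      other moves the opposite way ((Δψ ≥ 0.05 and Δψ ≤ 0) or
      (Δψ ≤ −0.05 and Δψ ≥ 0));
    - ``skip`` — Δψ ≤ −0.05 in either replicate and Δψ < 0 in the other;
    - ``inclusion`` — Δψ ≥ 0.05 in either replicate and Δψ > 0 in the other;
    - ``no_change`` — both replicates within (−0.05, 0.05).
    """
    if len(delta_psi) != 2:
        raise ValueError("exactly two replicate delta-psi values required")
    if any(d is None for d in delta_psi) or any(p is None for p in psi):
        return "others:no_expression"
    if psi and all(p < psi_floor for p in psi):
        return "others:psi_too_low"
    d1, d2 = delta_psi
    for a, b in ((d1, d2), (d2, d1)):
        if (a >= threshold and b <= 0) or (a <= -threshold and b >= 0):
            return "others:inconsistent"
    for a, b in ((d1, d2), (d2, d1)):
        if a <= -threshold and b < 0:
            return "skip"
    for a, b in ((d1, d2), (d2, d1)):
        if a >= threshold and b > 0:
            return "inclusion"
    return "no_change"


def strict_skip_call(
    psi_ctrl: Sequence[float],
    psi_treat: Sequence[float],
    dpsi_threshold: float = -0.25,
    alpha: float = 0.05,
) -> bool:
    """Strong skip-enhancement call: mean Δψ ≤ threshold and t-test p < alpha.

    The t-test is two-sample, pooled-variance (Student), two-sided, on the
    replicate ψ values.  With zero variance in both groups the p-value is
    taken as 0 when the means differ (a perfectly reproduced shift) and 1
    otherwise.
    """
    if len(psi_ctrl) < 2 or len(psi_treat) < 2:
        raise ValueError("at least two replicates per condition required")
    ctrl = np.asarray(psi_ctrl, dtype=float)
    treat = np.asarray(psi_treat, dtype=float)
    dpsi = treat.mean() - ctrl.mean()
    if dpsi > dpsi_threshold:
        return False
    if ctrl.var(ddof=1) == 0.0 and treat.var(ddof=1) == 0.0:
        p = 0.0 if dpsi != 0.0 else 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = sps.ttest_ind(treat, ctrl, equal_var=True)
    return bool(p < alpha)


def delta_psi_distribution(
    records: Sequence[dict],
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-event Δψ_avg and the between-replicate baseline fluctuation.

    Each record must provide ``psi_ctrl`` and ``psi_treat`` as two-replicate
    sequences.  Δψ_avg is the replicate mean of (ψ_treat − ψ_ctrl); the
    baseline statistic is the mean of the within-condition replicate-1 minus
    replicate-2 differences, ((ψ_ctrl.1 − ψ_ctrl.2) + (ψ_treat.1 − ψ_treat.2)) / 2.
    The returned frame also flags skip-enhanced (Δψ_avg ≤ −threshold) and
    inclusion-enhanced (Δψ_avg ≥ threshold) events; the per-class counts are
    stored in ``df.attrs``.
    """
    rows = []
    for rec in records:
        c1, c2 = rec["psi_ctrl"]
        t1, t2 = rec["psi_treat"]
        if None in (c1, c2, t1, t2):
            continue
        davg = ((t1 - c1) + (t2 - c2)) / 2.0
        baseline = ((c1 - c2) + (t1 - t2)) / 2.0
        rows.append(
            {
                "event_id": rec.get("event_id"),
                "delta_psi_avg": davg,
                "baseline": baseline,
                "skip_enhanced": davg <= -threshold,
                "inclusion_enhanced": davg >= threshold,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["event_id", "delta_psi_avg", "baseline",
                 "skip_enhanced", "inclusion_enhanced"],
    )
    df.attrs["n_skip_enhanced"] = int(df["skip_enhanced"].sum()) if len(df) else 0
    df.attrs["n_inclusion_enhanced"] = (
        int(df["inclusion_enhanced"].sum()) if len(df) else 0
    )
    return df


def event_junction_counts(
    event: SkippingEvent, jc: JunctionCounts, sample: str
) -> tuple[int, int, int]:
    """(upstream-inclusion, downstream-inclusion, skip) counts for one sample."""
    up = jc.get(sample, (event.chrom, event.coord1, event.coord2, event.strand))
    down = jc.get(sample, (event.chrom, event.coord3, event.coord4, event.strand))
    skip = jc.get(sample, (event.chrom, event.coord1, event.coord4, event.strand))
    return up, down, skip


def event_psi_record(
    event: SkippingEvent,
    jc: JunctionCounts,
    design: pd.DataFrame,
    threshold: float = 0.05,
    strict_threshold: float = -0.25,
    alpha: float = 0.05,
) -> PsiRecord:
    """ψ per sample, Δψ per replicate and response class for one event.

    The design table pairs control and treated samples by replicate number.
    """
    psi: dict[str, Optional[float]] = {}
    for sample in design["sample"]:
        up, down, skip = event_junction_counts(event, jc, sample)
        psi[sample] = compute_psi(up, down, skip)

    ctrl = design[design["condition"] == "control"].sort_values("replicate")
    treat = design[design["condition"] == "treated"].sort_values("replicate")
    if len(ctrl) != len(treat):
        raise ValueError("unbalanced design: control/treated replicate mismatch")
    psi_ctrl = [psi[s] for s in ctrl["sample"]]
    psi_treat = [psi[s] for s in treat["sample"]]
    deltas = tuple(
        (t - c) if (t is not None and c is not None) else None
        for c, t in zip(psi_ctrl, psi_treat)
    )
    defined = [d for d in deltas if d is not None]
    davg = float(np.mean(defined)) if len(defined) == len(deltas) and defined else None
    cls = classify_response(deltas[:2], list(psi.values()), threshold=threshold)
    strict = False
    if all(p is not None for p in psi_ctrl + psi_treat):
        strict = strict_skip_call(
            psi_ctrl, psi_treat, dpsi_threshold=strict_threshold, alpha=alpha
        )
    return PsiRecord(
        event_id=event.event_id,
        psi=psi,
        delta_psi=deltas,
        delta_psi_avg=davg,
        response_class=cls,
        strict_skip=strict,
    )
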