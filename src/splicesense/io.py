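"""Plain-text inter-stage formats.

Every stage of the pipeline communicates through small TSV files so that any
stage can be replaced by an external tool (e.g. feature tables produced by
other scorers can be injected).  Junction coordinates are 0-based half-open
intron intervals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from .annotation import SkippingEvent

EVENT_COLUMNS = [
    "event_id", "gene_id", "chrom", "strand",
    "coord1", "coord2", "coord3", "coord4",
]
JUNCTION_COLUMNS = ["chrom", "intron_start", "intron_end", "strand", "sample", "count"]
DESIGN_COLUMNS = ["sample", "condition", "replicate", "library_size"]
MOTIF_COLUMNS = ["factor", "motif", "score"]
HOMOLOGY_COLUMNS = ["gene_id_a", "gene_id_b"]


def write_events_tsv(events: list[SkippingEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.event_id, e.gene_id, e.chrom, e.strand,
             e.coord1, e.coord2, e.coord3, e.coord4)
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[SkippingEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SkippingEvent(
            event_id=row.event_id, gene_id=row.gene_id, chrom=row.chrom,
            strand=row.strand, coord1=int(row.coord1), coord2=int(row.coord2),
            coord3=int(row.coord3), coord4=int(row.coord4),
        )
        for row in df.itertuples(index=False)
    ]


def read_junction_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"junction table {path} lacks columns {sorted(missing)}")
    return df


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    """Design table: sample, condition (control/treated), replicate, library_size."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    missing = {"sample", "condition", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"design table {path} lacks columns {sorted(missing)}")
    return df


def read_motif_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"factor": str, "motif": str})
    missing = set(MOTIF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"motif table {path} lacks columns {sorted(missing)}")
    return df


def read_homology_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(HOMOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"homology table {path} lacks columns {sorted(missing)}")
    return df


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def open_genome(path: str | Path) -> Fasta:
    """Open an indexed FASTA genome (index built on first access)."""
    return Fasta(str(path), sequence_always_upper=True)
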