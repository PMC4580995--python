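"""Stratified enrichment of skip-enhanced exons over 48 feature bins.

Events are partitioned by exon length (2 bins), ESE count (3), ESS count (2)
and polypyrimidine-tract score (4) into 2 x 3 x 2 x 4 = 48 groups.  Within
each group the enrichment of strongly skip-enhanced exons is the group hit
fraction divided by the dataset-wide baseline (total hits / total events),
with an upper-tail hypergeometric p-value; groups with fewer than 3 hits are
marked non-reportable.  The stratification is rendered as a nested
"decision-tree" report (length -> ESS -> ESE -> PPT).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureVector

__all__ = ["BinScheme", "EnrichmentRow", "assign_bin", "enrichment_analysis",
           "enrichment_ratio", "decision_tree_report"]


def enrichment_ratio(hits: int, size: int, total_hits: int, total: int) -> float:
    """Group hit fraction over the dataset baseline fraction."""
    if min(size, total_hits, total) <= 0:
        raise ValueError("size, total_hits and total must be positive")
    return (hits / size) / (total_hits / total)


def _edges_to_bins(edges: Sequence[int]) -> list[tuple[int, Optional[int]]]:
    """[65] -> [(0, 64), (65, None)]; [5, 16] -> [(0,4),(5,15),(16,None)]."""
    bins = []
    low = 0
    for edge in edges:
        bins.append((low, edge - 1))
        low = edge
    bins.append((low, None))
    return bins


def _bin_label(prefix: str, lo: int, hi: Optional[int]) -> str:
    return f"{prefix}{lo}-{hi}" if hi is not None else f"{prefix}{lo}+"


@dataclass(frozen=True)
class BinScheme:
    """Cut points of the four feature axes (each edge starts a new bin).

    The defaults give the 48-group scheme: exon length 0-64 / >=65 nt,
    ESE 0-4 / 5-15 / >=16, ESS 0-19 / >=20, PPT 0-9 / 10-19 / 20-29 / >=30.
    """

    length_edges: tuple[int, ...] = (65,)
    ese_edges: tuple[int, ...] = (5, 16)
    ess_edges: tuple[int, ...] = (20,)
    ppt_edges: tuple[int, ...] = (10, 20, 30)

    def axis_bins(self) -> dict[str, list[tuple[int, Optional[int]]]]:
        return {
            "length": _edges_to_bins(self.length_edges),
            "ese": _edges_to_bins(self.ese_edges),
            "ess": _edges_to_bins(self.ess_edges),
            "ppt": _edges_to_bins(self.ppt_edges),
        }

    def bins(self) -> list[tuple[str, str, str, str]]:
        """All bin ids, in axis order length x ESE x ESS x PPT."""
        ax = self.axis_bins()
        out = []
        for lb in ax["length"]:
            for eb in ax["ese"]:
                for sb in ax["ess"]:
                    for pb in ax["ppt"]:
                        out.append(
                            (
                                _bin_label("len", *lb),
                                _bin_label("ese", *eb),
                                _bin_label("ess", *sb),
                                _bin_label("ppt", *pb),
                            )
                        )
        return out

    def _axis_assign(self, axis: str, value: float) -> str:
        for lo, hi in self.axis_bins()[axis]:
            if value >= lo and (hi is None or value <= hi):
                return _bin_label({"length": "len", "ese": "ese",
                                   "ess": "ess", "ppt": "ppt"}[axis], lo, hi)
        raise ValueError(f"value {value} outside {axis} bins")


def assign_bin(
    fv: FeatureVector | dict, scheme: Optional[BinScheme] = None
) -> Optional[tuple[str, str, str, str]]:
    """Bin id of a feature vector, or ``None`` when the PPT score is missing
    (no predictable branch point) — such events are excluded, not binned."""
    scheme = scheme or BinScheme()
    if isinstance(fv, FeatureVector):
        fv = fv.as_dict()
    ppt = fv.get("ppt_score")
    if ppt is None or (isinstance(ppt, float) and np.isnan(ppt)):
        return None
    return (
        scheme._axis_assign("length", fv["exon_length"]),
        scheme._axis_assign("ese", fv["n_ese"]),
        scheme._axis_assign("ess", fv["n_ess"]),
        scheme._axis_assign("ppt", ppt),
    )


@dataclass
class EnrichmentRow:
    bin_id: tuple[str, str, str, str]
    size: int
    hits: int
    enrichment: float  # NaN when undefined
    p_value: float
    reportable: bool

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bin_id"] = "|".join(self.bin_id)
        return d


def enrichment_analysis(
    event_bins: dict[str, tuple[str, str, str, str]],
    skip_set: set[str],
    scheme: Optional[BinScheme] = None,
    min_hits: int = 3,
) -> list[EnrichmentRow]:
    """Per-bin enrichment of the skip-enhanced set with hypergeometric tests.

    ``event_bins`` maps event id to its bin (excluded events absent);
    ``skip_set`` must be a subset of the binned events' universe.  Enrichment
    is (hits/size) / (total hits / total events); the p-value is the
    upper-tail hypergeometric probability of drawing at least ``hits``
    successes in ``size`` draws from a universe with ``total hits``
    successes.  Rows with fewer than ``min_hits`` hits are non-reportable.
    """
    scheme = scheme or BinScheme()
    unknown = skip_set - set(event_bins)
    total = len(event_bins)
    total_hits = len(skip_set & set(event_bins))
    if unknown:
        # hits without a bin (e.g. missing PPT) fall out of the universe
        skip_set = skip_set & set(event_bins)
    baseline = total_hits / total if total else np.nan
    per_bin: dict[tuple, list[str]] = {b: [] for b in scheme.bins()}
    for event_id, bin_id in event_bins.items():
        per_bin.setdefault(bin_id, []).append(event_id)
    rows: list[EnrichmentRow] = []
    for bin_id in scheme.bins():
        members = per_bin.get(bin_id, [])
        size = len(members)
        hits = sum(1 for m in members if m in skip_set)
        if total_hits == 0 or size == 0 or baseline == 0:
            enr = float("nan")
        else:
            enr = (hits / size) / baseline
        if size == 0 or total_hits == 0:
            p = float("nan")
        else:
            p = float(sps.hypergeom.sf(hits - 1, total, total_hits, size))
        rows.append(
            EnrichmentRow(
                bin_id=bin_id,
                size=size,
                hits=hits,
                enrichment=enr,
                p_value=p,
                reportable=hits >= min_hits,
            )
        )
    return rows


def decision_tree_report(
    rows: Sequence[EnrichmentRow],
    scheme: Optional[BinScheme] = None,
) -> dict:
    """Nested (length -> ESS -> ESE -> PPT) view of the enrichment rows.

    ``region_a`` lists, in order of ascending PPT bin, the rows of the
    short-exon, lowest-ESE, lowest-ESS stratum where the weak-tract trend is
    expected; ``region_b`` surfaces the strong-tract bins of the short,
    high-ESS strata without modelling them.
    """
    scheme = scheme or BinScheme()
    if not rows:
        return {"tree": {}, "region_a": [], "region_b": []}
    ax = scheme.axis_bins()
    short_label = _bin_label("len", *ax["length"][0])
    low_ese = _bin_label("ese", *ax["ese"][0])
    low_ess = _bin_label("ess", *ax["ess"][0])
    high_ess = _bin_label("ess", *ax["ess"][-1])
    strong_ppt = _bin_label("ppt", *ax["ppt"][-1])

    tree: dict = {}
    for row in rows:
        len_b, ese_b, ess_b, ppt_b = row.bin_id
        node = (
            tree.setdefault(len_b, {})
            .setdefault(ess_b, {})
            .setdefault(ese_b, {})
        )
        node[ppt_b] = {
            "size": row.size,
            "hits": row.hits,
            "enrichment": None if np.isnan(row.enrichment) else round(row.enrichment, 4),
            "p_value": None if np.isnan(row.p_value) else row.p_value,
            "reportable": row.reportable,
        }
    region_a = [
        row.as_dict()
        for row in rows
        if row.bin_id[0] == short_label
        and row.bin_id[1] == low_ese
        and row.bin_id[2] == low_ess
    ]
    region_b = [
        row.as_dict()
        for row in rows
        if row.bin_id[0] == short_label
        and row.bin_id[2] == high_ess
        and row.bin_id[3] == strong_ppt
    ]
    return {"tree": tree, "region_a": region_a, "region_b": region_b}


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
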