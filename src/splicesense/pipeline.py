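"""End-to-end orchestration of the comparative splicing analysis.

Stages (each reading/writing plain TSV so any one can be replaced by an
external tool): event extraction from annotation, ψ/Δψ quantification with
expression filtering and response classification, cross-species homologous
exon pairing, sequence-feature extraction, the four-way statistical
comparison plus nine-category conservation table, and the stratified
enrichment analysis.  A cascade-count table records how many events survive
each filter, and a manifest captures thresholds and the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation as ann
from . import enrichment as enr
from . import homology as hom
from . import quantify as q
from . import stats as st
from .features import MotifTable, feature_vector
from .io import (
    open_genome,
    read_design_tsv,
    read_events_tsv,
    read_homology_tsv,
    read_junction_tsv,
    read_motif_tsv,
    write_events_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full", "run_stage", "STAGES"]

STAGES = ("events", "quantify", "pair", "features", "stats", "enrich")


@dataclass
class PipelineConfig:
    """Paths and thresholds of one two-species run.

    Threshold defaults are the analysis' canonical values: 8-nt junction
    anchors, 16/4 RPK30M gene/junction expression cutoffs, ±0.05 Δψ class
    cutoff, −0.25 strict skip cutoff with t-test alpha 0.05, and the
    >70 % identity / >0.9 coverage homology rule.  Overrides are logged.
    """

    annotation: dict[str, str]
    genome: dict[str, str]
    junctions: dict[str, str]
    design: dict[str, str]
    homology: str
    motifs: str
    outdir: str
    anchor_nt: int = 8
    gene_rpk30m_cutoff: float = 16.0
    junction_rpk30m_cutoff: float = 4.0
    junction_feature_length: int = 100
    dpsi_class_cutoff: float = 0.05
    strict_dpsi_cutoff: float = -0.25
    alpha: float = 0.05
    min_identity: float = 70.0
    min_coverage: float = 0.9
    bin_scheme: enr.BinScheme = field(default_factory=enr.BinScheme)
    seed: int = 0

    def __post_init__(self) -> None:
        defaults = PipelineConfig.__dataclass_fields__
        for name in ("anchor_nt", "gene_rpk30m_cutoff", "junction_rpk30m_cutoff",
                     "dpsi_class_cutoff", "strict_dpsi_cutoff", "alpha",
                     "min_identity", "min_coverage"):
            if getattr(self, name) != defaults[name].default:
                logger.info("threshold override: %s = %r", name, getattr(self, name))

    @classmethod
    def from_bundle(cls, bundle, outdir: str | Path, **overrides) -> "PipelineConfig":
        """Config pointing at a :class:`~splicesense.simulate.DatasetBundle`."""
        return cls(
            annotation={sp: str(bundle.annotation[sp]) for sp in ("A", "B")},
            genome={sp: str(bundle.genome[sp]) for sp in ("A", "B")},
            junctions={sp: str(bundle.junctions[sp]) for sp in ("A", "B")},
            design={sp: str(bundle.design[sp]) for sp in ("A", "B")},
            homology=str(bundle.homology),
            motifs=str(bundle.motifs),
            outdir=str(outdir),
            **overrides,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "bin_scheme" in data:
            data["bin_scheme"] = enr.BinScheme(
                **{k: tuple(v) for k, v in data["bin_scheme"].items()}
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["bin_scheme"] = {
            k: list(v) for k, v in asdict(self.bin_scheme).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def _require(self, *paths: str | Path) -> None:
        missing = [str(p) for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _stage_events(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in ("A", "B"):
        cfg._require(cfg.annotation[sp])
        models = ann.parse_gtf(cfg.annotation[sp])
        events = ann.extract_skipping_events(models)
        write_events_tsv(events, out / f"events_{sp}.tsv")
        logger.info("species %s: %d annotated skipping events", sp, len(events))


def _load_junctions(cfg: PipelineConfig, sp: str):
    table = read_junction_tsv(cfg.junctions[sp])
    design = read_design_tsv(cfg.design[sp])
    lib = None
    if "library_size" in design.columns:
        lib = dict(zip(design["sample"], design["library_size"].astype(int)))
    return q.JunctionCounts.from_table(table, lib), design


def _gene_expression(models: ann.GeneModels, jc: q.JunctionCounts,
                     cfg: PipelineConfig) -> dict[str, dict[str, float]]:
    """Per-gene RPK30M from total junction reads over the exonic-union length.

    A documented proxy for exon-body counting, which this pipeline does not
    perform: all reads here are junction reads.
    """
    gene_expr: dict[str, dict[str, float]] = {}
    for gene in models:
        # exonic union length
        intervals = sorted(
            {e for tx in gene.transcripts for e in tx.exons}
        )
        union = 0
        cur_s, cur_e = None, None
        for s, e in intervals:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    union += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            union += cur_e - cur_s
        introns = {i for tx in gene.transcripts for i in tx.introns()}
        keys = [(gene.chrom, a, b, gene.strand) for a, b in introns]
        gene_expr[gene.gene_id] = {
            sample: q.rpk30m(
                sum(jc.get(sample, k) for k in keys),
                max(union, 1),
                jc.library_sizes[sample],
            )
            for sample in jc.counts
        }
    return gene_expr


def _stage_quantify(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    for sp in ("A", "B"):
        cfg._require(out / f"events_{sp}.tsv", cfg.junctions[sp], cfg.design[sp])
        events = read_events_tsv(out / f"events_{sp}.tsv")
        jc, design = _load_junctions(cfg, sp)
        models = ann.parse_gtf(cfg.annotation[sp])
        gene_expr = _gene_expression(models, jc, cfg)
        rows = []
        for event in events:
            rec = q.event_psi_record(
                event, jc, design,
                threshold=cfg.dpsi_class_cutoff,
                strict_threshold=cfg.strict_dpsi_cutoff,
                alpha=cfg.alpha,
            )
            junction_expr = {}
            for sample in jc.counts:
                up, down, skip = q.event_junction_counts(event, jc, sample)
                junction_expr[sample] = q.rpk30m(
                    up + down + skip,
                    cfg.junction_feature_length,
                    jc.library_sizes[sample],
                )
            expressed = q.passes_expression_filter(
                gene_expr[event.gene_id], junction_expr,
                cfg.gene_rpk30m_cutoff, cfg.junction_rpk30m_cutoff,
            )
            row = {
                "event_id": event.event_id,
                "gene_id": event.gene_id,
                "expressed": expressed,
                "response_class": rec.response_class,
                "strict_skip": rec.strict_skip,
                "delta_psi_avg": rec.delta_psi_avg,
            }
            for i, d in enumerate(rec.delta_psi, start=1):
                row[f"delta_psi_rep{i}"] = d
            for sample, value in rec.psi.items():
                row[f"psi_{sample}"] = value
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / f"psi_{sp}.tsv", sep="\t", index=False)
        n_expr = sum(r["expressed"] for r in rows)
        logger.info("species %s: %d/%d events pass expression filter",
                    sp, n_expr, len(rows))


def _event_exon_seq(event: ann.SkippingEvent, genome) -> str:
    from .features import revcomp

    seq = str(genome[event.chrom][event.coord2:event.coord3])
    return revcomp(seq) if event.strand == "-" else seq


def _stage_pair(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    cfg._require(out / "events_A.tsv", out / "psi_A.tsv", cfg.homology)
    events_a = read_events_tsv(out / "events_A.tsv")
    psi_a = pd.read_csv(out / "psi_A.tsv", sep="\t")
    expressed = set(psi_a.loc[psi_a["expressed"], "event_id"])
    homology = read_homology_tsv(cfg.homology)
    a_to_b = dict(zip(homology["gene_id_a"], homology["gene_id_b"]))
    genome_a = open_genome(cfg.genome["A"])
    genome_b = open_genome(cfg.genome["B"])
    models_b = ann.parse_gtf(cfg.annotation["B"])
    jc_b, design_b = _load_junctions(cfg, "B")

    rows = []
    for event in events_a:
        if event.event_id not in expressed:
            continue
        gene_b_id = a_to_b.get(event.gene_id)
        if gene_b_id is None or gene_b_id not in models_b.genes:
            logger.debug("gene %s absent from homology table", event.gene_id)
            continue
        gene_b = models_b.genes[gene_b_id]
        candidates = []
        for exon in sorted(ann.internal_exons(gene_b)):
            seq = str(genome_b[gene_b.chrom][exon[0]:exon[1]])
            if gene_b.strand == "-":
                from .features import revcomp
                seq = revcomp(seq)
            candidates.append((gene_b_id, exon, seq))
        pair = hom.select_homolog(
            event.event_id,
            _event_exon_seq(event, genome_a),
            candidates,
            min_identity=cfg.min_identity,
            min_coverage=cfg.min_coverage,
        )
        if pair is None:
            continue
        left, right = hom.resolve_flanking(pair.exon_b, gene_b, jc_b)
        event_b = ann.SkippingEvent(
            event_id=f"{gene_b_id}:{left[1]}-{pair.exon_b[0]}-"
                     f"{pair.exon_b[1]}-{right[0]}",
            gene_id=gene_b_id,
            chrom=gene_b.chrom,
            strand=gene_b.strand,
            coord1=left[1],
            coord2=pair.exon_b[0],
            coord3=pair.exon_b[1],
            coord4=right[0],
        )
        rec_b = q.event_psi_record(
            event_b, jc_b, design_b,
            threshold=cfg.dpsi_class_cutoff,
            strict_threshold=cfg.strict_dpsi_cutoff,
            alpha=cfg.alpha,
        )
        row = {
            "event_id_a": event.event_id,
            "event_id_b": event_b.event_id,
            "gene_id_b": gene_b_id,
            "percent_identity": pair.percent_identity,
            "coverage_a": pair.coverage_a,
            "coverage_b": pair.coverage_b,
            "response_class_b": rec_b.response_class,
            "delta_psi_avg_b": rec_b.delta_psi_avg,
        }
        for i, d in enumerate(rec_b.delta_psi, start=1):
            row[f"delta_psi_b_rep{i}"] = d
        rows.append(row)
    pd.DataFrame(
        rows,
        columns=["event_id_a", "event_id_b", "gene_id_b", "percent_identity",
                 "coverage_a", "coverage_b", "response_class_b",
                 "delta_psi_avg_b", "delta_psi_b_rep1", "delta_psi_b_rep2"],
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)
    logger.info("%d homologous pairs", len(rows))


def _stage_features(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    cfg._require(out / "events_A.tsv", out / "pairs.tsv", cfg.motifs)
    motifs = MotifTable.from_frame(read_motif_tsv(cfg.motifs))
    pairs = pd.read_csv(out / "pairs.tsv", sep="\t")
    for sp, event_file in (("A", "events_A.tsv"), ("B", None)):
        genome = open_genome(cfg.genome[sp])
        if sp == "A":
            events = read_events_tsv(out / event_file)
        else:
            # B-side pseudo-events reconstructed from the pair table
            models_b = ann.parse_gtf(cfg.annotation["B"])
            events = []
            for r in pairs.itertuples(index=False):
                gene_b = models_b.genes[r.gene_id_b]
                c1, c2, c3, c4 = (
                    int(x) for x in r.event_id_b.split(":")[1].split("-")
                )
                events.append(
                    ann.SkippingEvent(
                        event_id=r.event_id_b, gene_id=r.gene_id_b,
                        chrom=gene_b.chrom, strand=gene_b.strand,
                        coord1=c1, coord2=c2, coord3=c3, coord4=c4,
                    )
                )
        rows = []
        seen = set()
        for event in events:
            if event.event_id in seen:
                continue
            seen.add(event.event_id)
            fv = feature_vector(event, genome, motifs)
            rows.append(fv.as_dict())
        pd.DataFrame(rows).to_csv(out / f"features_{sp}.tsv", sep="\t",
                                  index=False)


def _stage_stats(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    cfg._require(out / "psi_A.tsv", out / "pairs.tsv",
                 out / "features_A.tsv", out / "features_B.tsv")
    psi_a = pd.read_csv(out / "psi_A.tsv", sep="\t")
    pairs = pd.read_csv(out / "pairs.tsv", sep="\t")
    feats = {
        sp: pd.read_csv(out / f"features_{sp}.tsv", sep="\t").set_index("event_id")
        for sp in ("A", "B")
    }
    by_id = psi_a.set_index("event_id")

    # nine-category conservation table over pairs with a clean class on
    # both sides
    class_map = {"skip": "skip", "inclusion": "inclusion",
                 "no_change": "no_effect"}
    pair_classes = []
    for r in pairs.itertuples(index=False):
        ca = class_map.get(by_id.loc[r.event_id_a, "response_class"])
        cb = class_map.get(r.response_class_b)
        if ca and cb:
            pair_classes.append((ca, cb))
    nine: Optional[st.NineCategoryTable] = None
    if pair_classes:
        nine = st.nine_category_analysis(pair_classes)
        with open(out / "nine_category.json", "w") as fh:
            json.dump(
                {
                    "classes": list(st.CATEGORY_CLASSES),
                    "observed": nine.observed.tolist(),
                    "expected": nine.expected.tolist(),
                    "chi2": nine.chi2,
                    "p_value": nine.p_value,
                    "n": nine.n,
                    "reliable": nine.reliable,
                },
                fh, indent=2,
            )

    # four-way comparison: strict A-side skips with insensitive B homologs
    # vs the delta-psi = 0 control pairs
    strict = set(psi_a.loc[psi_a["strict_skip"] & psi_a["expressed"],
                           "event_id"])
    diff_pairs = pairs[
        pairs["event_id_a"].isin(strict)
        & (pairs["response_class_b"] == "no_change")
    ]
    delta_a = {
        r.event_id: (r.delta_psi_rep1, r.delta_psi_rep2)
        for r in psi_a.itertuples(index=False)
    }
    delta_b = {
        r.event_id_b: (r.delta_psi_b_rep1, r.delta_psi_b_rep2)
        for r in pairs.itertuples(index=False)
    }
    control = st.build_control_set(
        list(zip(pairs["event_id_a"], pairs["event_id_b"])), delta_a, delta_b
    )
    groups = {
        "H_skip": feats["A"].loc[
            [e for e in diff_pairs["event_id_a"] if e in feats["A"].index]
        ],
        "M_paired": feats["B"].loc[
            [e for e in diff_pairs["event_id_b"] if e in feats["B"].index]
        ],
        "H_ctrl": feats["A"].loc[
            [a for a, _ in control if a in feats["A"].index]
        ],
        "M_ctrl": feats["B"].loc[
            [b for _, b in control if b in feats["B"].index]
        ],
    }
    comparison = None
    if all(len(v) for v in groups.values()):
        comparison = st.four_way_comparison(groups)
        comparison.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    else:
        logger.warning("four-way comparison skipped: empty group(s) %s",
                       [k for k, v in groups.items() if not len(v)])
    diff_pairs.to_csv(out / "pairs_differential.tsv", sep="\t", index=False)
    pd.DataFrame(control, columns=["event_id_a", "event_id_b"]).to_csv(
        out / "pairs_control.tsv", sep="\t", index=False
    )


def _stage_enrich(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    cfg._require(out / "psi_A.tsv", out / "features_A.tsv")
    psi_a = pd.read_csv(out / "psi_A.tsv", sep="\t")
    feats_a = pd.read_csv(out / "features_A.tsv", sep="\t")
    expressed = set(psi_a.loc[psi_a["expressed"], "event_id"])
    event_bins = {}
    for r in feats_a.itertuples(index=False):
        if r.event_id not in expressed:
            continue
        b = enr.assign_bin(r._asdict(), cfg.bin_scheme)
        if b is not None:
            event_bins[r.event_id] = b
    strict = set(psi_a.loc[psi_a["strict_skip"] & psi_a["expressed"],
                           "event_id"])
    rows = enr.enrichment_analysis(event_bins, strict, cfg.bin_scheme)
    pd.DataFrame([r.as_dict() for r in rows]).to_csv(
        out / "enrichment.tsv", sep="\t", index=False
    )
    enr.write_report(
        enr.decision_tree_report(rows, cfg.bin_scheme),
        out / "decision_tree.json",
    )


_STAGE_FUNCS = {
    "events": _stage_events,
    "quantify": _stage_quantify,
    "pair": _stage_pair,
    "features": _stage_features,
    "stats": _stage_stats,
    "enrich": _stage_enrich,
}


def run_stage(stage: str, cfg: PipelineConfig) -> None:
    """Run a single named stage; prerequisite files must already exist."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    _STAGE_FUNCS[stage](cfg)


def run_full(cfg: PipelineConfig) -> dict:
    """Run every stage in order and emit cascade counts plus a manifest.

    Returns a result dictionary with the cascade table (events surviving
    each filter, monotone non-increasing) and the paths of all outputs.
    """
    for sp in ("A", "B"):
        cfg._require(cfg.annotation[sp], cfg.genome[sp],
                     cfg.junctions[sp], cfg.design[sp])
    cfg._require(cfg.homology, cfg.motifs)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in STAGES:
        logger.info("stage: %s", stage)
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    psi_a = pd.read_csv(out / "psi_A.tsv", sep="\t")
    pairs = pd.read_csv(out / "pairs.tsv", sep="\t")
    diff = pd.read_csv(out / "pairs_differential.tsv", sep="\t")
    strict = psi_a["strict_skip"] & psi_a["expressed"]
    cascade = {
        "events_annotated": int(len(psi_a)),
        "events_expressed": int(psi_a["expressed"].sum()),
        "events_strict_skip": int(strict.sum()),
        "events_with_homolog": int(
            pairs["event_id_a"].isin(psi_a.loc[strict, "event_id"]).sum()
        ),
        "pairs_b_insensitive": int(len(diff)),
    }
    pd.Series(cascade).to_csv(out / "cascade.tsv", sep="\t", header=False)
    manifest = {
        "seed": cfg.seed,
        "thresholds": {
            "anchor_nt": cfg.anchor_nt,
            "gene_rpk30m_cutoff": cfg.gene_rpk30m_cutoff,
            "junction_rpk30m_cutoff": cfg.junction_rpk30m_cutoff,
            "dpsi_class_cutoff": cfg.dpsi_class_cutoff,
            "strict_dpsi_cutoff": cfg.strict_dpsi_cutoff,
            "alpha": cfg.alpha,
            "min_identity": cfg.min_identity,
            "min_coverage": cfg.min_coverage,
        },
        "bin_scheme": asdict(cfg.bin_scheme),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"cascade": cascade, "outdir": str(out)}
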