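"""Synthetic two-species cassette-exon dataset generator.

The generator emulates the statistical structure the comparative analysis
assumes: two homologous toy genomes (species A and B) whose genes each carry
one or more cassette exons, annotated with an inclusion and a skipping
transcript, plus junction read counts with replicate noise and a
ground-truth table of compound sensitivity.

Sensitivity is generated *from* sequence features, mirroring the biology the
analysis is meant to recover: sensitive exons (species A only) are short
(<65 nt), carry few enhancer/silencer motifs and a weak polypyrimidine
tract (score in [10, 20)); their species-B homologs — and all insensitive
exons — get strong tracts.  A configurable fraction of genes is
constitutively included (ψ = 1 in every sample, hence Δψ exactly 0), which
populates the Δψ = 0 control set that replicate noise would otherwise leave
empty.

Per sample, junction reads for an event are multinomial over
(upstream-inclusion, downstream-inclusion, skip) junctions with weights
(ψ, ψ, 1 − ψ), matching the ψ estimator's denominator weighting; replicate
noise acts on logit(ψ) and is clipped to (0.001, 0.999).  Every output file
round-trips through the pipeline's readers, and a fixed seed reproduces the
files byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import BinScheme, assign_bin
from .features import (
    MotifTable,
    count_motifs,
    ppt_score,
    predict_branch_point,
    revcomp,
)
from .io import write_fasta

__all__ = ["SimConfig", "TruthRecord", "DatasetBundle", "generate_dataset",
           "mutate_homolog", "DEFAULT_MOTIFS"]

BASES = np.array(list("ACGT"))

# Shipped motif table (SpliceAid-style): positive scores are ESEs, negative
# ESSs.  Every motif contains G while exon filler sequence is G/T-free, so
# realized counts equal planted counts exactly.
DEFAULT_MOTIFS: list[tuple[str, str, float]] = [
    ("SRSF1_like", "GGAAGA", 5.0),
    ("SRSF5_like", "GAAGGA", 3.5),
    ("hnRNPA1_like", "GGGTTT", -4.0),
    ("hnRNPH_like", "GGTTGG", -2.5),
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions of the synthetic dataset.

    ``identity_target`` is the point-substitution sequence similarity
    between homologous exons (default 0.936, the typical human/mouse exonic
    similarity level); ``effect_size_skip`` is the Δψ shift of sensitive
    exons under treatment (negative = skip-enhancing);
    ``replicate_noise_sd`` acts on logit(ψ); ``frac_constitutive`` genes are
    always fully included, providing the Δψ = 0 control pairs.
    """

    n_genes: int = 200
    n_cassette_per_gene: int = 1
    frac_sensitive: float = 0.05
    frac_constitutive: float = 0.4
    identity_target: float = 0.936
    effect_size_skip: float = -0.3
    replicate_noise_sd: float = 0.1
    library_size: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_sensitive", "frac_constitutive", "identity_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_sensitive + self.frac_constitutive > 1.0:
            raise ConfigError("frac_sensitive + frac_constitutive exceeds 1")
        if self.effect_size_skip >= 0:
            raise ConfigError("effect_size_skip must be negative")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.n_genes <= 0 or self.n_cassette_per_gene <= 0:
            raise ConfigError("n_genes and n_cassette_per_gene must be positive")
        if self.replicate_noise_sd < 0:
            raise ConfigError("replicate_noise_sd must be non-negative")


@dataclass
class TruthRecord:
    event_id: str
    species: str
    gene_id: str
    sensitive: bool
    constitutive: bool
    true_psi_ctrl: float
    true_psi_treat: float
    exon_length: int
    n_ese: int
    n_ess: int
    ppt_score: int
    feature_class: str

    def __post_init__(self) -> None:
        if self.sensitive and not self.true_psi_treat < self.true_psi_ctrl:
            raise ConfigError("sensitive event must have psi_treat < psi_ctrl")


@dataclass
class DatasetBundle:
    outdir: Path
    genome: dict[str, Path]
    annotation: dict[str, Path]
    junctions: dict[str, Path]
    design: dict[str, Path]
    homology: Path
    motifs: Path
    truth: Path
    truth_frame: pd.DataFrame = field(repr=False, default=None)


def mutate_homolog(seq: str, identity_target: float, seed: int) -> str:
    """Point-substituted copy of a sequence at a given identity level.

    Exactly ``round((1 - identity_target) * len(seq))`` positions are
    substituted to a different base, so the realised identity matches the
    target to within rounding; length is preserved.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if not 0.0 <= identity_target <= 1.0:
        raise ValueError("identity_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mut = int(round((1.0 - identity_target) * len(seq)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq.upper())
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _build_exon(rng: np.random.Generator, length: int, n_ese: int,
                n_ess: int, motifs: MotifTable) -> str:
    """Exon with exactly the planted motif counts, padded with C filler.

    Filler is 'C' only; since every shipped motif contains G, no occurrence
    can span a filler position and realised counts equal planted counts.
    """
    ese = motifs.ese_motifs
    ess = motifs.ess_motifs
    planted = [ese[rng.integers(len(ese))] for _ in range(n_ese)]
    planted += [ess[rng.integers(len(ess))] for _ in range(n_ess)]
    order = rng.permutation(len(planted)) if planted else []
    planted = [planted[i] for i in order]
    core = len("".join(planted))
    n_gaps = len(planted) + 1
    pad_total = length - core - 2 * n_gaps
    if pad_total < 0:
        raise ConfigError(
            f"exon length {length} cannot hold {len(planted)} motifs"
        )
    pads = np.full(n_gaps, 2)
    extra = rng.multinomial(pad_total, np.full(n_gaps, 1.0 / n_gaps))
    pads = pads + extra
    parts = []
    for i, motif in enumerate(planted):
        parts.append("C" * int(pads[i]))
        parts.append(motif)
    parts.append("C" * int(pads[-1]))
    return "".join(parts)


def _build_intron_tail(rng: np.random.Generator, run_length: int) -> str:
    """Last 100 nt of an intron with a single branch point and a controlled
    polypyrimidine tract.

    Layout: G-prefix + GGCTAAC (branch heptamer, A at consensus position) +
    G-pad + T-run + CAG.  The realised PPT score is 2 * run_length + 1 (the
    C following the branch adenosine plus the uninterrupted T run).
    """
    pad = int(rng.integers(1, 5))
    prefix = 100 - 7 - pad - run_length - 3
    if prefix < 0:
        raise ConfigError(f"tract run {run_length} too long for a 100-nt window")
    return "G" * prefix + "GGCTAAC" + "G" * pad + "T" * run_length + "CAG"


def _run_for_class(rng: np.random.Generator, kind: str) -> int:
    """Tract run length by feature class: weak scores in [10, 20), strong
    >= 30, broad anywhere in [5, 40)."""
    if kind == "weak":
        return int(rng.integers(5, 10))
    if kind == "strong":
        return int(rng.integers(15, 20))
    return int(rng.integers(2, 20))  # broad


@dataclass
class _GenePlan:
    gene_id: dict[str, str]
    strand: str
    kind: str                     # sensitive | constitutive | background
    # per species, per cassette:
    exon_seq: dict[str, list[str]]
    tail: dict[str, list[str]]    # engineered upstream-intron tails
    realized: dict[str, list[dict]]
    psi_ctrl: dict[str, float]
    psi_treat: dict[str, float]


def _plan_gene(cfg: SimConfig, rng: np.random.Generator, index: int,
               kind: str, motifs: MotifTable) -> _GenePlan:
    strand = "+" if index % 2 == 0 else "-"
    plan = _GenePlan(
        gene_id={"A": f"gA{index:04d}", "B": f"gB{index:04d}"},
        strand=strand, kind=kind,
        exon_seq={"A": [], "B": []}, tail={"A": [], "B": []},
        realized={"A": [], "B": []},
        psi_ctrl={}, psi_treat={},
    )
    for _ in range(cfg.n_cassette_per_gene):
        if kind == "sensitive":
            n_ese, n_ess = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            length = int(rng.integers(40, 65))
            tail_kind_a, tail_kind_b = "weak", "strong"
        elif kind == "constitutive":
            n_ese, n_ess = int(rng.integers(0, 9)), int(rng.integers(0, 6))
            length = int(rng.integers(40, 151))
            tail_kind_a = tail_kind_b = "broad"
        else:  # background insensitive
            n_ese, n_ess = int(rng.integers(0, 9)), int(rng.integers(0, 6))
            length = int(rng.integers(40, 181))
            tail_kind_a = tail_kind_b = "strong"
        needed = 6 * (n_ese + n_ess) + 2 * (n_ese + n_ess + 1)
        length = max(length, needed)
        if kind == "sensitive":
            length = min(length, 64)
        exon_a = _build_exon(rng, length, n_ese, n_ess, motifs)
        exon_b = mutate_homolog(
            exon_a, cfg.identity_target, int(rng.integers(2**31))
        )
        plan.exon_seq["A"].append(exon_a)
        plan.exon_seq["B"].append(exon_b)
        plan.tail["A"].append(_build_intron_tail(rng, _run_for_class(rng, tail_kind_a)))
        plan.tail["B"].append(_build_intron_tail(rng, _run_for_class(rng, tail_kind_b)))
    if kind == "sensitive":
        base_a = float(rng.uniform(0.55, 0.9))
        base_b = float(rng.uniform(0.55, 0.9))
        plan.psi_ctrl = {"A": base_a, "B": base_b}
        plan.psi_treat = {"A": base_a + cfg.effect_size_skip, "B": base_b}
    elif kind == "constitutive":
        plan.psi_ctrl = {"A": 1.0, "B": 1.0}
        plan.psi_treat = {"A": 1.0, "B": 1.0}
    else:
        base_a = float(rng.uniform(0.35, 0.9))
        base_b = float(rng.uniform(0.35, 0.9))
        plan.psi_ctrl = {"A": base_a, "B": base_b}
        plan.psi_treat = {"A": base_a, "B": base_b}
    return plan


def _assemble_gene(cfg: SimConfig, rng: np.random.Generator, plan: _GenePlan,
                   species: str) -> dict:
    """Sense-strand gene sequence plus exon layout for one species."""
    parts: list[str] = []
    exons: list[tuple[int, int, str]] = []  # (start, end, label) sense coords
    pos = 0

    def emit(seq: str, label: str | None = None) -> None:
        nonlocal pos
        if label is not None:
            exons.append((pos, pos + len(seq), label))
        parts.append(seq)
        pos += len(seq)

    emit(_rand_seq(rng, int(rng.integers(120, 181))), "flank")
    for k in range(cfg.n_cassette_per_gene):
        mid = int(rng.integers(150, 301)) - 106
        emit("GTAAGT" + _rand_seq(rng, mid) + plan.tail[species][k])
        emit(plan.exon_seq[species][k], f"cassette{k}")
        mid2 = int(rng.integers(150, 301)) - 106
        emit("GTAAGT" + _rand_seq(rng, mid2)
             + _build_intron_tail(rng, _run_for_class(rng, "broad")))
        emit(_rand_seq(rng, int(rng.integers(120, 181))), "flank")
    return {"seq": "".join(parts), "exons": exons}


def _genomic_layout(gene_seq: str, exons, strand: str, offset: int):
    """Map sense-coordinate exons to genomic coordinates at ``offset``."""
    L = len(gene_seq)
    if strand == "+":
        placed = [(offset + s, offset + e, label) for s, e, label in exons]
        seq = gene_seq
    else:
        placed = [(offset + L - e, offset + L - s, label)
                  for s, e, label in reversed(exons)]
        seq = revcomp(gene_seq)
    return seq, placed


def generate_dataset(config: SimConfig, outdir: str | Path) -> DatasetBundle:
    """Generate the full two-species dataset bundle under ``outdir``.

    Writes genome FASTAs, GTF annotations (one inclusion and one skipping
    transcript per cassette), per-species junction-count and design TSVs, the
    gene-homology table, the motif table and the ground-truth table.
    Deterministic for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    motifs = MotifTable(list(DEFAULT_MOTIFS))
    scheme = BinScheme()

    n_sens = int(round(config.frac_sensitive * config.n_genes))
    n_const = int(round(config.frac_constitutive * config.n_genes))
    kinds = (["sensitive"] * n_sens + ["constitutive"] * n_const
             + ["background"] * (config.n_genes - n_sens - n_const))
    kinds = [kinds[i] for i in rng.permutation(config.n_genes)]

    plans = [
        _plan_gene(config, rng, i, kind, motifs)
        for i, kind in enumerate(kinds)
    ]

    genomes: dict[str, dict[str, str]] = {}
    gtf_lines: dict[str, list[str]] = {"A": [], "B": []}
    events: dict[str, list[dict]] = {"A": [], "B": []}
    truth_rows: list[dict] = []

    for species in ("A", "B"):
        chrom = f"chr{species}1"
        chunks: list[str] = []
        offset = 0
        for plan in plans:
            assembled = _assemble_gene(config, rng, plan, species)
            spacer = _rand_seq(rng, 300)
            seq, placed = _genomic_layout(
                assembled["seq"], assembled["exons"], plan.strand, offset
            )
            chunks.append(seq)
            chunks.append(spacer)
            gene_id = plan.gene_id[species]
            # inclusion transcript: all exons; one skip transcript per cassette
            tx_exons = {f"{gene_id}.t0": [(s, e) for s, e, _ in placed]}
            cassette_idx = {
                label: i for i, (_, _, label) in enumerate(placed)
                if label.startswith("cassette")
            }
            for label, i in cassette_idx.items():
                k = label[len("cassette"):]
                tx_exons[f"{gene_id}.skip{k}"] = [
                    (s, e) for j, (s, e, _) in enumerate(placed) if j != i
                ]
            for tx_id, exon_list in tx_exons.items():
                for s, e in exon_list:
                    gtf_lines[species].append(
                        f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{plan.strand}\t."
                        f"\tgene_id \"{gene_id}\"; transcript_id \"{tx_id}\";"
                    )
            for label, i in sorted(cassette_idx.items()):
                k = int(label[len("cassette"):])
                c1 = placed[i - 1][1]
                c2, c3 = placed[i][0], placed[i][1]
                c4 = placed[i + 1][0]
                event_id = f"{gene_id}:{c1}-{c2}-{c3}-{c4}"
                # realised features, recomputed from the engineered parts;
                # the label index k is the sense-strand cassette index
                exon_seq = plan.exon_seq[species][k]
                tail = plan.tail[species][k]
                n_ese, n_ess = count_motifs(exon_seq, motifs)
                bp = predict_branch_point(tail)
                ppt = ppt_score(tail, bp[0]) if bp else None
                fclass = assign_bin(
                    {"exon_length": len(exon_seq), "n_ese": n_ese,
                     "n_ess": n_ess, "ppt_score": ppt},
                    scheme,
                )
                sensitive = plan.kind == "sensitive" and species == "A"
                rec = TruthRecord(
                    event_id=event_id,
                    species=species,
                    gene_id=gene_id,
                    sensitive=sensitive,
                    constitutive=plan.kind == "constitutive",
                    true_psi_ctrl=plan.psi_ctrl[species],
                    true_psi_treat=plan.psi_treat[species],
                    exon_length=len(exon_seq),
                    n_ese=n_ese,
                    n_ess=n_ess,
                    ppt_score=int(ppt) if ppt is not None else -1,
                    feature_class="|".join(fclass) if fclass else "unbinned",
                )
                truth_rows.append(rec.__dict__)
                events[species].append(
                    {
                        "plan": plan, "chrom": chrom, "c1": c1, "c2": c2,
                        "c3": c3, "c4": c4, "event_id": event_id,
                    }
                )
            offset += len(seq) + len(spacer)
        genomes[species] = {chrom: "".join(chunks)}

    # --- junction counts -------------------------------------------------
    design_frames: dict[str, pd.DataFrame] = {}
    junction_frames: dict[str, pd.DataFrame] = {}
    weights = rng.lognormal(mean=0.0, sigma=0.6, size=config.n_genes)
    weights /= weights.sum()
    gene_index = {plan.gene_id[sp]: i
                  for i, plan in enumerate(plans) for sp in ("A", "B")}
    for species in ("A", "B"):
        samples = [
            (f"{species}_control_1", "control", 1),
            (f"{species}_control_2", "control", 2),
            (f"{species}_treated_1", "treated", 1),
            (f"{species}_treated_2", "treated", 2),
        ]
        design_frames[species] = pd.DataFrame(
            [(s, cond, rep, config.library_size) for s, cond, rep in samples],
            columns=["sample", "condition", "replicate", "library_size"],
        )
        rows = []
        for sample, condition, _rep in samples:
            gene_depth = rng.multinomial(config.library_size, weights)
            per_gene_events: dict[str, list[dict]] = {}
            for ev in events[species]:
                per_gene_events.setdefault(ev["plan"].gene_id[species], []).append(ev)
            for gene_id, evs in per_gene_events.items():
                depth = gene_depth[gene_index[gene_id]]
                split = rng.multinomial(depth, np.full(len(evs), 1.0 / len(evs)))
                for ev, d in zip(evs, split):
                    plan = ev["plan"]
                    true_psi = (plan.psi_ctrl[species] if condition == "control"
                                else plan.psi_treat[species])
                    if plan.kind == "constitutive":
                        psi = 1.0
                    else:
                        t = np.clip(true_psi, 1e-3, 0.999)
                        logit = np.log(t / (1 - t))
                        logit += rng.normal(0.0, config.replicate_noise_sd)
                        psi = float(np.clip(1 / (1 + np.exp(-logit)), 0.001, 0.999))
                    probs = np.array([psi, psi, 1 - psi]) / (1 + psi)
                    j_up, j_down, j_skip = rng.multinomial(d, probs)
                    strand = plan.strand
                    rows.extend(
                        [
                            (ev["chrom"], ev["c1"], ev["c2"], strand, sample, j_up),
                            (ev["chrom"], ev["c3"], ev["c4"], strand, sample, j_down),
                            (ev["chrom"], ev["c1"], ev["c4"], strand, sample, j_skip),
                        ]
                    )
        junction_frames[species] = pd.DataFrame(
            rows,
            columns=["chrom", "intron_start", "intron_end", "strand",
                     "sample", "count"],
        )

    # --- write bundle -----------------------------------------------------
    paths = DatasetBundle(
        outdir=outdir,
        genome={sp: outdir / f"genome_{sp}.fa" for sp in ("A", "B")},
        annotation={sp: outdir / f"annotation_{sp}.gtf" for sp in ("A", "B")},
        junctions={sp: outdir / f"junctions_{sp}.tsv" for sp in ("A", "B")},
        design={sp: outdir / f"design_{sp}.tsv" for sp in ("A", "B")},
        homology=outdir / "homology.tsv",
        motifs=outdir / "motifs.tsv",
        truth=outdir / "truth.tsv",
    )
    for sp in ("A", "B"):
        write_fasta(genomes[sp], paths.genome[sp])
        # remove a stale pyfaidx index so re-generation never reads old data
        idx = Path(str(paths.genome[sp]) + ".fai")
        if idx.exists():
            idx.unlink()
        with open(paths.annotation[sp], "w") as fh:
            fh.write("\n".join(gtf_lines[sp]) + "\n")
        junction_frames[sp].to_csv(paths.junctions[sp], sep="\t", index=False)
        design_frames[sp].to_csv(paths.design[sp], sep="\t", index=False)
    pd.DataFrame(
        [(p.gene_id["A"], p.gene_id["B"]) for p in plans],
        columns=["gene_id_a", "gene_id_b"],
    ).to_csv(paths.homology, sep="\t", index=False)
    pd.DataFrame(DEFAULT_MOTIFS, columns=["factor", "motif", "score"]).to_csv(
        paths.motifs, sep="\t", index=False
    )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(paths.truth, sep="\t", index=False)
    paths.truth_frame = truth
    return paths
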