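import numpy as np
import pytest

from splicesense.annotation import Gene, GeneModels, Transcript
from splicesense.pipeline import PipelineConfig, run_full
from splicesense.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small two-species dataset shared across tests."""
    outdir = tmp_path_factory.mktemp("dataset")
    return generate_dataset(
        SimConfig(n_genes=40, frac_sensitive=0.1, seed=11, library_size=400_000),
        outdir,
    )


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """Full pipeline results on the small dataset."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = PipelineConfig.from_bundle(small_bundle, outdir)
    result = run_full(cfg)
    return small_bundle, outdir, result


def make_gene(gene_id, transcripts, chrom="chr1", strand="+"):
    return Gene(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=tuple(
            Transcript(f"{gene_id}.t{i}", tuple(exons))
            for i, exons in enumerate(transcripts)
        ),
    )


def make_models(*genes):
    models = GeneModels()
    for gene in genes:
        models.genes[gene.gene_id] = gene
    return models


def random_gene_models(rng: np.random.Generator, n_genes: int) -> GeneModels:
    """Random toy gene models for oracle-equivalence checks."""
    models = GeneModels()
    for g in range(n_genes):
        n_exons = int(rng.integers(3, 8))
        bounds = np.sort(rng.choice(np.arange(1, 600), 2 * n_exons, replace=False))
        exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1]))
                 for i in range(n_exons)]
        transcripts = [list(exons)]
        for _ in range(int(rng.integers(1, 4))):
            keep = [exons[0]]
            for exon in exons[1:-1]:
                if rng.random() < 0.6:
                    keep.append(exon)
            keep.append(exons[-1])
            transcripts.append(keep)
        gene = make_gene(f"g{g}", transcripts, strand="+" if g % 2 else "-")
        models.genes[gene.gene_id] = gene
    return models


def brute_force_events(gene):
    """Exhaustive (internal exon, other-transcript intron) enumeration."""
    found = set()
    for tx in gene.transcripts:
        for i in range(1, len(tx.exons) - 1):
            c1 = tx.exons[i - 1][1]
            c2, c3 = tx.exons[i]
            c4 = tx.exons[i + 1][0]
            for other in gene.transcripts:
                if other.transcript_id == tx.transcript_id:
                    continue
                for j in range(len(other.exons) - 1):
                    intron = (other.exons[j][1], other.exons[j + 1][0])
                    if intron == (c1, c4):
                        found.add((c1, c2, c3, c4))
    return found
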