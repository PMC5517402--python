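import os

import pytest
from hypothesis import settings

import circlife as cl
from circlife.pipeline import PipelineConfig, run_all

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_annotation() -> cl.GenomeAnnotation:
    """Two genes on Chr1 (one per strand), a gene-free scaffold, an organelle."""
    gene_a = cl.Gene(
        "gA", "Chr1", "+", 1001, 1700,
        [cl.Exon(1001, 1100), cl.Exon(1201, 1300), cl.Exon(1401, 1500), cl.Exon(1601, 1700)],
    )
    gene_b = cl.Gene("gB", "Chr1", "-", 3001, 3300, [cl.Exon(3001, 3100), cl.Exon(3201, 3300)])
    ann = cl.GenomeAnnotation(
        {
            "Chr1": cl.Chromosome("Chr1", 10000),
            "Chr2": cl.Chromosome("Chr2", 5000),
            "ChrC": cl.Chromosome("ChrC", 4000, "chloroplast"),
        },
        {"gA": gene_a, "gB": gene_b},
    )
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def toy_genome(toy_annotation) -> dict[str, str]:
    import numpy as np

    rng = np.random.default_rng(42)
    return {
        cid: "".join("ACGT"[i] for i in rng.integers(0, 4, ch.length))
        for cid, ch in toy_annotation.chromosomes.items()
    }


@pytest.fixture(scope="session")
def paper_fixture() -> cl.PaperFixture:
    return cl.make_paper_fixture()


@pytest.fixture(scope="session")
def paper_records(paper_fixture):
    records = [cl.classify_bsj(j, paper_fixture.annotation) for j in paper_fixture.junctions]
    return cl.flag_novel(records, paper_fixture.known_list)


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory, paper_fixture):
    """The full pipeline executed once on the deterministic fixture."""
    root = tmp_path_factory.mktemp("fixture_run")
    paths = paper_fixture.write(os.fspath(root / "inputs"))
    outdir = os.fspath(root / "out")
    config = PipelineConfig(
        gff3=paths["gff3"],
        genome_fasta=paths["genome"],
        bsj_table=paths["bsj"],
        gene_counts=paths["gene_counts"],
        mirna_counts=paths["mirna_counts"],
        mirna_fasta=paths["mirna_fasta"],
        known_circs=paths["known"],
        outdir=outdir,
    )
    report = run_all(config)
    return {"report": report, "paths": paths, "outdir": outdir, "config": config}
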