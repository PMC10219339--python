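import pytest

from fur_regulon.genome import (
    Gene,
    GenomeAnnotation,
    build_transcriptional_units,
)
from fur_regulon.pipeline import run_on_dataset
from fur_regulon.simulate import SimulationConfig, simulate_dataset


def make_annotation(genes, contig_len=100_000, contig="chr", tu_table=None,
                    max_gap_bp=50, tss=None):
    """Small hand-built annotation with TUs attached."""
    ann = GenomeAnnotation(
        contigs={contig: contig_len},
        genes={g.id: g for g in genes},
    )
    build_transcriptional_units(ann, tu_table, max_gap_bp)
    if tss:
        ann.tss = dict(tss)
    return ann


@pytest.fixture
def annotation_factory():
    return make_annotation


@pytest.fixture
def toy_genes():
    return [
        Gene("A", "chr", 101, 400, "+"),
        Gene("B", "chr", 451, 700, "+"),
        Gene("C", "chr", 801, 1000, "-"),
    ]


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The benchmark dataset: default generator settings, fixed seed."""
    outdir = tmp_path_factory.mktemp("dataset")
    sim = simulate_dataset(SimulationConfig(seed=0), outdir=outdir)
    return outdir, sim


@pytest.fixture(scope="session")
def default_report(default_dataset, tmp_path_factory):
    """Full pipeline output on the benchmark dataset."""
    dataset_dir, _ = default_dataset
    outdir = tmp_path_factory.mktemp("run")
    report = run_on_dataset(dataset_dir, outdir, seed=0)
    return report, outdir
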