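import pytest
from Bio import SeqIO

from leasurvey.pipeline import PipelineConfig, run
from leasurvey.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic dataset, seed 1."""
    out = tmp_path_factory.mktemp("sim-default")
    return generate_dataset(SimConfig(seed=1), out)


@pytest.fixture(scope="session")
def proteins(bundle):
    return {r.id: str(r.seq) for r in SeqIO.parse(str(bundle.proteome_fasta), "fasta")}


@pytest.fixture(scope="session")
def family_models(bundle, proteins):
    from leasurvey.structure import parse_gff3

    models = parse_gff3(str(bundle.gff3), str(bundle.genome_fasta))
    return [m for m in models if m.gene_id in proteins]


@pytest.fixture(scope="session")
def all_models(bundle):
    from leasurvey.structure import parse_gff3

    return parse_gff3(str(bundle.gff3), str(bundle.genome_fasta))


@pytest.fixture(scope="session")
def family_tree(bundle):
    """NJ point tree over the combined synthetic alignment (no bootstrap)."""
    from leasurvey import phylo

    aln = phylo.read_alignment(str(bundle.alignment_fasta))
    return phylo.nj_build(phylo.p_distance(aln))


@pytest.fixture(scope="session")
def report(tmp_path_factory):
    """Full pipeline run on the default simulation, seed 1."""
    out = tmp_path_factory.mktemp("pipeline-default")
    return run(PipelineConfig(out_dir=out, seed=1, simulate=SimConfig(seed=1)))
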