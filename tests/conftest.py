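import pytest

from snparray.model import CandidateSNP, GenomeAssembly
from snparray.simulate import generate_genome, generate_true_variants


@pytest.fixture(scope="session")
def toy_genome() -> GenomeAssembly:
    """1 chromosome (50 kb) + 3 contigs, fixed seed."""
    return generate_genome(
        n_chromosomes=1,
        chromosome_length=50_000,
        n_contigs=3,
        contig_length_range=(1_000, 3_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def toy_truth(toy_genome):
    return generate_true_variants(
        toy_genome,
        density_per_kb=2.0,
        af_distribution=("uniform", 0.05, 0.95),
        groups=("g1", "g2"),
        seed=12,
    )


def make_candidate(
    cid="c1",
    platform="gbs",
    seq_name="chr01",
    pos=100,
    ref="A",
    alt="G",
    **kwargs,
) -> CandidateSNP:
    return CandidateSNP(
        id=cid, platform=platform, seq_name=seq_name, pos=pos, ref=ref, alt=alt,
        **kwargs,
    )
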