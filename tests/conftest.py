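import pytest
from hypothesis import HealthCheck, settings

from spliceusage import ChainParameters, example_segmentation
from spliceusage.gene_model import END_SITE, START_SITE, GeneSegmentation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_seg():
    """The three-transcript worked-example gene (M=8, M_s=4, M_e=3)."""
    return example_segmentation()


@pytest.fixture(scope="session")
def cassette_seg():
    """Five-segment cassette-exon gene: exon, intron, cassette exon,
    intron, exon."""
    kinds = [END_SITE, START_SITE, END_SITE, START_SITE]
    return GeneSegmentation.from_lengths(
        [150, 200, 120, 250, 180], kinds, gene_id="cassette", chrom="chr1", origin=500
    )


@pytest.fixture()
def example_theta():
    """Mildly informative usage parameters for the worked-example gene."""
    return ChainParameters(0.45, [0.35, 0.75, 0.55, 0.30], [0.80, 0.85, 0.70])
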