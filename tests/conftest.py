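import numpy as np
import pytest
from hypothesis import settings

from flm_sweepmap.expression import GeneModelAnnot

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def locus_pair(rng):
    """A random 2 kb reference locus and a 1 kb insertion sequence."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref = rng.choice(bases, size=2000).tobytes().decode()
    ins = rng.choice(bases, size=1000).tobytes().decode()
    return ref, ins


@pytest.fixture(scope="session")
def seven_exon_gene():
    """Gene model with 7 exons (exon 1 long, as in the FLM locus sketch)."""
    return GeneModelAnnot(
        gene_id="FLM",
        chrom="chr1",
        strand="+",
        exons=(
            (0, 200),
            (1200, 1350),
            (1500, 1650),
            (1900, 2000),
            (2200, 2300),
            (2500, 2600),
            (2800, 3000),
        ),
    )
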