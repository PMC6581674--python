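import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ventphage.model import GeneAnnotation
from ventphage.simulate import simulate_sag


def make_gene(contig="c1", start=0, end=900, product="hypothetical protein",
              kind="gene", gene_id="", strand="+"):
    return GeneAnnotation(contig, start, end, strand, kind, product,
                          gene_id or f"{contig}_{start}")


@pytest.fixture(scope="session")
def prophage_sag():
    """One 60 kb synthetic SAG with a 20 kb implanted prophage."""
    contig, annotations, truth = simulate_sag(
        length_bp=60_000, with_prophage=True, prophage_len=20_000,
        shift=0.6, seed=11, sag_id="SAG-011",
    )
    return contig, annotations, truth


@pytest.fixture(scope="session")
def clean_sag():
    """One 60 kb phage-free synthetic SAG."""
    contig, annotations, truth = simulate_sag(
        length_bp=60_000, with_prophage=False, seed=12, sag_id="SAG-012",
    )
    return contig, annotations, truth
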