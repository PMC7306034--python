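import pytest

from ndokit.codehop import design_primer_pairs
from ndokit.synth import FamilySpec, gen_protein_family


@pytest.fixture(scope="session")
def ndo_family():
    """Synthetic reductase-like family: CGTC and WRAY motifs 246 aa apart,
    fully conserved, over a weakly conserved background."""
    spec = FamilySpec(
        n_seqs=8, length=320,
        motifs={50: "CGTC", 296: "WRAY"},
        conservation=0.5, motif_conservation=1.0, seed=3,
    )
    return gen_protein_family(spec)


@pytest.fixture(scope="session")
def ndo_pair(ndo_family):
    """The single hybrid primer pair designed on the fixture family."""
    pairs = design_primer_pairs(ndo_family, extend_nt=2,
                                product_range=(700, 800))
    assert len(pairs) == 1
    return pairs[0]
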