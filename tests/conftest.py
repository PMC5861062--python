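import pytest

from orthoflow import parse_newick, simulate_truth
from orthoflow.seqio import FastaRecord


@pytest.fixture(scope="session")
def four_species_tree():
    """Balanced 4-species tree, all pairwise path distances <= 0.7."""
    return parse_newick("((A:0.15,B:0.15):0.1,(C:0.15,D:0.15):0.1);")


@pytest.fixture(scope="session")
def asym_tree():
    """3-species tree with focal F at distance 0.4 to A and 0.8 to B."""
    return parse_newick("((F:0.2,A:0.2):0.2,B:0.4);")


@pytest.fixture(scope="session")
def small_truth(four_species_tree):
    """60 single-copy + specific families over 4 species, 150 aa roots."""
    return simulate_truth(
        four_species_tree,
        60,
        {"universal-single": 0.8, "species-specific": 0.2},
        seed=42,
        root_length=150,
    )


@pytest.fixture
def family_records(small_truth):
    """Gene records grouped per family id."""
    fam = {}
    for g in small_truth.genes:
        fam.setdefault(g.family_id, []).append(FastaRecord(g.gene_id, g.seq))
    return {fid: sorted(rs, key=lambda r: r.id) for fid, rs in fam.items()}
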