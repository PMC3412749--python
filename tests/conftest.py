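import dendropy
import pytest

from ugtfam import simkit

# two 6-leaf clades separated by a long internal edge
DEEP_CLADE_NEWICK = (
    "((((A1:0.05,A2:0.05):0.05,(A3:0.05,A4:0.05):0.05):0.05,"
    "(A5:0.1,A6:0.1):0.05):0.4,"
    "(((B1:0.05,B2:0.05):0.05,(B3:0.05,B4:0.05):0.05):0.05,"
    "(B5:0.1,B6:0.1):0.05):0.4);"
)


@pytest.fixture(scope="session")
def family_sim():
    """Default simulated family: 16 leaves, 4 intron classes, 30% decoys."""
    return simkit.simulate_family(seed=1)


@pytest.fixture(scope="session")
def family_files(family_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return family_sim, family_sim.write(outdir)


@pytest.fixture(scope="session")
def deep_clade_sim():
    """12-leaf family on a fixed tree with two deeply separated clades."""
    tree = dendropy.Tree.get(data=DEEP_CLADE_NEWICK, schema="newick")
    return simkit.simulate_family(tree=tree, subst_rate=0.5, indel_rate=0.0,
                                  seed=3, decoy_frac=0.0, n_intron_classes=2,
                                  n_groups=2)
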