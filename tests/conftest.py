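import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, print_blob=False)
settings.load_profile("ci")

from branchsel.alignments import CodonAlignment
from branchsel.engine import BACKGROUND, CodonModelParams
from branchsel.trees import parse_newick


@pytest.fixture
def quartet_tree():
    return parse_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);")


@pytest.fixture
def six_taxon_tree():
    return parse_newick(
        "((sp1:0.12,sp2:0.15):0.05,(sp3:0.2,(sp4:0.1,sp5:0.1):0.08):0.04,sp6:0.3);"
    )


@pytest.fixture
def m0_params():
    return CodonModelParams(kappa=2.0, omega_by_class={BACKGROUND: 0.2})


def make_alignment(gene_id="g", **sequences):
    return CodonAlignment(gene_id=gene_id, sequences=dict(sequences))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
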