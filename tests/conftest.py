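import dendropy
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def glud2_cds():
    from paleocds.simulate import make_glud2_like_cds

    return make_glud2_like_cds(seed=0)


@pytest.fixture(scope="session")
def glud1_cds():
    from paleocds.simulate import make_glud1_like_cds

    return make_glud1_like_cds(seed=0)


@pytest.fixture
def four_leaf_tree():
    return dendropy.Tree.get(
        data="((A:0.1,B:0.2):0.15,(C:0.3,D:0.05):0.1);", schema="newick"
    )


@pytest.fixture
def four_leaf_alignment():
    from paleocds.phylo import SiteAlignment

    return SiteAlignment(
        ids=("A", "B", "C", "D"), rows=("ACGTA", "ACGAA", "GCTTC", "ACNTC")
    )
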