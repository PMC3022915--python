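import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from niltkit.simulate import GeneSpec, LocusConfig, salmon_bac_config, simulate_locus
from niltkit.tables import salmon_templates


@pytest.fixture(scope="session")
def templates():
    return salmon_templates()


@pytest.fixture(scope="session")
def salmon_truth():
    """Full study emulation: six genes + two pseudogenes on one locus."""
    return simulate_locus(salmon_bac_config(spacer_length=1000), seed=11)


@pytest.fixture(scope="session")
def small_truth(templates):
    """Compact three-gene locus (group 1, group 2 on minus strand, two-Ig)."""
    cfg = LocusConfig(
        genes=[
            GeneSpec(templates["Ssa-NILT1"]),
            GeneSpec(templates["Ssa-NILT5"], strand="-"),
            GeneSpec(templates["Ssa-NILT3"]),
        ],
        spacer_length=400,
    )
    return simulate_locus(cfg, seed=5)


@pytest.fixture(scope="session")
def small_models(small_truth):
    return {m.gene_id: m for m in small_truth.models()}
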