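import pytest

from retrotrace.synthdata import emit_fixture_paper_clade, make_ancestral_he_gene


@pytest.fixture(scope="session")
def ancestral_gene():
    return make_ancestral_he_gene(0)


@pytest.fixture(scope="session")
def fixture_clade():
    """The deterministic 16-species worked-example clade."""
    return emit_fixture_paper_clade()


@pytest.fixture(scope="session")
def fixture_report(fixture_clade):
    from retrotrace.pipeline import run_simulated
    return run_simulated(fixture_clade)
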