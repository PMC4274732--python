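import pytest

from symsieve import pipeline as pipe
from symsieve.simulate import SimConfig, emit_fixture_bundle
from symsieve.species import make_groups


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default-condition synthetic bundle (200 families, fixed seed)."""
    out = tmp_path_factory.mktemp("bundle") / "fixture"
    return emit_fixture_bundle(SimConfig(seed=0), out)


@pytest.fixture(scope="session")
def bundle_run(default_bundle, tmp_path_factory):
    """A full pipeline run over the default bundle."""
    out = tmp_path_factory.mktemp("run") / "out"
    config = pipe.config_for_bundle(default_bundle, out)
    manifest = pipe.run_pipeline(config)
    return out, manifest


@pytest.fixture
def toy_groups():
    """Nine clustered species: six trait-positive dicots + three negatives,
    plus two monocots known only from hit tables."""
    return make_groups(
        group_a=["Mtr", "Gma", "Sly", "Stu", "Vvi", "Ptr"],
        group_b=["Osa", "Zma"],
        group_c=["Ath", "Aly", "Bra"],
        clustered=["Mtr", "Gma", "Sly", "Stu", "Vvi", "Ptr", "Ath", "Aly", "Bra"],
    )
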