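import pytest

from chemoscreen.simulate import make_fixture_bundle


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The hand-designed 6-line / 4-drug screen bundle with truth JSON."""
    out = tmp_path_factory.mktemp("fixture_bundle")
    return make_fixture_bundle(out, seed=7)


@pytest.fixture(scope="session")
def fixture_datasets(fixture_bundle):
    from chemoscreen.io import read_screen_datasets

    return read_screen_datasets(
        fixture_bundle["reads"], fixture_bundle["layout"], fixture_bundle["library"]
    )
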