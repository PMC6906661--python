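import pytest

from famescreen.profile_io import load_reference_isolates, load_reference_profiles


@pytest.fixture(scope="session")
def reference_profiles():
    """The four packaged isolate composition profiles."""
    return load_reference_profiles()


@pytest.fixture(scope="session")
def profiles_by_id(reference_profiles):
    return {p.sample_id: p for p in reference_profiles}


@pytest.fixture(scope="session")
def reference_isolates():
    """Culture metrics joined to the packaged profiles."""
    return load_reference_isolates()
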