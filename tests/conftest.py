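import pytest
from hypothesis import settings

from mutscape import load_reference
from mutscape import synthdata as sd

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def collection_1040(reference):
    return sd.make_collection(reference, min_per_position=15, total=1040, seed=42)


@pytest.fixture(scope="session")
def manifest_1040(collection_1040):
    return sd.manifest_frame(collection_1040)
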