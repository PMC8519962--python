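import pytest

from vetptr import pipeline, resources
from vetptr.config import load_dialects


@pytest.fixture(scope="session")
def context():
    """Bundled dialects, lexicons, normalization maps, aggregation rules."""
    return pipeline.load_context()


@pytest.fixture(scope="session")
def dialects():
    return load_dialects()


@pytest.fixture(scope="session")
def lexicons(context):
    return context["lexicons"]


@pytest.fixture(scope="session")
def maps(context):
    return context["maps"]


@pytest.fixture(scope="session")
def example_path():
    return resources.example_export_path()


@pytest.fixture(scope="session")
def example_record(example_path, dialects):
    records = pipeline.records_from_export(example_path, "default", dialects)
    assert len(records) == 1
    return records[0]


@pytest.fixture(scope="session")
def example_registry(example_path, context):
    return pipeline.registry_from_export(example_path, "default", context)
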