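import pytest
from hypothesis import settings

from herbmars import load_reference_dataset

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    """The packaged study dataset (7 plants, 35 compound dossiers)."""
    return load_reference_dataset()


@pytest.fixture(scope="session")
def by_name(reference):
    """Index (plant botanical name, compound name) -> record."""
    return {
        (rec.plant.botanical_name, rec.name): rec
        for rec in reference.compounds
    }
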