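import logging

import pytest
from importlib import resources

import digestate as dg

logging.getLogger("digestate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def data_dir():
    return resources.files("digestate") / "data"


@pytest.fixture(scope="session")
def survey_records(data_dir):
    """The bundled nine-plant survey fixture, parsed."""
    return dg.read_plant_table(
        data_dir / "survey_streams.tsv", data_dir / "survey_analytes.tsv"
    )


@pytest.fixture(scope="session")
def fw1(survey_records):
    """The fully characterized food-waste line (substrate + 2 stages)."""
    return next(r for r in survey_records if r.name == "FW1")


@pytest.fixture(scope="session")
def noiseless_survey():
    """Nine synthetic plants, exact measurements."""
    return dg.generate_survey(9, seed=3, noise_cv=0.0)
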