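import datetime

import pytest

from semforge import build_schema, build_shapes
from semforge.dataset_io import resolve_inheritance
from semforge.fixtures import billed_diagnosis_model, demo_model

FIXED_DATE = datetime.date(2025, 1, 1)


@pytest.fixture(scope="session")
def billed_model():
    return resolve_inheritance(billed_diagnosis_model())


@pytest.fixture(scope="session")
def demo_dataset():
    return resolve_inheritance(demo_model())


@pytest.fixture(scope="session")
def billed_schema(billed_model):
    return build_schema(billed_model)


@pytest.fixture(scope="session")
def demo_schema(demo_dataset):
    return build_schema(demo_dataset)


@pytest.fixture(scope="session")
def demo_shapes(demo_schema, demo_dataset):
    return build_shapes(
        demo_schema, coding_systems=demo_dataset.coding_systems, today=FIXED_DATE
    )
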