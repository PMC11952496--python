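import numpy as np
import pandas as pd
import pytest

import cordmap as cm
from cordmap.synthetic import DEFAULT_FAMILY_DEPTHS, DEFAULT_WAVES


@pytest.fixture(scope="session")
def template():
    return cm.make_template("brachial")


@pytest.fixture(scope="session")
def section(template):
    return cm.perturb_section(template, seed=42, section_id="S1")


@pytest.fixture(scope="session")
def section_cells(section):
    return cm.sample_family_cells(section, DEFAULT_FAMILY_DEPTHS, 200, seed=7)


@pytest.fixture(scope="session")
def pulse_panel():
    model = cm.BirthWaveModel(families=DEFAULT_WAVES)
    return cm.simulate_pulse_panel(model, seed=11)


@pytest.fixture()
def anchors_as_cells(section):
    """The section's raw anchors formatted as a cell table."""
    df = section.anchors_raw.rename(columns={"anchor_name": "cell_id"}).copy()
    return df
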