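import pytest

from enamelkit.chronology import dsr_profile, spacing_table_to_measurements
from enamelkit.synthetic import SectionConfig, generate_section


@pytest.fixture(scope="session")
def noiseless_section():
    """Paper-matched synthetic section without noise."""
    return generate_section(SectionConfig(noise_sd=0.0))


@pytest.fixture(scope="session")
def default_section():
    """Paper-matched synthetic section at the default noise level."""
    return generate_section(SectionConfig())


@pytest.fixture(scope="session")
def noiseless_dsr_profile(noiseless_section):
    return dsr_profile(
        spacing_table_to_measurements(noiseless_section.tables["spacing"]))
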