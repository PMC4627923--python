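import pytest

from vesidens import SucroseCalibration, TreatmentMeasurements, load_reference_dataset


@pytest.fixture(scope="session")
def reference_data() -> dict:
    return load_reference_dataset()


@pytest.fixture(scope="session")
def reference_measurements(reference_data) -> TreatmentMeasurements:
    return reference_data["measurements"]


@pytest.fixture(scope="session")
def calibration() -> SucroseCalibration:
    return SucroseCalibration.from_table()
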