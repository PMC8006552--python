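import pytest

from ringflow import (Tracheidogram, get_profile, load_reference_table,
                      load_reference_tracheidograms)


@pytest.fixture(scope="session")
def params22():
    """Generic Pinaceae calibration: 22 µm membrane cap (curve experiments)."""
    return get_profile("pinaceae_22")


@pytest.fixture(scope="session")
def params25():
    """Larix sibirica calibration: 25 µm membrane cap (worked example)."""
    return get_profile("larix_25")


@pytest.fixture(scope="session")
def larix_tracheidograms() -> list[Tracheidogram]:
    """The two bundled measured rings (T10-1994: 21 cells, T10-2009: 15)."""
    return load_reference_tracheidograms()


@pytest.fixture(scope="session")
def larix_reference():
    """Published per-cell table for the bundled rings (fixture of record)."""
    return load_reference_table()
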