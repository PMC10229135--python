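from pathlib import Path

import pytest

from allopharm.synthetic import PRESETS

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def truth_cells():
    """Independently transcribed published table cells, for cross-checking
    the preset tables in the synthetic-data module."""
    import pandas as pd

    return pd.read_csv(DATA_DIR / "table_truth_cells.csv")


@pytest.fixture(scope="session")
def binding_presets():
    return {k: v for k, v in PRESETS.items()
            if v.binding is not None and not k.startswith("SATURATION")}


@pytest.fixture(scope="session")
def functional_presets():
    return {k: v for k, v in PRESETS.items() if v.functional is not None}
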