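import pandas as pd
import pytest

from genefam.core_model import load_bundled_table


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return load_bundled_table("table1.tsv")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return load_bundled_table("table2.tsv")
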