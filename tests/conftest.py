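from pathlib import Path

import pandas as pd
import pytest

from evmirna import read_sample_sheet, read_well_table

DATA = Path(__file__).resolve().parents[1] / "examples" / "data"


@pytest.fixture(scope="session")
def toy_wells() -> pd.DataFrame:
    return read_well_table(DATA / "toy_wells.csv")


@pytest.fixture(scope="session")
def toy_sheet() -> pd.DataFrame:
    return read_sample_sheet(DATA / "toy_sample_sheet.csv")


@pytest.fixture(scope="session")
def toy_paths() -> dict[str, Path]:
    return {"wells": DATA / "toy_wells.csv",
            "sheet": DATA / "toy_sample_sheet.csv"}
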