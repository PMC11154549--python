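from pathlib import Path

import pandas as pd
import pytest
import yaml

from crystalhabit import FaceForm, UnitCell

DATA_DIR = Path(__file__).resolve().parent.parent / "examples" / "data" / "ismn"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def ismn_cell() -> UnitCell:
    """Force-field-optimized tetragonal ISMN cell."""
    return UnitCell(a=15.419, b=15.419, c=6.572)


@pytest.fixture(scope="session")
def vacuum_forms_config() -> dict:
    with (DATA_DIR / "vacuum_forms.yaml").open() as fh:
        return yaml.safe_load(fh)


@pytest.fixture(scope="session")
def vacuum_forms(ismn_cell, vacuum_forms_config) -> list[FaceForm]:
    return [
        FaceForm.from_cell(ismn_cell, f["hkl"], f["e_att"], point_group="4",
                           expected_multiplicity=f["multiplicity"])
        for f in vacuum_forms_config["forms"]
    ]


@pytest.fixture(scope="session")
def mae_ch2cl2() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "mae_ch2cl2.csv")


@pytest.fixture(scope="session")
def mae_mixed() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "mae_ch2cl2_c6h14.csv")


@pytest.fixture(scope="session")
def rugosity_table() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "rugosity.csv")


@pytest.fixture(scope="session")
def hbond_census_tables() -> dict[str, pd.DataFrame]:
    return {
        "ch2cl2": pd.read_csv(DATA_DIR / "hbond_census_ch2cl2.csv"),
        "ch2cl2_c6h14": pd.read_csv(DATA_DIR / "hbond_census_ch2cl2_c6h14.csv"),
    }
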