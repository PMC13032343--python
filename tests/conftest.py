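import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture(scope="session")
def toy_dir() -> Path:
    return FIXTURES / "toy"


@pytest.fixture()
def toy_run_config(toy_dir, tmp_path):
    from jadersig.pipeline import RunConfig

    return RunConfig(
        drug_table=str(toy_dir / "drug.csv"),
        reac_table=str(toy_dir / "reac.csv"),
        dialect="ascii",
        category_map=str(toy_dir / "category_map.csv"),
        out_dir=str(tmp_path / "toy_out"),
    )
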