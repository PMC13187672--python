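import numpy as np
import pytest

from darkinhib.io import load_table1_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def fixture_means(fixture_dataset):
    return np.array([s.mean_di_percent for s in fixture_dataset.summaries])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def obs_table(tmp_path):
    """Write a small observation TSV and return its path."""

    def _write(rows, header=None):
        header = header or (
            "source_id\torder_code\ttribe\tspecies\tlight_activity\t"
            "dark_activity\tmethod"
        )
        path = tmp_path / "obs.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
        return path

    return _write
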