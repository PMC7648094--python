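import pandas as pd
import pytest

from salivadecoy import simulate


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(
        seed=11, ref_len=60_000, n_typical_pairs=300, n_atypical_pairs=30
    )


@pytest.fixture(scope="session")
def sim_dataset(sim_config, tmp_path_factory):
    """One small synthetic dataset shared across tests (read-only)."""
    outdir = tmp_path_factory.mktemp("simdata")
    paths = simulate.simulate_dataset(sim_config, outdir)
    return paths


@pytest.fixture(scope="session")
def truth_pairs(sim_dataset) -> pd.DataFrame:
    return pd.read_csv(sim_dataset["truth_pairs"], sep="\t")


@pytest.fixture(scope="session")
def truth_blast(sim_dataset) -> pd.DataFrame:
    return pd.read_csv(sim_dataset["truth_blast"], sep="\t", keep_default_na=False)


@pytest.fixture(scope="session")
def truth_changes(sim_dataset) -> pd.DataFrame:
    return pd.read_csv(sim_dataset["truth_changes"], sep="\t")
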