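import numpy as np
import pandas as pd
import pytest

from cortimir import synthetic_data as sd
from cortimir import target_integration as ti


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return sd.load_fixture("table1")


@pytest.fixture(scope="session")
def table2() -> pd.DataFrame:
    return sd.load_fixture("table2")


@pytest.fixture(scope="session")
def table3() -> pd.DataFrame:
    return sd.load_fixture("table3")


@pytest.fixture(scope="session")
def small_hairpins() -> list[sd.HairpinReference]:
    return sd.gen_hairpins(12, seed=20)


@pytest.fixture(scope="session")
def table2_evidence(table2):
    """Evidence tables rebuilt from the published per-gene annotations."""
    annotations = {
        str(row.gene_id): (row.targetscan_span, row.trust) for row in table2.itertuples()
    }
    tables = sd.evidence_from_annotations(annotations, seed=1, n_decoys=3)
    priors = {
        "wang": set(table2.loc[table2.in_wang, "gene_id"].astype(str)),
        "he": set(table2.loc[table2.in_he, "gene_id"].astype(str)),
    }
    return tables, priors


def integrate_evidence(tables, priors=None):
    runs = {run_id: tables[run_id] for run_id in ti.RUN_IDS}
    return ti.integrate(runs, tables["homologs"], tables["interactions"], priors)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
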