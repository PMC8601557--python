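import numpy as np
import pandas as pd
import pytest

from gutbalance.io_tables import AbundanceTable, ClinicalTable
from gutbalance.synthetic import default_study_spec, generate


@pytest.fixture
def uniform4_table():
    """3 samples, each uniform over 4 features."""
    vals = pd.DataFrame(np.full((3, 4), 0.25),
                        index=["s1", "s2", "s3"],
                        columns=["fA", "fB", "fC", "fD"])
    return AbundanceTable(vals)


@pytest.fixture(scope="session")
def demo_dataset():
    """One small planted study reused across read-only tests."""
    return generate(default_study_spec(seed=7, n_patients=15, n_features=40))


@pytest.fixture
def clinical_15(demo_dataset):
    return demo_dataset.clinical


def make_table(matrix, sample_ids=None, feature_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(d)]
    return AbundanceTable(pd.DataFrame(matrix, index=sample_ids,
                                       columns=feature_ids))


def write_taxa_tsv(path, columns, rows):
    """rows: list of (feature_id, values)."""
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(columns) + "\n")
        for fid, vals in rows:
            fh.write(fid + "\t" + "\t".join(f"{v:.10g}" for v in vals) + "\n")
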