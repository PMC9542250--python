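import numpy as np
import pandas as pd
import pytest

from cerna_moml.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by read-only tests."""
    cfg = SimulationConfig(seed=7, n_tumour=80, n_normal=40, n_mrna=20,
                           n_lncrna=5, n_mirna=12, n_tf=5, n_cerna_pairs=4)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def write_tsv(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture()
def toy_counts_files(tmp_path):
    """3 features x 2 samples with versioned Ensembl ids."""
    counts = write_tsv(tmp_path / "counts.tsv",
                       "feature_id\tS1\tS2\n"
                       "ENSG01.4\t10\t20\n"
                       "ENSG02.1\t5\t0\n"
                       "MIR1\t7\t9\n")
    classes = write_tsv(tmp_path / "classes.tsv",
                        "ENSG01\tmRNA\nENSG02\tlncRNA\nMIR1\tmiRNA\n")
    groups = write_tsv(tmp_path / "groups.tsv", "S1\ttumour\nS2\tnormal\n")
    return counts, classes, groups
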