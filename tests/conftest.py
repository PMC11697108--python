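import numpy as np
import pandas as pd
import pytest

from symbiotrans import synthetic


@pytest.fixture(scope="session")
def catalog_truth():
    """Zero-noise annotation table + TM + localization votes with truth."""
    hits, truth = synthetic.gen_annotations(
        300, frac_transporter=0.3, frac_sugar=0.1, seed=42
    )
    tm = synthetic.gen_tm_predictions(truth, disagreement_sd=0.0, seed=42)
    locs = synthetic.gen_localizations(truth, agreement=1.0, seed=42)
    return hits, tm, locs, truth


@pytest.fixture(scope="session")
def de_dataset():
    """Counts at the study's replicate numbers with planted two-fold-log-3 DE."""
    counts, design, truth = synthetic.gen_counts(
        1500,
        {"free_living": 9, "symbiosis": 17},
        frac_de=0.1,
        lfc=3.0,
        dispersion=0.1,
        seed=7,
    )
    return counts, design, truth


@pytest.fixture(scope="session")
def meta_dataset():
    tpm, meta, ann, truth = synthetic.gen_metatranscriptome(
        n_genes=600, samples_per_fraction=8, n_hk=40, seed=3
    )
    return tpm, meta, ann, truth
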