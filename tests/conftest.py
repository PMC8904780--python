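import warnings

import pytest

from rainwin.cli import prepare_tables
from rainwin.synthetic import SimConfig, gen_study, null_config


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (seed 1) with prepared tables."""
    bundle, truth = gen_study(SimConfig(seed=1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained, records, matrix, rounds = prepare_tables(bundle)
    return {
        "bundle": bundle,
        "truth": truth,
        "retained": retained,
        "records": records,
        "matrix": matrix,
        "rounds": rounds,
    }


@pytest.fixture(scope="session")
def null_study():
    """A study with all effects and variance components switched off."""
    bundle, truth = gen_study(null_config(seed=5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained, records, matrix, rounds = prepare_tables(bundle)
    return {
        "bundle": bundle,
        "truth": truth,
        "retained": retained,
        "records": records,
        "matrix": matrix,
        "rounds": rounds,
    }
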