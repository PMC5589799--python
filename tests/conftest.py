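"""Shared fixtures: a small synthetic normative cohort and fitted model.

Session-scoped so the (few-second) model fit is paid once; tests that need
different study conditions build their own cohorts.
"""

import numpy as np
import pandas as pd
import pytest

import morphonorm as mn


@pytest.fixture(scope="session")
def small_cfg() -> mn.GeneratorConfig:
    return mn.GeneratorConfig(seed=11, n_controls=140, n_repeat_pairs=25, artifact_rate=0.0)


@pytest.fixture(scope="session")
def small_controls(small_cfg):
    frame, pairs = mn.generate_controls(small_cfg)
    return frame


@pytest.fixture(scope="session")
def small_model(small_controls) -> mn.NormativeModel:
    return mn.build_normative_model(small_controls)


@pytest.fixture(scope="session")
def schema():
    return mn.assemble_schema()


@pytest.fixture()
def null_profile(schema, small_model) -> mn.AbnormalityProfile:
    """A profile with every feature exactly at its expectation (p = 1)."""
    ids = schema.ids()
    odds_raw = small_model.tables["raw"]["odds_valid"].to_numpy()
    odds_norm = small_model.tables["normalized"]["odds_valid"].to_numpy()
    table = pd.DataFrame(
        {
            "value_raw": 1.0,
            "pred_raw": 1.0,
            "sign_raw": 0.0,
            "p_raw": 1.0,
            "flag_raw": "none",
            "odds_raw": odds_raw,
            "value_normalized": 1.0,
            "pred_normalized": 1.0,
            "sign_normalized": 0.0,
            "p_normalized": 1.0,
            "flag_normalized": "none",
            "odds_normalized": odds_norm,
            "measurement_sd_raw": 0.1,
        },
        index=ids,
    )
    return mn.AbnormalityProfile(dataset_id="null", age=40.0, table=table)
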