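import datetime as dt

import numpy as np
import pandas as pd
import pytest

from nocturne import experiments
from nocturne.data_io import DEFAULT_TZ, RunConfig
from nocturne.preprocess import MEASURED, GlucoseSeries
from nocturne.synthetic_data import SynthConfig, generate


def make_series(
    values,
    start="2023-07-10 10:00",
    step_min=5,
    pid="P01",
    provenance=None,
) -> GlucoseSeries:
    """Build a measured-provenance glucose series on a uniform grid."""
    idx = pd.date_range(
        pd.Timestamp(start).tz_localize(DEFAULT_TZ),
        periods=len(values),
        freq=f"{step_min}min",
    )
    vals = pd.Series(np.asarray(values, dtype=float), index=idx)
    prov = pd.Series(
        provenance if provenance is not None else [MEASURED] * len(values),
        index=idx,
        dtype=object,
    )
    return GlucoseSeries(pid, vals, prov, step_min)


@pytest.fixture(scope="session")
def default_bundle():
    """The default camp-like cohort: 13 children, 6 scheduled days, 66
    analyzable nights."""
    return generate(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_config():
    return RunConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_bundle, default_config):
    b = default_bundle
    return experiments.curate_cohort(
        b.cgm + b.smbg, b.wearable, b.static, b.activity, default_config
    )
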