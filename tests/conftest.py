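import datetime as dt

import numpy as np
import pandas as pd
import pytest

from circamood import CohortSpec, SensorStream, generate_cohort, generate_subject


def hr_stream(mesor=70.0, amplitude=10.0, acrophase=14.0, noise_sd=0.0,
              hours=48, freq_minutes=1, seed=0, subject_id="t"):
    """Heart-rate stream following a known 24-h cosine rhythm."""
    n = int(hours * 60 / freq_minutes)
    idx = pd.date_range("2023-01-01", periods=n, freq=f"{freq_minutes}min")
    tod = (np.arange(n) * freq_minutes % 1440) / 60.0
    y = mesor + amplitude * np.cos(2 * np.pi * (tod - acrophase) / 24.0)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, n)
    return SensorStream(subject_id, "heart_rate",
                        pd.Series(y, index=idx, dtype=float))


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(n_crm=2, n_control=2, days=20, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def clean_subject():
    """One noiseless, fully worn subject whose generator parameters are
    exactly the cohort-level values."""
    spec = CohortSpec(n_crm=1, n_control=0, days=16, seed=2,
                      hr_noise_sd=0.0, hr_mesor_sd=0.0, hr_amplitude_sd=0.0,
                      hr_acrophase_sd=0.0, wear_prob=1.0)
    subject, truth = generate_subject(spec, 0, "CRM")
    return spec, subject, truth


def date_series(values, start=dt.date(2023, 1, 1)):
    """Daily series indexed by consecutive dates."""
    idx = [start + dt.timedelta(days=i) for i in range(len(values))]
    return pd.Series(list(values), index=pd.Index(idx), dtype=float)
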