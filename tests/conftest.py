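import pytest

import ecgmcm as e

#: Fixed seed for every deterministic-by-seed test run.
SEED = 12345

#: Sample count for the reference budgets: the minimum-count rule at 95%
#: coverage, which keeps the Monte Carlo error of a reported sd near 0.1 mV.
M = 200_000


@pytest.fixture(scope="session")
def ecg_sys():
    return e.ecg_measurement_system()


@pytest.fixture(scope="session")
def full_run(ecg_sys):
    return e.run_full(ecg_sys, m=M, seed=SEED)


@pytest.fixture(scope="session")
def default_budget(ecg_sys):
    return e.budget(ecg_sys, e.ECG_GROUPING, m=M, seed=SEED)


@pytest.fixture(scope="session")
def clean_ecg():
    return e.generate_ecg(heart_rate_bpm=60, duration_s=10, fs=500)
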