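import random
from datetime import date, datetime, timezone

import pytest

from trialchain.hashchain import init_device, sign_record
from trialchain.records import HealthRecord, TrialConfig, generate_trial
from trialchain.simulation import RunConfig, run_trial


def utc(y, m, d, hh, mm, ss=0):
    return datetime(y, m, d, hh, mm, ss, tzinfo=timezone.utc)


@pytest.fixture
def pinned_record():
    """A fully pinned one-day record used by the serialization oracles."""
    return HealthRecord(
        account_id="acct-1",
        seq=1,
        log_id="acct-1:1:deadbeef",
        record_date=date(2018, 9, 1),
        ais_total=12,
        ess_total=8,
        qids_total=10,
        bed_time=utc(2018, 9, 1, 22, 30),
        sleep_time=utc(2018, 9, 1, 22, 45),
        wake_time=utc(2018, 9, 2, 6, 10),
        rise_time=utc(2018, 9, 2, 6, 20),
        pvt_trials=(250, 300),
        app_timestamps=(utc(2018, 9, 2, 7, 0),),
    )


@pytest.fixture
def small_config():
    return RunConfig(trial=TrialConfig(n_patients=3, n_days=10, rng_seed=42))


@pytest.fixture(scope="session")
def clean_state():
    """One committed clean study (3 patients x 10 days), shared read-only."""
    return run_trial(RunConfig(trial=TrialConfig(n_patients=3, n_days=10, rng_seed=42)))


def make_chain(n_links, seed=5, account="acct-1"):
    """An honest device plus its signed chain over generated records."""
    (_, recs), = generate_trial(TrialConfig(n_patients=1, n_days=n_links, rng_seed=seed))
    recs = [r.replace(account_id=account, log_id=f"{account}:{r.seq}:aa00aa00")
            for r in recs]
    device = init_device(account, rng=random.Random(seed))
    links = []
    for r in recs:
        link, device = sign_record(device, r)
        links.append(link)
    return device, links


@pytest.fixture
def chain5():
    return make_chain(5)
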