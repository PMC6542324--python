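"""mHealth record schema, canonical serialization and synthetic-trial generation.

One :class:`HealthRecord` is one day's entry for one study account: three
questionnaire totals (Athens Insomnia Scale, Epworth Sleepiness Scale, Quick
Inventory of Depressive Symptomatology), four sleep-diary timestamps,
Psychomotor Vigilance Test reaction times, and the app-operation timestamps.
Records are hashed on the client, so they need a *canonical* byte form:
:func:`canonicalize` emits UTF-8 JSON with sorted keys, no insignificant
whitespace and ISO-8601 UTC timestamps, so that two structurally equal records
always hash identically.

The synthetic generator (:func:`generate_trial`) stands in for the study's
patient data; it is a pure function of :class:`TrialConfig`.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta, timezone
from typing import Iterable, Iterator

__all__ = [
    "AIS_MAX",
    "ESS_MAX",
    "QIDS_MAX",
    "HealthRecord",
    "TrialConfig",
    "Violation",
    "SerializationError",
    "canonicalize",
    "parse_record",
    "validate_record",
    "generate_trial",
    "write_jsonl",
    "read_jsonl",
]

AIS_MAX = 24
ESS_MAX = 24
QIDS_MAX = 27

_TS_FMT = "%Y-%m-%dT%H:%M:%SZ"


class SerializationError(ValueError):
    """Raised when a record cannot be canonically serialized; names the field."""


@dataclass(frozen=True)
class Violation:
    """One schema violation: the offending field and the rule it breaks."""

    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule}"


@dataclass(frozen=True)
class HealthRecord:
    """One day's mHealth entry for one account."""

    account_id: str
    seq: int
    log_id: str
    record_date: date
    ais_total: int
    ess_total: int
    qids_total: int
    bed_time: datetime
    sleep_time: datetime
    wake_time: datetime
    rise_time: datetime
    pvt_trials: tuple[int, ...] = ()
    app_timestamps: tuple[datetime, ...] = ()

    def replace(self, **changes) -> "HealthRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of one synthetic trial; generation is a pure function of this."""

    n_patients: int
    n_days: int
    records_per_day: int = 1
    rng_seed: int = 0
    start_date: date = date(2018, 9, 1)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_days < 0:
            raise ValueError("n_days must be >= 0")
        if self.records_per_day < 1:
            raise ValueError("records_per_day must be >= 1")


def _ts(dt: datetime) -> str:
    """Render a datetime as an ISO-8601 UTC string at second resolution."""
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    dt = dt.astimezone(timezone.utc)
    return (f"{dt.year:04d}-{dt.month:02d}-{dt.day:02d}"
            f"T{dt.hour:02d}:{dt.minute:02d}:{dt.second:02d}Z")


def _parse_ts(s: str) -> datetime:
    return datetime.strptime(s, _TS_FMT).replace(tzinfo=timezone.utc)


def validate_record(record: HealthRecord) -> list[Violation]:
    """Check all schema invariants; returns violations instead of raising."""
    out: list[Violation] = []
    for name, hi in (("ais_total", AIS_MAX), ("ess_total", ESS_MAX), ("qids_total", QIDS_MAX)):
        v = getattr(record, name)
        if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= hi:
            out.append(Violation(name, f"must be an integer in [0, {hi}]"))
    if not isinstance(record.seq, int) or record.seq < 1:
        out.append(Violation("seq", "must be an integer >= 1"))
    order = [
        ("bed_time", record.bed_time),
        ("sleep_time", record.sleep_time),
        ("wake_time", record.wake_time),
        ("rise_time", record.rise_time),
    ]
    for (an, a), (bn, b) in zip(order, order[1:]):
        if a > b:
            out.append(Violation(bn, f"must not precede {an}"))
    for i, rt in enumerate(record.pvt_trials):
        if rt <= 0:
            out.append(Violation("pvt_trials", f"trial {i} reaction time must be > 0 ms"))
    if not record.account_id:
        out.append(Violation("account_id", "must be non-empty"))
    if not record.log_id:
        out.append(Violation("log_id", "must be non-empty"))
    return out


def canonicalize(record: HealthRecord) -> bytes:
    """Serialize a record to its unique canonical JSON byte form.

    Sorted keys, UTF-8, ``,``/``:`` separators and ISO-8601 UTC timestamps:
    structurally equal records map to identical bytes regardless of how they
    were constructed, which is what the client hash and the ledger hash over.
    """
    violations = validate_record(record)
    if violations:
        v = violations[0]
        raise SerializationError(f"invalid field {v.field}: {v.rule}")
    doc = {
        "account_id": record.account_id,
        "seq": record.seq,
        "log_id": record.log_id,
        "record_date": record.record_date.isoformat(),
        "ais_total": record.ais_total,
        "ess_total": record.ess_total,
        "qids_total": record.qids_total,
        "bed_time": _ts(record.bed_time),
        "sleep_time": _ts(record.sleep_time),
        "wake_time": _ts(record.wake_time),
        "rise_time": _ts(record.rise_time),
        "pvt_trials": list(record.pvt_trials),
        "app_timestamps": [_ts(t) for t in record.app_timestamps],
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"), ensure_ascii=False).encode("utf-8")


def parse_record(data: bytes | str) -> HealthRecord:
    """Inverse of :func:`canonicalize`."""
    doc = json.loads(data)
    return HealthRecord(
        account_id=doc["account_id"],
        seq=doc["seq"],
        log_id=doc["log_id"],
        record_date=date.fromisoformat(doc["record_date"]),
        ais_total=doc["ais_total"],
        ess_total=doc["ess_total"],
        qids_total=doc["qids_total"],
        bed_time=_parse_ts(doc["bed_time"]),
        sleep_time=_parse_ts(doc["sleep_time"]),
        wake_time=_parse_ts(doc["wake_time"]),
        rise_time=_parse_ts(doc["rise_time"]),
        pvt_trials=tuple(doc["pvt_trials"]),
        app_timestamps=tuple(_parse_ts(t) for t in doc["app_timestamps"]),
    )


def _gen_day(rng: random.Random, account_id: str, seq: int, day: date, day_index: int,
             n_days: int, slot: int) -> HealthRecord:
    # AIS drifts mildly downward over the study (plausible treatment effect);
    # other scores are uniform within their clinical ranges.
    frac = day_index / max(n_days - 1, 1)
    ais_hi = max(4, int(round(AIS_MAX * (1.0 - 0.4 * frac))))
    ais = rng.randint(0, ais_hi)
    ess = rng.randint(0, ESS_MAX)
    qids = rng.randint(0, QIDS_MAX)

    base = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    bed = base + timedelta(hours=22, minutes=rng.randint(0, 119))
    sleep = bed + timedelta(minutes=rng.randint(5, 60))
    wake = base + timedelta(days=1, hours=5, minutes=rng.randint(30, 180))
    rise = wake + timedelta(minutes=rng.randint(2, 40))
    pvt = tuple(rng.randint(180, 600) for _ in range(10))
    apps = tuple(
        rise + timedelta(minutes=rng.randint(1, 240) + 30 * slot) for _ in range(3)
    )
    log_id = f"{account_id}:{seq}:{rng.getrandbits(32):08x}"
    return HealthRecord(
        account_id=account_id,
        seq=seq,
        log_id=log_id,
        record_date=day,
        ais_total=ais,
        ess_total=ess,
        qids_total=qids,
        bed_time=bed,
        sleep_time=sleep,
        wake_time=wake,
        rise_time=rise,
        pvt_trials=pvt,
        app_timestamps=tuple(sorted(apps)),
    )


def generate_trial(config: TrialConfig) -> list[tuple[str, list[HealthRecord]]]:
    """Generate the synthetic trial: one ordered record list per account.

    Each account gets ``n_days * records_per_day`` records with consecutive
    ``seq`` starting at 1; every record passes :func:`validate_record`; the
    output is byte-identical for identical configs.
    """
    config.validate()
    out: list[tuple[str, list[HealthRecord]]] = []
    for p in range(config.n_patients):
        account_id = f"patient-{p + 1:03d}"
        # per-account stream so accounts are independent of patient count order
        rng = random.Random(f"{config.rng_seed}:{account_id}")
        recs: list[HealthRecord] = []
        seq = 1
        for d in range(config.n_days):
            day = config.start_date + timedelta(days=d)
            for slot in range(config.records_per_day):
                recs.append(_gen_day(rng, account_id, seq, day, d, config.n_days, slot))
                seq += 1
        out.append((account_id, recs))
    return out


def write_jsonl(records: Iterable[HealthRecord], path) -> None:
    """Write records as JSON Lines, one canonical record per line."""
    with open(path, "wb") as fh:
        for rec in records:
            fh.write(canonicalize(rec))
            fh.write(b"\n")


def read_jsonl(path) -> Iterator[HealthRecord]:
    with open(path, "rb") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield parse_record(line)
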