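"""End-to-end trial simulation: generate → sign → dispatch → commit → reveal.

A run wires together the synthetic trial, one client device per account, the
authentication server, the relay pool and the ledger network, then replays the
study day by day. Fraud scenarios are injected declaratively via
:class:`AttackSpec`:

* ``RELAY`` — one relay is hacked; it rewrites the targeted record in flight
  and recomputes the client hash under a fresh attacker string (the device
  secret is not stolen).
* ``AUTH_SERVER`` — the account's authentication key is stolen; a second
  device submits a forged record reusing an existing log ID, hashed under an
  attacker string.
* ``CLIENT_DEVICE`` — a root exploit steals both the key and the secure
  string; the forged branch is hashed under the *true* secret, so it is
  cryptographically indistinguishable from the original.

At study end each device reveals its secure string to the ledger through the
relay path, enabling the retrospective audit.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from datetime import timedelta
from enum import Enum
from typing import Optional

from . import records as rec
from .hashchain import (
    ChainLink,
    DeviceState,
    SecureString,
    init_device,
    next_hash,
    random_secure_string,
    sign_record,
)
from .ledger import order_and_commit
from .records import AIS_MAX, HealthRecord, TrialConfig, canonicalize, parse_record
from .relay import (
    DispatchPlan,
    Network,
    RelayServer,
    Submission,
    authenticate,
    build_network,
    dispatch,
    select_relays,
)

__all__ = [
    "Scenario",
    "AttackSpec",
    "RunConfig",
    "SimulationState",
    "run_trial",
    "reveal_secret",
    "reveal_all_secrets",
    "DuplicateReveal",
    "StudyNotEnded",
]


class Scenario(str, Enum):
    RELAY = "RELAY"
    AUTH_SERVER = "AUTH_SERVER"
    CLIENT_DEVICE = "CLIENT_DEVICE"


@dataclass(frozen=True)
class AttackSpec:
    """One declarative fraud scenario (a single manipulation by default).

    ``target`` is the hacked relay id for RELAY, the victim account id
    otherwise. ``account_id`` names the victim account whose record a hacked
    relay rewrites (RELAY only; defaults to the first account).
    ``record_index`` is the 0-based index of the attacked record within the
    account's chain; ``None`` means every record of the account (used for
    stress tests; the deployed scenarios manipulate exactly one).
    """

    scenario: Scenario
    target: str
    account_id: Optional[str] = None
    record_index: Optional[int] = 0
    mutation: str = "ais_total"
    rng_seed: int = 0


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one reproducible run (deployed defaults)."""

    trial: TrialConfig
    n_relays: int = 3
    fanout_k: int = 2
    n_orgs: int = 3
    peers_per_org: int = 2
    threshold: int = 2
    max_block_txs: int = 10

    @property
    def seed(self) -> int:
        return self.trial.rng_seed


@dataclass
class SimulationState:
    """Everything a run produced: network, relays, devices, chains, records."""

    config: RunConfig
    network: Network
    relays: dict[str, RelayServer]
    devices: dict[str, DeviceState]
    tokens: dict[str, str]
    chains: dict[str, list[ChainLink]] = field(default_factory=dict)
    trial_records: dict[str, list[HealthRecord]] = field(default_factory=dict)
    study_ended: bool = False
    revealed: set[str] = field(default_factory=set)
    attack: Optional[AttackSpec] = None


class DuplicateReveal(RuntimeError):
    pass


class StudyNotEnded(RuntimeError):
    pass


def _mutate_record(record: HealthRecord) -> HealthRecord:
    """The attacker's payload edit: shift the insomnia score (always changes)."""
    return record.replace(ais_total=(record.ais_total + 7) % (AIS_MAX + 1))


def _relay_hook(spec: AttackSpec, victim: str, attacker_secret: SecureString):
    """Mutation hook for a hacked relay: rewrite bytes, re-hash with a wrong string."""

    def hook(sub: Submission) -> Submission:
        if sub.account_id != victim:
            return sub
        if spec.record_index is not None and sub.link.seq != spec.record_index + 1:
            return sub
        mutated = _mutate_record(parse_record(sub.link.record_bytes))
        mb = canonicalize(mutated)
        link = ChainLink(
            seq=sub.link.seq,
            record_bytes=mb,
            client_hash=next_hash(sub.link.prev_hash, mb, attacker_secret),
            prev_hash=sub.link.prev_hash,
        )
        return replace(sub, link=link)

    return hook


def run_trial(config: RunConfig, attack: Optional[AttackSpec] = None,
              reveal: bool = True) -> SimulationState:
    """Execute one full study; a pure function of (config, attack).

    Records are signed on each device in order, dispatched to ``fanout_k`` of
    ``n_relays`` randomly chosen relays, endorsed, and committed into blocks
    once per study day. If an attack is given it is injected at the targeted
    record. With ``reveal`` the devices send their secure strings at study end.
    """
    seed = config.seed
    network, relays = build_network(
        seed, n_orgs=config.n_orgs, peers_per_org=config.peers_per_org,
        threshold=config.threshold, n_relays=config.n_relays,
        max_block_txs=config.max_block_txs,
    )
    trial = rec.generate_trial(config.trial)
    pool = sorted(relays)

    devices: dict[str, DeviceState] = {}
    tokens: dict[str, str] = {}
    keys: dict[str, str] = {}
    for account_id, _ in trial:
        keys[account_id] = network.auth.register(account_id)
        network.authorized_clients.add(account_id)
        dev = init_device(account_id, rng=random.Random(f"{seed}:device:{account_id}"))
        devices[account_id] = dev
        tokens[account_id] = authenticate(network.auth, account_id,
                                          keys[account_id], dev.device_id)

    state = SimulationState(config=config, network=network, relays=relays,
                            devices=devices, tokens=tokens, attack=attack,
                            trial_records={a: list(r) for a, r in trial})
    for account_id, _ in trial:
        state.chains[account_id] = []

    attacker_rng = random.Random(f"{attack.rng_seed}:attacker") if attack else None
    attacker_secret = random_secure_string(attacker_rng) if attacker_rng else None

    victim = None
    if attack is not None:
        if attack.scenario is Scenario.RELAY:
            if attack.target not in relays:
                raise ValueError(f"unknown relay {attack.target!r}")
            victim = attack.account_id or (trial[0][0] if trial else None)
            if victim not in devices:
                raise ValueError(f"unknown account {victim!r}")
            hacked = relays[attack.target]
            hacked.compromised = True
            hacked.mutation_hook = _relay_hook(attack, victim, attacker_secret)
        else:
            victim = attack.target
            if victim not in devices:
                raise ValueError(f"unknown account {victim!r}")

    dispatch_rng = random.Random(f"{seed}:dispatch")
    n_days = config.trial.n_days
    per_day = config.trial.records_per_day

    for day in range(n_days):
        for account_id, account_records in trial:
            for slot in range(per_day):
                idx = day * per_day + slot
                record = account_records[idx]
                dev = devices[account_id]
                link, devices[account_id] = sign_record(dev, record)
                state.chains[account_id].append(link)
                plan = select_relays(pool, config.fanout_k, dispatch_rng,
                                     seq=record.seq)
                if (attack is not None and attack.scenario is Scenario.RELAY
                        and account_id == victim
                        and (attack.record_index is None
                             or idx == attack.record_index)
                        and attack.target not in plan.chosen_relays):
                    # the scenario presumes the attacked data passed through
                    # the hacked relay; force it onto the path
                    others = [r for r in pool if r != attack.target]
                    keep = dispatch_rng.sample(others, config.fanout_k - 1)
                    plan = DispatchPlan(seq=record.seq,
                                        chosen_relays=(attack.target, *keep))
                submitted_at = rec._ts(record.rise_time + timedelta(minutes=5))
                dispatch(link, record.log_id, account_id, dev.device_id,
                         tokens[account_id], plan, relays, network, submitted_at)

                if (attack is not None
                        and attack.scenario in (Scenario.AUTH_SERVER,
                                                Scenario.CLIENT_DEVICE)
                        and account_id == victim
                        and (attack.record_index is None
                             or idx == attack.record_index)):
                    _forge_branch(state, attack, record, link, keys[victim],
                                  attacker_secret, attacker_rng, pool)

        if network.pending:
            order_and_commit(network.pending, network.ledger,
                             config.max_block_txs)
            network.pending.clear()

    state.study_ended = True
    if reveal:
        reveal_all_secrets(state)
    return state


def _forge_branch(state: SimulationState, attack: AttackSpec,
                  record: HealthRecord, honest_link: ChainLink, stolen_key: str,
                  attacker_secret: SecureString, attacker_rng: random.Random,
                  pool: list[str]) -> None:
    """Impersonation branch: a second device reuses the record's log ID.

    AUTH_SERVER hashes the forged record under an attacker string;
    CLIENT_DEVICE under the stolen true secret.
    """
    victim = attack.target
    device_id = f"{victim}-attacker-device"
    token = authenticate(state.network.auth, victim, stolen_key, device_id)
    forged = _mutate_record(record)  # same seq and log_id: a branch, not a new link
    fb = canonicalize(forged)
    if attack.scenario is Scenario.CLIENT_DEVICE:
        secret = state.devices[victim].secure
    else:
        secret = attacker_secret
    link = ChainLink(
        seq=forged.seq,
        record_bytes=fb,
        client_hash=next_hash(honest_link.prev_hash, fb, secret),
        prev_hash=honest_link.prev_hash,
    )
    plan = select_relays(pool, state.config.fanout_k, attacker_rng,
                         seq=forged.seq)
    submitted_at = rec._ts(record.rise_time + timedelta(minutes=25))
    dispatch(link, forged.log_id, victim, device_id, token, plan,
             state.relays, state.network, submitted_at)


def reveal_secret(state: SimulationState, account_id: str) -> None:
    """Send one device's secure string to the ledger via the relay path."""
    if not state.study_ended:
        raise StudyNotEnded("secrets are revealed only after study end")
    if account_id in state.revealed:
        raise DuplicateReveal(f"DUPLICATE: secret for {account_id} already revealed")
    dev = state.devices[account_id]
    pool = sorted(state.relays)
    rng = random.Random(f"{state.config.seed}:reveal:{account_id}")
    plan = select_relays(pool, state.config.fanout_k, rng)
    last_day = state.config.trial.start_date + timedelta(days=state.config.trial.n_days + 1)
    submitted_at = f"{last_day.isoformat()}T12:00:00Z"
    for rid in plan.chosen_relays:
        state.relays[rid].forward_secret(
            account_id, dev.device_id, dev.secure.value,
            state.tokens[account_id], submitted_at, state.network)
    state.revealed.add(account_id)
    if state.network.pending:
        order_and_commit(state.network.pending, state.network.ledger,
                         state.config.max_block_txs)
        state.network.pending.clear()


def reveal_all_secrets(state: SimulationState) -> None:
    for account_id in sorted(state.devices):
        reveal_secret(state, account_id)
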