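"""Fraud detection and resolution over the committed ledger.

Two detectors run over the full commit history (not just the latest state):

* **Relay mismatch** — one device submission travels over two relays, so its
  committed copies must be byte-identical; copies that differ expose a relay
  that rewrote data in flight.
* **Branch** — two different devices committing records that claim the same
  log ID, or the same predecessor digest, fork one account's chain; this is
  the signature of impersonation with a stolen authentication key.

Resolution then re-verifies every implicated candidate against the account's
revealed secure string: a candidate whose client hash recomputes under the
true secret was produced by the secret holder. Exactly one verifying
candidate → the fraud is resolved automatically; two or more verifying
candidates (the root-exploit case, where the secret itself was stolen) →
``BRANCH_UNRESOLVED``, flagging the offline device check that only a human
can perform.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .hashchain import ChainLink, SecureString, verify_link
from .ledger import Capability, LedgerState, iter_committed_payloads, read_state
from .simulation import (  # re-exported: attack plumbing lives with the run loop
    AttackSpec,
    Scenario,
    SimulationState,
    reveal_secret,
    run_trial,
)

__all__ = [
    "AttackSpec",
    "Scenario",
    "FraudKind",
    "Classification",
    "FraudEvent",
    "AuditReport",
    "AUDITOR_CAPABILITY",
    "simulate_attack",
    "reveal_secret",
    "detect_mismatches",
    "detect_branches",
    "revealed_secrets",
    "resolve",
    "run_audit",
]

#: auditors may read the state database; relays may not
AUDITOR_CAPABILITY = Capability(name="auditor", can_read=True, can_write=False)


class FraudKind(str, Enum):
    RELAY_MISMATCH = "RELAY_MISMATCH"
    BRANCH = "BRANCH"


class Classification(str, Enum):
    VALID = "VALID"
    TAMPERED_REJECTED = "TAMPERED_REJECTED"
    BRANCH_RESOLVED_LEGAL = "BRANCH_RESOLVED_LEGAL"
    BRANCH_REJECTED_ILLEGAL = "BRANCH_REJECTED_ILLEGAL"
    BRANCH_UNRESOLVED = "BRANCH_UNRESOLVED"
    UNVERIFIABLE = "UNVERIFIABLE"


@dataclass(frozen=True)
class FraudEvent:
    """One detected fraud: the implicated candidate groups of committed payloads.

    ``candidates`` is a tuple of groups; each group is a tuple of tx_ids whose
    payloads carry identical (record_bytes, client_hash, prev_hash) content.
    A RELAY_MISMATCH references exactly two differing copies; a BRANCH
    references at least two candidate contents.
    """

    kind: FraudKind
    account_id: str
    seq: int
    log_id: str
    candidates: tuple[tuple[str, ...], ...]

    def to_json(self) -> dict:
        return {
            "kind": self.kind.value,
            "account_id": self.account_id,
            "seq": self.seq,
            "log_id": self.log_id,
            "candidates": [list(g) for g in self.candidates],
        }


@dataclass(frozen=True)
class AuditReport:
    """Detected events plus one legality classification per committed payload."""

    events: tuple[FraudEvent, ...]
    classification: dict[str, Classification]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.classification.values():
            out[c.value] = out.get(c.value, 0) + 1
        return out

    def to_json(self) -> dict:
        return {
            "events": [e.to_json() for e in self.events],
            "classification": {k: v.value for k, v in
                               sorted(self.classification.items())},
            "summary": dict(sorted(self.counts().items())),
        }


def simulate_attack(config, spec: AttackSpec) -> SimulationState:
    """Run the full study with one fraud scenario injected."""
    return run_trial(config, attack=spec)


def _content(payload: dict) -> tuple[bytes, str, str]:
    return payload["record_bytes"], payload["client_hash"], payload["prev_hash"]


def _record_payloads(ledger: LedgerState) -> list[tuple[str, dict]]:
    return [(t, p) for t, p in iter_committed_payloads(ledger)
            if p["type"] == "record"]


def detect_mismatches(ledger: LedgerState) -> list[FraudEvent]:
    """Relay-copy comparison: one device submission must be byte-identical
    across the relays it was sent to."""
    groups: dict[tuple[str, int, str], list[tuple[str, dict]]] = {}
    for tx_id, p in _record_payloads(ledger):
        groups.setdefault((p["account_id"], p["seq"], p["device_id"]), []).append((tx_id, p))
    events = []
    for (account, seq, _device), members in sorted(groups.items()):
        by_content: dict[tuple, list[str]] = {}
        for tx_id, p in members:
            by_content.setdefault(_content(p), []).append(tx_id)
        if len(by_content) >= 2:
            events.append(FraudEvent(
                kind=FraudKind.RELAY_MISMATCH,
                account_id=account,
                seq=seq,
                log_id=members[0][1]["log_id"],
                candidates=tuple(tuple(v) for _, v in sorted(by_content.items())),
            ))
    return events


def detect_branches(ledger: LedgerState) -> list[FraudEvent]:
    """Fork detection: distinct devices claiming one log ID or one predecessor.

    Groups are formed per (account, log_id) and per (account, claimed
    prev_hash); a group spanning at least two devices with at least two
    distinct contents is a branch. A fork usually collides on both keys, so
    events implicating the same candidate set are reported once.
    """
    by_log: dict[tuple[str, str], list[tuple[str, dict]]] = {}
    by_prev: dict[tuple[str, str], list[tuple[str, dict]]] = {}
    for tx_id, p in _record_payloads(ledger):
        by_log.setdefault((p["account_id"], p["log_id"]), []).append((tx_id, p))
        by_prev.setdefault((p["account_id"], p["prev_hash"]), []).append((tx_id, p))

    events: list[FraudEvent] = []
    seen: set[frozenset] = set()
    for grouping in (by_log, by_prev):
        for (account, _key), members in sorted(grouping.items()):
            devices = {p["device_id"] for _, p in members}
            by_content: dict[tuple, list[str]] = {}
            for tx_id, p in members:
                by_content.setdefault(_content(p), []).append(tx_id)
            if len(devices) < 2 or len(by_content) < 2:
                continue
            fingerprint = frozenset(tx for _, v in by_content.items() for tx in v)
            if fingerprint in seen:
                continue
            seen.add(fingerprint)
            events.append(FraudEvent(
                kind=FraudKind.BRANCH,
                account_id=account,
                seq=members[0][1]["seq"],
                log_id=members[0][1]["log_id"],
                candidates=tuple(tuple(v) for _, v in sorted(by_content.items())),
            ))
    return events


def revealed_secrets(ledger: LedgerState) -> dict[str, SecureString]:
    """Secure strings committed via end-of-study reveal transactions."""
    state = read_state(ledger, AUDITOR_CAPABILITY)
    out = {}
    for key, payload in state.items():
        if key.startswith("secret::"):
            out[payload["account_id"]] = SecureString(payload["secure"])
    return out


def _verifies(payload: dict, secret: SecureString) -> bool:
    link = ChainLink(seq=payload["seq"], record_bytes=payload["record_bytes"],
                     client_hash=payload["client_hash"],
                     prev_hash=payload["prev_hash"])
    return verify_link(link, secret)


def resolve(ledger: LedgerState, events: list[FraudEvent],
            secrets: Optional[dict[str, SecureString]] = None) -> AuditReport:
    """Classify every committed record payload using the revealed secrets.

    Implicated candidates are re-verified under the account's secret; exactly
    one verifying candidate resolves the fraud automatically, two or more
    leave the branch unresolved (offline device check required). Accounts
    whose secret was never revealed are UNVERIFIABLE throughout.
    """
    if secrets is None:
        secrets = revealed_secrets(ledger)
    payloads = dict(_record_payloads(ledger))
    classification: dict[str, Classification] = {}

    for event in events:
        secret = secrets.get(event.account_id)
        if secret is None:
            for group in event.candidates:
                for tx in group:
                    classification[tx] = Classification.UNVERIFIABLE
            continue
        verdicts = [(_verifies(payloads[group[0]], secret), group)
                    for group in event.candidates]
        n_ok = sum(1 for ok, _ in verdicts if ok)
        for ok, group in verdicts:
            if event.kind is FraudKind.RELAY_MISMATCH:
                status = Classification.VALID if ok else Classification.TAMPERED_REJECTED
            elif n_ok >= 2:
                status = Classification.BRANCH_UNRESOLVED
            elif ok:
                status = Classification.BRANCH_RESOLVED_LEGAL
            else:
                status = Classification.BRANCH_REJECTED_ILLEGAL
            for tx in group:
                classification.setdefault(tx, status)

    for tx_id, payload in payloads.items():
        if tx_id in classification:
            continue
        secret = secrets.get(payload["account_id"])
        if secret is None:
            classification[tx_id] = Classification.UNVERIFIABLE
        elif _verifies(payload, secret):
            classification[tx_id] = Classification.VALID
        else:
            classification[tx_id] = Classification.TAMPERED_REJECTED

    return AuditReport(events=tuple(events), classification=classification)


def run_audit(ledger: LedgerState) -> AuditReport:
    """Detect mismatches and branches, then resolve with the revealed secrets."""
    events = detect_mismatches(ledger) + detect_branches(ledger)
    return resolve(ledger, events)
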