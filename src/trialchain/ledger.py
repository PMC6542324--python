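"""Permissioned-ledger simulation: endorsement, ordering, hash-linked blocks.

Models a small consortium network in-process: organizations each run endorsing
peers and hold a keyed-MAC endorsement key. A transaction goes through the
five-step lifecycle — proposal, endorse (four checks: well-formed, not a
replay, valid client signature, authorized client), submit against the
endorsement policy, ordering into chronological blocks, commit. Blocks are
hash-linked (each block hashes its transactions and the previous block hash),
and a key-value state database holds the latest committed payload per
(account, seq, relay) key. The default network mirrors the deployed one:
three organizations, two peers each, 2-of-3 endorsement.
"""

from __future__ import annotations

import hashlib
import hmac
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

from .hashchain import GENESIS_HASH

__all__ = [
    "Organization",
    "Transaction",
    "Block",
    "EndorsementPolicy",
    "LedgerState",
    "Capability",
    "EndorseFailure",
    "Endorsement",
    "ReadForbidden",
    "tx_id_for",
    "make_transaction",
    "endorse",
    "sign_endorsement",
    "verify_endorsement",
    "submit",
    "order_and_commit",
    "verify_ledger",
    "read_state",
    "state_key",
    "serialize_blocks",
    "ledger_to_json",
    "ledger_from_json",
    "new_ledger",
    "iter_committed_payloads",
]

_SEP = b"\x1f"

#: payload keys every record transaction must carry to be well formed
_RECORD_PAYLOAD_KEYS = frozenset(
    {"type", "account_id", "seq", "log_id", "record_bytes", "client_hash",
     "prev_hash", "relay_id", "device_id", "submitted_at"}
)
_SECRET_PAYLOAD_KEYS = frozenset(
    {"type", "account_id", "secure", "relay_id", "device_id", "submitted_at"}
)


class EndorseFailure(str, Enum):
    MALFORMED = "MALFORMED"
    DUPLICATE = "DUPLICATE"
    BAD_SIGNATURE = "BAD_SIGNATURE"
    UNAUTHORIZED = "UNAUTHORIZED"


class ReadForbidden(PermissionError):
    """Raised when a write-only capability attempts to read the state database."""


@dataclass(frozen=True)
class Organization:
    """A consortium member: endorsement key shared by its validating peers."""

    org_id: str
    endorsement_key: bytes
    n_peers: int = 2


@dataclass(frozen=True)
class Endorsement:
    org_id: str
    signature: str


@dataclass(frozen=True)
class EndorsementPolicy:
    """Threshold of distinct-organization signatures required to commit."""

    threshold: int = 2
    n_orgs: int = 3

    def __post_init__(self) -> None:
        if not 1 <= self.threshold <= self.n_orgs:
            raise ValueError("threshold must satisfy 1 <= threshold <= n_orgs")


@dataclass(frozen=True)
class Capability:
    """Ledger access handle; relays get write-only, auditors read-write."""

    name: str
    can_read: bool
    can_write: bool


@dataclass(frozen=True)
class Transaction:
    tx_id: str
    payload: dict
    client_signature: dict
    endorsements: tuple[Endorsement, ...] = ()


@dataclass(frozen=True)
class Block:
    index: int
    prev_block_hash: str
    tx_list: tuple[Transaction, ...]
    payload_hash: str
    timestamp: str
    block_hash: str


@dataclass
class LedgerState:
    """Append-only blocks plus the latest-payload key-value state."""

    blocks: list[Block] = field(default_factory=list)
    state: dict[str, dict] = field(default_factory=dict)
    committed_tx_ids: set[str] = field(default_factory=set)


def canonical_payload_bytes(payload: dict) -> bytes:
    # surrogateescape keeps hashing total and injective even for payloads whose
    # record bytes are not valid UTF-8 (e.g. under tamper testing)
    enc = dict(payload)
    if isinstance(enc.get("record_bytes"), (bytes, bytearray)):
        enc["record_bytes"] = bytes(enc["record_bytes"]).decode("utf-8", "surrogateescape")
    return json.dumps(enc, sort_keys=True, separators=(",", ":"),
                      ensure_ascii=False).encode("utf-8", "surrogateescape")


def tx_id_for(payload: dict) -> str:
    return hashlib.sha256(canonical_payload_bytes(payload)).hexdigest()


def make_transaction(payload: dict, client_signature: dict) -> Transaction:
    return Transaction(tx_id=tx_id_for(payload), payload=payload,
                       client_signature=client_signature)


def sign_endorsement(org: Organization, tx_id: str) -> Endorsement:
    sig = hmac.new(org.endorsement_key, tx_id.encode("utf-8"), hashlib.sha256).hexdigest()
    return Endorsement(org_id=org.org_id, signature=sig)


def verify_endorsement(org: Organization, tx_id: str, endorsement: Endorsement) -> bool:
    expected = hmac.new(org.endorsement_key, tx_id.encode("utf-8"), hashlib.sha256).hexdigest()
    return endorsement.org_id == org.org_id and hmac.compare_digest(expected, endorsement.signature)


def _well_formed(tx: Transaction) -> bool:
    if not isinstance(tx.payload, dict):
        return False
    kind = tx.payload.get("type")
    required = {"record": _RECORD_PAYLOAD_KEYS, "secret_reveal": _SECRET_PAYLOAD_KEYS}.get(kind)
    if required is None or set(tx.payload) != required:
        return False
    return tx.tx_id == tx_id_for(tx.payload)


def endorse(tx: Transaction, org: Organization, ledger: LedgerState,
            authorized_clients: set[str],
            verify_client_signature=None) -> Endorsement | EndorseFailure:
    """Run the endorser's four checks in order; one signature per organization.

    Checks: (1) the proposal is well formed, (2) it is not a replay of a
    committed transaction, (3) the client signature is valid, (4) the client
    account is authorized. ``verify_client_signature(tx) -> bool`` is supplied
    by the network (it delegates to the authentication server); when omitted
    the signature check is skipped-as-valid.
    """
    if not _well_formed(tx):
        return EndorseFailure.MALFORMED
    if tx.tx_id in ledger.committed_tx_ids:
        return EndorseFailure.DUPLICATE
    if verify_client_signature is not None and not verify_client_signature(tx):
        return EndorseFailure.BAD_SIGNATURE
    if tx.payload.get("account_id") not in authorized_clients:
        return EndorseFailure.UNAUTHORIZED
    return sign_endorsement(org, tx.tx_id)


def submit(tx: Transaction, endorsements: Sequence[Endorsement],
           policy: EndorsementPolicy,
           orgs: Sequence[Organization]) -> Transaction | EndorseFailure:
    """Client-side policy check before handing off to the ordering service.

    Accepts iff the number of *valid* signatures from *distinct* organizations
    reaches the policy threshold; returns the endorsed transaction, or the
    refusal reason POLICY_UNSATISFIED (spelled via ValueError-free sentinel).
    """
    by_id = {o.org_id: o for o in orgs}
    valid_orgs: set[str] = set()
    for e in endorsements:
        org = by_id.get(e.org_id)
        if org is not None and verify_endorsement(org, tx.tx_id, e):
            valid_orgs.add(e.org_id)
    if len(valid_orgs) < policy.threshold:
        return POLICY_UNSATISFIED
    kept = tuple(e for e in endorsements if e.org_id in valid_orgs)
    return Transaction(tx_id=tx.tx_id, payload=tx.payload,
                       client_signature=tx.client_signature, endorsements=kept)


class _PolicyUnsatisfied(str, Enum):
    POLICY_UNSATISFIED = "POLICY_UNSATISFIED"


POLICY_UNSATISFIED = _PolicyUnsatisfied.POLICY_UNSATISFIED


def _payload_hash(tx_ids: Sequence[str]) -> str:
    h = hashlib.sha256()
    for i, t in enumerate(tx_ids):
        if i:
            h.update(_SEP)
        h.update(t.encode("utf-8"))
    return h.hexdigest()


def _block_hash(index: int, prev_block_hash: str, payload_hash: str, timestamp: str) -> str:
    h = hashlib.sha256()
    h.update(str(index).encode("utf-8"))
    h.update(_SEP)
    h.update(prev_block_hash.encode("utf-8"))
    h.update(_SEP)
    h.update(payload_hash.encode("utf-8"))
    h.update(_SEP)
    h.update(timestamp.encode("utf-8"))
    return h.hexdigest()


def _make_block(index: int, prev: str, txs: Sequence[Transaction], timestamp: str) -> Block:
    ph = _payload_hash([t.tx_id for t in txs])
    return Block(index=index, prev_block_hash=prev, tx_list=tuple(txs),
                 payload_hash=ph, timestamp=timestamp,
                 block_hash=_block_hash(index, prev, ph, timestamp))


GENESIS_TIMESTAMP = "1970-01-01T00:00:00Z"


def new_ledger() -> LedgerState:
    """Fresh ledger containing only the (empty) genesis block."""
    genesis = _make_block(0, GENESIS_HASH, (), GENESIS_TIMESTAMP)
    return LedgerState(blocks=[genesis])


def state_key(payload: dict) -> str:
    """State-database key: both relay copies of one record coexist."""
    if payload["type"] == "secret_reveal":
        return f"secret::{payload['account_id']}"
    return (f"record::{payload['account_id']}::{int(payload['seq']):06d}"
            f"::{payload['relay_id']}::{payload['device_id']}")


def order_and_commit(pending: Sequence[Transaction], ledger: LedgerState,
                     max_block_txs: int = 10) -> LedgerState:
    """Ordering service + commit: chronological sort, batch, hash-link, apply.

    Transactions are sorted by (submitted_at, tx_id) — the digest breaks
    timestamp ties deterministically — and batched into blocks of at most
    ``max_block_txs``. Existing blocks are never touched (append-only).
    """
    if max_block_txs < 1:
        raise ValueError("max_block_txs must be >= 1")
    ordered = sorted(pending, key=lambda t: (t.payload["submitted_at"], t.tx_id))
    for start in range(0, len(ordered), max_block_txs):
        batch = ordered[start:start + max_block_txs]
        prev = ledger.blocks[-1].block_hash
        ts = batch[-1].payload["submitted_at"]
        block = _make_block(len(ledger.blocks), prev, batch, ts)
        ledger.blocks.append(block)
        for tx in batch:
            ledger.state[state_key(tx.payload)] = tx.payload
            ledger.committed_tx_ids.add(tx.tx_id)
    return ledger


def verify_ledger(ledger: LedgerState) -> tuple[bool, Optional[int]]:
    """Recompute every block hash and check the chain; (ok, first broken index)."""
    prev = GENESIS_HASH
    for block in ledger.blocks:
        if block.prev_block_hash != prev:
            return False, block.index
        ph = _payload_hash([t.tx_id for t in block.tx_list])
        if ph != block.payload_hash:
            return False, block.index
        for t in block.tx_list:
            if t.tx_id != tx_id_for(t.payload):
                return False, block.index
        bh = _block_hash(block.index, block.prev_block_hash, block.payload_hash,
                         block.timestamp)
        if bh != block.block_hash:
            return False, block.index
        prev = block.block_hash
    return True, None


def read_state(ledger: LedgerState, capability: Capability) -> dict[str, dict]:
    """Read the committed key-value state; refused for write-only capabilities."""
    if not capability.can_read:
        raise ReadForbidden(f"capability {capability.name!r} is write-only: READ_FORBIDDEN")
    return dict(ledger.state)


def iter_committed_payloads(ledger: LedgerState) -> Iterator[tuple[str, dict]]:
    """All committed (tx_id, payload) pairs in commit order, from the blocks.

    The state database keeps only the latest payload per key; the audit walks
    the blocks so that overwritten history remains visible.
    """
    for block in ledger.blocks:
        for tx in block.tx_list:
            yield tx.tx_id, tx.payload


# ---------------------------------------------------------------------------
# serialization

def _tx_to_json(tx: Transaction) -> dict:
    p = dict(tx.payload)
    if isinstance(p.get("record_bytes"), (bytes, bytearray)):
        p["record_bytes"] = p["record_bytes"].decode("utf-8")
    return {
        "tx_id": tx.tx_id,
        "payload": p,
        "client_signature": tx.client_signature,
        "endorsements": [{"org_id": e.org_id, "signature": e.signature}
                         for e in tx.endorsements],
    }


def _tx_from_json(doc: dict) -> Transaction:
    p = dict(doc["payload"])
    if isinstance(p.get("record_bytes"), str):
        p["record_bytes"] = p["record_bytes"].encode("utf-8")
    return Transaction(
        tx_id=doc["tx_id"], payload=p, client_signature=doc["client_signature"],
        endorsements=tuple(Endorsement(e["org_id"], e["signature"])
                           for e in doc["endorsements"]),
    )


def _block_to_json(block: Block) -> dict:
    return {
        "index": block.index,
        "prev_block_hash": block.prev_block_hash,
        "tx_list": [_tx_to_json(t) for t in block.tx_list],
        "payload_hash": block.payload_hash,
        "timestamp": block.timestamp,
        "block_hash": block.block_hash,
    }


def _block_from_json(doc: dict) -> Block:
    return Block(
        index=doc["index"], prev_block_hash=doc["prev_block_hash"],
        tx_list=tuple(_tx_from_json(t) for t in doc["tx_list"]),
        payload_hash=doc["payload_hash"], timestamp=doc["timestamp"],
        block_hash=doc["block_hash"],
    )


def serialize_blocks(ledger: LedgerState) -> bytes:
    """One JSON line per block; commits only ever append lines (prefix property)."""
    return b"".join(
        json.dumps(_block_to_json(b), sort_keys=True, separators=(",", ":")).encode("utf-8") + b"\n"
        for b in ledger.blocks
    )


def ledger_to_json(ledger: LedgerState) -> dict:
    state = {}
    for k, p in ledger.state.items():
        p = dict(p)
        if isinstance(p.get("record_bytes"), (bytes, bytearray)):
            p["record_bytes"] = p["record_bytes"].decode("utf-8")
        state[k] = p
    return {"blocks": [_block_to_json(b) for b in ledger.blocks], "state": state}


def ledger_from_json(doc: dict) -> LedgerState:
    blocks = [_block_from_json(b) for b in doc["blocks"]]
    ledger = LedgerState(blocks=blocks)
    for block in blocks:
        for tx in block.tx_list:
            ledger.state[state_key(tx.payload)] = tx.payload
            ledger.committed_tx_ids.add(tx.tx_id)
    return ledger
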