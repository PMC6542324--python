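"""Authentication server, relay servers and random multi-relay dispatch.

Clients never talk to the ledger directly. A single common authentication
server issues tokens bound to one (account, device) pair; the app then picks
k of the n relay servers uniformly at random (deployed configuration: 2 of 3)
and sends the signed record to each. Every relay holds a *write-only* ledger
capability — it can forward transactions but can never read the state
database — and an honest relay forwards payloads byte-identically. Because
each record travels over two independently chosen relays, a single hacked
relay that rewrites data in flight produces two differing committed copies,
which is exactly the evidence the audit looks for.
"""

from __future__ import annotations

import hashlib
import hmac
import json
import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .hashchain import ChainLink
from .ledger import (
    Capability,
    EndorseFailure,
    EndorsementPolicy,
    LedgerState,
    Organization,
    Transaction,
    endorse,
    make_transaction,
    new_ledger,
    submit,
    POLICY_UNSATISFIED,
)

__all__ = [
    "AuthError",
    "AuthServer",
    "RelayServer",
    "DispatchPlan",
    "Network",
    "Submission",
    "authenticate",
    "select_relays",
    "client_sign",
    "dispatch",
    "build_network",
]


class AuthError(Exception):
    """Authentication failure; .reason is AUTH_FAILED or UNKNOWN_ACCOUNT."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class AuthServer:
    """Single common authentication server.

    Holds each account's authentication key and the tokens it has issued;
    a token authenticates exactly one (account, device) pair.
    """

    rng: random.Random
    accounts: dict[str, str] = field(default_factory=dict)
    issued_tokens: dict[str, tuple[str, str]] = field(default_factory=dict)

    def register(self, account_id: str) -> str:
        key = f"{self.rng.getrandbits(256):064x}"
        self.accounts[account_id] = key
        return key

    def verify_token(self, token: str, account_id: str, device_id: str) -> bool:
        return self.issued_tokens.get(token) == (account_id, device_id)


def authenticate(auth: AuthServer, account_id: str, credential: str,
                 device_id: str) -> str:
    """Issue a fresh token for a (account, device) pair given the right key.

    A stolen authentication key yields a second valid token for the same
    account from a different device — the impersonation path of the
    authentication-server attack.
    """
    key = auth.accounts.get(account_id)
    if key is None:
        raise AuthError("UNKNOWN_ACCOUNT")
    if not hmac.compare_digest(key, credential):
        raise AuthError("AUTH_FAILED")
    token = f"{auth.rng.getrandbits(256):064x}"
    auth.issued_tokens[token] = (account_id, device_id)
    return token


@dataclass(frozen=True)
class DispatchPlan:
    """k distinct relays chosen for one record submission."""

    seq: int
    chosen_relays: tuple[str, ...]


def select_relays(pool: Sequence[str], k: int, rng: random.Random,
                  seq: int = 0) -> DispatchPlan:
    """Uniform sample of k distinct relays from the pool; seeded → deterministic."""
    if k > len(pool):
        raise ValueError(f"cannot select {k} relays from a pool of {len(pool)}")
    return DispatchPlan(seq=seq, chosen_relays=tuple(rng.sample(list(pool), k)))


def client_sign(token: str, record_bytes: bytes, client_hash: str,
                prev_hash: str) -> str:
    """Token-derived tag over the submission content."""
    msg = record_bytes + b"\x1f" + client_hash.encode() + b"\x1f" + prev_hash.encode()
    return hmac.new(token.encode("utf-8"), msg, hashlib.sha256).hexdigest()


@dataclass(frozen=True)
class Submission:
    """What a client hands to each chosen relay for one record."""

    account_id: str
    device_id: str
    link: ChainLink
    log_id: str
    token: str
    tag: str
    submitted_at: str


@dataclass
class Network:
    """The in-process blockchain network the relays write into."""

    orgs: list[Organization]
    policy: EndorsementPolicy
    ledger: LedgerState
    auth: AuthServer
    authorized_clients: set[str] = field(default_factory=set)
    pending: list[Transaction] = field(default_factory=list)
    max_block_txs: int = 10

    def verify_client_signature(self, tx: Transaction) -> bool:
        sig = tx.client_signature
        token = sig.get("token", "")
        p = tx.payload
        if not self.auth.verify_token(token, p.get("account_id", ""),
                                      p.get("device_id", "")):
            return False
        if p["type"] == "record":
            expected = client_sign(token, p["record_bytes"], p["client_hash"],
                                   p["prev_hash"])
        else:
            expected = hmac.new(token.encode(), p["secure"].encode(),
                                hashlib.sha256).hexdigest()
        return hmac.compare_digest(expected, sig.get("tag", ""))

    def propose(self, tx: Transaction):
        """Endorse at every organization, then the policy check; queue if accepted."""
        endorsements = []
        failures = []
        for org in self.orgs:
            res = endorse(tx, org, self.ledger, self.authorized_clients,
                          self.verify_client_signature)
            if isinstance(res, EndorseFailure):
                failures.append(res)
            else:
                endorsements.append(res)
        accepted = submit(tx, endorsements, self.policy, self.orgs)
        if accepted is POLICY_UNSATISFIED:
            return failures[0] if failures else POLICY_UNSATISFIED
        self.pending.append(accepted)
        return accepted


@dataclass
class RelayServer:
    """A relay: write-only forwarder; `compromised` activates its mutation hook."""

    relay_id: str
    capability: Capability
    compromised: bool = False
    mutation_hook: Optional[Callable[[Submission], Submission]] = None

    def forward(self, sub: Submission, network: Network):
        """Verify the token with the auth server, then propose the transaction.

        A compromised relay first applies its mutation hook and re-signs the
        (possibly rewritten) content with the stolen token.
        """
        if not network.auth.verify_token(sub.token, sub.account_id, sub.device_id):
            return EndorseFailure.UNAUTHORIZED
        if self.compromised and self.mutation_hook is not None:
            sub = self.mutation_hook(sub)
            sub = Submission(
                account_id=sub.account_id, device_id=sub.device_id, link=sub.link,
                log_id=sub.log_id, token=sub.token,
                tag=client_sign(sub.token, sub.link.record_bytes,
                                sub.link.client_hash, sub.link.prev_hash),
                submitted_at=sub.submitted_at,
            )
        payload = {
            "type": "record",
            "account_id": sub.account_id,
            "seq": sub.link.seq,
            "log_id": sub.log_id,
            "record_bytes": sub.link.record_bytes,
            "client_hash": sub.link.client_hash,
            "prev_hash": sub.link.prev_hash,
            "relay_id": self.relay_id,
            "device_id": sub.device_id,
            "submitted_at": sub.submitted_at,
        }
        tx = make_transaction(payload, {"token": sub.token, "tag": sub.tag})
        return network.propose(tx)

    def forward_secret(self, account_id: str, device_id: str, secure_hex: str,
                       token: str, submitted_at: str, network: Network):
        """Forward the end-of-study secret-reveal transaction."""
        if not network.auth.verify_token(token, account_id, device_id):
            return EndorseFailure.UNAUTHORIZED
        payload = {
            "type": "secret_reveal",
            "account_id": account_id,
            "secure": secure_hex,
            "relay_id": self.relay_id,
            "device_id": device_id,
            "submitted_at": submitted_at,
        }
        tag = hmac.new(token.encode(), secure_hex.encode(), hashlib.sha256).hexdigest()
        tx = make_transaction(payload, {"token": token, "tag": tag})
        return network.propose(tx)


def dispatch(link: ChainLink, record_log_id: str, account_id: str, device_id: str,
             token: str, plan: DispatchPlan, relays: dict[str, RelayServer],
             network: Network, submitted_at: str) -> list[tuple[str, object]]:
    """Send one signed record to every relay in the plan.

    Returns (relay_id, outcome) per chosen relay, where outcome is the endorsed
    transaction or a refusal reason. With an invalid token nothing is forwarded.
    """
    tag = client_sign(token, link.record_bytes, link.client_hash, link.prev_hash)
    sub = Submission(account_id=account_id, device_id=device_id, link=link,
                     log_id=record_log_id, token=token, tag=tag,
                     submitted_at=submitted_at)
    outcomes = []
    for rid in plan.chosen_relays:
        outcomes.append((rid, relays[rid].forward(sub, network)))
    return outcomes


def build_network(seed: int, n_orgs: int = 3, peers_per_org: int = 2,
                  threshold: int = 2, n_relays: int = 3,
                  max_block_txs: int = 10) -> tuple[Network, dict[str, RelayServer]]:
    """Assemble the deployed topology: orgs, policy, auth server and relay pool."""
    rng = random.Random(f"{seed}:network")
    orgs = [
        Organization(org_id=f"org-{i + 1}",
                     endorsement_key=rng.getrandbits(256).to_bytes(32, "big"),
                     n_peers=peers_per_org)
        for i in range(n_orgs)
    ]
    policy = EndorsementPolicy(threshold=threshold, n_orgs=n_orgs)
    auth = AuthServer(rng=random.Random(f"{seed}:auth"))
    network = Network(orgs=orgs, policy=policy, ledger=new_ledger(), auth=auth,
                      max_block_txs=max_block_txs)
    relays = {
        f"relay-{i + 1}": RelayServer(
            relay_id=f"relay-{i + 1}",
            capability=Capability(name=f"relay-{i + 1}", can_read=False, can_write=True),
        )
        for i in range(n_relays)
    }
    return network, relays
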