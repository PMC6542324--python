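"""Client hashchain: device secret, chained SHA-256 digests, verification.

Each client device holds a *secure string* — 256 random bits, hex-encoded —
that never leaves the device during the study (except via :func:`escrow_export`
to the user's own storage). Every record it submits is accompanied by

    client_hash = SHA-256(record_bytes | 0x1F | secure_string | 0x1F | prev_hash)

with the previous link's digest chained in, so the digests form a chain rooted
at a 64-zero genesis constant. After the study the secret is revealed and the
whole chain can be re-verified: a digest only recomputes correctly if it was
produced by the secret holder, which is what lets the audit reject impersonated
records retrospectively.
"""

from __future__ import annotations

import hashlib
import random
import secrets as _secrets
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

from .records import HealthRecord, canonicalize

__all__ = [
    "GENESIS_HASH",
    "SecureString",
    "DeviceState",
    "ChainLink",
    "VerifyStatus",
    "VerificationResult",
    "init_device",
    "random_secure_string",
    "next_hash",
    "sign_record",
    "verify_chain",
    "verify_link",
    "escrow_export",
]

#: prev_hash of the first link in every chain (blockchain genesis convention)
GENESIS_HASH = "0" * 64

_HEX = set("0123456789abcdef")
_SEP = b"\x1f"  # ASCII unit separator: prevents cross-field splicing


def _is_digest(s: str) -> bool:
    return isinstance(s, str) and len(s) == 64 and set(s) <= _HEX


@dataclass(frozen=True)
class SecureString:
    """Device-resident secret: 64 lowercase hex chars (256 bits)."""

    value: str

    def __post_init__(self) -> None:
        if not _is_digest(self.value):
            raise ValueError("secure string must be 64 lowercase hex characters")


@dataclass(frozen=True)
class DeviceState:
    """A client device: identity, secret, chain head and next sequence number."""

    account_id: str
    device_id: str
    secure: SecureString
    last_hash: str = GENESIS_HASH
    next_seq: int = 1


@dataclass(frozen=True)
class ChainLink:
    """One signed record: canonical bytes plus its chained digest."""

    seq: int
    record_bytes: bytes
    client_hash: str
    prev_hash: str


class VerifyStatus(str, Enum):
    VERIFIED = "VERIFIED"
    HASH_MISMATCH = "HASH_MISMATCH"
    LINK_BROKEN = "LINK_BROKEN"
    NO_SECRET = "NO_SECRET"


@dataclass(frozen=True)
class VerificationResult:
    seq: int
    status: VerifyStatus


def random_secure_string(rng: Optional[random.Random] = None) -> SecureString:
    """Fresh 256-bit hex secret; cryptographically strong unless an rng is given
    (seeded test/simulation mode)."""
    if rng is None:
        return SecureString(_secrets.token_hex(32))
    return SecureString(f"{rng.getrandbits(256):064x}")


def init_device(account_id: str, rng: Optional[random.Random] = None,
                device_id: Optional[str] = None,
                secure: Optional[SecureString] = None) -> DeviceState:
    """Set up a device at login: generate (or adopt) the secret, genesis head."""
    return DeviceState(
        account_id=account_id,
        device_id=device_id or f"{account_id}-device",
        secure=secure if secure is not None else random_secure_string(rng),
    )


def next_hash(prev_hash: str, record_bytes: bytes, secure: SecureString) -> str:
    """The chained digest over (record bytes, device secret, previous digest)."""
    if not _is_digest(prev_hash):
        raise ValueError("prev_hash must be a 64-char lowercase hex digest")
    h = hashlib.sha256()
    h.update(record_bytes)
    h.update(_SEP)
    h.update(secure.value.encode("utf-8"))
    h.update(_SEP)
    h.update(prev_hash.encode("utf-8"))
    return h.hexdigest()


def sign_record(device: DeviceState, record: HealthRecord) -> tuple[ChainLink, DeviceState]:
    """Sign the next record on a device, advancing the chain head.

    The honest device never skips or reorders: the record's seq must equal the
    device's next_seq and belong to the device's account.
    """
    if record.account_id != device.account_id:
        raise ValueError(
            f"record account {record.account_id!r} does not match device account "
            f"{device.account_id!r}"
        )
    if record.seq != device.next_seq:
        raise ValueError(
            f"out-of-order record: seq {record.seq} but device expects {device.next_seq}"
        )
    rb = canonicalize(record)
    digest = next_hash(device.last_hash, rb, device.secure)
    link = ChainLink(seq=record.seq, record_bytes=rb, client_hash=digest,
                     prev_hash=device.last_hash)
    new_device = replace(device, last_hash=digest, next_seq=device.next_seq + 1)
    return link, new_device


def verify_link(link: ChainLink, secure: SecureString) -> bool:
    """Does this link's digest recompute from its own stored fields and the secret?

    Because the secret is mixed into the digest, a positive answer proves the
    secret holder produced exactly these bytes after exactly this predecessor.
    """
    return next_hash(link.prev_hash, link.record_bytes, secure) == link.client_hash


def verify_chain(links: Sequence[ChainLink],
                 secure: Optional[SecureString]) -> list[VerificationResult]:
    """Retrospectively verify an ordered chain against the revealed secret.

    Per link: VERIFIED if the stored digest recomputes from the stored
    predecessor digest, record bytes and the secret — only the secret holder
    can produce such a digest, so a tampered link does not condemn its
    successors, which still verify against the predecessor digest they
    recorded at signing time. A failing link is LINK_BROKEN when its stored
    prev_hash additionally departs from the preceding link's stored digest
    (genesis for the first link) — the linkage itself was altered — and
    HASH_MISMATCH otherwise (content or digest altered).
    """
    if secure is None:
        return [VerificationResult(l.seq, VerifyStatus.NO_SECRET) for l in links]
    results: list[VerificationResult] = []
    structural_prev = GENESIS_HASH
    for link in links:
        if verify_link(link, secure):
            results.append(VerificationResult(link.seq, VerifyStatus.VERIFIED))
        elif link.prev_hash != structural_prev:
            results.append(VerificationResult(link.seq, VerifyStatus.LINK_BROKEN))
        else:
            results.append(VerificationResult(link.seq, VerifyStatus.HASH_MISMATCH))
        structural_prev = link.client_hash
    return results


def escrow_export(device: DeviceState) -> SecureString:
    """Copy of the secret for out-of-band escrow (e.g. the user's mailbox)."""
    return device.secure
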