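# Methods

## Overview

`trialchain` simulates, in one process, a data-integrity architecture for
mobile-health clinical trials: client devices sign their daily records into a
secret-keyed hashchain, submissions travel over randomly chosen relay servers
into a permissioned hash-linked ledger, and a retrospective audit classifies
every committed record as legal or illegal once the device secrets are
revealed. Nothing here talks to a real network, database or blockchain stack;
the point of the simulator is that the *logical* detection and resolution
guarantees can be tested deterministically and exhaustively.

## Record schema and canonical serialization

A `HealthRecord` is one day's entry for one account: Athens Insomnia Scale
(0–24), Epworth Sleepiness Scale (0–24) and Quick Inventory of Depressive
Symptomatology (0–27) totals; bed/sleep/wake/rise timestamps (ordered,
full datetimes so overnight wrap is unambiguous); Psychomotor Vigilance Test
reaction times (positive, milliseconds); and app-operation timestamps. The
app-operation timestamps are included in the hashed bytes — they are part of
the record, and covering them costs nothing while extending tamper evidence
to usage metadata.

Hashing requires a *canonical* byte form. The dialect is fixed as: JSON,
UTF-8, lexicographically sorted keys, `,`/`:` separators, integers unquoted,
timestamps as zero-padded ISO-8601 UTC strings at second resolution
(`YYYY-MM-DDTHH:MM:SSZ`). This makes serialization deterministic and
injective over valid records; the test suite pins one fully specified record
against a hand-written serialization and checks injectivity over 1,000
generated records.

## Synthetic trial generator

The generator emulates the structure of the study data, not sleep physiology:

* questionnaire totals uniform within their clinical ranges, with a mild
  downward drift of the insomnia score over study days (a plausible treatment
  effect; the audit logic is distribution-agnostic, so the drift only makes
  eyeballed output look sane);
* bed time 22:00–24:00, sleep latency 5–60 min, wake 05:30–08:00, rise within
  40 min of waking; ten PVT trials of 180–600 ms; three app operations after
  rising;
* `log_id = "<account>:<seq>:<8 hex chars>"`;
* one record per day by default (`records_per_day` is exposed because real
  app transactions occur several times per day).

Each account draws from its own seeded stream
(`Random(f"{seed}:{account_id}")`), so output is byte-identical across runs
and independent of patient-iteration order. Consequences for interpretation:
passing tests show the *pipeline's* integrity properties; they say nothing
about realism of score dynamics, missing-data patterns, or device clock
skew, none of which the detectors depend on.

## Client hashchain

Digest: `SHA-256(record_bytes ‖ 0x1F ‖ secret ‖ 0x1F ‖ prev_hash_hex)`, with
a 64-zero genesis. Field order and the 0x1F unit-separator are fixed to
prevent cross-field splicing ambiguity. The secret is 256 bits to match the
digest width; digests are lowercase hex strings throughout for JSON fidelity.

Verification after secret reveal is per link: a link is `VERIFIED` iff its
stored digest recomputes from its *own stored* predecessor digest, record
bytes and the secret. This is the cryptographically meaningful predicate —
only the secret holder can produce such a digest — and it deliberately does
not condemn the successors of a tampered link: they verify against the
predecessor digest they recorded at signing time. A failing link is
`LINK_BROKEN` when its stored `prev_hash` also departs from the preceding
link's stored digest (the linkage itself was altered; a structural check,
independent of the secret) and `HASH_MISMATCH` otherwise. With a wrong
secret an untampered chain therefore reports uniform `HASH_MISMATCH`, and in
the exhaustive single-mutation sweep exactly the mutated link fails.

## Ledger simulation

Organizations sign endorsements as HMAC-SHA256 tags over the transaction id —
the simulator needs verifiable per-org attestation, not a PKI. Peers within
an organization are replicas sharing the org key; peer count does not affect
endorsement counting (one signature per organization). The endorsement
policy defaults to 2-of-3: the deployed description is ambiguous between
2-of-3 and 3-of-3, and the majority reading is taken, with the threshold
configurable and both values covered by tests.

The ordering service sorts by `(submitted_at, tx_id)` — the digest breaks
timestamp ties deterministically — and batches into blocks of at most 10
transactions (configurable). `block_hash = SHA-256(index ‖ prev ‖
H(tx ids) ‖ timestamp)`; the genesis block is empty with an epoch timestamp.
Tamper verification recomputes every transaction id from its payload and
every block hash from raw contents, so any single-byte payload mutation
breaks verification (payload canonicalization uses surrogate-escape decoding
so the check is total even over non-UTF-8 tampered bytes).

The state database key is `(account, seq, relay, device)` so that both relay
copies of one record coexist for later comparison; the audit nevertheless
walks the blocks, not the state, so overwritten history stays visible.
Relays hold write-only capabilities; `read_state` refuses them.

## Relay layer and attack injection

Tokens are opaque 256-bit values bound server-side to one (account, device)
pair; clients tag each submission with an HMAC keyed by the token, and
endorsers verify both binding and tag via the single common auth server. A
compromised relay applies its mutation hook and re-signs with the (stolen)
token — without re-signing the endorsement layer would reject the rewrite as
a bad client signature, which would make the relay scenario untestable.

The attacker's "incorrect string" in the relay and auth-server scenarios is a
fresh random 64-hex string; under SHA-256 any string unequal to the true
secret is equivalent. Forged branches reuse the victim record's log ID and
claimed predecessor digest with a mutated insomnia score (`(x + 7) mod 25`,
which always changes the value). Because relay selection is random, the
hacked relay is forced onto the dispatch path of the targeted record — the
scenario is *conditional* on the attacked data passing through the hacked
relay, and without forcing, a 1/3 of seeds would silently test nothing.

## Audit semantics

* **Relay mismatch** — copies of one `(account, seq, device)` submission must
  be byte-identical across relays. Grouping by device (not merely by
  `(account, seq)`) keeps a forged second-device submission from masquerading
  as a relay mismatch; cross-device duplication is branch evidence instead.
* **Branch** — a group per `(account, log_id)` and per `(account, claimed
  prev_hash)` spanning ≥ 2 devices with ≥ 2 distinct contents. A fork
  normally collides on both keys, so events implicating the same candidate
  set are deduplicated and reported once.
* **Resolution** — every implicated candidate is re-verified under the
  account's revealed secret. Exactly one verifying candidate: it is
  `VALID`/`BRANCH_RESOLVED_LEGAL`, the rest `TAMPERED_REJECTED`/
  `BRANCH_REJECTED_ILLEGAL`. Two or more verifying: all
  `BRANCH_UNRESOLVED` (the offline device check is represented as this
  report outcome, not simulated — it is a human procedure). Zero verifying
  candidates in a branch: all rejected. Unflagged records verify to `VALID`;
  accounts without a revealed secret are `UNVERIFIABLE` throughout.

With two relay copies per submission there is no cross-relay majority, so
resolution happens only after secret reveal; a larger fan-out (e.g. 2-of-5)
would allow pre-reveal majority voting, which this simulator does not
implement.

## Determinism and problem sizes

Every randomness source is a `random.Random` seeded with a string derived
from the global seed and a role label (`"{seed}:dispatch"`, per-account
generator streams, etc.), so runs are byte-identical across processes.
Default study size for the scenario analyses is 3 patients × 10 days (60
committed copies), which exercises every code path while keeping the full
test suite and the acceptance script each well under a minute; the
mutation sweeps are exhaustive at 5 chain links and a 3-block ledger, and
dispatch uniformity uses 30,000 draws (binomial standard error ≈ 0.27%,
against a ±2% acceptance band).

## Known limitations

* No real networking, consensus under node failure, Byzantine fault
  tolerance, channel partitioning or throughput modeling.
* IP-address restriction is modeled as the write-only capability flag, not as
  packet filtering.
* A single device per account; key rotation and multi-device chains are out
  of scope.
* An attacker who spoofs the honest device's identifier in a forged
  submission would surface as a relay mismatch rather than a branch; either
  way the fraud is detected and the forged copy fails verification.
* Scores are totals only; item-level questionnaire content is not modeled.
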