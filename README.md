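# trialchain

A desk-scale simulator of tamper-evident data management for mobile-health
(mHealth) clinical trials. It models, entirely in-process, a pipeline in which
patients' phones collect daily insomnia-study records, sign them into a
**client hashchain**, send them through randomly chosen **relay servers** into
a **permissioned hash-linked ledger**, and in which an **audit engine**
detects and — where cryptographically possible — resolves three kinds of
fraud: a hacked relay rewriting data in flight, an impersonator with a stolen
authentication key, and a root-exploited device whose chain secret itself was
stolen.

It is intended for researchers and engineers studying data-integrity
architectures for decentralized trials: every component is deterministic under
a seed, so detection and resolution claims can be tested exhaustively rather
than anecdotally.

## The model

Each device holds a *secure string* `s` (256 random bits, hex) that never
leaves the device during the study. For record `i` with canonical JSON bytes
`m_i`, the device computes

```
h_i = SHA-256( m_i || 0x1F || s || 0x1F || h_{i-1} ),     h_0 = 64 x '0'
```

and submits `(m_i, h_i, h_{i-1})` to `k = 2` of `n = 3` relay servers chosen
uniformly at random. Relays hold write-only ledger capabilities and forward
byte-identically. The ledger network (3 organizations × 2 peers, 2-of-3
keyed-MAC endorsement) runs the five-step lifecycle — proposal, endorse,
submit, ordering, commit — batching transactions chronologically into blocks
where `block_hash = SHA-256(index || prev_block_hash || H(tx ids) || t)`.

At study end `s` is revealed to the ledger. A committed record is *authentic*
iff its stored digest recomputes from its own stored fields under `s` — only
the secret holder can produce such a digest. The audit flags

* **relay mismatches** — the two relay copies of one device submission differ;
* **branches** — two devices committed records claiming one log ID or one
  predecessor digest;

and classifies every candidate by re-verification: exactly one verifying
candidate resolves the fraud automatically; two verifying candidates (the
root-exploit case) are reported `BRANCH_UNRESOLVED`, which in practice
requires an offline inspection of the patient's device.

## Worked example

```bash
$ trialchain simulate --patients 3 --days 10 --seed 42 --out-ledger ledger.json
committed 60 record entries over 13 blocks -> ledger.json

$ trialchain ledger verify ledger.json
ledger OK: 14 blocks, hash links intact
```

3 patients × 10 days × 2 relay copies = 60 committed record entries; the 13
transaction blocks (plus genesis) all re-hash correctly. Now the worst-case
attack — a malware root exploit steals both the authentication key and the
secure string, and forges a branch of patient 1's chain:

```bash
$ trialchain attack --scenario client --patients 3 --days 10 --seed 42 --out report.json
fraud events: 1
  BRANCH  account=patient-001 seq=1 candidates=2
classification summary:
  BRANCH_UNRESOLVED        4
  VALID                    58
$ echo $?
3
```

The fork is *detected* (one branch, two candidate contents, four committed
copies), but because both candidates verify under the stolen secret, neither
can be rejected automatically — exit code 3 flags the required offline check.
The milder scenarios resolve fully: `--scenario relay` reports one
`RELAY_MISMATCH` with the rewritten copy `TAMPERED_REJECTED` and the honest
copy `VALID`; `--scenario auth` reports one `BRANCH` whose forged candidate is
`BRANCH_REJECTED_ILLEGAL` (exit code 0 in both cases).

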