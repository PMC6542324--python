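"""Endorsement, ordering/commit, block hashing and tamper evidence."""

import copy
import hashlib
import hmac as hmac_mod
import itertools
import json
import random

import pytest

from trialchain.ledger import (
    Capability,
    EndorseFailure,
    EndorsementPolicy,
    Organization,
    POLICY_UNSATISFIED,
    ReadForbidden,
    Transaction,
    endorse,
    iter_committed_payloads,
    ledger_from_json,
    ledger_to_json,
    make_transaction,
    new_ledger,
    order_and_commit,
    read_state,
    serialize_blocks,
    sign_endorsement,
    submit,
    tx_id_for,
    verify_endorsement,
    verify_ledger,
)

ORGS = [Organization(f"org-{i}", endorsement_key=bytes([i]) * 32) for i in (1, 2, 3)]


def make_payload(account="acct-1", seq=1, relay="relay-1", device=None,
                 submitted_at="2018-09-02T06:25:00Z", body=b'{"v":1}',
                 client_hash="ab" * 32, prev_hash="0" * 64):
    return {
        "type": "record",
        "account_id": account,
        "seq": seq,
        "log_id": f"{account}:{seq}:cafe0000",
        "record_bytes": body,
        "client_hash": client_hash,
        "prev_hash": prev_hash,
        "relay_id": relay,
        "device_id": device or f"{account}-device",
        "submitted_at": submitted_at,
    }


def make_tx(**kw):
    return make_transaction(make_payload(**kw), {"token": "t", "tag": "x"})


def endorsed(tx):
    return tuple(sign_endorsement(o, tx.tx_id) for o in ORGS)


def committed_ledger(n_txs=6, max_block_txs=2, seed=0):
    """A small committed ledger built from distinct transactions."""
    rng = random.Random(seed)
    txs = [make_tx(account=f"acct-{i % 2 + 1}", seq=i // 2 + 1,
                   relay=f"relay-{rng.randint(1, 3)}",
                   body=json.dumps({"v": i}).encode(),
                   submitted_at=f"2018-09-02T06:{20 + i:02d}:00Z")
           for i in range(n_txs)]
    ledger = new_ledger()
    order_and_commit(txs, ledger, max_block_txs=max_block_txs)
    return ledger, txs


class TestEndorse:
    def test_valid_tx_one_verifiable_signature_per_org(self):
        tx = make_tx()
        ledger = new_ledger()
        sigs = [endorse(tx, org, ledger, {"acct-1"}) for org in ORGS]
        assert all(not isinstance(s, EndorseFailure) for s in sigs)
        # each organization issued one signature and it verifies under its key
        for org, sig in zip(ORGS, sigs):
            assert sig.org_id == org.org_id
            assert verify_endorsement(org, tx.tx_id, sig)

    def test_malformed_missing_field(self):
        p = make_payload()
        del p["log_id"]
        tx = Transaction(tx_id=tx_id_for(p), payload=p, client_signature={})
        assert endorse(tx, ORGS[0], new_ledger(), {"acct-1"}) is EndorseFailure.MALFORMED

    def test_malformed_wrong_tx_id(self):
        p = make_payload()
        tx = Transaction(tx_id="0" * 64, payload=p, client_signature={})
        assert endorse(tx, ORGS[0], new_ledger(), {"acct-1"}) is EndorseFailure.MALFORMED

    def test_replay_of_committed_tx_is_duplicate(self):
        ledger, txs = committed_ledger()
        assert endorse(txs[0], ORGS[0], ledger, {"acct-1", "acct-2"}) \
            is EndorseFailure.DUPLICATE

    def test_bad_client_signature(self):
        tx = make_tx()
        res = endorse(tx, ORGS[0], new_ledger(), {"acct-1"},
                      verify_client_signature=lambda t: False)
        assert res is EndorseFailure.BAD_SIGNATURE

    def test_unauthorized_account(self):
        tx = make_tx(account="stranger")
        assert endorse(tx, ORGS[0], new_ledger(), {"acct-1"}) \
            is EndorseFailure.UNAUTHORIZED


class TestSubmit:
    def test_threshold_boundary(self):
        tx = make_tx()
        sigs = endorsed(tx)
        policy = EndorsementPolicy(threshold=2, n_orgs=3)
        assert not isinstance(submit(tx, sigs[:2], policy, ORGS), type(POLICY_UNSATISFIED))
        assert submit(tx, sigs[:1], policy, ORGS) is POLICY_UNSATISFIED

    def test_duplicate_org_signatures_count_once(self):
        tx = make_tx()
        sig = sign_endorsement(ORGS[0], tx.tx_id)
        policy = EndorsementPolicy(threshold=2, n_orgs=3)
        assert submit(tx, [sig, sig], policy, ORGS) is POLICY_UNSATISFIED

    @pytest.mark.parametrize("corrupt_at", [0, 1, 2])
    def test_one_corrupted_signature_fails_threshold_three(self, corrupt_at):
        """All corruption positions: an oracle recount of valid signatures
        must match what submit accepts at threshold 3."""
        tx = make_tx()
        sigs = list(endorsed(tx))
        bad = sigs[corrupt_at]
        flipped = ("0" if bad.signature[0] != "0" else "1") + bad.signature[1:]
        sigs[corrupt_at] = type(bad)(bad.org_id, flipped)
        # oracle: recompute the keyed MAC per org and count matches
        n_valid = sum(
            1 for org, s in zip(ORGS, sigs)
            if hmac_mod.new(org.endorsement_key, tx.tx_id.encode(),
                            hashlib.sha256).hexdigest() == s.signature
        )
        assert n_valid == 2
        policy = EndorsementPolicy(threshold=3, n_orgs=3)
        assert submit(tx, sigs, policy, ORGS) is POLICY_UNSATISFIED

    def test_all_org_subsets_against_all_thresholds(self):
        """Acceptance iff valid distinct-org signatures >= threshold, for every
        subset of the three organizations and every threshold."""
        tx = make_tx()
        sigs = endorsed(tx)
        for threshold in (1, 2, 3):
            policy = EndorsementPolicy(threshold=threshold, n_orgs=3)
            for r in range(4):
                for subset in itertools.combinations(range(3), r):
                    chosen = [sigs[i] for i in subset]
                    res = submit(tx, chosen, policy, ORGS)
                    if len(subset) >= threshold:
                        assert isinstance(res, Transaction)
                        assert len(res.endorsements) == len(subset)
                    else:
                        assert res is POLICY_UNSATISFIED

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            EndorsementPolicy(threshold=4, n_orgs=3)
        with pytest.raises(ValueError):
            EndorsementPolicy(threshold=0, n_orgs=3)


class TestOrderAndCommit:
    def test_batching_arithmetic(self):
        ledger, _ = committed_ledger(n_txs=5, max_block_txs=2)
        sizes = [len(b.tx_list) for b in ledger.blocks]
        assert sizes == [0, 2, 2, 1]  # genesis + batches

    def test_chronological_order_with_tx_id_tiebreak(self):
        txs = [make_tx(seq=i + 1, body=json.dumps({"v": i}).encode(),
                       submitted_at="2018-09-02T06:25:00Z") for i in range(4)]
        ledger_a = order_and_commit(list(txs), new_ledger(), 10)
        ledger_b = order_and_commit(list(reversed(txs)), new_ledger(), 10)
        ids_a = [t.tx_id for t in ledger_a.blocks[1].tx_list]
        ids_b = [t.tx_id for t in ledger_b.blocks[1].tx_list]
        assert ids_a == ids_b == sorted(t.tx_id for t in txs)

    def test_block_hashes_match_independent_recomputation(self):
        ledger, _ = committed_ledger(n_txs=6, max_block_txs=2)
        prev = "0" * 64
        for block in ledger.blocks:
            h = hashlib.sha256()
            for i, t in enumerate(block.tx_list):
                if i:
                    h.update(b"\x1f")
                h.update(t.tx_id.encode())
            payload_hash = h.hexdigest()
            assert payload_hash == block.payload_hash
            expected = hashlib.sha256(
                b"\x1f".join([str(block.index).encode(), prev.encode(),
                              payload_hash.encode(), block.timestamp.encode()])
            ).hexdigest()
            assert block.block_hash == expected
            assert block.prev_block_hash == prev
            prev = block.block_hash

    def test_append_only_byte_prefix(self):
        ledger, _ = committed_ledger(n_txs=4, max_block_txs=2)
        before = serialize_blocks(ledger)
        extra = make_tx(account="acct-1", seq=99, body=b'{"v":99}',
                        submitted_at="2018-09-03T06:00:00Z")
        order_and_commit([extra], ledger, 2)
        after = serialize_blocks(ledger)
        assert after.startswith(before) and len(after) > len(before)

    def test_conservation_over_random_workload(self):
        """Every submitted tx lands in exactly one block, none duplicated."""
        rng = random.Random(13)
        txs = [make_tx(account=f"acct-{i}", seq=1,
                       body=json.dumps({"v": rng.random()}).encode(),
                       submitted_at=f"2018-09-02T{rng.randint(10, 20)}:00:00Z")
               for i in range(37)]
        ledger = order_and_commit(txs, new_ledger(), max_block_txs=5)
        committed = [t for _, t in iter_committed_payloads(ledger)]
        assert len(committed) == 37
        assert len({tx_id_for(p) for p in committed}) == 37
        assert ledger.committed_tx_ids == {t.tx_id for t in txs}


class TestVerifyLedger:
    def test_fresh_ledger_ok(self):
        ledger, _ = committed_ledger()
        assert verify_ledger(ledger) == (True, None)

    def test_genesis_only_ok(self):
        assert verify_ledger(new_ledger()) == (True, None)

    def test_every_single_byte_mutation_detected(self):
        """Brute force: flipping any byte of any committed record payload in a
        3-block ledger breaks verification at or before the mutated block."""
        ledger, _ = committed_ledger(n_txs=4, max_block_txs=2)  # genesis + 2
        assert len(ledger.blocks) == 3
        for b_idx, block in enumerate(ledger.blocks):
            for t_idx, tx in enumerate(block.tx_list):
                body = tx.payload["record_bytes"]
                for pos in range(len(body)):
                    tampered = copy.deepcopy(ledger)
                    mutated = bytearray(body)
                    mutated[pos] ^= 0x01
                    tampered.blocks[b_idx].tx_list[t_idx].payload["record_bytes"] = bytes(mutated)
                    ok, broken = verify_ledger(tampered)
                    assert not ok and broken <= b_idx

    def test_block_relink_attack_detected(self):
        """Rewriting a mid-chain block hash breaks the link to its successor."""
        ledger, _ = committed_ledger(n_txs=6, max_block_txs=2)
        tampered = copy.deepcopy(ledger)
        b = tampered.blocks[1]
        tampered.blocks[1] = type(b)(b.index, b.prev_block_hash, b.tx_list,
                                     b.payload_hash, b.timestamp, "f" * 64)
        ok, broken = verify_ledger(tampered)
        assert not ok and broken == 1


class TestReadState:
    def test_auditor_reads_full_map(self):
        ledger, txs = committed_ledger(n_txs=6)
        auditor = Capability("auditor", can_read=True, can_write=False)
        state = read_state(ledger, auditor)
        assert len(state) == 6  # distinct (account, seq, relay, device) keys

    def test_write_only_capability_refused(self):
        ledger, _ = committed_ledger()
        relay_cap = Capability("relay-1", can_read=False, can_write=True)
        with pytest.raises(ReadForbidden):
            read_state(ledger, relay_cap)


class TestSerialization:
    def test_json_round_trip_preserves_verification(self):
        ledger, _ = committed_ledger(n_txs=6, max_block_txs=2)
        doc = json.loads(json.dumps(ledger_to_json(ledger)))
        restored = ledger_from_json(doc)
        assert verify_ledger(restored) == (True, None)
        assert restored.state == ledger.state
        assert serialize_blocks(restored) == serialize_blocks(ledger)
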