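"""Publication workflow: reviewer state machine, DOI minting, migration."""

import itertools
from datetime import datetime, timedelta, timezone

import pytest

from edarch import make_metadata, mount
from edarch.errors import (
    EntityDeletedError,
    MigrationError,
    PermissionDeniedError,
    WorkflowError,
)
from edarch.publication import (
    FileOutbox,
    IdentifierType,
    RecordingRegistrar,
    ReviewerRole,
    ReviewStatus,
    Verdict,
    decide_with_token,
    decision_token,
    load_reference,
    mint_doi,
    parse_datacite_record,
    record_decision,
    request_publication,
    resolve_outcome,
    retry_registration,
    to_datacite_record,
)

from conftest import NGS_METADATA, NGS_SIZE_BYTES, make_pubconfig

T0 = datetime(2013, 5, 1, tzinfo=timezone.utc)


def _published_file(repo, session, name="F32CY7K01.sff", meta=None):
    eid = repo.create_file(repo.root, name, session).id
    repo.store(
        eid, b"sff payload", metadata=make_metadata(meta or NGS_METADATA), session=session
    )
    return eid


class TestMintDoi:
    def test_printed_doi_forms(self):
        assert mint_doi("10.5072", "IPK/Test", 2013, 0) == "10.5072/IPK/Test/2013/0"
        assert mint_doi("10.5447", "DPPN", 2014, 0) == "10.5447/DPPN/2014/0"

    def test_sequence_increments_within_namespace_year(self, repo, alice):
        for i in range(3):
            eid = _published_file(repo, alice, name=f"d{i}.sff")
            ref = request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)
            ref = record_decision(repo, ref, ReviewerRole.MASTER, Verdict.ACCEPT, T0)
            assert ref.identifier == f"10.5072/IPK/Test/2013/{i}"


class TestRequest:
    def test_request_creates_pending_and_notifies_three_reviewers(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)
        assert ref.status is ReviewStatus.PENDING
        assert ref.identifier is None
        messages = FileOutbox(repo.outbox_dir).messages()
        assert len(messages) == 3
        assert {m["to"] for m in messages} == {
            "legal@example.org", "scientific@example.org", "master@example.org",
        }

    def test_request_on_deletion_marker_rejected(self, repo, alice):
        eid = _published_file(repo, alice)
        terminal = repo.delete(eid, alice)
        with pytest.raises(EntityDeletedError):
            request_publication(repo, alice, eid, terminal.revision, now=T0)

    def test_duplicate_pending_request_rejected(self, repo, alice):
        eid = _published_file(repo, alice)
        request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)
        with pytest.raises(WorkflowError):
            request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)

    def test_requires_publication_permission(self, repo, alice, bob):
        eid = _published_file(repo, alice)
        with pytest.raises(PermissionDeniedError):
            request_publication(repo, bob, eid, 2, now=T0)


def _oracle_outcome(verdicts: dict, default: Verdict):
    """Independent statement of the decision rule: an explicit master
    verdict decides; otherwise silent roles get the default at the
    deadline, a (defaulted) master reject rejects, and a defaulted
    master accept requires unanimity."""
    master = verdicts[ReviewerRole.MASTER]
    if master is not None:
        return ReviewStatus.ACCEPTED if master is Verdict.ACCEPT else ReviewStatus.REJECTED
    effective = {
        role: (v if v is not None else default) for role, v in verdicts.items()
    }
    if effective[ReviewerRole.MASTER] is Verdict.REJECT:
        return ReviewStatus.REJECTED
    return (
        ReviewStatus.ACCEPTED
        if all(v is Verdict.ACCEPT for v in effective.values())
        else ReviewStatus.REJECTED
    )


class TestDecisionTable:
    @pytest.mark.parametrize("default", [Verdict.ACCEPT, Verdict.REJECT])
    def test_all_27_verdict_combinations(self, tmp_path, alice, default):
        """Exhaustive verdict table (accept/reject/silent per role) against
        an independently stated rule oracle, for both default verdicts."""
        options = [Verdict.ACCEPT, Verdict.REJECT, None]
        for i, combo in enumerate(itertools.product(options, repeat=3)):
            verdicts = dict(zip(list(ReviewerRole), combo))
            cfg = make_pubconfig(default_verdict=default, registrar=RecordingRegistrar())
            repo = mount(tmp_path / f"{default.value}-{i}", alice, publication_config=cfg)
            try:
                eid = _published_file(repo, alice)
                ref = request_publication(repo, alice, eid, 2, IdentifierType.URL, now=T0)
                # Non-master decisions first so the master's veto is tested last.
                for role in (ReviewerRole.LEGAL, ReviewerRole.SCIENTIFIC, ReviewerRole.MASTER):
                    if verdicts[role] is None:
                        continue
                    current = load_reference(repo, ref.token)
                    if current.status is not ReviewStatus.PENDING:
                        break
                    record_decision(repo, current, role, verdicts[role], T0 + timedelta(days=1))
                status = resolve_outcome(repo, ref, now=T0 + timedelta(days=15))
                assert status == _oracle_outcome(verdicts, default), verdicts
                # Terminal states never change.
                assert resolve_outcome(repo, ref, now=T0 + timedelta(days=40)) == status
                final = load_reference(repo, ref.token)
                assert (final.identifier is not None) == (status is ReviewStatus.ACCEPTED)
                # Master reject never yields acceptance.
                if verdicts[ReviewerRole.MASTER] is Verdict.REJECT:
                    assert status is ReviewStatus.REJECTED
            finally:
                repo.close()

    def test_double_decision_by_same_role_rejected(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        record_decision(repo, ref, ReviewerRole.LEGAL, Verdict.ACCEPT, T0)
        with pytest.raises(WorkflowError):
            record_decision(repo, ref, ReviewerRole.LEGAL, Verdict.REJECT, T0)

    def test_decision_after_terminal_state_rejected(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        record_decision(repo, ref, ReviewerRole.MASTER, Verdict.ACCEPT, T0)
        with pytest.raises(WorkflowError):
            record_decision(repo, ref, ReviewerRole.LEGAL, Verdict.ACCEPT, T0)


class TestRemindersAndDefaults:
    def test_quiet_before_reminder_window(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        n_before = len(FileOutbox(repo.outbox_dir).messages())
        status = resolve_outcome(repo, ref, now=T0 + timedelta(days=2))
        assert status is ReviewStatus.PENDING
        assert len(FileOutbox(repo.outbox_dir).messages()) == n_before

    def test_reminders_sent_once_to_silent_reviewers(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        record_decision(repo, ref, ReviewerRole.LEGAL, Verdict.ACCEPT, T0)
        resolve_outcome(repo, ref, now=T0 + timedelta(days=8))
        resolve_outcome(repo, ref, now=T0 + timedelta(days=9))
        reminders = [
            m for m in FileOutbox(repo.outbox_dir).messages()
            if m["subject"].startswith("Reminder")
        ]
        assert {m["to"] for m in reminders} == {
            "scientific@example.org", "master@example.org",
        }
        assert len(reminders) == 2  # emitted once, not per call

    def test_two_accepts_master_silent_default_reject(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        record_decision(repo, ref, ReviewerRole.LEGAL, Verdict.ACCEPT, T0)
        record_decision(repo, ref, ReviewerRole.SCIENTIFIC, Verdict.ACCEPT, T0)
        assert resolve_outcome(repo, ref, now=T0 + timedelta(days=15)) is ReviewStatus.REJECTED
        decisions = load_reference(repo, ref.token).decisions
        assert any(d.via == "default" for d in decisions)

    def test_requester_notified_on_terminal_transition(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        record_decision(repo, ref, ReviewerRole.MASTER, Verdict.ACCEPT, T0)
        to_requester = [
            m for m in FileOutbox(repo.outbox_dir).messages()
            if m["to"] == "user:alice"
        ]
        assert len(to_requester) == 1


class TestSignedLinks:
    def test_token_round_trip_applies_verdict(self, repo, alice):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        token = decision_token(repo, ref.token, ReviewerRole.MASTER, Verdict.REJECT)
        assert decide_with_token(repo, token, T0).status is ReviewStatus.REJECTED

    def test_tampered_token_rejected(self, repo, alice):
        from edarch.errors import ValidationError

        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, now=T0)
        token = decision_token(repo, ref.token, ReviewerRole.LEGAL, Verdict.REJECT)
        forged = token.replace(".reject.", ".accept.")
        with pytest.raises(ValidationError):
            decide_with_token(repo, forged, T0)


class TestRegistrar:
    def test_accepted_doi_registered_exactly_once(self, repo, alice, pubconfig):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)
        ref = record_decision(repo, ref, ReviewerRole.MASTER, Verdict.ACCEPT, T0)
        calls = pubconfig.registrar.calls
        assert len(calls) == 1
        assert calls[0]["doi"] == ref.identifier
        assert calls[0]["landing_url"].endswith(f"/ref/{ref.token}")

    def test_rejected_reference_never_registered(self, repo, alice, pubconfig):
        eid = _published_file(repo, alice)
        ref = request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)
        record_decision(repo, ref, ReviewerRole.MASTER, Verdict.REJECT, T0)
        assert pubconfig.registrar.calls == []

    def test_transport_failure_keeps_acceptance_and_flags_retry(self, tmp_path, alice):
        class FlakyRegistrar:
            def __init__(self):
                self.calls = []
                self.fail = True

            def register(self, doi, landing_url, record_xml):
                if self.fail:
                    raise ConnectionError("registrar down")
                self.calls.append(doi)
                return "ok"

        flaky = FlakyRegistrar()
        cfg = make_pubconfig(registrar=flaky)
        repo = mount(tmp_path / "flaky", alice, publication_config=cfg)
        try:
            eid = _published_file(repo, alice)
            ref = request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)
            ref = record_decision(repo, ref, ReviewerRole.MASTER, Verdict.ACCEPT, T0)
            assert ref.status is ReviewStatus.ACCEPTED
            assert ref.registration_pending
            minted = ref.identifier
            flaky.fail = False
            ref = retry_registration(repo, ref)
            assert not ref.registration_pending
            assert ref.identifier == minted  # no duplicate mint
            assert flaky.calls == [minted]
        finally:
            repo.close()

    def test_doi_uniqueness_and_gapless_sequences(self, repo, alice):
        minted = []
        for i in range(4):
            eid = _published_file(repo, alice, name=f"u{i}.dat")
            ref = request_publication(repo, alice, eid, 2, IdentifierType.DOI, now=T0)
            verdict = Verdict.ACCEPT if i != 2 else Verdict.REJECT
            ref = record_decision(repo, ref, ReviewerRole.MASTER, verdict, T0)
            if ref.identifier:
                minted.append(ref.identifier)
        assert len(set(minted)) == len(minted)
        sequences = [int(d.rsplit("/", 1)[1]) for d in minted]
        assert sequences == list(range(len(minted)))  # gapless 0..k


class TestDataCiteMigration:
    def test_ngs_record_maps_mandatory_and_optional_fields(self):
        meta = make_metadata(NGS_METADATA)
        doc = to_datacite_record(meta, "10.5072/IPK/Test/2013/0", NGS_SIZE_BYTES, 2013)
        parsed = parse_datacite_record(doc)
        assert parsed["doi"] == "10.5072/IPK/Test/2013/0"
        assert parsed["creator"] == meta.display("creator")
        assert parsed["title"] == "F32CY7K01.sff"
        assert parsed["publisher"] == (
            "Leibniz Institute of Plant Genetics and Crop Plant Research Gatersleben"
        )
        assert parsed["publication_year"] == 2013
        assert parsed["subjects"] == ["NGS", "Rye"]
        assert parsed["size"] == "98.7 KB"
        assert parsed["rights"] == meta.display("rights")
        assert parsed["description"] == meta.display("description")

    def test_missing_creator_names_the_absentee(self):
        meta = make_metadata({"title": "t", "publisher": "p"})
        with pytest.raises(MigrationError) as err:
            to_datacite_record(meta, "10.5072/X/2013/0", 0, 2013)
        assert err.value.missing == ["creator"]

    def test_serialization_deterministic(self):
        meta = make_metadata(NGS_METADATA)
        a = to_datacite_record(meta, "10.5072/IPK/Test/2013/0", NGS_SIZE_BYTES, 2013)
        b = to_datacite_record(meta, "10.5072/IPK/Test/2013/0", NGS_SIZE_BYTES, 2013)
        assert a == b
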