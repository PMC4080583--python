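"""Persistent-identifier publication: review workflow, DOI minting,
registrar-metadata migration.

Publishing a stored version is a formal act, so every request passes a
review gate before an identifier (URL or DOI) is released:

1. The request immediately gets a resolvable landing page, with the
   download locked while the request is pending or embargoed.
2. Three configured reviewers — one *legal*, one *scientific*, and one
   *master* with veto power — are each notified with signed accept and
   reject links.
3. An explicit master verdict is decisive either way; otherwise the
   request resolves once all three roles have verdicts.  Unresponsive
   reviewers are reminded after ``reminder_after`` and receive the
   configured default verdict after ``default_after`` (shipped default:
   reject — conservative for a publication act).  When the defaulted
   master verdict is *accept*, unanimity of all three verdicts is
   required.
4. On acceptance a DOI of the form ``<prefix>/<namespace>/<year>/<seq>``
   is minted (sequence numbers are gapless per namespace and year), the
   Dublin Core record is migrated to the registrar's XML metadata
   format, and the registration transport is invoked exactly once.
   The requester is notified of every terminal transition.

Email and registrar transports are pluggable; the shipped file-backed
outbox and recording registrar make the whole workflow testable offline.
"""

from __future__ import annotations

import enum
import hashlib
import hmac
import uuid
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Protocol

from lxml import etree

from .errors import (
    ArchiveError,
    EntityDeletedError,
    MigrationError,
    ValidationError,
    WorkflowError,
)
from .metadata import MetaData, format_size
from .permissions import GrantableAction, Principal, Session


class IdentifierType(str, enum.Enum):
    URL = "URL"
    DOI = "DOI"


class ReviewStatus(str, enum.Enum):
    PENDING = "PENDING"
    ACCEPTED = "ACCEPTED"
    REJECTED = "REJECTED"


class ReviewerRole(str, enum.Enum):
    LEGAL = "legal"
    SCIENTIFIC = "scientific"
    MASTER = "master"


class Verdict(str, enum.Enum):
    ACCEPT = "accept"
    REJECT = "reject"


@dataclass(frozen=True)
class Reviewer:
    email: str
    role: ReviewerRole


class Notifier(Protocol):
    def send(self, to: str, subject: str, body: str) -> None: ...


class Registrar(Protocol):
    def register(self, doi: str, landing_url: str, record_xml: bytes) -> str: ...


class FileOutbox:
    """Notification transport writing one RFC-822-style text file per
    message (``outbox/0001.eml`` ...)."""

    def __init__(self, directory: Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def send(self, to: str, subject: str, body: str) -> None:
        n = len(list(self.directory.glob("*.eml"))) + 1
        path = self.directory / f"{n:04d}.eml"
        path.write_text(
            f"To: {to}\nSubject: {subject}\n\n{body}\n", encoding="utf-8"
        )

    def messages(self) -> list[dict]:
        out = []
        for path in sorted(self.directory.glob("*.eml")):
            header, _, body = path.read_text(encoding="utf-8").partition("\n\n")
            fields = dict(
                line.split(": ", 1) for line in header.splitlines() if ": " in line
            )
            out.append({"to": fields.get("To", ""), "subject": fields.get("Subject", ""), "body": body})
        return out


class RecordingRegistrar:
    """Offline registrar transport that records every call."""

    def __init__(self):
        self.calls: list[dict] = []

    def register(self, doi: str, landing_url: str, record_xml: bytes) -> str:
        self.calls.append(
            {"doi": doi, "landing_url": landing_url, "record_xml": record_xml}
        )
        return f"receipt-{len(self.calls)}"


@dataclass(frozen=True)
class PublicationConfig:
    """Mount-time publication settings.

    Exactly one reviewer per role; reminder/default windows are
    positive durations counted from the request time.
    """

    reviewers: tuple[Reviewer, ...]
    doi_prefix: str = "10.5072"
    namespace: str = "TEST"
    base_url: str = "http://localhost:8080"
    notifier: Notifier | None = None
    registrar: Registrar | None = None
    reminder_after: timedelta = timedelta(days=7)
    default_after: timedelta = timedelta(days=14)
    default_verdict: Verdict = Verdict.REJECT

    def __post_init__(self):
        roles = sorted(r.role for r in self.reviewers)
        if roles != sorted(ReviewerRole):
            raise ValidationError(
                "publication config requires exactly one legal, one scientific, "
                "and one master reviewer"
            )
        if self.reminder_after <= timedelta(0) or self.default_after <= timedelta(0):
            raise ValidationError("reminder/default durations must be positive")

    def reviewer(self, role: ReviewerRole) -> Reviewer:
        return next(r for r in self.reviewers if r.role == role)


@dataclass(frozen=True)
class Decision:
    role: ReviewerRole
    verdict: Verdict
    time: datetime
    via: str  # "link" | "default"


@dataclass(frozen=True)
class PublicReference:
    """A publication request and its review state."""

    token: str
    entity: str
    revision: int
    id_type: IdentifierType
    status: ReviewStatus
    identifier: str | None
    request_time: datetime
    release_date: datetime
    requester: Principal
    decisions: tuple[Decision, ...] = ()
    reminded: bool = False
    registration_pending: bool = False


def _utc(ts: datetime) -> datetime:
    return ts if ts.tzinfo else ts.replace(tzinfo=timezone.utc)


def _now(now: datetime | None) -> datetime:
    return _utc(now) if now else datetime.now(timezone.utc)


def _config(repo) -> PublicationConfig:
    if repo.publication_config is None:
        raise ArchiveError("repository mounted without a publication configuration")
    return repo.publication_config


def _notifier(repo) -> Notifier:
    cfg = _config(repo)
    if cfg.notifier is not None:
        return cfg.notifier
    # Default file-backed outbox under the storage root.
    outbox = FileOutbox(repo.outbox_dir)
    object.__setattr__(cfg, "notifier", outbox)
    return outbox


def landing_url(repo, reference: PublicReference) -> str:
    return f"{_config(repo).base_url}/ref/{reference.token}"


# -- signed accept/reject links -----------------------------------------


def decision_token(repo, ref_token: str, role: ReviewerRole, verdict: Verdict) -> str:
    """Signed token encoding one reviewer verdict, usable offline."""
    payload = f"{ref_token}.{role.value}.{verdict.value}"
    sig = hmac.new(repo.secret.encode(), payload.encode(), hashlib.sha256).hexdigest()[:16]
    return f"{payload}.{sig}"


def parse_decision_token(repo, token: str) -> tuple[str, ReviewerRole, Verdict]:
    try:
        ref_token, role, verdict, sig = token.rsplit(".", 3)
    except ValueError:
        raise ValidationError("malformed decision token")
    expected = hmac.new(
        repo.secret.encode(), f"{ref_token}.{role}.{verdict}".encode(), hashlib.sha256
    ).hexdigest()[:16]
    if not hmac.compare_digest(sig, expected):
        raise ValidationError("decision token signature mismatch")
    return ref_token, ReviewerRole(role), Verdict(verdict)


# -- persistence --------------------------------------------------------


def load_reference(repo, token: str) -> PublicReference:
    row = repo.conn.execute("SELECT * FROM refs WHERE token = ?", (token,)).fetchone()
    if row is None:
        from .errors import NotFoundError

        raise NotFoundError(f"no publication reference {token!r}")
    (token, entity, revision, id_type, status, identifier, request_time,
     release_date, requester, reminded, registration_pending) = row
    decisions = tuple(
        Decision(ReviewerRole(r), Verdict(v), datetime.fromisoformat(t), via)
        for r, v, t, via in repo.conn.execute(
            "SELECT role, verdict, time, via FROM decisions WHERE token = ? ORDER BY time, role",
            (token,),
        ).fetchall()
    )
    return PublicReference(
        token=token,
        entity=entity,
        revision=revision,
        id_type=IdentifierType(id_type),
        status=ReviewStatus(status),
        identifier=identifier,
        request_time=datetime.fromisoformat(request_time),
        release_date=datetime.fromisoformat(release_date),
        requester=Principal.parse(requester),
        decisions=decisions,
        reminded=bool(reminded),
        registration_pending=bool(registration_pending),
    )


def list_references(repo) -> list[PublicReference]:
    tokens = [r[0] for r in repo.conn.execute("SELECT token FROM refs ORDER BY request_time, token")]
    return [load_reference(repo, t) for t in tokens]


def find_by_identifier(repo, identifier: str) -> PublicReference:
    row = repo.conn.execute(
        "SELECT token FROM refs WHERE identifier = ?", (identifier,)
    ).fetchone()
    if row is None:
        from .errors import NotFoundError

        raise NotFoundError(f"no reference with identifier {identifier!r}")
    return load_reference(repo, row[0])


# -- workflow operations -------------------------------------------------


def request_publication(
    repo,
    session: Session,
    entity: str,
    revision: int,
    id_type: IdentifierType = IdentifierType.DOI,
    release_date: datetime | None = None,
    now: datetime | None = None,
) -> PublicReference:
    """File a publication request; the reference starts PENDING and each
    reviewer is notified with signed accept/reject links."""
    cfg = _config(repo)
    repo._guard(session, GrantableAction.PUBLICATION, entity)
    version = repo.get_version(entity, revision)
    if version.deleted:
        raise EntityDeletedError("cannot publish the deletion marker of an entity")
    if IdentifierType(id_type) is IdentifierType.DOI:
        # Fail early: a DOI cannot be registered without the mandatory
        # registrar metadata, so an unfulfillable request is refused.
        missing = [
            n for n in ("creator", "title", "publisher")
            if not version.metadata.is_set(n)
        ]
        if missing:
            raise MigrationError(missing)
    dup = repo.conn.execute(
        "SELECT 1 FROM refs WHERE entity = ? AND revision = ? AND id_type = ? "
        "AND status = 'PENDING'",
        (entity, revision, IdentifierType(id_type).value),
    ).fetchone()
    if dup:
        raise WorkflowError(
            "a pending publication request already exists for this version"
        )
    now_dt = _now(now)
    release = _utc(release_date) if release_date else now_dt
    token = uuid.uuid4().hex
    repo.conn.execute(
        "INSERT INTO refs (token, entity, revision, id_type, status, identifier, "
        "request_time, release_date, requester, reminded, registration_pending) "
        "VALUES (?, ?, ?, ?, 'PENDING', NULL, ?, ?, ?, 0, 0)",
        (
            token,
            entity,
            revision,
            IdentifierType(id_type).value,
            now_dt.isoformat(),
            release.isoformat(),
            str(session.user),
        ),
    )
    reference = load_reference(repo, token)
    notifier = _notifier(repo)
    url = landing_url(repo, reference)
    for reviewer in cfg.reviewers:
        accept = decision_token(repo, token, reviewer.role, Verdict.ACCEPT)
        reject = decision_token(repo, token, reviewer.role, Verdict.REJECT)
        notifier.send(
            to=reviewer.email,
            subject=f"Publication request {token} ({reviewer.role.value} review)",
            body=(
                f"A {id_type.value} publication has been requested by "
                f"{session.user}.\nLanding page: {url}\n"
                f"accept: {accept}\nreject: {reject}\n"
            ),
        )
    return reference


def record_decision(
    repo,
    reference: PublicReference,
    role: ReviewerRole,
    verdict: Verdict,
    time: datetime | None = None,
) -> PublicReference:
    """Record one reviewer's verdict (at most one per role) and
    re-evaluate the outcome."""
    current = load_reference(repo, reference.token)
    if current.status is not ReviewStatus.PENDING:
        raise WorkflowError(f"reference is {current.status.value}, not PENDING")
    if any(d.role == role for d in current.decisions):
        raise WorkflowError(f"{role.value} reviewer has already decided")
    when = _now(time)
    repo.conn.execute(
        "INSERT INTO decisions (token, role, verdict, time, via) VALUES (?, ?, ?, ?, 'link')",
        (current.token, ReviewerRole(role).value, Verdict(verdict).value, when.isoformat()),
    )
    return _evaluate(repo, load_reference(repo, current.token), when)


def decide_with_token(repo, token: str, time: datetime | None = None) -> PublicReference:
    """Apply a signed accept/reject link token."""
    ref_token, role, verdict = parse_decision_token(repo, token)
    return record_decision(repo, load_reference(repo, ref_token), role, verdict, time)


def resolve_outcome(
    repo, reference: PublicReference, now: datetime | None = None
) -> ReviewStatus:
    """Advance the clock-driven part of the workflow: emit reminders to
    silent reviewers after ``reminder_after``, apply default verdicts
    after ``default_after``, and finalize when decidable."""
    cfg = _config(repo)
    current = load_reference(repo, reference.token)
    if current.status is not ReviewStatus.PENDING:
        return current.status
    now_dt = _now(now)
    decided_roles = {d.role for d in current.decisions}
    silent = [r for r in ReviewerRole if r not in decided_roles]

    if silent and not current.reminded and now_dt >= current.request_time + cfg.reminder_after:
        notifier = _notifier(repo)
        for role in silent:
            notifier.send(
                to=cfg.reviewer(role).email,
                subject=f"Reminder: publication request {current.token}",
                body=f"Your {role.value} review of request {current.token} is still pending.\n",
            )
        repo.conn.execute(
            "UPDATE refs SET reminded = 1 WHERE token = ?", (current.token,)
        )

    if silent and now_dt >= current.request_time + cfg.default_after:
        for role in silent:
            repo.conn.execute(
                "INSERT INTO decisions (token, role, verdict, time, via) "
                "VALUES (?, ?, ?, ?, 'default')",
                (current.token, role.value, cfg.default_verdict.value, now_dt.isoformat()),
            )
    return _evaluate(repo, load_reference(repo, current.token), now_dt).status


def _evaluate(repo, reference: PublicReference, now: datetime) -> PublicReference:
    """Apply the decision rule and finalize when the outcome is known."""
    decisions = {d.role: d for d in reference.decisions}
    master = decisions.get(ReviewerRole.MASTER)

    outcome: ReviewStatus | None = None
    if master is not None and master.via == "link":
        # Explicit master verdict is decisive either way (veto power).
        outcome = (
            ReviewStatus.ACCEPTED
            if master.verdict is Verdict.ACCEPT
            else ReviewStatus.REJECTED
        )
    elif len(decisions) == len(ReviewerRole):
        if master.verdict is Verdict.REJECT:
            outcome = ReviewStatus.REJECTED
        else:
            # Defaulted master accept: unanimity required.
            unanimous = all(d.verdict is Verdict.ACCEPT for d in decisions.values())
            outcome = ReviewStatus.ACCEPTED if unanimous else ReviewStatus.REJECTED

    if outcome is None:
        return reference
    return _finalize(repo, reference, outcome, now)


def mint_doi(prefix: str, namespace: str, year: int, sequence: int) -> str:
    """DOI syntax ``<prefix>/<namespace>/<year>/<sequence>``,
    e.g. ``10.5072/IPK/Test/2013/0``."""
    if sequence < 0:
        raise ValidationError("DOI sequence must be >= 0")
    return f"{prefix}/{namespace}/{year}/{sequence}"


def _next_sequence(repo, prefix: str, namespace: str, year: int) -> int:
    """Count of previously accepted DOIs for (namespace, year) — keeps
    sequences gapless 0..k."""
    stem = f"{prefix}/{namespace}/{year}/"
    row = repo.conn.execute(
        "SELECT COUNT(*) FROM refs WHERE id_type = 'DOI' AND status = 'ACCEPTED' "
        "AND identifier LIKE ?",
        (stem + "%",),
    ).fetchone()
    return row[0]


def _finalize(
    repo, reference: PublicReference, outcome: ReviewStatus, now: datetime
) -> PublicReference:
    cfg = _config(repo)
    notifier = _notifier(repo)
    identifier: str | None = None
    registration_pending = False

    if outcome is ReviewStatus.ACCEPTED:
        if reference.id_type is IdentifierType.DOI:
            year = now.year
            seq = _next_sequence(repo, cfg.doi_prefix, cfg.namespace, year)
            identifier = mint_doi(cfg.doi_prefix, cfg.namespace, year, seq)
        else:
            identifier = landing_url(repo, reference)

    repo.conn.execute(
        "UPDATE refs SET status = ?, identifier = ? WHERE token = ?",
        (outcome.value, identifier, reference.token),
    )

    if outcome is ReviewStatus.ACCEPTED and reference.id_type is IdentifierType.DOI:
        version = repo.get_version(reference.entity, reference.revision)
        record = to_datacite_record(
            version.metadata, identifier, version.size_bytes, now.year
        )
        registrar = cfg.registrar
        if registrar is not None:
            try:
                registrar.register(identifier, landing_url(repo, reference), record)
            except Exception:
                # Keep the acceptance; flag the registration for retry.
                registration_pending = True
                repo.conn.execute(
                    "UPDATE refs SET registration_pending = 1 WHERE token = ?",
                    (reference.token,),
                )

    if outcome is ReviewStatus.ACCEPTED:
        body = f"Your publication request was accepted: {identifier}\n"
    else:
        body = f"Your publication request {reference.token} was rejected.\n"
    notifier.send(
        to=str(reference.requester),
        subject=f"Publication request {reference.token}: {outcome.value}",
        body=body,
    )
    return load_reference(repo, reference.token)


def retry_registration(repo, reference: PublicReference) -> PublicReference:
    """Retry a flagged registration without re-minting the identifier."""
    cfg = _config(repo)
    current = load_reference(repo, reference.token)
    if not current.registration_pending:
        return current
    version = repo.get_version(current.entity, current.revision)
    record = to_datacite_record(
        version.metadata, current.identifier, version.size_bytes,
        current.request_time.year,
    )
    cfg.registrar.register(current.identifier, landing_url(repo, current), record)
    repo.conn.execute(
        "UPDATE refs SET registration_pending = 0 WHERE token = ?", (current.token,)
    )
    return load_reference(repo, current.token)


# -- Dublin Core -> DataCite migration -----------------------------------

_DATACITE_NS = "http://datacite.org/schema/kernel-4"


def to_datacite_record(
    metadata: MetaData, doi: str, size_bytes: int, publication_year: int
) -> bytes:
    """Migrate a Dublin Core record to DataCite XML.

    Mandatory DataCite fields (identifier, creators, titles, publisher,
    publicationYear) come from the DCMES creator, title, and publisher
    elements plus the minted DOI and the acceptance year; a
    :class:`~edarch.errors.MigrationError` lists any absent mandatory
    element.  Optional blocks map subject -> subjects (comma-split),
    contributor -> contributors, date -> dates, language -> language,
    description -> descriptions, format -> formats, rights -> rightsList,
    and the version's byte size -> sizes.
    """
    missing = [n for n in ("creator", "title", "publisher") if not metadata.is_set(n)]
    if missing:
        raise MigrationError(missing)

    E = lambda tag: "{%s}%s" % (_DATACITE_NS, tag)  # noqa: E731
    root = etree.Element(E("resource"), nsmap={None: _DATACITE_NS})

    identifier = etree.SubElement(root, E("identifier"), identifierType="DOI")
    identifier.text = doi

    creators = etree.SubElement(root, E("creators"))
    creator = etree.SubElement(creators, E("creator"))
    etree.SubElement(creator, E("creatorName")).text = metadata.display("creator")

    titles = etree.SubElement(root, E("titles"))
    etree.SubElement(titles, E("title")).text = metadata.display("title")

    etree.SubElement(root, E("publisher")).text = metadata.display("publisher")
    etree.SubElement(root, E("publicationYear")).text = str(publication_year)

    if metadata.is_set("subject"):
        subjects = etree.SubElement(root, E("subjects"))
        for subj in metadata.display("subject").split(","):
            etree.SubElement(subjects, E("subject")).text = subj.strip()
    if metadata.is_set("contributor"):
        contributors = etree.SubElement(root, E("contributors"))
        contributor = etree.SubElement(
            contributors, E("contributor"), contributorType="Other"
        )
        etree.SubElement(contributor, E("contributorName")).text = metadata.display(
            "contributor"
        )
    if metadata.is_set("date"):
        dates = etree.SubElement(root, E("dates"))
        etree.SubElement(dates, E("date"), dateType="Issued").text = metadata.display(
            "date"
        )
    if metadata.is_set("language"):
        etree.SubElement(root, E("language")).text = metadata.display("language")

    sizes = etree.SubElement(root, E("sizes"))
    etree.SubElement(sizes, E("size")).text = format_size(size_bytes)

    if metadata.is_set("format"):
        formats = etree.SubElement(root, E("formats"))
        etree.SubElement(formats, E("format")).text = metadata.display("format")
    if metadata.is_set("rights"):
        rights_list = etree.SubElement(root, E("rightsList"))
        etree.SubElement(rights_list, E("rights")).text = metadata.display("rights")
    if metadata.is_set("description"):
        descriptions = etree.SubElement(root, E("descriptions"))
        etree.SubElement(
            descriptions, E("description"), descriptionType="Abstract"
        ).text = metadata.display("description")

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def parse_datacite_record(document: bytes) -> dict:
    """Parse the mapped fields back out of a DataCite record (oracle for
    migration round-trips)."""
    root = etree.fromstring(document)
    ns = {"d": _DATACITE_NS}

    def text(xpath: str) -> str | None:
        found = root.findall(xpath, ns)
        return found[0].text if found else None

    return {
        "doi": text("d:identifier"),
        "creator": text("d:creators/d:creator/d:creatorName"),
        "title": text("d:titles/d:title"),
        "publisher": text("d:publisher"),
        "publication_year": int(text("d:publicationYear")),
        "subjects": [e.text for e in root.findall("d:subjects/d:subject", ns)],
        "contributor": text("d:contributors/d:contributor/d:contributorName"),
        "date": text("d:dates/d:date"),
        "language": text("d:language"),
        "size": text("d:sizes/d:size"),
        "format": text("d:formats/d:format"),
        "rights": text("d:rightsList/d:rights"),
        "description": text("d:descriptions/d:description"),
    }
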