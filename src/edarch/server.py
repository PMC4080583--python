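"""Public access layer: landing pages, embargoed downloads, virtual trees.

The public channel serves *published* data only.  Every persistent
identifier resolves to a landing page showing the citation line, the
Dublin Core metadata listing, and either a download link or a lock
notice; the download itself is released only for ACCEPTED references
whose release date has passed.  No session is required on this channel
— the review gate and the release date are the access control.

The archive's versioned tree can also be exported as a *virtual tree*
for file-browser-style consumers: each archived file maps to a virtual
folder that contains, per version, the version's content file and an
XML metadata document.

The clock is injected everywhere (``now`` parameters) so embargo
behavior is deterministic and testable.
"""

from __future__ import annotations

import enum
import html
import threading
from dataclasses import dataclass
from datetime import datetime, timezone
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .errors import NotFoundError, PermissionDeniedError
from .metadata import render_listing, to_xml
from .permissions import GrantableAction, Session
from .publication import (
    PublicReference,
    ReviewStatus,
    find_by_identifier,
    load_reference,
)


class DownloadState(str, enum.Enum):
    AVAILABLE = "available"
    PENDING_REVIEW = "pending_review"
    EMBARGOED = "embargoed"
    GONE = "gone"


def _now(now: datetime | None) -> datetime:
    if now is None:
        return datetime.now(timezone.utc)
    return now if now.tzinfo else now.replace(tzinfo=timezone.utc)


def download_state(reference: PublicReference, now: datetime | None = None) -> DownloadState:
    """Availability of the published bytes at time *now*."""
    if reference.status is ReviewStatus.REJECTED:
        return DownloadState.GONE
    if reference.status is ReviewStatus.PENDING:
        return DownloadState.PENDING_REVIEW
    if _now(now) < reference.release_date:
        return DownloadState.EMBARGOED
    return DownloadState.AVAILABLE


def citation_line(repo, reference: PublicReference) -> str:
    """``creators (year): title. publisher. identifier`` — a common
    data-citation convention (no canonical format is mandated)."""
    version = repo.get_version(reference.entity, reference.revision)
    meta = version.metadata
    creator = meta.display("creator") or str(reference.requester)
    title = meta.display("title") or repo.get_entity(reference.entity).name
    publisher = meta.display("publisher")
    identifier = reference.identifier or f"(pending: {reference.token})"
    year = reference.request_time.year
    parts = [f"{creator} ({year}): {title}."]
    if publisher:
        parts.append(f"{publisher}.")
    parts.append(identifier)
    return " ".join(parts)


_PAGE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>{title}</title></head>
<body>
<h1>{title}</h1>
<p class="citation">{citation}</p>
<table>
{rows}
</table>
{download}
</body>
</html>
"""


def landing_page(repo, reference: PublicReference, now: datetime | None = None) -> str:
    """Deterministic HTML landing page for a reference.

    Resolvable for PENDING and ACCEPTED references; a rejected reference
    renders a gone notice.  The same reference and clock always produce
    byte-identical HTML (citability requires stable pages).
    """
    state = download_state(reference, now)
    if state is DownloadState.GONE:
        return (
            "<!DOCTYPE html>\n<html><body><h1>410 Gone</h1>"
            "<p>This publication request was rejected.</p></body></html>\n"
        )
    version = repo.get_version(reference.entity, reference.revision)
    rows = "\n".join(
        f"<tr><th>{html.escape(label)}</th><td>{html.escape(value)}</td></tr>"
        for label, value in render_listing(version.metadata, version.size_bytes)
    )
    if state is DownloadState.AVAILABLE:
        download = f'<p><a href="/ref/{reference.token}/download">Download</a></p>'
    elif state is DownloadState.EMBARGOED:
        until = reference.release_date.date().isoformat()
        download = f"<p>Download locked: embargoed until {until}.</p>"
    else:
        download = "<p>Download locked: publication request under review.</p>"
    title = version.metadata.display("title") or repo.get_entity(reference.entity).name
    return _PAGE.format(
        title=html.escape(title),
        citation=html.escape(citation_line(repo, reference)),
        rows=rows,
        download=download,
    )


def download(repo, reference: PublicReference, now: datetime | None = None) -> bytes:
    """Exact bytes of the published revision; forbidden unless the
    reference is ACCEPTED and the release date has passed."""
    state = download_state(reference, now)
    if state is not DownloadState.AVAILABLE:
        raise PermissionDeniedError(f"download is {state.value}")
    version = repo.get_version(reference.entity, reference.revision)
    return repo.store_backend.get(version.content)


# -- virtual tree export -------------------------------------------------


class NodeKind(str, enum.Enum):
    FOLDER = "folder"
    CONTENT = "content file"
    METADATA = "metadata document"


@dataclass(frozen=True)
class VirtualNode:
    """One node of the exported version-aware virtual tree."""

    path: str
    kind: NodeKind
    entity: str
    revision: int | None = None


def export_virtual_tree(repo, entity: str, session: Session) -> list[VirtualNode]:
    """Map an entity to virtual folders exposing all versions.

    An archived file becomes one folder containing, for each version
    ``r``, a content file ``v<r>_<name>`` and a metadata document
    ``v<r>_metadata.xml``; directories map recursively.
    """
    repo._guard(session, GrantableAction.READ, entity)
    info = repo.get_entity(entity)
    base = repo.path_of(entity)
    nodes = [VirtualNode(base if base != "/" else "/", NodeKind.FOLDER, entity)]
    if info.is_directory:
        for child in repo.list_children(entity, session):
            nodes.extend(export_virtual_tree(repo, child.id, session))
    else:
        prefix = base.rstrip("/")
        for version in repo.list_versions(entity, session):
            if version.deleted:
                continue
            nodes.append(
                VirtualNode(
                    f"{prefix}/v{version.revision}_{info.name}",
                    NodeKind.CONTENT,
                    entity,
                    version.revision,
                )
            )
            nodes.append(
                VirtualNode(
                    f"{prefix}/v{version.revision}_metadata.xml",
                    NodeKind.METADATA,
                    entity,
                    version.revision,
                )
            )
    return nodes


def read_virtual_node(repo, node: VirtualNode, session: Session) -> bytes:
    """Payload of a virtual node: stored bytes for content files, the
    version's metadata XML document for metadata nodes."""
    if node.kind is NodeKind.FOLDER:
        raise NotFoundError("folders have no payload")
    if node.kind is NodeKind.CONTENT:
        return repo.read(node.entity, node.revision, session)
    repo._guard(session, GrantableAction.READ, node.entity)
    version = repo.get_version(node.entity, node.revision)
    return to_xml(version.metadata)


# -- embedded HTTP service -----------------------------------------------


def _make_handler(repo, clock):
    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *a):  # quiet
            pass

        def _reference(self):
            parts = [p for p in self.path.split("/") if p]
            if len(parts) >= 2 and parts[0] == "ref":
                return load_reference(repo, parts[1]), parts[2:] == ["download"]
            if len(parts) >= 2 and parts[0] == "doi":
                doi = "/".join(parts[1:])
                return find_by_identifier(repo, doi), False
            raise NotFoundError(self.path)

        def do_GET(self):
            now = clock()
            try:
                reference, want_download = self._reference()
            except NotFoundError:
                self.send_error(404, "unknown reference")
                return
            if want_download:
                try:
                    payload = download(repo, reference, now)
                except PermissionDeniedError as exc:
                    self.send_error(403, str(exc))
                    return
                self.send_response(200)
                self.send_header("Content-Type", "application/octet-stream")
                self.send_header("Content-Length", str(len(payload)))
                self.end_headers()
                self.wfile.write(payload)
                return
            page = landing_page(repo, reference, now).encode("utf-8")
            status = 410 if reference.status is ReviewStatus.REJECTED else 200
            self.send_response(status)
            self.send_header("Content-Type", "text/html; charset=utf-8")
            self.send_header("Content-Length", str(len(page)))
            self.end_headers()
            self.wfile.write(page)

    return Handler


def serve(repo, host: str = "127.0.0.1", port: int = 8080, clock=None):
    """Start the embedded HTTP service in a background thread.

    Returns the server object; call ``shutdown()`` to stop.  Routes:
    ``/ref/<token>``, ``/ref/<token>/download``, ``/doi/<doi>``.
    """
    clock = clock or (lambda: datetime.now(timezone.utc))
    httpd = ThreadingHTTPServer((host, port), _make_handler(repo, clock))
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    return httpd
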