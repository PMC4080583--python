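"""The versioned entity tree: mounting, files, directories, version chains.

A repository is a file-system-like tree of *entities* (files and
directories), each owning an append-only chain of immutable *versions*.
Every data or metadata update appends a version; nothing is ever
rewritten.  Deleting an entity appends a terminal version tagged
``deleted`` — the end of the chain: no new version can be created for a
deleted entity and the deletion cannot be undone, but all previous
versions stay readable.  This is the deletion policy long-term
preservation demands: primary data is never destroyed.

Persistence is plain files under the storage root — a single SQLite
database (``db/archive.sqlite``) for the tree, versions, permissions and
publication state; content objects under ``objects/`` (see
:mod:`edarch.storage`); the rebuildable search index under ``index/``.
Ordinary file-system backup tools therefore suffice for maintenance.

A single-writer lock per mounted root keeps the embedded database
consistent; concurrent mounts of the same root fail fast.
"""

from __future__ import annotations

import fcntl
import sqlite3
import uuid
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Union

from . import metadata as md
from .errors import (
    DuplicateNameError,
    EntityDeletedError,
    IntegrityError,
    NotFoundError,
    PermissionDeniedError,
    RepositoryLockedError,
    StorageError,
    ValidationError,
)
from .permissions import (
    ALL_ACTIONS,
    GrantableAction,
    Principal,
    Session,
)
from .search import SearchIndex
from .storage import DEFAULT_MAX_ENTRIES_PER_CHUNK, Locator, ObjectStore

EntityId = str

DIRECTORY = "directory"
FILE = "file"

_SCHEMA = """
CREATE TABLE IF NOT EXISTS entities (
    id TEXT PRIMARY KEY,
    kind TEXT NOT NULL CHECK (kind IN ('directory', 'file')),
    name TEXT NOT NULL,
    parent TEXT REFERENCES entities(id),
    owner TEXT NOT NULL,
    UNIQUE (parent, name)
);
CREATE TABLE IF NOT EXISTS versions (
    entity TEXT NOT NULL REFERENCES entities(id),
    revision INTEGER NOT NULL,
    created_at TEXT NOT NULL,
    metadata TEXT NOT NULL,
    chunk_index INTEGER,
    object_name TEXT,
    checksum TEXT,
    size_bytes INTEGER NOT NULL DEFAULT 0,
    deleted INTEGER NOT NULL DEFAULT 0,
    creator TEXT NOT NULL,
    PRIMARY KEY (entity, revision)
);
CREATE TABLE IF NOT EXISTS acl (
    entity TEXT NOT NULL,
    principal TEXT NOT NULL,
    action TEXT NOT NULL,
    PRIMARY KEY (entity, principal, action)
);
CREATE TABLE IF NOT EXISTS refs (
    token TEXT PRIMARY KEY,
    entity TEXT NOT NULL,
    revision INTEGER NOT NULL,
    id_type TEXT NOT NULL,
    status TEXT NOT NULL,
    identifier TEXT,
    request_time TEXT NOT NULL,
    release_date TEXT NOT NULL,
    requester TEXT NOT NULL,
    reminded INTEGER NOT NULL DEFAULT 0,
    registration_pending INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS decisions (
    token TEXT NOT NULL REFERENCES refs(token),
    role TEXT NOT NULL,
    verdict TEXT NOT NULL,
    time TEXT NOT NULL,
    via TEXT NOT NULL,
    PRIMARY KEY (token, role)
);
CREATE TABLE IF NOT EXISTS settings (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
"""


def _now_utc() -> datetime:
    return datetime.now(timezone.utc)


def _iso(ts: datetime | None) -> str:
    return (ts or _now_utc()).astimezone(timezone.utc).isoformat()


@dataclass(frozen=True)
class PrimaryDataEntity:
    """Snapshot of one tree node (identity, not content)."""

    id: EntityId
    kind: str
    name: str
    parent: EntityId | None
    deleted: bool

    @property
    def is_directory(self) -> bool:
        return self.kind == DIRECTORY


@dataclass(frozen=True)
class Version:
    """One immutable snapshot in an entity's chain."""

    entity: EntityId
    revision: int
    created_at: str
    metadata: md.MetaData
    content: Locator | None
    size_bytes: int
    deleted: bool
    creator: Principal


class Repository:
    """A mounted archive.  Obtain via :func:`mount`; close when done
    (context-manager protocol supported)."""

    def __init__(
        self,
        storage_root: Union[str, Path],
        session: Session,
        publication_config=None,
        max_entries_per_chunk: int = DEFAULT_MAX_ENTRIES_PER_CHUNK,
    ):
        self.storage_root = Path(storage_root)
        if self.storage_root.exists() and not self.storage_root.is_dir():
            raise StorageError(f"not a directory: {self.storage_root}")
        self.storage_root.mkdir(parents=True, exist_ok=True)

        self._lock_path = self.storage_root / ".lock"
        self._lock_file = open(self._lock_path, "w")
        try:
            fcntl.flock(self._lock_file, fcntl.LOCK_EX | fcntl.LOCK_NB)
        except OSError:
            self._lock_file.close()
            raise RepositoryLockedError(
                f"repository at {self.storage_root} is mounted by another process"
            )

        db_dir = self.storage_root / "db"
        db_dir.mkdir(exist_ok=True)
        self.db_path = db_dir / "archive.sqlite"
        existing = self.db_path.exists()
        # check_same_thread off: the embedded HTTP service reads from a
        # worker thread; writes stay on the mounting thread.
        self.conn = sqlite3.connect(
            self.db_path, isolation_level=None, check_same_thread=False
        )
        self.conn.execute("PRAGMA journal_mode=WAL")
        self.conn.execute("PRAGMA synchronous=NORMAL")
        self.conn.execute("PRAGMA foreign_keys=ON")
        if existing:
            check = self.conn.execute("PRAGMA quick_check").fetchone()[0]
            if check != "ok":
                raise IntegrityError(f"corrupt repository database: {check}")
        self.conn.executescript(_SCHEMA)

        self.store_backend = ObjectStore(self.storage_root, max_entries_per_chunk)
        self.index = SearchIndex(self.storage_root / "index")
        self.publication_config = publication_config
        self.outbox_dir = self.storage_root / "outbox"

        root = self._setting("root_id")
        if root is None:
            root = uuid.uuid4().hex
            self._set_setting("root_id", root)
            self._set_setting("secret", uuid.uuid4().hex)
            self.conn.execute(
                "INSERT INTO entities (id, kind, name, parent, owner) "
                "VALUES (?, 'directory', '/', NULL, ?)",
                (root, str(session.user)),
            )
            self._insert_version(
                entity=root,
                revision=1,
                metadata=md.make_metadata(),
                locator=None,
                size_bytes=0,
                deleted=False,
                creator=session.user,
                now=None,
            )
            for action in ALL_ACTIONS:
                self.conn.execute(
                    "INSERT OR IGNORE INTO acl (entity, principal, action) "
                    "VALUES (?, ?, ?)",
                    (root, str(session.user), action.value),
                )
        self.root: EntityId = root

    # -- lifecycle -------------------------------------------------------

    def close(self) -> None:
        self.conn.close()
        self.index.close()
        try:
            fcntl.flock(self._lock_file, fcntl.LOCK_UN)
        finally:
            self._lock_file.close()

    def __enter__(self) -> "Repository":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- settings --------------------------------------------------------

    def _setting(self, key: str) -> str | None:
        row = self.conn.execute(
            "SELECT value FROM settings WHERE key = ?", (key,)
        ).fetchone()
        return row[0] if row else None

    def _set_setting(self, key: str, value: str) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO settings (key, value) VALUES (?, ?)", (key, value)
        )

    @property
    def secret(self) -> str:
        return self._setting("secret") or ""

    # -- lookups ---------------------------------------------------------

    def _entity_row(self, entity: EntityId):
        row = self.conn.execute(
            "SELECT id, kind, name, parent, owner FROM entities WHERE id = ?",
            (entity,),
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no such entity: {entity}")
        return row

    def _latest(self, entity: EntityId):
        return self.conn.execute(
            "SELECT revision, deleted FROM versions WHERE entity = ? "
            "ORDER BY revision DESC LIMIT 1",
            (entity,),
        ).fetchone()

    def _is_deleted(self, entity: EntityId) -> bool:
        latest = self._latest(entity)
        return bool(latest and latest[1])

    def get_entity(self, entity: EntityId) -> PrimaryDataEntity:
        eid, kind, name, parent, _ = self._entity_row(entity)
        return PrimaryDataEntity(eid, kind, name, parent, self._is_deleted(eid))

    def owner(self, entity: EntityId) -> Principal:
        return Principal.parse(self._entity_row(entity)[4])

    def acl_entries(self, entity: EntityId) -> list[tuple[Principal, GrantableAction]]:
        self._entity_row(entity)
        rows = self.conn.execute(
            "SELECT principal, action FROM acl WHERE entity = ? "
            "ORDER BY principal, action",
            (entity,),
        ).fetchall()
        return [(Principal.parse(p), GrantableAction(a)) for p, a in rows]

    # -- permission guard -------------------------------------------------

    def check(self, session: Session, action: GrantableAction, entity: EntityId) -> bool:
        """Pure allow/deny decision for *action* on *entity*."""
        from .permissions import evaluate

        owner = self.owner(entity)
        return evaluate(session, action, owner, self.acl_entries(entity))

    def _guard(self, session: Session, action: GrantableAction, entity: EntityId) -> None:
        if not self.check(session, action, entity):
            raise PermissionDeniedError(
                f"{session.user} lacks {action.value} on entity {entity}"
            )

    def grant(
        self,
        session: Session,
        entity: EntityId,
        principal: Principal,
        action: GrantableAction,
    ) -> None:
        self._entity_row(entity)
        self._guard(session, GrantableAction.PERMISSION_CHANGE, entity)
        self.conn.execute(
            "INSERT OR IGNORE INTO acl (entity, principal, action) VALUES (?, ?, ?)",
            (entity, str(principal), GrantableAction(action).value),
        )

    def revoke(
        self,
        session: Session,
        entity: EntityId,
        principal: Principal,
        action: GrantableAction,
    ) -> None:
        self._entity_row(entity)
        self._guard(session, GrantableAction.PERMISSION_CHANGE, entity)
        self.conn.execute(
            "DELETE FROM acl WHERE entity = ? AND principal = ? AND action = ?",
            (entity, str(principal), GrantableAction(action).value),
        )

    # -- version plumbing -------------------------------------------------

    def _insert_version(
        self,
        entity: EntityId,
        revision: int,
        metadata: md.MetaData,
        locator: Locator | None,
        size_bytes: int,
        deleted: bool,
        creator: Principal,
        now: datetime | None,
    ) -> Version:
        created_at = _iso(now)
        self.conn.execute(
            "INSERT INTO versions (entity, revision, created_at, metadata, "
            "chunk_index, object_name, checksum, size_bytes, deleted, creator) "
            "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            (
                entity,
                revision,
                created_at,
                _json_dumps(metadata.to_dict()),
                locator.chunk_index if locator else None,
                locator.object_name if locator else None,
                locator.checksum if locator else None,
                size_bytes,
                int(deleted),
                str(creator),
            ),
        )
        self.index.index_version(entity, revision, metadata, deleted)
        return Version(
            entity, revision, created_at, metadata, locator, size_bytes, deleted, creator
        )

    def _version_row_to_obj(self, row) -> Version:
        (entity, revision, created_at, meta_json, chunk, objname, checksum,
         size_bytes, deleted, creator) = row
        locator = None
        if objname is not None:
            locator = Locator(chunk, objname, size_bytes, checksum)
        return Version(
            entity,
            revision,
            created_at,
            md.MetaData.from_dict(_json_loads(meta_json)),
            locator,
            size_bytes,
            bool(deleted),
            Principal.parse(creator),
        )

    def get_version(self, entity: EntityId, revision: int | str = "latest") -> Version:
        self._entity_row(entity)
        if revision == "latest":
            row = self.conn.execute(
                "SELECT * FROM versions WHERE entity = ? ORDER BY revision DESC LIMIT 1",
                (entity,),
            ).fetchone()
        else:
            if not isinstance(revision, int) or revision < 1:
                raise NotFoundError(f"revisions start at 1, got {revision!r}")
            row = self.conn.execute(
                "SELECT * FROM versions WHERE entity = ? AND revision = ?",
                (entity, revision),
            ).fetchone()
        if row is None:
            raise NotFoundError(f"entity {entity} has no revision {revision!r}")
        return self._version_row_to_obj(row)

    # -- tree operations ---------------------------------------------------

    def _create_child(
        self,
        parent: EntityId,
        name: str,
        kind: str,
        session: Session,
        now: datetime | None,
    ) -> PrimaryDataEntity:
        if not name or "/" in name:
            raise ValidationError(f"invalid entity name: {name!r}")
        _, pkind, _, _, _ = self._entity_row(parent)
        if pkind != DIRECTORY:
            raise ValidationError("files cannot have children")
        if self._is_deleted(parent):
            raise EntityDeletedError(f"parent directory {parent} is deleted")
        self._guard(session, GrantableAction.CREATE, parent)
        dup = self.conn.execute(
            "SELECT 1 FROM entities WHERE parent = ? AND name = ?", (parent, name)
        ).fetchone()
        if dup:
            raise DuplicateNameError(f"name {name!r} already exists under {parent}")
        eid = uuid.uuid4().hex
        self.conn.execute(
            "INSERT INTO entities (id, kind, name, parent, owner) VALUES (?, ?, ?, ?, ?)",
            (eid, kind, name, parent, str(session.user)),
        )
        # Creation-time ACL inheritance: snapshot of the parent's entries.
        self.conn.execute(
            "INSERT INTO acl (entity, principal, action) "
            "SELECT ?, principal, action FROM acl WHERE entity = ?",
            (eid, parent),
        )
        locator = None
        if kind == FILE:
            locator = self.store_backend.put(b"")
        self._insert_version(
            entity=eid,
            revision=1,
            metadata=md.make_metadata(),
            locator=locator,
            size_bytes=0,
            deleted=False,
            creator=session.user,
            now=now,
        )
        return PrimaryDataEntity(eid, kind, name, parent, False)

    def create_directory(
        self, parent: EntityId, name: str, session: Session, now: datetime | None = None
    ) -> PrimaryDataEntity:
        return self._create_child(parent, name, DIRECTORY, session, now)

    def create_file(
        self, parent: EntityId, name: str, session: Session, now: datetime | None = None
    ) -> PrimaryDataEntity:
        return self._create_child(parent, name, FILE, session, now)

    def store(
        self,
        entity: EntityId,
        content: bytes,
        metadata: md.MetaData | dict | None = None,
        session: Session = None,
        now: datetime | None = None,
    ) -> Version:
        """Append a new content version to a file."""
        _, kind, _, _, _ = self._entity_row(entity)
        if kind != FILE:
            raise ValidationError("store() applies to files only")
        latest = self.get_version(entity)
        if latest.deleted:
            raise EntityDeletedError(
                f"cannot create a new version for deleted entity {entity}"
            )
        self._guard(session, GrantableAction.STORE, entity)
        if metadata is None:
            meta = latest.metadata
        elif isinstance(metadata, md.MetaData):
            meta = metadata
        else:
            meta = md.make_metadata(metadata)
        locator = self.store_backend.put(content)
        return self._insert_version(
            entity=entity,
            revision=latest.revision + 1,
            metadata=meta,
            locator=locator,
            size_bytes=len(content),
            deleted=False,
            creator=session.user,
            now=now,
        )

    def read(
        self,
        entity: EntityId,
        revision: int | str = "latest",
        session: Session = None,
    ) -> bytes:
        """Exact stored bytes of a file revision (checksum-verified)."""
        _, kind, _, _, _ = self._entity_row(entity)
        if kind != FILE:
            raise ValidationError("read() applies to files only")
        self._guard(session, GrantableAction.READ, entity)
        version = self.get_version(entity, revision)
        if version.deleted:
            raise EntityDeletedError(
                f"revision {version.revision} is the deletion marker and has no content"
            )
        assert version.content is not None
        return self.store_backend.get(version.content)

    def set_metadata(
        self,
        entity: EntityId,
        metadata: md.MetaData | dict,
        session: Session = None,
        now: datetime | None = None,
    ) -> Version:
        """Append a metadata-only version sharing the previous content."""
        self._entity_row(entity)
        latest = self.get_version(entity)
        if latest.deleted:
            raise EntityDeletedError(
                f"cannot create a new version for deleted entity {entity}"
            )
        self._guard(session, GrantableAction.METADATA_CHANGE, entity)
        meta = metadata if isinstance(metadata, md.MetaData) else md.make_metadata(metadata)
        return self._insert_version(
            entity=entity,
            revision=latest.revision + 1,
            metadata=meta,
            locator=latest.content,
            size_bytes=latest.size_bytes,
            deleted=False,
            creator=session.user,
            now=now,
        )

    def delete(
        self, entity: EntityId, session: Session = None, now: datetime | None = None
    ) -> Version:
        """Append the terminal ``deleted`` version, ending the chain.

        Directories must have all children deleted first; deleted names
        stay reserved under the parent so old versions remain addressable.
        """
        _, kind, _, _, _ = self._entity_row(entity)
        latest = self.get_version(entity)
        if latest.deleted:
            raise EntityDeletedError(f"entity {entity} is already deleted")
        if kind == DIRECTORY:
            children = self.conn.execute(
                "SELECT id FROM entities WHERE parent = ?", (entity,)
            ).fetchall()
            for (child,) in children:
                if not self._is_deleted(child):
                    raise ValidationError(
                        f"directory {entity} has non-deleted children"
                    )
        self._guard(session, GrantableAction.MODIFY, entity)
        return self._insert_version(
            entity=entity,
            revision=latest.revision + 1,
            metadata=latest.metadata,
            locator=None,
            size_bytes=0,
            deleted=True,
            creator=session.user,
            now=now,
        )

    def list_children(self, entity: EntityId, session: Session) -> list[PrimaryDataEntity]:
        """Name-sorted listing; deleted children included, flag visible."""
        _, kind, _, _, _ = self._entity_row(entity)
        if kind != DIRECTORY:
            raise ValidationError("list_children() applies to directories only")
        self._guard(session, GrantableAction.READ, entity)
        rows = self.conn.execute(
            "SELECT id, kind, name, parent FROM entities WHERE parent = ? "
            "ORDER BY name",
            (entity,),
        ).fetchall()
        return [
            PrimaryDataEntity(eid, k, n, p, self._is_deleted(eid))
            for eid, k, n, p in rows
        ]

    def list_versions(self, entity: EntityId, session: Session) -> list[Version]:
        """All versions in ascending, contiguous revision order."""
        self._entity_row(entity)
        self._guard(session, GrantableAction.READ, entity)
        rows = self.conn.execute(
            "SELECT * FROM versions WHERE entity = ? ORDER BY revision", (entity,)
        ).fetchall()
        return [self._version_row_to_obj(r) for r in rows]

    def resolve_path(self, path: str, session: Session = None) -> EntityId:
        """Resolve a ``/``-separated path from the root to an entity id."""
        current = self.root
        for component in [c for c in path.split("/") if c]:
            row = self.conn.execute(
                "SELECT id FROM entities WHERE parent = ? AND name = ?",
                (current, component),
            ).fetchone()
            if row is None:
                raise NotFoundError(f"path not found: {path!r} (at {component!r})")
            current = row[0]
        return current

    def path_of(self, entity: EntityId) -> str:
        """Inverse of :meth:`resolve_path`."""
        parts: list[str] = []
        current = entity
        while True:
            _, _, name, parent, _ = self._entity_row(current)
            if parent is None:
                break
            parts.append(name)
            current = parent
        return "/" + "/".join(reversed(parts))

    # -- maintenance -------------------------------------------------------

    def reindex(self) -> int:
        """Rebuild the search index from the database; returns the number
        of versions indexed."""
        self.index.clear()
        count = 0
        for row in self.conn.execute("SELECT * FROM versions ORDER BY entity, revision"):
            version = self._version_row_to_obj(row)
            self.index.index_version(
                version.entity, version.revision, version.metadata, version.deleted
            )
            count += 1
        return count

    def dump(self) -> dict:
        """Canonical, deterministic snapshot of all persisted state
        (entities, version chains, ACLs, publication references).

        Used for persistence round-trip and no-state-change assertions.
        """
        entities = {}
        for eid, kind, name, parent, owner in self.conn.execute(
            "SELECT id, kind, name, parent, owner FROM entities ORDER BY id"
        ):
            versions = []
            for row in self.conn.execute(
                "SELECT * FROM versions WHERE entity = ? ORDER BY revision", (eid,)
            ):
                v = self._version_row_to_obj(row)
                versions.append(
                    {
                        "revision": v.revision,
                        "created_at": v.created_at,
                        "metadata": v.metadata.to_dict(),
                        "locator": v.content.to_dict() if v.content else None,
                        "size_bytes": v.size_bytes,
                        "deleted": v.deleted,
                        "creator": str(v.creator),
                    }
                )
            acl = sorted(
                (str(p), a.value) for p, a in self.acl_entries(eid)
            )
            entities[eid] = {
                "kind": kind,
                "name": name,
                "parent": parent,
                "owner": owner,
                "versions": versions,
                "acl": acl,
            }
        refs = [
            dict(zip([c[0] for c in cur.description], row))
            for cur in [self.conn.execute("SELECT * FROM refs ORDER BY token")]
            for row in cur.fetchall()
        ]
        return {"root": self.root, "entities": entities, "refs": refs}


def mount(
    storage_root: Union[str, Path],
    session: Session,
    publication_config=None,
    max_entries_per_chunk: int = DEFAULT_MAX_ENTRIES_PER_CHUNK,
) -> Repository:
    """Mount (and on first use initialize) the archive at *storage_root*.

    Re-mounting an existing root recovers the persisted tree and version
    chains; the first mounting principal becomes the root owner and
    holds all grantable actions on it.
    """
    return Repository(storage_root, session, publication_config, max_entries_per_chunk)


# JSON helpers kept local so the storage format is one obvious function pair.
import json as _json  # noqa: E402


def _json_dumps(obj) -> str:
    return _json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _json_loads(text: str):
    return _json.loads(text)
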