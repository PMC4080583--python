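"""Full-text metadata retrieval with exact, substring, and phonetic matching.

Every persisted version's set metadata elements are tokenized
(lowercased, split on non-alphanumeric characters) into a persistent
inverted index kept as a small SQLite database under
``<storage_root>/index`` — separate from the main database so it can be
dropped and rebuilt (``reindex``) at any time.

Query modes:

``exact``
    token equality,
``substring``
    token *contains* the query text (partial-string match),
``phonetic``
    equal Metaphone codes (``smith`` finds ``smyth``).

Matches can target one Dublin Core element or all of them.  Scoring is
deterministic: 1.0 per exactly matched element, 0.7 per substring match,
0.5 per phonetic match, summed over elements; ties are broken by
``(entity id, revision)``.  Deleted versions stay searchable — history
must remain findable — but hits expose the deleted flag.
"""

from __future__ import annotations

import enum
import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError
from .metadata import ELEMENT_NAMES, UNKNOWN, MetaData
from .phonetic import metaphone

_TOKEN_RE = re.compile(r"[^0-9a-z]+")

ALL = "ALL"


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric characters."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


class MatchMode(str, enum.Enum):
    EXACT = "exact"
    SUBSTRING = "substring"
    PHONETIC = "phonetic"


_MODE_SCORE = {
    MatchMode.EXACT: 1.0,
    MatchMode.SUBSTRING: 0.7,
    MatchMode.PHONETIC: 0.5,
}


@dataclass(frozen=True)
class Query:
    """A keyword query over metadata.

    ``target`` is either :data:`ALL` or one DCMES element name.
    """

    text: str
    target: str = ALL
    mode: MatchMode = MatchMode.EXACT

    def __post_init__(self):
        if not self.text.strip():
            raise ValidationError("query text must be non-empty")
        if self.target != ALL and self.target not in ELEMENT_NAMES:
            raise ValidationError(f"unknown query target: {self.target!r}")


@dataclass(frozen=True)
class Hit:
    entity: str
    revision: int
    element: str
    score: float
    deleted: bool = False


class SearchIndex:
    """SQLite-backed inverted index over version metadata."""

    def __init__(self, directory: Path):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.path = directory / "index.sqlite"
        self.conn = sqlite3.connect(
            self.path, isolation_level=None, check_same_thread=False
        )
        self.conn.execute("PRAGMA journal_mode=WAL")
        self.conn.execute("PRAGMA synchronous=NORMAL")
        self.conn.executescript(
            """
            CREATE TABLE IF NOT EXISTS tokens (
                entity TEXT NOT NULL,
                revision INTEGER NOT NULL,
                element TEXT NOT NULL,
                token TEXT NOT NULL,
                phonetic TEXT NOT NULL
            );
            CREATE INDEX IF NOT EXISTS ix_tokens_token ON tokens(token);
            CREATE INDEX IF NOT EXISTS ix_tokens_phon ON tokens(phonetic);
            CREATE INDEX IF NOT EXISTS ix_tokens_ver ON tokens(entity, revision);
            CREATE TABLE IF NOT EXISTS versions (
                entity TEXT NOT NULL,
                revision INTEGER NOT NULL,
                deleted INTEGER NOT NULL,
                PRIMARY KEY (entity, revision)
            );
            """
        )

    def close(self) -> None:
        self.conn.close()

    def clear(self) -> None:
        self.conn.execute("DELETE FROM tokens")
        self.conn.execute("DELETE FROM versions")

    def index_version(
        self, entity: str, revision: int, metadata: MetaData, deleted: bool
    ) -> None:
        """(Re-)index one version's set metadata elements; idempotent."""
        cur = self.conn.cursor()
        cur.execute("BEGIN")
        cur.execute(
            "DELETE FROM tokens WHERE entity = ? AND revision = ?", (entity, revision)
        )
        rows = []
        for name, value in metadata.items():
            if value is UNKNOWN:
                continue
            for token in set(tokenize(metadata.display(name))):
                rows.append((entity, revision, name, token, metaphone(token)))
        cur.executemany(
            "INSERT INTO tokens (entity, revision, element, token, phonetic) "
            "VALUES (?, ?, ?, ?, ?)",
            rows,
        )
        cur.execute(
            "INSERT OR REPLACE INTO versions (entity, revision, deleted) "
            "VALUES (?, ?, ?)",
            (entity, revision, int(deleted)),
        )
        cur.execute("COMMIT")

    def size(self) -> int:
        """Number of indexed (entity, revision, element, token) postings."""
        return self.conn.execute("SELECT COUNT(*) FROM tokens").fetchone()[0]

    def raw_matches(self, query: Query) -> list[tuple[str, int, str, bool]]:
        """All ``(entity, revision, element, deleted)`` postings matching
        *query*, before permission filtering and scoring."""
        text = query.text.strip().lower()
        if query.mode is MatchMode.EXACT:
            cond, arg = "t.token = ?", text
        elif query.mode is MatchMode.SUBSTRING:
            cond, arg = "instr(t.token, ?) > 0", text
        else:
            cond, arg = "t.phonetic = ? AND t.phonetic != ''", metaphone(text)
        sql = (
            "SELECT DISTINCT t.entity, t.revision, t.element, v.deleted "
            "FROM tokens t JOIN versions v "
            "ON v.entity = t.entity AND v.revision = t.revision "
            f"WHERE {cond}"
        )
        params = [arg]
        if query.target != ALL:
            sql += " AND t.element = ?"
            params.append(query.target)
        return [
            (e, r, el, bool(d))
            for e, r, el, d in self.conn.execute(sql, params).fetchall()
        ]


def search(repo, query: Query, session) -> list[Hit]:
    """Run *query* against the repository index.

    Results are restricted to versions the session may read and ordered
    by descending score, then ``(entity id, revision)``.
    """
    from .permissions import GrantableAction

    matches = repo.index.raw_matches(query)
    per_version: dict[tuple[str, int], list[str]] = {}
    deleted_flags: dict[tuple[str, int], bool] = {}
    for entity, revision, element, deleted in matches:
        per_version.setdefault((entity, revision), []).append(element)
        deleted_flags[(entity, revision)] = deleted

    readable: dict[str, bool] = {}
    hits = []
    score_unit = _MODE_SCORE[query.mode]
    for (entity, revision), elements in per_version.items():
        if entity not in readable:
            readable[entity] = repo.check(session, GrantableAction.READ, entity)
        if not readable[entity]:
            continue
        hits.append(
            Hit(
                entity=entity,
                revision=revision,
                element=min(elements),
                score=score_unit * len(elements),
                deleted=deleted_flags[(entity, revision)],
            )
        )
    hits.sort(key=lambda h: (-h.score, h.entity, h.revision))
    return hits
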