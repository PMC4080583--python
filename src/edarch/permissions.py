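"""Principals, sessions, grantable actions, and pluggable authentication.

Access control is default-deny: an operation is allowed only when the
session's user (or one of its group/role memberships) holds a matching
ACL entry on the entity — or is the entity's owner, who always passes
for all seven grantable actions.  The seven actions cover creation,
modification, read, store, metadata change, permission change, and
publication; every sensitive repository operation is wrapped in a
uniform guard that consults :func:`evaluate`.

Authentication is pluggable: a provider maps credentials to a user
principal plus group/role memberships.  Built-ins are a salted local
user table, an OS-account echo provider, and a permissive test provider.
"""

from __future__ import annotations

import enum
import getpass
import hashlib
import secrets
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol

from .errors import AuthenticationError


class PrincipalKind(str, enum.Enum):
    USER = "user"
    GROUP = "group"
    ROLE = "role"


@dataclass(frozen=True)
class Principal:
    kind: PrincipalKind
    name: str

    def __str__(self) -> str:
        return f"{self.kind.value}:{self.name}"

    @classmethod
    def parse(cls, text: str) -> "Principal":
        kind, _, name = text.partition(":")
        return cls(PrincipalKind(kind), name)


def user(name: str) -> Principal:
    return Principal(PrincipalKind.USER, name)


def group(name: str) -> Principal:
    return Principal(PrincipalKind.GROUP, name)


def role(name: str) -> Principal:
    return Principal(PrincipalKind.ROLE, name)


class GrantableAction(str, enum.Enum):
    """The seven permission-controlled operation categories."""

    CREATE = "CREATE"
    MODIFY = "MODIFY"
    READ = "READ"
    STORE = "STORE"
    METADATA_CHANGE = "METADATA_CHANGE"
    PERMISSION_CHANGE = "PERMISSION_CHANGE"
    PUBLICATION = "PUBLICATION"


ALL_ACTIONS = frozenset(GrantableAction)


@dataclass(frozen=True)
class Session:
    """An authenticated user context; produced only by :func:`login`."""

    user: Principal
    memberships: frozenset[Principal] = field(default_factory=frozenset)
    authenticated_via: str = ""

    def principals(self) -> frozenset[Principal]:
        return self.memberships | {self.user}


def evaluate(
    session: Session,
    action: GrantableAction,
    owner: Principal,
    granted: Iterable[tuple[Principal, GrantableAction]],
) -> bool:
    """Pure ACL decision: allow iff the session's user is the owner, or
    any of its principals holds a matching grant. Absence denies."""
    if session.user == owner:
        return True
    principals = session.principals()
    return any(p in principals and a == action for p, a in granted)


# -- authentication providers -------------------------------------------


class AuthProvider(Protocol):
    """Contract for pluggable login modules."""

    name: str

    def authenticate(self, credentials: Mapping) -> tuple[Principal, frozenset[Principal]]:
        """Return ``(user principal, memberships)`` or raise
        :class:`~edarch.errors.AuthenticationError`."""
        ...


class TestProvider:
    """Accepts any username; memberships come from a configured map.

    Intended for tests and embedded single-user use.
    """

    name = "test"
    __test__ = False  # not a pytest collection target

    def __init__(self, memberships: Mapping[str, Iterable[Principal]] | None = None):
        self._memberships = {k: frozenset(v) for k, v in (memberships or {}).items()}

    def authenticate(self, credentials):
        username = credentials.get("username", "").strip()
        if not username:
            raise AuthenticationError("test provider requires a username")
        return user(username), self._memberships.get(username, frozenset())


class OSAccountProvider:
    """Echoes the operating-system account of the calling process."""

    name = "os"

    def authenticate(self, credentials):
        return user(getpass.getuser()), frozenset()


class LocalUserProvider:
    """Salted-hash user table stored as a plain text file.

    One line per user: ``name:salt:sha256(salt+password):group1,group2``.
    """

    name = "local"

    def __init__(self, table_path: Path):
        self.table_path = Path(table_path)

    @staticmethod
    def _hash(salt: str, password: str) -> str:
        return hashlib.sha256((salt + password).encode()).hexdigest()

    def add_user(self, username: str, password: str, groups: Iterable[str] = ()) -> None:
        salt = secrets.token_hex(8)
        line = f"{username}:{salt}:{self._hash(salt, password)}:{','.join(groups)}\n"
        with open(self.table_path, "a", encoding="utf-8") as fh:
            fh.write(line)

    def authenticate(self, credentials):
        username = credentials.get("username", "")
        password = credentials.get("password", "")
        if self.table_path.exists():
            for line in self.table_path.read_text(encoding="utf-8").splitlines():
                if not line.strip():
                    continue
                name, salt, digest, groups = line.split(":", 3)
                if name != username:
                    continue
                if secrets.compare_digest(digest, self._hash(salt, password)):
                    memberships = frozenset(
                        group(g) for g in groups.split(",") if g
                    )
                    return user(name), memberships
                break
        raise AuthenticationError(f"bad credentials for {username!r}")


def login(provider: AuthProvider, credentials: Mapping | None = None, **kw) -> Session:
    """Authenticate against *provider* and return a session.

    Credentials may be given as a mapping or keyword arguments
    (``login(p, username="alice")``).
    """
    creds = dict(credentials or {})
    creds.update(kw)
    principal, memberships = provider.authenticate(creds)
    return Session(
        user=principal, memberships=memberships, authenticated_via=provider.name
    )
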