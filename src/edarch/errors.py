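"""Exception hierarchy for the archive.

Every error raised by the public API derives from :class:`ArchiveError`,
so embedding applications can catch a single base class.
"""


class ArchiveError(Exception):
    """Base class for all archive errors."""


class IntegrityError(ArchiveError):
    """Persisted state is corrupt (checksum mismatch, hash collision)."""


class StorageError(ArchiveError):
    """I/O failure or missing object in the content store."""


class NotFoundError(ArchiveError):
    """Entity, revision, path, or reference does not exist."""


class ValidationError(ArchiveError):
    """Metadata or input value failed validation."""


class DuplicateNameError(ArchiveError):
    """Sibling name already in use under the parent directory."""


class EntityDeletedError(ArchiveError):
    """The entity's version chain has been terminated by a deletion."""


class PermissionDeniedError(ArchiveError):
    """Session does not hold the required grantable action."""


class AuthenticationError(ArchiveError):
    """Login failed (bad credentials or unknown provider)."""


class RepositoryLockedError(ArchiveError):
    """Another process holds the single-writer lock on the storage root."""


class WorkflowError(ArchiveError):
    """Invalid publication-workflow transition (double decision, terminal state)."""


class MigrationError(ValidationError):
    """Metadata record is missing elements mandatory for identifier registration.

    ``missing`` lists the absent element names.
    """

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "metadata lacks mandatory elements: " + ", ".join(self.missing)
        )
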