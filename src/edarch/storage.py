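"""Content-addressed chunked object store.

Every stored byte stream lives as one plain file
``objects/chunk-<k>/<sha256-hex>``; a new chunk directory is opened
whenever the current one reaches ``max_entries_per_chunk`` objects, so
no directory ever grows beyond the threshold and ordinary file-system
tools (cp, rsync, tar) suffice for backup and disaster recovery.

Content addressing by SHA-256 gives free integrity checking (checksums
are re-verified on every read) and deduplication (storing identical
bytes twice returns the same locator).
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from pathlib import Path

from .errors import IntegrityError, StorageError

DEFAULT_MAX_ENTRIES_PER_CHUNK = 1000


@dataclass(frozen=True)
class Locator:
    """Handle to one stored object: chunk directory index, content-hash
    object name, byte size, and the SHA-256 checksum of the bytes."""

    chunk_index: int
    object_name: str
    size_bytes: int
    checksum: str

    def to_dict(self) -> dict:
        return {
            "chunk_index": self.chunk_index,
            "object_name": self.object_name,
            "size_bytes": self.size_bytes,
            "checksum": self.checksum,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Locator":
        return cls(**d)


class ObjectStore:
    """The on-disk object store rooted at ``<root>/objects``."""

    def __init__(self, root: Path, max_entries_per_chunk: int = DEFAULT_MAX_ENTRIES_PER_CHUNK):
        if max_entries_per_chunk <= 0:
            raise ValueError("max_entries_per_chunk must be > 0")
        self.root = Path(root)
        self.max_entries_per_chunk = max_entries_per_chunk
        self.objects_dir = self.root / "objects"
        self.objects_dir.mkdir(parents=True, exist_ok=True)
        # Content-hash -> locator map, rebuilt from the directory tree so
        # the store has no state beyond the plain files themselves.
        self._by_hash: dict[str, Locator] = {}
        self._chunk_counts: dict[int, int] = {}
        self._scan()

    def _scan(self) -> None:
        for chunk_dir in sorted(self.objects_dir.glob("chunk-*")):
            try:
                k = int(chunk_dir.name.split("-", 1)[1])
            except ValueError:
                continue
            count = 0
            for obj in chunk_dir.iterdir():
                if not obj.is_file():
                    continue
                count += 1
                size = obj.stat().st_size
                self._by_hash[obj.name] = Locator(k, obj.name, size, obj.name)
            self._chunk_counts[k] = count

    def _open_chunk(self) -> int:
        """Index of the chunk directory the next object goes into."""
        if not self._chunk_counts:
            return 0
        last = max(self._chunk_counts)
        if self._chunk_counts[last] >= self.max_entries_per_chunk:
            return last + 1
        return last

    def put(self, content: bytes) -> Locator:
        """Store *content*, returning its locator; identical content is
        deduplicated to the already-stored object."""
        digest = hashlib.sha256(content).hexdigest()
        existing = self._by_hash.get(digest)
        if existing is not None:
            path = self._path(existing)
            if path.stat().st_size != len(content):
                raise IntegrityError(
                    f"hash collision for {digest}: differing sizes on disk"
                )
            return existing
        k = self._open_chunk()
        chunk_dir = self.objects_dir / f"chunk-{k}"
        chunk_dir.mkdir(exist_ok=True)
        tmp = chunk_dir / f".tmp-{os.getpid()}-{digest[:12]}"
        try:
            tmp.write_bytes(content)
            tmp.replace(chunk_dir / digest)
        except OSError as exc:
            tmp.unlink(missing_ok=True)
            raise StorageError(f"cannot write object {digest}: {exc}") from exc
        locator = Locator(k, digest, len(content), digest)
        self._by_hash[digest] = locator
        self._chunk_counts[k] = self._chunk_counts.get(k, 0) + 1
        return locator

    def _path(self, locator: Locator) -> Path:
        return self.objects_dir / f"chunk-{locator.chunk_index}" / locator.object_name

    def get(self, locator: Locator) -> bytes:
        """Retrieve the exact original bytes; the checksum is re-verified."""
        path = self._path(locator)
        if not path.is_file():
            raise StorageError(f"missing object {locator.object_name}")
        content = path.read_bytes()
        if hashlib.sha256(content).hexdigest() != locator.checksum:
            raise IntegrityError(
                f"checksum mismatch for object {locator.object_name}"
            )
        return content

    def stats(self) -> tuple[int, int, int]:
        """``(object count, chunk count, total bytes)`` computed purely
        from the directory tree, for external backup verification."""
        objects = chunks = total = 0
        for chunk_dir in self.objects_dir.glob("chunk-*"):
            if not chunk_dir.is_dir():
                continue
            chunks += 1
            for obj in chunk_dir.iterdir():
                if obj.is_file() and not obj.name.startswith("."):
                    objects += 1
                    total += obj.stat().st_size
        return objects, chunks, total
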