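"""Synthetic benchmark corpora and the benchmark harness.

The generator reproduces the archive's reference benchmark design:
*n* folders each holding *m* files of a fixed size (the reference scale
is 10,000 files in 100 folders at 0.1–1.0 MB per file), with metadata
planted so that keyword queries have a known answer — every file's
``subject`` element carries exactly one keyword shared by exactly one
group of ``keyword_group_size`` files, so a search for any planted
keyword must return exactly that many hits regardless of corpus size.

Generation is fully deterministic given the seed: file contents are
seeded pseudo-random bytes prefixed with the file index (guaranteeing
unique content, hence no store-level deduplication), and the returned
manifest records path, checksum, and planted keyword per file for
oracle-style verification.

Benchmark timings are reported for information only, never asserted —
they are hardware-bound.
"""

from __future__ import annotations

import hashlib
import random
import time
from dataclasses import dataclass, field

from .errors import ValidationError
from .metadata import Person, make_metadata
from .permissions import Session
from .search import MatchMode, Query, search

FIXTURE_CREATOR = Person(name="Archive, Fixture", affiliation="synthetic benchmark corpus")


@dataclass(frozen=True)
class FixturePlan:
    """Shape of a synthetic corpus.

    ``keyword_group_size`` files share each planted keyword; the total
    file count must be divisible by it.
    """

    n_folders: int = 100
    files_per_folder: int = 100
    file_size_bytes: int = 102_400
    keyword_group_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_folders <= 0 or self.files_per_folder <= 0:
            raise ValidationError("fixture plan must produce at least one file")
        if self.file_size_bytes < 0:
            raise ValidationError("file size must be >= 0")
        if self.keyword_group_size <= 0:
            raise ValidationError("keyword group size must be > 0")
        if self.total_files % self.keyword_group_size:
            raise ValidationError(
                "total file count must be a multiple of the keyword group size"
            )

    @property
    def total_files(self) -> int:
        return self.n_folders * self.files_per_folder

    @property
    def keywords(self) -> list[str]:
        return [
            f"kw{g:04d}" for g in range(self.total_files // self.keyword_group_size)
        ]


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    entity: str
    checksum: str
    keyword: str
    size_bytes: int


def _file_content(plan: FixturePlan, index: int) -> bytes:
    rng = random.Random((plan.seed << 24) ^ index)
    prefix = index.to_bytes(8, "big")  # unique content per file -> no dedup
    body = rng.randbytes(max(plan.file_size_bytes - len(prefix), 0))
    return (prefix + body)[: plan.file_size_bytes] if plan.file_size_bytes else b""


def generate_fixture(repo, plan: FixturePlan, session: Session) -> list[ManifestEntry]:
    """Create the corpus inside *repo* under ``/fixture``; deterministic
    given ``plan.seed``.  Returns the per-file manifest."""
    base = repo.create_directory(repo.root, "fixture", session).id
    manifest: list[ManifestEntry] = []
    index = 0
    for folder_i in range(plan.n_folders):
        folder = repo.create_directory(base, f"folder{folder_i:03d}", session).id
        for _ in range(plan.files_per_folder):
            name = f"f{index:05d}.dat"
            keyword = f"kw{index // plan.keyword_group_size:04d}"
            content = _file_content(plan, index)
            entity = repo.create_file(folder, name, session).id
            meta = make_metadata(
                {"title": name, "subject": keyword, "creator": FIXTURE_CREATOR}
            )
            repo.store(entity, content, metadata=meta, session=session)
            manifest.append(
                ManifestEntry(
                    path=f"/fixture/folder{folder_i:03d}/{name}",
                    entity=entity,
                    checksum=hashlib.sha256(content).hexdigest(),
                    keyword=keyword,
                    size_bytes=len(content),
                )
            )
            index += 1
    return manifest


@dataclass
class BenchmarkReport:
    """Counts are exact and assertable; timings are informational only."""

    n_stored: int
    n_read: int
    bytes_read: int
    search_hits: dict[str, int]
    store_seconds: float = field(repr=False, default=0.0)
    read_seconds: float = field(repr=False, default=0.0)
    search_seconds: float = field(repr=False, default=0.0)


def run_benchmark(
    repo, plan: FixturePlan, session: Session, n_queries: int = 5
) -> BenchmarkReport:
    """Store the corpus, read every payload back (verifying checksums),
    and run planted-keyword searches with a known answer size."""
    t0 = time.perf_counter()
    manifest = generate_fixture(repo, plan, session)
    t_store = time.perf_counter() - t0

    t0 = time.perf_counter()
    n_read = bytes_read = 0
    for entry in manifest:
        payload = repo.read(entry.entity, "latest", session)
        if hashlib.sha256(payload).hexdigest() != entry.checksum:
            raise ValidationError(f"read-back mismatch for {entry.path}")
        n_read += 1
        bytes_read += len(payload)
    t_read = time.perf_counter() - t0

    rng = random.Random(plan.seed)
    queried = rng.sample(plan.keywords, min(n_queries, len(plan.keywords)))
    t0 = time.perf_counter()
    hits = {
        kw: len(search(repo, Query(kw, target="subject", mode=MatchMode.EXACT), session))
        for kw in queried
    }
    t_search = time.perf_counter() - t0

    return BenchmarkReport(
        n_stored=len(manifest),
        n_read=n_read,
        bytes_read=bytes_read,
        search_hits=hits,
        store_seconds=t_store,
        read_seconds=t_read,
        search_seconds=t_search,
    )
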