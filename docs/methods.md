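# Methods

This note documents the archive's data model, the decision rules that
were genuinely open choices, the numerical/representation conventions,
what the synthetic corpus generator does and does not emulate, and the
known limitations.

## Data model

A repository is a rooted tree of **entities** — directories and files —
each identified by a stable opaque id and owning an **append-only chain
of immutable versions** numbered contiguously from 1.  Operations never
mutate: storing content, changing metadata, and deleting all *append* a
version.  The deletion version is terminal: it carries no content, it
must be the last link of the chain, and any attempt to store, re-tag, or
re-delete afterwards fails.  Earlier revisions remain readable forever,
which is the preservation contract the model exists for.

Representation conventions:

- Revisions are integers starting at 1 (the base version created with
  the entity).  A file's revision 1 is an empty placeholder with
  all-unknown metadata, so every entity has at least one version.
- Timestamps are UTC ISO-8601 strings.
- Directory deletion requires all children to be deleted first.
  Recursive deletion is deliberately not offered: a single call that
  terminates many version chains is too destructive for an archive.
- Deleted names stay reserved under their parent, because the deleted
  entity's history must remain addressable by path and listing.
- One process mounts a storage root at a time (an advisory
  single-writer lock, `flock` on `<root>/.lock`).  This is the simplest
  correct concurrency contract for an embedded database; shared access
  belongs to a server deployment in front of the library.

Persistence is deliberately boring: a single SQLite database (WAL mode,
`synchronous=NORMAL`) under `db/`, content objects as plain files under
`objects/`, the search index under `index/`, notification files under
`outbox/`.  Everything is ordinary files, so file-system backup tooling
is the disaster-recovery story; the search index is derived state and
can always be rebuilt (`reindex`).

## Metadata

Records use the 15-element Dublin Core element set with one typed slot
per element: `creator`/`contributor` are structured persons
(name + affiliation, displayed as `"name, affiliation"`), `date` is an
ISO calendar date, `format` a media-type string, the rest UTF-8 text.
Unset slots hold an explicit *unknown* marker rather than being absent,
which keeps records fixed-shape for indexing and migration.  Validation
is type-level only; no element beyond what DOI registration needs is
treated as mandatory, because archiving must not be blocked on
incomplete annotation.

File **size is not a metadata element** — the element set stays at
exactly 15.  Size is an attribute of the version and is injected into
human-readable listings as a synthetic `Size` row, formatted as KB with
one decimal (101,069 bytes → `98.7 KB`), slotted into the listing's
alphabetical label order between `Rights` and `Source`.

Format sniffing uses a small magic-byte table (gzip, zip, PDF, PNG),
then a printable-byte heuristic for plain text (≥ 95% printable in the
first KiB; the threshold is a keyword argument), then the filename
extension, else `application/octet-stream`.

## Content store

Objects are content-addressed by SHA-256 and stored one file per object
as `objects/chunk-<k>/<hex digest>`.  A chunk directory admits at most
`max_entries_per_chunk` objects (default 1000); when full, the next
index opens.  This keeps directories small for file-system tooling — the
"self-tuning" behavior is threshold-triggered rollover, the simplest
mechanism with that property.  Content addressing buys integrity
(checksums re-verified on every read; a hash collision with differing
sizes raises an integrity error) and deduplication (identical payloads
share one object).  `stats()` is computed purely from the directory
tree, so an administrator can verify a backup without the database.

## Retrieval

Indexed text is the display string of every set element, lowercased and
split on non-alphanumerics.  Three match modes:

- *exact*: token equality;
- *substring*: the query text occurs inside a token (token-level, not
  across token boundaries; no wildcard syntax);
- *phonetic*: equal classic Metaphone codes (so `smith` ↔ `smyth`,
  `night` ↔ `nite`).  Metaphone was chosen as the canonical, simple
  phonetic code for English; the encoder implements the standard
  consonant rule set.

Scores are deterministic by construction — 1.0 / 0.7 / 0.5 per matched
element for exact / substring / phonetic, summed over elements of a
version — with ties broken by (entity id, revision).  No corpus
statistics enter the score, so result order is stable across corpus
growth.  Deleted versions remain searchable (history must stay
findable) with the deleted flag exposed on the hit; results are
filtered to entities the session may READ.

## Permissions

Default-deny allow-lists over seven grantable actions.  The entity's
creator is its owner and passes every check; other principals need an
ACL entry for (entity, action) matching their user or a group/role
membership.  A child entity copies its parent's ACL entries *at creation
time* — a snapshot, not a live link, so later changes to the parent do
not propagate.  ACLs are not versioned (version chains record data and
metadata; permissions are operational state).  Every sensitive operation
calls one shared guard before touching state, so a denied call provably
performs no state change (asserted by repository-dump comparison in the
tests).  Published, accepted references are world-readable through the
public server channel only, which reconciles private ACLs with public
data access.

## Publication workflow

Three reviewers — legal, scientific, and a master with veto power — are
configured with email addresses.  A request immediately creates a
PENDING reference with a resolvable landing page (download locked) and
sends each reviewer a notification containing HMAC-signed accept/reject
tokens usable offline (`decide --token`).

The decision rule, made precise here because "exclusively or
collaboratively" admits several readings:

1. An **explicit master verdict is decisive either way** — that is the
   veto, and it allows the master to decide alone.
2. Otherwise the request resolves once all three roles hold verdicts.
   Silent reviewers are reminded once after `reminder_after` (default
   7 days) and receive the configured `default_verdict` after
   `default_after` (default 14 days).
3. A defaulted master *reject* rejects.  A defaulted master *accept*
   requires unanimity of all three verdicts.

The shipped default verdict is **reject**: publication is a formal act
and silence should not publish data.  Both defaults are configuration,
not policy baked into code.  The tests verify the rule exhaustively over
all 3³ verdict combinations against an independently stated oracle.

On acceptance: DOIs are minted as `prefix/namespace/year/sequence`, with
the year taken from the acceptance time and sequence = count of
previously accepted DOIs in that namespace and year (hence gapless from
0).  The Dublin Core record is migrated to DataCite XML — mandatory
fields identifier/creators/titles/publisher/publicationYear from the
DOI, `creator`, `title`, `publisher`, and the acceptance year; optional
blocks map `subject` (comma-split) → subjects, `contributor` →
contributors, `date` → dates (Issued), `description` → descriptions
(Abstract), `format` → formats, `rights` → rightsList, `language` →
language, and the version's byte size → sizes.  `coverage`, `relation`,
`source`, `type`, and the free-text `identifier` element have no clean
DataCite slot in the mandatory-plus-common subset and are not migrated.
A DOI request is refused up front when creator/title/publisher are
unset, so acceptance can never strand a half-finished registration.
The registrar transport is invoked exactly once per accepted DOI; a
transport failure keeps the acceptance, flags the reference
`registration_pending`, and `retry_registration` re-sends without
re-minting.  Every terminal transition notifies the requester once.

Identifier registration delays only the *download* when a release date
lies in the future; the landing page and the registration itself are
not embargoed — the identifier should resolve from day one.

## Public channel and virtual tree

Landing pages are deterministic HTML (same reference + same clock →
byte-identical output) showing the citation line
`creators (year): title. publisher. identifier` — a common convention,
adopted here, not a mandated format — plus the metadata listing and the
download link or lock notice.  The clock is an injected parameter
throughout, so embargo behavior is testable without waiting.  The HTTP
service is a thin stdlib server over these pure functions with routes
`/ref/<token>`, `/ref/<token>/download`, `/doi/<doi>`.

For file-browser consumers the versioned tree exports as a *virtual
tree*: each archived file becomes a folder containing, per non-deleted
version `r`, a content file `v<r>_<name>` and a metadata document
`v<r>_metadata.xml` (which parses back to the exact record); network
file-system wire protocols are out of scope — the export plus a local
mirror is the supported path.

## Synthetic corpus generator

`edarch.fixtures` reproduces the reference benchmark design: `n_folders ×
files_per_folder` files of a fixed size, each file's `subject` carrying
one keyword shared by exactly `keyword_group_size` files, title = file
name, a fixed synthetic creator.  Contents are seeded pseudo-random
bytes prefixed with the file index, so payloads are unique (no
dedup) and two runs with equal seeds are byte-identical.  The reference
scale is 100 folders × 100 files (10,000 files) with groups of 10, so
every planted-keyword query has exactly 10 correct answers regardless of
corpus size — the property the retrieval benchmark measures.

What the generator does *not* emulate: realistic file-format mixtures,
skewed size distributions, correlated or free-text metadata, concurrent
writers, or clock skew.  Passing tests therefore demonstrate the
archive's bookkeeping and retrieval contracts, not ranking quality on
real annotations.

Problem sizes: the test suite exercises the full 10,000-file corpus at
1 KiB per file plus small corpora for oracle-equivalence checks;
`scripts/acceptance.py` uses the same 100 × 100 / 1 KiB configuration.
The planted-keyword hit count is independent of the file size, which is
why a small payload size is the package's default for the retrieval
benchmark; the 0.1–1.0 MB payload range of the original wall-clock
benchmark matters only for I/O timing, which is hardware-bound and
reported by `run_benchmark` but never asserted.

## Known limitations

- No rename/move and no hard deletion or garbage collection: version
  chains and identifiers must stay stable.
- Single-writer embedded use; no remote-object protocol.
- Substring matching is within-token only; no mid-token wildcards.
- The local login provider is a salted-SHA-256 user table intended for
  small deployments; enterprise authentication should come through a
  custom provider.
- The DataCite document targets the kernel-4 namespace's mandatory
  subset plus common optional blocks; it is not a complete schema
  implementation.
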