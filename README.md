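# edarch

An embeddable, file-based archive for *primary research data* — the raw
and preprocessed files that underlie a publication and must remain
intact, findable, and citable long after the paper appears.  Most such
data never reaches a repository because archiving is a side task:
`edarch` is a library (plus a thin CLI) that applications and pipelines
can mount like a file system, so preservation happens where the data is
produced.

It combines, in one storage root of plain files:

- **Append-only version chains.**  Every entity (file or directory) owns
  an immutable sequence of versions, revision 1..n; every data or
  metadata update appends, nothing rewrites.  Deletion appends a
  terminal version tagged *deleted* — the chain ends, but every earlier
  revision stays readable.  Primary data is never destroyed.
- **Dublin Core technical metadata.**  Each version carries a typed
  15-element DCMES record (creator/contributor as structured persons,
  ISO dates, media-type format, free text elsewhere).
- **Fuzzy metadata retrieval.**  A rebuildable inverted index supports
  exact, partial-string, and phonetic (Metaphone) keyword search, over
  all elements or one element.
- **Default-deny permissions.**  Seven grantable actions (CREATE,
  MODIFY, READ, STORE, METADATA_CHANGE, PERMISSION_CHANGE, PUBLICATION),
  owner supremacy, creation-time ACL inheritance from the parent
  directory, pluggable login providers.
- **Reviewed publication with persistent identifiers.**  A publication
  request immediately gets a landing page (download locked), notifies a
  legal, a scientific, and a veto-holding master reviewer, and on
  acceptance mints an identifier — for DOIs
  `prefix/namespace/year/sequence`, e.g. `10.5072/IPK/Test/2013/0` —
  migrates the metadata to DataCite XML, and invokes the (pluggable)
  registrar transport exactly once.  Release dates in the future embargo
  the download while the landing page stays resolvable.
- **Chunked content storage.**  Payloads live as content-addressed plain
  files `objects/chunk-<k>/<sha256>`; a new chunk directory opens at a
  configurable entry threshold, so ordinary backup tools suffice and
  integrity is checksum-verified on every read.

## Worked example

```python
from datetime import datetime, timezone
from edarch import (mount, login, TestProvider, PublicationConfig,
                    IdentifierType, ReviewerRole, Verdict)
from edarch.publication import (Reviewer, RecordingRegistrar,
                                request_publication, record_decision)
from edarch.search import Query, MatchMode, search

alice = login(TestProvider(), username="alice")
cfg = PublicationConfig(
    reviewers=(Reviewer("legal@ipk", ReviewerRole.LEGAL),
               Reviewer("sci@ipk", ReviewerRole.SCIENTIFIC),
               Reviewer("master@ipk", ReviewerRole.MASTER)),
    doi_prefix="10.5072", namespace="IPK/Test",
    registrar=RecordingRegistrar())
repo = mount("/tmp/archive", alice, publication_config=cfg)

f = repo.create_file(repo.root, "F32CY7K01.sff", alice)
v = repo.store(f.id, b"...sequence reads...", metadata={
    "creator": "Schmutzer, Thomas, IPK Gatersleben",
    "title": "F32CY7K01.sff",
    "subject": "NGS, Rye",
    "publisher": "Leibniz Institute of Plant Genetics and Crop Plant Research Gatersleben",
}, session=alice)
print(v.revision)                       # 2  (revision 1 is the empty placeholder)

hits = search(repo, Query("rye", target="subject"), alice)
print(len(hits), hits[0].revision)      # 1 2   (the planted subject keyword, revision 2)

ref = request_publication(repo, alice, f.id, v.revision, IdentifierType.DOI,
                          now=datetime(2013, 5, 1, tzinfo=timezone.utc))
print(ref.status.value)                 # PENDING  (3 reviewer notifications in the outbox)
ref = record_decision(repo, ref, ReviewerRole.MASTER, Verdict.ACCEPT,
                      datetime(2013, 5, 2, tzinfo=timezone.utc))
print(ref.status.value, ref.identifier) # ACCEPTED 10.5072/IPK/Test/2013/0
repo.close()
```

The minted identifier is the archive's DOI pattern
`prefix/namespace/year/sequence`; sequence numbers per namespace and
year are gapless, starting at 0.  The same workflow is available from
the shell:

```sh
edarch --repo /tmp/archive store /exp1/reads.fa reads.fa
edarch --repo /tmp/archive meta set /exp1/reads.fa "subject=NGS, Rye"
edarch --repo /tmp/archive search rye
edarch --repo /tmp/archive publish request /exp1/reads.fa
edarch --repo /tmp/archive serve --port 8080     # landing pages + downloads
```

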