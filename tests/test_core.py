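"""Entity tree, append-only version chains, terminal deletion, persistence."""

import random

import pytest

from edarch import make_metadata, mount
from edarch.errors import (
    DuplicateNameError,
    EntityDeletedError,
    NotFoundError,
    RepositoryLockedError,
    StorageError,
    ValidationError,
)


class TestMount:
    def test_fresh_mount_creates_root_with_one_version(self, repo, alice):
        versions = repo.list_versions(repo.root, alice)
        assert [v.revision for v in versions] == [1]
        assert repo.get_entity(repo.root).is_directory

    def test_mounting_principal_holds_all_actions_on_root(self, repo, alice):
        from edarch.permissions import ALL_ACTIONS

        assert all(repo.check(alice, a, repo.root) for a in ALL_ACTIONS)

    def test_mount_on_regular_file_fails(self, tmp_path, alice):
        target = tmp_path / "a-file"
        target.write_text("not a directory")
        with pytest.raises(StorageError):
            mount(target, alice)

    def test_concurrent_mount_of_same_root_is_refused(self, repo, alice):
        with pytest.raises(RepositoryLockedError):
            mount(repo.storage_root, alice)

    def test_remount_recovers_identical_state(self, tmp_path, alice):
        r = mount(tmp_path / "r", alice)
        d = r.create_directory(r.root, "exp1", alice).id
        for i in range(3):
            f = r.create_file(d, f"f{i}.txt", alice).id
            r.store(f, f"payload {i}".encode(), session=alice)
        r.set_metadata(f, {"title": "f2.txt"}, alice)
        before = r.dump()
        r.close()
        r2 = mount(tmp_path / "r", alice)
        try:
            assert r2.dump() == before
            assert r2.read(f, 2, alice) == b"payload 2"
        finally:
            r2.close()


class TestTreeOperations:
    def test_create_directory(self, repo, alice):
        d = repo.create_directory(repo.root, "exp1", alice)
        assert d.is_directory
        assert [v.revision for v in repo.list_versions(d.id, alice)] == [1]

    def test_duplicate_sibling_name_rejected(self, repo, alice):
        repo.create_directory(repo.root, "exp1", alice)
        with pytest.raises(DuplicateNameError):
            repo.create_directory(repo.root, "exp1", alice)
        with pytest.raises(DuplicateNameError):
            repo.create_file(repo.root, "exp1", alice)

    def test_create_file_starts_empty(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice)
        v = repo.get_version(f.id)
        assert (v.revision, v.size_bytes) == (1, 0)
        assert repo.read(f.id, 1, alice) == b""

    def test_files_have_no_children(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice)
        with pytest.raises(ValidationError):
            repo.create_file(f.id, "b.txt", alice)
        with pytest.raises(ValidationError):
            repo.list_children(f.id, alice)

    def test_store_appends_and_preserves_history(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        repo.store(f, b"ACGT", session=alice)
        repo.store(f, b"ACGTT", session=alice)
        assert repo.read(f, 2, alice) == b"ACGT"
        assert repo.read(f, 3, alice) == b"ACGTT"
        assert repo.read(f, "latest", alice) == b"ACGTT"

    def test_read_revision_zero_rejected(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        with pytest.raises(NotFoundError):
            repo.read(f, 0, alice)
        with pytest.raises(NotFoundError):
            repo.read(f, 99, alice)

    def test_metadata_carried_over_when_not_given(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        repo.store(f, b"x", metadata={"title": "a.txt"}, session=alice)
        v = repo.store(f, b"y", session=alice)
        assert v.metadata.display("title") == "a.txt"

    def test_set_metadata_always_versions(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        meta = make_metadata({"title": "a.txt"})
        v1 = repo.set_metadata(f, meta, alice)
        v2 = repo.set_metadata(f, meta, alice)
        assert (v1.revision, v2.revision) == (2, 3)
        assert v1.content == v2.content  # shares the content locator

    def test_list_children_sorted_and_complete(self, repo, alice):
        assert repo.list_children(repo.root, alice) == []
        repo.create_file(repo.root, "b.txt", alice)
        repo.create_file(repo.root, "a.txt", alice)
        names = [c.name for c in repo.list_children(repo.root, alice)]
        assert names == ["a.txt", "b.txt"]

    def test_resolve_path(self, repo, alice):
        d = repo.create_directory(repo.root, "exp1", alice).id
        f = repo.create_file(d, "a.txt", alice).id
        assert repo.resolve_path("/", alice) == repo.root
        assert repo.resolve_path("/exp1/a.txt", alice) == f
        assert repo.path_of(f) == "/exp1/a.txt"
        with pytest.raises(NotFoundError):
            repo.resolve_path("/nope", alice)


class TestDeletion:
    def test_delete_appends_terminal_version(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        repo.store(f, b"1", session=alice)
        repo.store(f, b"2", session=alice)
        repo.delete(f, alice)
        versions = repo.list_versions(f, alice)
        assert [v.revision for v in versions] == [1, 2, 3, 4]
        assert [v.deleted for v in versions] == [False, False, False, True]

    def test_previous_versions_stay_readable(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        repo.store(f, b"keep me", session=alice)
        repo.delete(f, alice)
        assert repo.read(f, 2, alice) == b"keep me"

    def test_no_new_versions_after_delete(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        repo.delete(f, alice)
        with pytest.raises(EntityDeletedError):
            repo.store(f, b"undelete attempt", session=alice)
        with pytest.raises(EntityDeletedError):
            repo.set_metadata(f, {"title": "t"}, alice)
        with pytest.raises(EntityDeletedError):
            repo.delete(f, alice)

    def test_deleted_name_stays_reserved(self, repo, alice):
        f = repo.create_file(repo.root, "a.txt", alice).id
        repo.delete(f, alice)
        with pytest.raises(DuplicateNameError):
            repo.create_file(repo.root, "a.txt", alice)
        listed = repo.list_children(repo.root, alice)
        assert [(c.name, c.deleted) for c in listed] == [("a.txt", True)]

    def test_directory_delete_requires_deleted_children(self, repo, alice):
        d = repo.create_directory(repo.root, "exp1", alice).id
        f = repo.create_file(d, "a.txt", alice).id
        with pytest.raises(ValidationError):
            repo.delete(d, alice)
        repo.delete(f, alice)
        assert repo.delete(d, alice).deleted


class TestRandomOperationSequences:
    """Version chains stay append-only and contiguous under random use."""

    def _run_ops(self, repo, session, rng, n_ops):
        files, log = [], []
        for _ in range(n_ops):
            op = rng.choice(["create", "store", "meta", "delete"])
            if op == "create" or not files:
                name = f"f{len(log)}.dat"
                eid = repo.create_file(repo.root, name, session).id
                files.append(eid)
                log.append((eid, 1))
            else:
                eid = rng.choice(files)
                latest = repo.get_version(eid)
                if latest.deleted:
                    continue
                if op == "store":
                    v = repo.store(eid, rng.randbytes(rng.randrange(64)), session=session)
                elif op == "meta":
                    v = repo.set_metadata(eid, {"title": f"t{rng.random()}"}, session)
                else:
                    v = repo.delete(eid, session)
                log.append((eid, v.revision))
        return files, log

    def test_chains_contiguous_and_append_only(self, repo, alice):
        rng = random.Random(7)
        snapshots = {}
        files, _ = self._run_ops(repo, alice, rng, 120)
        for eid in files:
            versions = repo.list_versions(eid, alice)
            assert [v.revision for v in versions] == list(range(1, len(versions) + 1))
            deleted_flags = [v.deleted for v in versions]
            assert deleted_flags.count(True) <= 1
            if any(deleted_flags):
                assert deleted_flags[-1]  # only the last version may be deleted
        # append-only: re-reading never changes previously seen versions
        for eid in files:
            snapshots[eid] = repo.list_versions(eid, alice)
        repo.create_file(repo.root, "one-more.dat", alice)
        for eid, before in snapshots.items():
            assert repo.list_versions(eid, alice) == before

    def test_persistence_round_trip_after_random_ops(self, tmp_path, alice):
        r = mount(tmp_path / "rr", alice)
        rng = random.Random(11)
        self._run_ops(r, alice, rng, 80)
        before = r.dump()
        r.close()
        r2 = mount(tmp_path / "rr", alice)
        try:
            assert r2.dump() == before
        finally:
            r2.close()
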