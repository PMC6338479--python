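"""Derivation, versioning, status transitions and lineage reconstruction."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcokit import canonical, forge
from bcokit.errors import LifecycleError, LineageError
from bcokit.lifecycle import (
    TRANSITIONS, BcoRepository, ChangeClass, build_lineage, bump_version,
    derive_child, parse_semver, transition_status, update_domains,
)
from bcokit.model import (
    Parameter, ParametricDomain, Status, UsabilityDomain, validate_envelope,
)

NOW = "2024-06-01T00:00:00Z"


def _published_sealed():
    return canonical.seal_envelope(forge.forge_minimal_envelope())


def _param_edit(value: str) -> dict:
    return {"parametric": ParametricDomain(parameters=[
        Parameter(param="min_qual", value=value, step=2)])}


# ---------------------------------------------------------------- versions

@pytest.mark.parametrize("version,change,expected", [
    ("1.2.3", ChangeClass.EDITORIAL, "1.2.4"),
    ("1.2.3", ChangeClass.PARAMETRIC, "1.3.0"),
    ("1.2.3", ChangeClass.STRUCTURAL, "2.0.0"),
    ("0.0.0", ChangeClass.EDITORIAL, "0.0.1"),
])
def test_bump_version_policy(version, change, expected):
    assert bump_version(version, change) == expected


def test_malformed_semver_rejected():
    with pytest.raises(LifecycleError) as exc:
        bump_version("1.2", ChangeClass.EDITORIAL)
    assert exc.value.code == "VERSION_PARSE"


@settings(max_examples=100, derandomize=True)
@given(st.tuples(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)),
       st.sampled_from(list(ChangeClass)))
def test_bump_always_increases_semver_order(trio, change):
    v = "{}.{}.{}".format(*trio)
    assert parse_semver(bump_version(v, change)) > parse_semver(v)


# ---------------------------------------------------------------- derivation

def test_derive_child_links_bumps_and_resets(minimal_env):
    parent = _published_sealed()
    child = derive_child(parent, _param_edit("31"), now=NOW)
    assert child.provenance.inheritance == [parent.object_id]
    assert child.provenance.version == "1.1.0"   # parametric edit of 1.0.0
    assert child.provenance.status == Status.DRAFT
    assert child.provenance.created == child.provenance.modified == NOW
    assert child.object_id != parent.object_id
    assert child.digital_signature is None
    # parent untouched, still verifiable
    assert canonical.verify_seal(parent)
    assert validate_envelope(canonical.seal_envelope(child)).ok


def test_derive_requires_seal_and_published(minimal_env):
    with pytest.raises(LifecycleError) as exc:
        derive_child(minimal_env, _param_edit("31"))
    assert exc.value.code == "DERIVE_FROM_UNSEALED"

    draft = forge.forge_minimal_envelope()
    draft.provenance.status = Status.DRAFT
    with pytest.raises(LifecycleError) as exc:
        derive_child(canonical.seal_envelope(draft), _param_edit("31"))
    assert exc.value.code == "DERIVE_FROM_NONFINAL"


def test_change_class_from_domains():
    from bcokit.lifecycle import classify_edits
    assert classify_edits(["usability"]) is ChangeClass.EDITORIAL
    assert classify_edits(["parametric"]) is ChangeClass.PARAMETRIC
    assert classify_edits(["execution", "usability"]) is ChangeClass.STRUCTURAL
    assert classify_edits(["description"]) is ChangeClass.STRUCTURAL


# ---------------------------------------------------------------- status

def test_transition_matrix_exhaustive():
    """All 25 status pairs behave exactly per the transition table."""
    for src, dst in itertools.product(Status, Status):
        env = forge.forge_minimal_envelope()
        env.provenance.status = src
        if dst in TRANSITIONS[src]:
            out = transition_status(env, dst, now=NOW)
            assert out.provenance.status == dst
            assert out.provenance.modified == NOW
            assert env.provenance.status == src     # input untouched
        else:
            with pytest.raises(LifecycleError) as exc:
                transition_status(env, dst, now=NOW)
            assert exc.value.code == "ILLEGAL_TRANSITION"


def test_published_objects_are_immutable(minimal_env):
    with pytest.raises(LifecycleError) as exc:
        update_domains(minimal_env, usability=UsabilityDomain(
            statements=["edited"]))
    assert exc.value.code == "IMMUTABLE_PUBLISHED"


def test_draft_objects_are_editable(minimal_env):
    minimal_env.provenance.status = Status.DRAFT
    out = update_domains(minimal_env, now=NOW,
                         usability=UsabilityDomain(statements=["edited"]))
    assert out.usability.statements == ["edited"]
    assert out.provenance.modified == NOW


# ---------------------------------------------------------------- lineage

def _grow_chain(generations: int):
    repo = BcoRepository()
    root = _published_sealed()
    repo.add(root)
    cur = root
    for g in range(generations - 1):
        child = derive_child(cur, _param_edit(str(40 + g)), now=NOW)
        child = transition_status(child, Status.IN_REVIEW, now=NOW)
        child = transition_status(child, Status.PUBLISHED, now=NOW)
        child = canonical.seal_envelope(child)
        repo.add(child)
        cur = child
    return repo, root, cur


def _naive_pointer_walk(env, repo):
    # independent oracle: follow last-inheritance pointers, root first
    chain = []
    cur = env
    while True:
        chain.append(cur.object_id)
        if not cur.provenance.inheritance:
            break
        cur = repo.get(cur.provenance.inheritance[-1])
    return list(reversed(chain))


def test_root_lineage_is_singleton():
    repo = BcoRepository()
    root = _published_sealed()
    repo.add(root)
    assert build_lineage(root, repo).chain == [root.object_id]


def test_four_generation_lineage_matches_pointer_walk():
    repo, root, tip = _grow_chain(4)
    lineage = build_lineage(tip, repo)
    assert lineage.chain == _naive_pointer_walk(tip, repo)
    assert len(lineage) == 4
    assert lineage.chain[0] == root.object_id


def test_versions_strictly_increase_along_lineage():
    repo, _, tip = _grow_chain(5)
    versions = [parse_semver(repo.get(i).provenance.version)
                for i in build_lineage(tip, repo).chain]
    assert all(a < b for a, b in zip(versions, versions[1:]))


def test_dangling_ancestor_and_cycle_detected():
    env = forge.forge_minimal_envelope()
    env.provenance.inheritance = ["https://example.org/bco/ghost"]
    with pytest.raises(LineageError) as exc:
        build_lineage(env, BcoRepository())
    assert exc.value.code == "DANGLING_ANCESTOR"

    a = forge.forge_minimal_envelope()
    b = forge.forge_minimal_envelope()
    b.object_id = "https://example.org/bco/minimal-0002"
    a.provenance.inheritance = [b.object_id]
    b.provenance.inheritance = [a.object_id]
    repo = BcoRepository()
    repo.store[a.object_id] = a
    repo.store[b.object_id] = b
    with pytest.raises(LineageError) as exc:
        build_lineage(a, repo)
    assert exc.value.code == "CYCLE"


def test_repository_roundtrips_through_directory(tmp_path):
    repo, _, tip = _grow_chain(3)
    repo.save_dir(tmp_path / "store")
    loaded = BcoRepository.load_dir(tmp_path / "store")
    assert len(loaded) == 3
    assert build_lineage(loaded.get(tip.object_id), loaded).chain == \
        build_lineage(tip, repo).chain
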