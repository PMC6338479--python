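"""Versioning, derivation, status transitions and lineage over a BCO store.

A published BCO is immutable: refining an analysis (new parameters, a swapped
tool, a reworded scope statement) produces a *derived child* whose
provenance records the parent in its inheritance chain and whose version is
bumped according to how substantive the edit was.  A typical analysis goes
through many such iterations before one snapshot is published.
"""

from __future__ import annotations

import copy
import re
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional

from . import canonical
from .errors import LifecycleError, LineageError, UnsignedError
from .model import BcoEnvelope, Status, format_timestamp

__all__ = [
    "ChangeClass", "classify_edits", "bump_version", "derive_child",
    "transition_status", "update_domains", "BcoRepository", "Lineage",
    "build_lineage", "parse_semver",
]

_SEMVER_RE = re.compile(
    r"^(?P<major>0|[1-9]\d*)\.(?P<minor>0|[1-9]\d*)\.(?P<patch>0|[1-9]\d*)"
    r"(?:-(?P<pre>[0-9A-Za-z.-]+))?(?:\+(?P<build>[0-9A-Za-z.-]+))?$")


def parse_semver(v: str) -> tuple[int, int, int]:
    """(major, minor, patch) of a semantic version string.

    Raises :class:`LifecycleError` (``VERSION_PARSE``) on malformed input.
    Pre-release/build suffixes are accepted and ignored for ordering, which
    is all the lifecycle policy needs.
    """
    m = _SEMVER_RE.match(v) if isinstance(v, str) else None
    if not m:
        raise LifecycleError(f"{v!r} is not a semantic version",
                             code="VERSION_PARSE")
    return int(m["major"]), int(m["minor"]), int(m["patch"])


class ChangeClass(str, Enum):
    """How substantive an edit is, as a pure function of the domains touched."""

    EDITORIAL = "EDITORIAL"      # wording, provenance metadata, extensions
    PARAMETRIC = "PARAMETRIC"    # parameters, io files, error tolerances
    STRUCTURAL = "STRUCTURAL"    # pipeline steps or execution domain


_STRUCTURAL_DOMAINS = {"description", "execution"}
_PARAMETRIC_DOMAINS = {"parametric", "io", "error"}


def classify_edits(domains_changed: Iterable[str]) -> ChangeClass:
    changed = set(domains_changed)
    if changed & _STRUCTURAL_DOMAINS:
        return ChangeClass.STRUCTURAL
    if changed & _PARAMETRIC_DOMAINS:
        return ChangeClass.PARAMETRIC
    return ChangeClass.EDITORIAL


def bump_version(v: str, c: ChangeClass) -> str:
    """EDITORIAL bumps patch, PARAMETRIC bumps minor, STRUCTURAL bumps major."""
    major, minor, patch = parse_semver(v)
    if c is ChangeClass.STRUCTURAL:
        return f"{major + 1}.0.0"
    if c is ChangeClass.PARAMETRIC:
        return f"{major}.{minor + 1}.0"
    return f"{major}.{minor}.{patch + 1}"


#: Legal status transitions.  Published objects can only be withdrawn
#: (suspended/obsoleted); any content change requires derivation.
TRANSITIONS: dict[Status, frozenset[Status]] = {
    Status.DRAFT: frozenset({Status.IN_REVIEW}),
    Status.IN_REVIEW: frozenset({Status.DRAFT, Status.PUBLISHED}),
    Status.PUBLISHED: frozenset({Status.SUSPENDED, Status.OBSOLETE}),
    Status.SUSPENDED: frozenset({Status.PUBLISHED, Status.OBSOLETE}),
    Status.OBSOLETE: frozenset(),
}


def _now_or(now: Optional[str]) -> str:
    return now if now is not None else format_timestamp(
        datetime.now(timezone.utc))


def transition_status(env: BcoEnvelope, new: Status, *,
                      now: Optional[str] = None) -> BcoEnvelope:
    """Move an envelope to a new status along the allowed table.

    Returns an updated copy (modified timestamp refreshed; signature cleared
    since content changed).  Illegal moves raise ``ILLEGAL_TRANSITION``.
    ``now`` may inject a deterministic timestamp.
    """
    if env.provenance is None:
        raise LifecycleError("envelope has no provenance domain",
                             code="ILLEGAL_TRANSITION")
    current = env.provenance.status
    if not isinstance(current, Status):
        raise LifecycleError(f"current status {current!r} is not a known token",
                             code="ILLEGAL_TRANSITION")
    new = Status(new)
    if new not in TRANSITIONS[current]:
        raise LifecycleError(
            f"transition {current.value} -> {new.value} is not allowed",
            code="ILLEGAL_TRANSITION")
    out = copy.deepcopy(env)
    out.provenance.status = new
    out.provenance.modified = _now_or(now)
    out.digital_signature = None
    return out


def update_domains(env: BcoEnvelope, *, now: Optional[str] = None,
                   **edits: Any) -> BcoEnvelope:
    """Apply in-place domain replacements to a non-published envelope.

    Published objects are immutable (``IMMUTABLE_PUBLISHED``): use
    :func:`derive_child` instead.  The signature is cleared because the
    content changed; re-seal when done editing.
    """
    if env.provenance is not None and env.provenance.status == Status.PUBLISHED:
        raise LifecycleError(
            "published BCOs are immutable; derive a child instead",
            code="IMMUTABLE_PUBLISHED")
    unknown = set(edits) - set(vars(BcoEnvelope()))
    if unknown:
        raise LifecycleError(f"unknown domains {sorted(unknown)}",
                             code="UNKNOWN_DOMAIN")
    out = copy.deepcopy(env)
    for name, value in edits.items():
        setattr(out, name, copy.deepcopy(value))
    if out.provenance is not None:
        out.provenance.modified = _now_or(now)
    out.digital_signature = None
    return out


def derive_child(parent: BcoEnvelope, edits: dict[str, Any], *,
                 id_namespace: str = "https://example.org/bco",
                 object_id: Optional[str] = None,
                 now: Optional[str] = None) -> BcoEnvelope:
    """Derive a new DRAFT BCO from a sealed, PUBLISHED parent.

    ``edits`` maps envelope attribute names (``parametric``, ``usability``,
    ...) to replacement domain values.  The child appends the parent's
    object_id to its inheritance chain, bumps the version according to the
    change class of the edited domains, gets a fresh object_id (UUIDv4 under
    ``id_namespace`` unless given explicitly) and fresh timestamps.  The
    parent is never mutated; the child is returned unsealed.
    """
    try:
        sealed = canonical.verify_seal(parent)
    except UnsignedError:
        sealed = False
    if not sealed:
        raise LifecycleError("parent must be sealed before derivation",
                             code="DERIVE_FROM_UNSEALED")
    if parent.provenance is None or parent.provenance.status != Status.PUBLISHED:
        raise LifecycleError(
            "only PUBLISHED objects can be derived from",
            code="DERIVE_FROM_NONFINAL")
    change = classify_edits(edits.keys())
    child = copy.deepcopy(parent)
    child.digital_signature = None
    for name, value in edits.items():
        if name not in vars(BcoEnvelope()):
            raise LifecycleError(f"unknown domain {name!r}",
                                 code="UNKNOWN_DOMAIN")
        setattr(child, name, copy.deepcopy(value))
    ts = _now_or(now)
    child.object_id = object_id or f"{id_namespace.rstrip('/')}/{uuid.uuid4()}"
    child.provenance.inheritance = list(parent.provenance.inheritance) + [
        parent.object_id]
    child.provenance.version = bump_version(parent.provenance.version, change)
    child.provenance.status = Status.DRAFT
    child.provenance.created = ts
    child.provenance.modified = ts
    return child


# --------------------------------------------------------------------------
# repository + lineage
# --------------------------------------------------------------------------

@dataclass
class Lineage:
    """Root-first chain of object_ids linked by inheritance."""

    chain: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.chain)


class BcoRepository:
    """A local store of sealed BCOs keyed by object_id.

    On disk this is simply a directory of ``.json`` files; any index is
    derivable from the files and never authoritative.
    """

    def __init__(self) -> None:
        self.store: dict[str, BcoEnvelope] = {}

    def add(self, env: BcoEnvelope) -> None:
        if not canonical.verify_seal(env):   # raises UNSIGNED when absent
            raise LifecycleError(
                f"{env.object_id!r} fails seal verification",
                code="STORE_UNVERIFIED")
        if env.object_id in self.store:
            raise LifecycleError(f"duplicate object_id {env.object_id!r}",
                                 code="STORE_DUPLICATE_ID")
        self.store[env.object_id] = env

    def get(self, object_id: str) -> Optional[BcoEnvelope]:
        return self.store.get(object_id)

    def __len__(self) -> int:
        return len(self.store)

    def __contains__(self, object_id: str) -> bool:
        return object_id in self.store

    @classmethod
    def load_dir(cls, path: str | Path) -> "BcoRepository":
        repo = cls()
        for f in sorted(Path(path).glob("*.json")):
            env, _ = canonical.parse_bco(f.read_text(encoding="utf-8"))
            repo.add(env)
        return repo

    def save_dir(self, path: str | Path) -> None:
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        for i, object_id in enumerate(sorted(self.store)):
            target = out / f"bco_{i:04d}.json"
            target.write_text(canonical.emit_json(self.store[object_id]),
                              encoding="utf-8")


def build_lineage(env: BcoEnvelope, repo: BcoRepository) -> Lineage:
    """Walk the inheritance chain of ``env`` back to its root through ``repo``.

    The immediate parent is the *last* entry of the inheritance list.  A
    missing ancestor raises ``DANGLING_ANCESTOR``; a repeated id raises
    ``CYCLE``.
    """
    chain = [env.object_id]
    seen = {env.object_id}
    current = env
    while current.provenance is not None and current.provenance.inheritance:
        parent_id = current.provenance.inheritance[-1]
        if parent_id in seen:
            raise LineageError(
                f"inheritance cycle at {parent_id!r}", code="CYCLE")
        parent = repo.get(parent_id)
        if parent is None:
            raise LineageError(
                f"ancestor {parent_id!r} not present in repository",
                code="DANGLING_ANCESTOR")
        chain.append(parent_id)
        seen.add(parent_id)
        current = parent
    chain.reverse()
    return Lineage(chain=chain)
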