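"""Typed in-memory model of a BioCompute Object (BCO) and its validation rules.

A BCO is a JSON document that snapshots a complete high-throughput sequencing
analysis: who performed it (provenance domain), what it is for (usability
domain), the pipeline itself (description domain), how to execute it
(execution domain), non-default parameters (parametric domain), the files it
consumed and produced (input/output domain) and the error tolerances within
which a repeat run still counts as the same result (error domain).

The model is deliberately permissive: any parseable document can be held in
memory, including invalid ones.  ``validate_envelope`` reports every violated
invariant as a :class:`Finding` with a stable code and never raises — parsing
problems are the serializer's concern (:mod:`bcokit.canonical`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from enum import Enum
from typing import Any, Optional
from urllib.parse import urlparse

__all__ = [
    "Status", "PAV_ROLES", "Finding", "ValidationReport",
    "Contributor", "ProvenanceDomain", "UsabilityDomain", "ExtensionEntry",
    "ExtensionDomain", "Xref", "PipelineStep", "DescriptionDomain",
    "Prerequisite", "Endpoint", "EnvVar", "ExecutionDomain", "Parameter",
    "ParametricDomain", "FileRef", "IoDomain", "ToleranceRange", "ErrorDomain",
    "BcoEnvelope", "validate_envelope", "check_dataflow", "resolve_param_refs",
    "validate_orcid", "normalize_orcid", "parse_timestamp", "format_timestamp",
]


class Status(str, Enum):
    """Review status of a BCO; transitions are policed by the lifecycle module."""

    DRAFT = "DRAFT"
    IN_REVIEW = "IN_REVIEW"
    PUBLISHED = "PUBLISHED"
    SUSPENDED = "SUSPENDED"
    OBSOLETE = "OBSOLETE"


#: Contribution roles, after the Provenance/Authoring/Versioning (PAV) vocabulary.
PAV_ROLES = frozenset({
    "authoredBy", "contributedBy", "createdBy", "createdWith", "curatedBy",
    "derivedFrom", "importedBy", "providedBy", "retrievedBy",
    "sourceAccessedBy", "reviewedBy",
})


@dataclass
class Finding:
    code: str
    severity: str          # "ERROR" or "WARNING"
    path: str              # dotted location within the document
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.code} at {self.path}: {self.message}"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        """True iff the report carries no ERROR-severity finding."""
        return not any(f.severity == "ERROR" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "ERROR"]

    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "WARNING"]

    def codes(self) -> list[str]:
        return [f.code for f in self.findings]


# --------------------------------------------------------------------------
# domain dataclasses
# --------------------------------------------------------------------------

@dataclass
class Contributor:
    name: str
    contribution: list[str] = field(default_factory=list)
    affiliation: Optional[str] = None
    email: Optional[str] = None
    orcid: Optional[str] = None
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class ProvenanceDomain:
    """Who made this object, its version, ancestry and review status."""

    name: str = ""
    version: str = "0.0.0"
    inheritance: list[str] = field(default_factory=list)
    status: Any = Status.DRAFT          # Status, or raw token if unrecognized
    contributors: list[Contributor] = field(default_factory=list)
    license: str = ""
    created: str = ""                   # ISO 8601 UTC, seconds precision
    modified: str = ""
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class UsabilityDomain:
    statements: list[str] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class ExtensionEntry:
    schema_ref: str
    payload: Any = None


@dataclass
class ExtensionDomain:
    entries: list[ExtensionEntry] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class Xref:
    namespace: str
    ids: list[str] = field(default_factory=list)


@dataclass
class FileRef:
    uri: str
    filename: Optional[str] = None
    access_time: Optional[str] = None
    sha256: Optional[str] = None
    size_bytes: Optional[int] = None
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class PipelineStep:
    number: int
    name: str = ""
    description: str = ""
    version: str = ""
    inputs: list[FileRef] = field(default_factory=list)
    outputs: list[FileRef] = field(default_factory=list)
    prerequisites: Optional[list[str]] = None
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class DescriptionDomain:
    keywords: list[str] = field(default_factory=list)
    xrefs: list[Xref] = field(default_factory=list)
    platform: Optional[str] = None
    steps: list[PipelineStep] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class Prerequisite:
    name: str
    version: str = ""
    uri: Optional[str] = None
    digest: Optional[str] = None


@dataclass
class Endpoint:
    name: str
    uri: str


@dataclass
class EnvVar:
    key: str
    value: str


@dataclass
class ExecutionDomain:
    scripts: list[str] = field(default_factory=list)
    script_driver: str = "shell"
    software_prerequisites: list[Prerequisite] = field(default_factory=list)
    external_data_endpoints: list[Endpoint] = field(default_factory=list)
    environment_variables: list[EnvVar] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class Parameter:
    param: str
    value: str
    step: int


@dataclass
class ParametricDomain:
    parameters: list[Parameter] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class IoDomain:
    inputs: list[FileRef] = field(default_factory=list)
    outputs: list[FileRef] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)


@dataclass
class ToleranceRange:
    """Inclusive acceptance interval for one named metric."""

    metric: str
    min: float
    max: float
    inclusive: bool = True


@dataclass
class ErrorDomain:
    """Acceptable deviation from expected results.

    ``empirical`` ranges bound observed performance metrics (recall,
    precision); ``algorithmic`` ranges bound method-intrinsic quantities.
    The split is descriptive — both are evaluated identically.
    """

    empirical: list[ToleranceRange] = field(default_factory=list)
    algorithmic: list[ToleranceRange] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def all_ranges(self) -> list[ToleranceRange]:
        return list(self.empirical) + list(self.algorithmic)


@dataclass
class BcoEnvelope:
    """Top-level BCO: identifier, type, spec version, signature, domains."""

    object_id: str = ""
    bco_type: str = "general"
    spec_version: str = ""
    digital_signature: Optional[str] = None
    provenance: Optional[ProvenanceDomain] = None
    usability: Optional[UsabilityDomain] = None
    extension: Optional[ExtensionDomain] = None
    description: Optional[DescriptionDomain] = None
    execution: Optional[ExecutionDomain] = None
    parametric: Optional[ParametricDomain] = None
    io: Optional[IoDomain] = None
    error: Optional[ErrorDomain] = None
    extra: dict[str, Any] = field(default_factory=dict)


# --------------------------------------------------------------------------
# small validators
# --------------------------------------------------------------------------

_SEMVER_RE = re.compile(
    r"^(0|[1-9]\d*)\.(0|[1-9]\d*)\.(0|[1-9]\d*)"
    r"(?:-[0-9A-Za-z.-]+)?(?:\+[0-9A-Za-z.-]+)?$")

_ORCID_BARE_RE = re.compile(r"^\d{4}-\d{4}-\d{4}-\d{3}[\dX]$")

_SHA256_RE = re.compile(r"^[0-9a-f]{64}$")


def is_absolute_uri(s: Any) -> bool:
    if not isinstance(s, str) or not s:
        return False
    parsed = urlparse(s)
    return bool(parsed.scheme) and bool(parsed.netloc or parsed.path)


def is_semver(s: Any) -> bool:
    return isinstance(s, str) and bool(_SEMVER_RE.match(s))


def parse_timestamp(s: str) -> Optional[datetime]:
    """ISO 8601 → aware UTC datetime; None if unparseable."""
    if not isinstance(s, str):
        return None
    try:
        dt = datetime.fromisoformat(s.replace("Z", "+00:00"))
    except ValueError:
        return None
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def format_timestamp(dt: datetime) -> str:
    return dt.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _orcid_check_char(base15: str) -> str:
    # ISO 7064 mod 11-2 over the 15 leading digits
    total = 0
    for ch in base15:
        total = (total + int(ch)) * 2
    check = (12 - total % 11) % 11
    return "X" if check == 10 else str(check)


def validate_orcid(id_string: Any) -> bool:
    """True iff ``id_string`` is a well-formed ORCID with a valid ISO 7064
    mod 11-2 check character.  Bare ``XXXX-XXXX-XXXX-XXXX`` and
    ``https://orcid.org/...`` URI forms are both accepted."""
    if not isinstance(id_string, str):
        return False
    s = id_string.strip()
    for prefix in ("https://orcid.org/", "http://orcid.org/"):
        if s.startswith(prefix):
            s = s[len(prefix):]
            break
    if not _ORCID_BARE_RE.match(s):
        return False
    digits = s.replace("-", "")
    return digits[15] == _orcid_check_char(digits[:15])


def normalize_orcid(id_string: str) -> str:
    """Canonical https URI form of an ORCID (input may be bare or URI)."""
    s = id_string.strip()
    for prefix in ("https://orcid.org/", "http://orcid.org/"):
        if s.startswith(prefix):
            s = s[len(prefix):]
            break
    return f"https://orcid.org/{s}"


# --------------------------------------------------------------------------
# structural/semantic validation
# --------------------------------------------------------------------------

def _err(code: str, path: str, message: str) -> Finding:
    return Finding(code=code, severity="ERROR", path=path, message=message)


def check_dataflow(desc: DescriptionDomain, io: Optional[IoDomain]) -> list[Finding]:
    """Dataflow closure: every step input must be a declared external input
    or the output of a strictly earlier step.

    Findings are ordered by step.  Inputs produced only by a *later* step get
    ``DATAFLOW_FORWARD_REF``; inputs produced nowhere get
    ``DATAFLOW_UNDECLARED_INPUT``.  File identity is exact URI string match.
    """
    findings: list[Finding] = []
    external = {f.uri for f in (io.inputs if io else [])}
    steps = sorted(desc.steps, key=lambda s: s.number)
    produced_by: dict[str, int] = {}
    for step in steps:
        for out in step.outputs:
            produced_by.setdefault(out.uri, step.number)
    seen: set[str] = set(external)
    for step in steps:
        for inp in step.inputs:
            if inp.uri in seen:
                continue
            path = f"description.steps[{step.number}].inputs"
            if inp.uri in produced_by and produced_by[inp.uri] >= step.number:
                findings.append(_err(
                    "DATAFLOW_FORWARD_REF", path,
                    f"step {step.number} consumes {inp.uri!r}, first produced "
                    f"by step {produced_by[inp.uri]}"))
            else:
                findings.append(_err(
                    "DATAFLOW_UNDECLARED_INPUT", path,
                    f"step {step.number} consumes {inp.uri!r}, which is neither "
                    f"a declared external input nor an earlier step's output"))
        for out in step.outputs:
            seen.add(out.uri)
    return findings


def resolve_param_refs(
    par: ParametricDomain, desc: DescriptionDomain,
) -> tuple[dict[int, list[Parameter]], list[Finding]]:
    """Map each pipeline step number to its non-default parameters.

    Unresolvable step references yield ``PARAM_DANGLING_STEP``; repeated
    (param, step) pairs yield ``PARAM_DUPLICATE``.
    """
    findings: list[Finding] = []
    valid_steps = {s.number for s in desc.steps}
    mapping: dict[int, list[Parameter]] = {}
    seen_pairs: set[tuple[str, int]] = set()
    for i, p in enumerate(par.parameters):
        path = f"parametric.parameters[{i}]"
        key = (p.param, p.step)
        if key in seen_pairs:
            findings.append(_err(
                "PARAM_DUPLICATE", path,
                f"parameter {p.param!r} listed more than once for step {p.step}"))
            continue
        seen_pairs.add(key)
        if p.step not in valid_steps:
            findings.append(_err(
                "PARAM_DANGLING_STEP", path,
                f"parameter {p.param!r} references step {p.step}, which does "
                f"not exist"))
            continue
        mapping.setdefault(p.step, []).append(p)
    return mapping, findings


def _validate_fileref(ref: FileRef, path: str, out: list[Finding]) -> None:
    if ref.sha256 is not None and not _SHA256_RE.match(str(ref.sha256)):
        out.append(_err("FILEREF_SHA256_MALFORMED", path,
                        f"sha256 of {ref.uri!r} is not 64 lowercase hex chars"))
    if ref.size_bytes is not None and (
            not isinstance(ref.size_bytes, int) or ref.size_bytes < 0):
        out.append(_err("FILEREF_SIZE_NEGATIVE", path,
                        f"size_bytes of {ref.uri!r} must be a non-negative int"))


def _validate_provenance(prov: ProvenanceDomain, out: list[Finding]) -> None:
    if not is_semver(prov.version):
        out.append(_err("VERSION_PARSE", "provenance.version",
                        f"{prov.version!r} is not a semantic version"))
    created = parse_timestamp(prov.created)
    modified = parse_timestamp(prov.modified)
    if created is None:
        out.append(_err("TIME_PARSE", "provenance.created",
                        f"unparseable timestamp {prov.created!r}"))
    if modified is None:
        out.append(_err("TIME_PARSE", "provenance.modified",
                        f"unparseable timestamp {prov.modified!r}"))
    if created and modified and modified < created:
        out.append(_err("PROV_TIME_ORDER", "provenance.modified",
                        "modification date precedes creation date"))
    if not isinstance(prov.status, Status):
        try:
            Status(prov.status)
        except ValueError:
            out.append(_err("STATUS_INVALID", "provenance.status",
                            f"unknown status token {prov.status!r}"))
    if not prov.contributors:
        out.append(_err("CONTRIB_EMPTY", "provenance.contributors",
                        "at least one contributor is required"))
    else:
        has_author = False
        for i, c in enumerate(prov.contributors):
            cpath = f"provenance.contributors[{i}]"
            for role in c.contribution:
                if role not in PAV_ROLES:
                    out.append(_err("CONTRIB_ROLE_UNKNOWN", cpath,
                                    f"{role!r} is not a PAV contribution role"))
            if "authoredBy" in c.contribution:
                has_author = True
            if c.orcid is not None and not validate_orcid(c.orcid):
                out.append(_err("ORCID_INVALID", cpath,
                                f"{c.orcid!r} fails the ISO 7064 mod 11-2 "
                                f"check or is malformed"))
        if not has_author:
            out.append(_err("CONTRIB_NO_AUTHOR", "provenance.contributors",
                            "no contributor carries the authoredBy role"))
    if not prov.license:
        out.append(_err("LICENSE_EMPTY", "provenance.license",
                        "license identifier or URL required"))


def _validate_description(desc: DescriptionDomain, io: Optional[IoDomain],
                          out: list[Finding]) -> None:
    if not desc.steps:
        out.append(_err("STEPS_EMPTY", "description.steps",
                        "pipeline must declare at least one step"))
        return
    numbers = [s.number for s in desc.steps]
    contiguous = sorted(numbers) == list(range(1, len(numbers) + 1))
    if not contiguous:
        out.append(_err("STEPS_NONCONTIGUOUS", "description.steps",
                        f"step numbers {numbers} are not 1..{len(numbers)}"))
    for s in desc.steps:
        spath = f"description.steps[{s.number}]"
        for r in list(s.inputs) + list(s.outputs):
            _validate_fileref(r, spath, out)
    if contiguous:
        # dataflow precondition: numbering already valid
        out.extend(check_dataflow(desc, io))


def _validate_execution(ex: ExecutionDomain, out: list[Finding]) -> None:
    if not ex.scripts:
        out.append(_err("SCRIPTS_EMPTY", "execution.scripts",
                        "at least one script or command is required"))
    keys = [v.key for v in ex.environment_variables]
    for k in sorted({k for k in keys if keys.count(k) > 1}):
        out.append(_err("ENV_DUP_KEY", "execution.environment_variables",
                        f"environment variable {k!r} declared more than once"))
    for i, pre in enumerate(ex.software_prerequisites):
        if not pre.version:
            out.append(_err(
                "PREREQ_NO_VERSION", f"execution.software_prerequisites[{i}]",
                f"prerequisite {pre.name!r} lacks a version"))


def _validate_io(io: IoDomain, out: list[Finding]) -> None:
    for side in ("inputs", "outputs"):
        refs: list[FileRef] = getattr(io, side)
        uris = [r.uri for r in refs]
        for u in sorted({u for u in uris if uris.count(u) > 1}):
            out.append(_err("IO_DUP_URI", f"io.{side}",
                            f"file URI {u!r} listed more than once"))
        for i, r in enumerate(refs):
            _validate_fileref(r, f"io.{side}[{i}]", out)


def _validate_error_domain(ed: ErrorDomain, out: list[Finding]) -> None:
    names = [t.metric for t in ed.all_ranges()]
    for n in sorted({n for n in names if names.count(n) > 1}):
        out.append(_err("ERROR_METRIC_DUP", "error",
                        f"metric {n!r} appears in more than one tolerance"))
    for t in ed.all_ranges():
        if t.min > t.max:
            out.append(_err("TOLERANCE_INVERTED", f"error[{t.metric}]",
                            f"min {t.min} exceeds max {t.max}"))


_REQUIRED_DOMAINS = ("provenance", "usability", "description", "execution", "io")


def validate_envelope(env: BcoEnvelope, *, check_signature: bool = True) -> ValidationReport:
    """Check every structural and semantic invariant of a BCO.

    Pure and idempotent: the envelope is never mutated and repeated calls
    return identical reports.  Zero ERROR findings means the document is
    valid.  When a digital signature is present (and ``check_signature``),
    it is recomputed over the canonical bytes and compared.
    """
    out: list[Finding] = []
    if not is_absolute_uri(env.object_id):
        out.append(_err("OBJECT_ID_NOT_URI", "object_id",
                        f"{env.object_id!r} is not an absolute URI"))
    if not env.bco_type or not str(env.bco_type).strip():
        out.append(_err("TYPE_EMPTY", "bco_type", "type token is empty"))
    if not env.spec_version or not str(env.spec_version).strip():
        out.append(_err("SPEC_VERSION_EMPTY", "spec_version",
                        "specification version is empty"))
    for name in _REQUIRED_DOMAINS:
        if getattr(env, name) is None:
            out.append(_err("DOMAIN_MISSING", name,
                            f"required domain {name!r} is absent"))

    if env.provenance is not None:
        _validate_provenance(env.provenance, out)
    if env.usability is not None:
        if not env.usability.statements:
            out.append(_err("USABILITY_EMPTY", "usability",
                            "usability domain must state the intended use"))
        else:
            for i, s in enumerate(env.usability.statements):
                if not str(s).strip():
                    out.append(_err("USABILITY_BLANK_STATEMENT",
                                    f"usability.statements[{i}]",
                                    "statement is empty or whitespace-only"))
    if env.extension is not None:
        for i, e in enumerate(env.extension.entries):
            if not is_absolute_uri(e.schema_ref):
                out.append(_err("EXT_SCHEMA_NOT_URI",
                                f"extension.entries[{i}].schema_ref",
                                f"{e.schema_ref!r} is not a URI"))
    if env.description is not None:
        _validate_description(env.description, env.io, out)
    if env.execution is not None:
        _validate_execution(env.execution, out)
    if env.parametric is not None and env.description is not None:
        _, findings = resolve_param_refs(env.parametric, env.description)
        out.extend(findings)
    if env.io is not None:
        _validate_io(env.io, out)
    if env.error is not None:
        _validate_error_domain(env.error, out)

    if env.digital_signature is not None and check_signature:
        if not _SHA256_RE.match(str(env.digital_signature)):
            out.append(_err("SIGNATURE_MALFORMED", "digital_signature",
                            "signature is not a 64-char lowercase hex digest"))
        else:
            from . import canonical  # deferred: canonical imports this module
            try:
                digest = canonical.compute_digest(canonical.emit_canonical(env))
            except Exception as exc:  # unserializable content
                out.append(_err("SIGNATURE_UNVERIFIABLE", "digital_signature",
                                f"cannot canonicalize envelope: {exc}"))
            else:
                if digest.hex != env.digital_signature:
                    out.append(_err("SIGNATURE_MISMATCH", "digital_signature",
                                    "signature does not match canonical digest"))
    return ValidationReport(findings=out)
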