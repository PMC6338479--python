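"""Parse/emit BCO JSON, canonical bytes, and the content-digest seal.

The "digital signature" here is a self-signature: a SHA-256 digest over a
canonical byte serialization of the document with the signature member itself
excluded.  Canonical form is UTF-8, object members in lexicographic
(code-point) key order, no insignificant whitespace, numbers in their
shortest round-trip decimal form.  Any two semantically equal envelopes —
regardless of member order or whitespace in their source text — therefore
digest to the same value, and any other single-field change alters it.

A detached public-key signature could be layered on top of the canonical
bytes; only the digest seal is implemented.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from typing import Any, Optional

from .errors import BcoParseError, EmitError, UnsignedError
from .model import (
    BcoEnvelope, Contributor, DescriptionDomain, Endpoint, EnvVar,
    ErrorDomain, ExecutionDomain, ExtensionDomain, ExtensionEntry, FileRef,
    Finding, IoDomain, Parameter, ParametricDomain, PipelineStep,
    Prerequisite, ProvenanceDomain, Status, ToleranceRange, UsabilityDomain,
    ValidationReport, Xref, normalize_orcid, validate_orcid,
)

__all__ = [
    "CanonicalBytes", "Digest", "parse_bco", "emit_json", "emit_canonical",
    "compute_digest", "seal_envelope", "verify_seal", "to_tree", "from_tree",
]


@dataclass(frozen=True)
class CanonicalBytes:
    payload: bytes


@dataclass(frozen=True)
class Digest:
    hex: str
    algorithm: str = "sha256"


# Single mapping table between model attribute names and JSON member names.
# Kept explicit (even where identical) so a rename against an external schema
# touches exactly one place.
_TOP_KEYS: dict[str, str] = {
    "object_id": "object_id",
    "bco_type": "bco_type",
    "spec_version": "spec_version",
    "digital_signature": "digital_signature",
    "provenance": "provenance",
    "usability": "usability",
    "extension": "extension",
    "description": "description",
    "execution": "execution",
    "parametric": "parametric",
    "io": "io",
    "error": "error",
}
_TOP_ATTRS = {v: k for k, v in _TOP_KEYS.items()}


# --------------------------------------------------------------------------
# model -> plain JSON tree
# --------------------------------------------------------------------------

def _fileref_tree(r: FileRef) -> dict:
    d: dict[str, Any] = {"uri": r.uri}
    if r.filename is not None:
        d["filename"] = r.filename
    if r.access_time is not None:
        d["access_time"] = r.access_time
    if r.sha256 is not None:
        d["sha256"] = r.sha256
    if r.size_bytes is not None:
        d["size_bytes"] = r.size_bytes
    d.update(r.extra)
    return d


def _status_token(s: Any) -> str:
    return s.value if isinstance(s, Status) else str(s)


def to_tree(env: BcoEnvelope, *, include_signature: bool = True) -> dict:
    """Plain-dict JSON tree of an envelope; optional members are omitted
    when absent, unknown (preserved) members are merged back in place."""
    t: dict[str, Any] = {
        _TOP_KEYS["object_id"]: env.object_id,
        _TOP_KEYS["bco_type"]: env.bco_type,
        _TOP_KEYS["spec_version"]: env.spec_version,
    }
    if include_signature and env.digital_signature is not None:
        t[_TOP_KEYS["digital_signature"]] = env.digital_signature

    if env.provenance is not None:
        p = env.provenance
        contribs = []
        for c in p.contributors:
            cd: dict[str, Any] = {"name": c.name, "contribution": list(c.contribution)}
            if c.affiliation is not None:
                cd["affiliation"] = c.affiliation
            if c.email is not None:
                cd["email"] = c.email
            if c.orcid is not None:
                cd["orcid"] = c.orcid
            cd.update(c.extra)
            contribs.append(cd)
        pd: dict[str, Any] = {
            "name": p.name, "version": p.version,
            "inheritance": list(p.inheritance),
            "status": _status_token(p.status),
            "contributors": contribs, "license": p.license,
            "created": p.created, "modified": p.modified,
        }
        pd.update(p.extra)
        t[_TOP_KEYS["provenance"]] = pd

    if env.usability is not None:
        ud: dict[str, Any] = {"statements": list(env.usability.statements)}
        ud.update(env.usability.extra)
        t[_TOP_KEYS["usability"]] = ud

    if env.extension is not None:
        xd: dict[str, Any] = {"entries": [
            {"schema_ref": e.schema_ref, "payload": e.payload}
            for e in env.extension.entries]}
        xd.update(env.extension.extra)
        t[_TOP_KEYS["extension"]] = xd

    if env.description is not None:
        d = env.description
        steps = []
        for s in d.steps:
            sd: dict[str, Any] = {
                "number": s.number, "name": s.name,
                "description": s.description, "version": s.version,
                "inputs": [_fileref_tree(r) for r in s.inputs],
                "outputs": [_fileref_tree(r) for r in s.outputs],
            }
            if s.prerequisites is not None:
                sd["prerequisites"] = list(s.prerequisites)
            sd.update(s.extra)
            steps.append(sd)
        dd: dict[str, Any] = {
            "keywords": list(d.keywords),
            "xrefs": [{"namespace": x.namespace, "ids": list(x.ids)} for x in d.xrefs],
            "steps": steps,
        }
        if d.platform is not None:
            dd["platform"] = d.platform
        dd.update(d.extra)
        t[_TOP_KEYS["description"]] = dd

    if env.execution is not None:
        e = env.execution
        prereqs = []
        for pr in e.software_prerequisites:
            prd: dict[str, Any] = {"name": pr.name, "version": pr.version}
            if pr.uri is not None:
                prd["uri"] = pr.uri
            if pr.digest is not None:
                prd["digest"] = pr.digest
            prereqs.append(prd)
        ed: dict[str, Any] = {
            "scripts": list(e.scripts),
            "script_driver": e.script_driver,
            "software_prerequisites": prereqs,
            "external_data_endpoints": [
                {"name": ep.name, "uri": ep.uri}
                for ep in e.external_data_endpoints],
            "environment_variables": [
                {"key": v.key, "value": v.value}
                for v in e.environment_variables],
        }
        ed.update(e.extra)
        t[_TOP_KEYS["execution"]] = ed

    if env.parametric is not None:
        md: dict[str, Any] = {"parameters": [
            {"param": p.param, "value": p.value, "step": p.step}
            for p in env.parametric.parameters]}
        md.update(env.parametric.extra)
        t[_TOP_KEYS["parametric"]] = md

    if env.io is not None:
        iod: dict[str, Any] = {
            "inputs": [_fileref_tree(r) for r in env.io.inputs],
            "outputs": [_fileref_tree(r) for r in env.io.outputs],
        }
        iod.update(env.io.extra)
        t[_TOP_KEYS["io"]] = iod

    if env.error is not None:
        def _tol(tr: ToleranceRange) -> dict:
            return {"metric": tr.metric, "min": tr.min, "max": tr.max,
                    "inclusive": tr.inclusive}
        erd: dict[str, Any] = {
            "empirical": [_tol(x) for x in env.error.empirical],
            "algorithmic": [_tol(x) for x in env.error.algorithmic],
        }
        erd.update(env.error.extra)
        t[_TOP_KEYS["error"]] = erd

    t.update(env.extra)
    return t


# --------------------------------------------------------------------------
# plain JSON tree -> model
# --------------------------------------------------------------------------

def _warn(out: list[Finding], code: str, path: str, msg: str) -> None:
    out.append(Finding(code=code, severity="WARNING", path=path, message=msg))


def _split_known(d: dict, known: tuple[str, ...], path: str,
                 out: list[Finding]) -> dict[str, Any]:
    extra = {k: v for k, v in d.items() if k not in known}
    for k in extra:
        _warn(out, "UNKNOWN_FIELD", f"{path}.{k}",
              f"unknown member {k!r} preserved for round-trip")
    return extra


def _fileref_from(d: Any, path: str, out: list[Finding]) -> FileRef:
    if not isinstance(d, dict):
        return FileRef(uri=str(d))
    known = ("uri", "filename", "access_time", "sha256", "size_bytes")
    return FileRef(
        uri=d.get("uri", ""), filename=d.get("filename"),
        access_time=d.get("access_time"), sha256=d.get("sha256"),
        size_bytes=d.get("size_bytes"),
        extra=_split_known(d, known, path, out))


def from_tree(tree: dict, *, findings: Optional[list[Finding]] = None) -> BcoEnvelope:
    """Rebuild an envelope from a plain JSON tree.  Tolerant: structurally
    odd content is kept where possible so that invalid documents can still
    be validated and diffed."""
    out = findings if findings is not None else []
    env = BcoEnvelope(
        object_id=tree.get("object_id", ""),
        bco_type=tree.get("bco_type", ""),
        spec_version=tree.get("spec_version", ""),
        digital_signature=tree.get("digital_signature"),
    )
    env.extra = {k: v for k, v in tree.items() if k not in _TOP_ATTRS}
    for k in env.extra:
        _warn(out, "UNKNOWN_FIELD", k, f"unknown member {k!r} preserved")
    for name in ("provenance", "usability", "description", "execution", "io"):
        if name not in tree:
            _warn(out, "MISSING_FIELD", name, f"required domain {name!r} absent")

    p = tree.get("provenance")
    if isinstance(p, dict):
        contribs = []
        for i, cd in enumerate(p.get("contributors", []) or []):
            if not isinstance(cd, dict):
                continue
            known = ("name", "affiliation", "email", "orcid", "contribution")
            orcid = cd.get("orcid")
            if isinstance(orcid, str) and validate_orcid(orcid):
                orcid = normalize_orcid(orcid)
            contribs.append(Contributor(
                name=cd.get("name", ""), affiliation=cd.get("affiliation"),
                email=cd.get("email"), orcid=orcid,
                contribution=list(cd.get("contribution", []) or []),
                extra=_split_known(cd, known,
                                   f"provenance.contributors[{i}]", out)))
        status = p.get("status", "")
        try:
            status = Status(status)
        except ValueError:
            pass  # raw token kept; validation reports STATUS_INVALID
        known = ("name", "version", "inheritance", "status", "contributors",
                 "license", "created", "modified")
        env.provenance = ProvenanceDomain(
            name=p.get("name", ""), version=p.get("version", ""),
            inheritance=list(p.get("inheritance", []) or []),
            status=status, contributors=contribs,
            license=p.get("license", ""),
            created=p.get("created", ""), modified=p.get("modified", ""),
            extra=_split_known(p, known, "provenance", out))

    u = tree.get("usability")
    if isinstance(u, dict):
        env.usability = UsabilityDomain(
            statements=list(u.get("statements", []) or []),
            extra=_split_known(u, ("statements",), "usability", out))

    x = tree.get("extension")
    if isinstance(x, dict):
        env.extension = ExtensionDomain(
            entries=[ExtensionEntry(schema_ref=e.get("schema_ref", ""),
                                    payload=e.get("payload"))
                     for e in x.get("entries", []) or [] if isinstance(e, dict)],
            extra=_split_known(x, ("entries",), "extension", out))

    d = tree.get("description")
    if isinstance(d, dict):
        steps = []
        for i, sd in enumerate(d.get("steps", []) or []):
            if not isinstance(sd, dict):
                continue
            spath = f"description.steps[{i}]"
            known = ("number", "name", "description", "version", "inputs",
                     "outputs", "prerequisites")
            steps.append(PipelineStep(
                number=sd.get("number", 0), name=sd.get("name", ""),
                description=sd.get("description", ""),
                version=sd.get("version", ""),
                inputs=[_fileref_from(r, f"{spath}.inputs", out)
                        for r in sd.get("inputs", []) or []],
                outputs=[_fileref_from(r, f"{spath}.outputs", out)
                         for r in sd.get("outputs", []) or []],
                prerequisites=(list(sd["prerequisites"])
                               if "prerequisites" in sd else None),
                extra=_split_known(sd, known, spath, out)))
        known = ("keywords", "xrefs", "platform", "steps")
        env.description = DescriptionDomain(
            keywords=list(d.get("keywords", []) or []),
            xrefs=[Xref(namespace=xr.get("namespace", ""),
                        ids=list(xr.get("ids", []) or []))
                   for xr in d.get("xrefs", []) or [] if isinstance(xr, dict)],
            platform=d.get("platform"), steps=steps,
            extra=_split_known(d, known, "description", out))

    e = tree.get("execution")
    if isinstance(e, dict):
        known = ("scripts", "script_driver", "software_prerequisites",
                 "external_data_endpoints", "environment_variables")
        env.execution = ExecutionDomain(
            scripts=list(e.get("scripts", []) or []),
            script_driver=e.get("script_driver", ""),
            software_prerequisites=[
                Prerequisite(name=pr.get("name", ""),
                             version=pr.get("version", ""),
                             uri=pr.get("uri"), digest=pr.get("digest"))
                for pr in e.get("software_prerequisites", []) or []
                if isinstance(pr, dict)],
            external_data_endpoints=[
                Endpoint(name=ep.get("name", ""), uri=ep.get("uri", ""))
                for ep in e.get("external_data_endpoints", []) or []
                if isinstance(ep, dict)],
            environment_variables=[
                EnvVar(key=v.get("key", ""), value=v.get("value", ""))
                for v in e.get("environment_variables", []) or []
                if isinstance(v, dict)],
            extra=_split_known(e, known, "execution", out))

    m = tree.get("parametric")
    if isinstance(m, dict):
        env.parametric = ParametricDomain(
            parameters=[Parameter(param=pp.get("param", ""),
                                  value=pp.get("value", ""),
                                  step=pp.get("step", 0))
                        for pp in m.get("parameters", []) or []
                        if isinstance(pp, dict)],
            extra=_split_known(m, ("parameters",), "parametric", out))

    io = tree.get("io")
    if isinstance(io, dict):
        env.io = IoDomain(
            inputs=[_fileref_from(r, "io.inputs", out)
                    for r in io.get("inputs", []) or []],
            outputs=[_fileref_from(r, "io.outputs", out)
                     for r in io.get("outputs", []) or []],
            extra=_split_known(io, ("inputs", "outputs"), "io", out))

    er = tree.get("error")
    if isinstance(er, dict):
        def _tol(td: dict) -> ToleranceRange:
            return ToleranceRange(metric=td.get("metric", ""),
                                  min=td.get("min", 0.0), max=td.get("max", 0.0),
                                  inclusive=td.get("inclusive", True))
        env.error = ErrorDomain(
            empirical=[_tol(td) for td in er.get("empirical", []) or []
                       if isinstance(td, dict)],
            algorithmic=[_tol(td) for td in er.get("algorithmic", []) or []
                         if isinstance(td, dict)],
            extra=_split_known(er, ("empirical", "algorithmic"), "error", out))

    return env


# --------------------------------------------------------------------------
# parsing / emission
# --------------------------------------------------------------------------

def _reject_duplicate_pairs(pairs: list[tuple[str, Any]]) -> dict:
    d: dict[str, Any] = {}
    for k, v in pairs:
        if k in d:
            raise BcoParseError(f"duplicate member name {k!r}",
                                code="DUPLICATE_KEY")
        d[k] = v
    return d


def parse_bco(text: str) -> tuple[BcoEnvelope, ValidationReport]:
    """Parse BCO JSON text into an envelope.

    Member order and whitespace never affect the result.  Unknown members
    are preserved (round-trip) and flagged as ``UNKNOWN_FIELD`` warnings;
    malformed JSON raises :class:`BcoParseError` (``PARSE_ERROR``) with
    line/column, repeated member names raise ``DUPLICATE_KEY``.
    """
    try:
        tree = json.loads(text, object_pairs_hook=_reject_duplicate_pairs)
    except BcoParseError:
        raise
    except json.JSONDecodeError as exc:
        raise BcoParseError(f"malformed JSON: {exc.msg}", code="PARSE_ERROR",
                            line=exc.lineno, column=exc.colno) from exc
    if not isinstance(tree, dict):
        raise BcoParseError("top-level JSON value must be an object",
                            code="PARSE_ERROR")
    findings: list[Finding] = []
    env = from_tree(tree, findings=findings)
    return env, ValidationReport(findings=findings)


def emit_json(env: BcoEnvelope, *, pretty: bool = True,
              include_signature: bool = True) -> str:
    """Human-oriented JSON emit (sorted keys; indented when ``pretty``).

    This form round-trips through :func:`parse_bco` but never feeds the
    digest — only :func:`emit_canonical` does.
    """
    tree = to_tree(env, include_signature=include_signature)
    try:
        if pretty:
            return json.dumps(tree, indent=2, sort_keys=True,
                              ensure_ascii=False, allow_nan=False) + "\n"
        return json.dumps(tree, sort_keys=True, ensure_ascii=False,
                          allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise EmitError(f"envelope is not JSON-serializable: {exc}") from exc


def emit_canonical(env: BcoEnvelope) -> CanonicalBytes:
    """Canonical bytes of an envelope: UTF-8, lexicographic member order,
    no insignificant whitespace, shortest-form numbers, signature excluded."""
    tree = to_tree(env, include_signature=False)
    try:
        text = json.dumps(tree, sort_keys=True, separators=(",", ":"),
                          ensure_ascii=False, allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise EmitError(f"envelope is not canonicalizable: {exc}") from exc
    return CanonicalBytes(payload=text.encode("utf-8"))


def compute_digest(c: CanonicalBytes) -> Digest:
    return Digest(hex=hashlib.sha256(c.payload).hexdigest())


def seal_envelope(env: BcoEnvelope) -> BcoEnvelope:
    """Return a copy of ``env`` whose digital_signature is the digest of its
    canonical bytes.  Idempotent; the input is not mutated."""
    sealed = copy.deepcopy(env)
    sealed.digital_signature = compute_digest(emit_canonical(env)).hex
    return sealed


def verify_seal(env: BcoEnvelope) -> bool:
    """True iff the stored signature equals the recomputed canonical digest.

    An envelope with no signature at all raises :class:`UnsignedError`
    (``UNSIGNED``) — being unsigned is distinct from being tampered with.
    """
    if env.digital_signature is None:
        raise UnsignedError("envelope carries no digital signature")
    return env.digital_signature == compute_digest(emit_canonical(env)).hex
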