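"""Verification kit: judge observed pipeline runs against an error domain.

A verification kit packages inputs with known ground truth (a reference
sequence plus simulated reads carrying planted mutations, and the truth VCF)
together with tolerance ranges for the metrics a faithful re-execution must
reproduce.  Running the kit on a new platform executes the pipeline on the
kit inputs, compares the called variants against the truth set, and checks
that every metric falls inside its acceptable range — the error domain's
operational meaning of "the BCO was used as intended".

Variant identity is the exact (chrom, pos, ref, alt) key, 1-based positions
as in VCF; indels are not left-normalized (documented limitation).
"""

from __future__ import annotations

import hashlib
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Optional, Protocol, Union

from .errors import KitError
from .model import BcoEnvelope, ErrorDomain, FileRef, ToleranceRange

__all__ = [
    "VariantKey", "MetricObservation", "MetricOutcome", "VerificationReport",
    "VerificationCase", "case_to_json", "case_from_json",
    "evaluate_metric", "evaluate_error_domain",
    "variant_keys_from_vcf", "compare_variant_sets", "hash_artifact",
    "StepRunner", "ShellRunner", "run_kit",
]

VariantKey = tuple[str, int, str, str]    # (chrom, pos, ref, alt)


@dataclass
class MetricObservation:
    metric: str
    value: Optional[float]    # None = undefined (fails downstream, fail-safe)


@dataclass
class MetricOutcome:
    metric: str
    observed: Optional[float]
    range: ToleranceRange
    passed: bool
    code: Optional[str] = None   # MET_UNDEFINED / MISSING_METRIC on failure


@dataclass
class VerificationReport:
    outcomes: list[MetricOutcome] = field(default_factory=list)
    replicate_count: int = 1
    per_replicate: list[dict[str, Optional[float]]] = field(default_factory=list)

    @property
    def overall(self) -> bool:
        return all(o.passed for o in self.outcomes)

    def to_json_obj(self) -> dict:
        return {
            "overall": self.overall,
            "replicate_count": self.replicate_count,
            "outcomes": [
                {"metric": o.metric, "observed": o.observed,
                 "min": o.range.min, "max": o.range.max,
                 "pass": o.passed, "code": o.code}
                for o in self.outcomes],
            "per_replicate": self.per_replicate,
        }


@dataclass
class VerificationCase:
    """Kit inputs + truth set + expected tolerances for one verification."""

    inputs: list[FileRef] = field(default_factory=list)
    truth: Optional[FileRef] = None
    expected: list[ToleranceRange] = field(default_factory=list)


def _fileref_obj(r: FileRef) -> dict:
    d: dict[str, Any] = {"uri": r.uri}
    for k in ("filename", "access_time", "sha256", "size_bytes"):
        if getattr(r, k) is not None:
            d[k] = getattr(r, k)
    return d


def _fileref_from_obj(d: dict) -> FileRef:
    return FileRef(uri=d.get("uri", ""), filename=d.get("filename"),
                   access_time=d.get("access_time"), sha256=d.get("sha256"),
                   size_bytes=d.get("size_bytes"))


def case_to_json(case: VerificationCase) -> str:
    """Serialize a verification case to JSON text (for ``case.json`` files)."""
    import json
    obj = {
        "inputs": [_fileref_obj(r) for r in case.inputs],
        "truth": _fileref_obj(case.truth) if case.truth else None,
        "expected": [{"metric": t.metric, "min": t.min, "max": t.max}
                     for t in case.expected],
    }
    return json.dumps(obj, indent=2, sort_keys=True) + "\n"


def case_from_json(text: str) -> VerificationCase:
    import json
    obj = json.loads(text)
    return VerificationCase(
        inputs=[_fileref_from_obj(d) for d in obj.get("inputs", [])],
        truth=_fileref_from_obj(obj["truth"]) if obj.get("truth") else None,
        expected=[ToleranceRange(metric=t["metric"], min=t["min"], max=t["max"])
                  for t in obj.get("expected", [])])


def evaluate_metric(obs: MetricObservation, tol: ToleranceRange) -> MetricOutcome:
    """Inclusive range check of one observation against one tolerance.

    Undefined observations fail with ``MET_UNDEFINED`` rather than pass —
    fail-safe behaviour for regulatory use.  Mismatched metric names raise
    ``METRIC_MISMATCH``.
    """
    if obs.metric != tol.metric:
        raise KitError(
            f"observation {obs.metric!r} evaluated against tolerance "
            f"{tol.metric!r}", code="METRIC_MISMATCH")
    if obs.value is None:
        return MetricOutcome(metric=tol.metric, observed=None, range=tol,
                             passed=False, code="MET_UNDEFINED")
    ok = tol.min <= obs.value <= tol.max
    return MetricOutcome(metric=tol.metric, observed=obs.value, range=tol,
                         passed=ok, code=None if ok else "OUT_OF_RANGE")


def evaluate_error_domain(ed: ErrorDomain,
                          obs: Iterable[MetricObservation]) -> VerificationReport:
    """Judge every tolerance of an error domain against the observations.

    A tolerance with no matching observation fails with ``MISSING_METRIC``;
    overall pass is the conjunction of per-metric outcomes.  Widening any
    range can never turn a pass into a fail (monotone).
    """
    by_name = {o.metric: o for o in obs}
    outcomes: list[MetricOutcome] = []
    for tol in ed.all_ranges():
        if tol.metric not in by_name:
            outcomes.append(MetricOutcome(
                metric=tol.metric, observed=None, range=tol, passed=False,
                code="MISSING_METRIC"))
        else:
            outcomes.append(evaluate_metric(by_name[tol.metric], tol))
    return VerificationReport(outcomes=outcomes)


# --------------------------------------------------------------------------
# variant-set comparison
# --------------------------------------------------------------------------

def variant_keys_from_vcf(path: str | Path) -> list[VariantKey]:
    """(chrom, pos, ref, alt) keys of every record in a VCF file, one key
    per alternate allele, parsed through pysam."""
    import pysam
    keys: list[VariantKey] = []
    try:
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in (rec.alts or ()):
                    keys.append((rec.chrom, rec.pos, rec.ref, alt))
    except (OSError, ValueError) as exc:
        raise KitError(f"cannot parse VCF {path}: {exc}",
                       code="VCF_PARSE") from exc
    return keys


VariantsLike = Union[str, Path, Iterable[VariantKey]]


def _as_key_set(v: VariantsLike) -> set[VariantKey]:
    if isinstance(v, (str, Path)):
        return set(variant_keys_from_vcf(v))
    return {tuple(k) for k in v}  # type: ignore[arg-type]


def compare_variant_sets(truth: VariantsLike,
                         called: VariantsLike) -> dict[str, MetricObservation]:
    """Recall/precision of a call set against planted truth.

    tp = |truth ∩ called|, fp = |called \\ truth|, fn = |truth \\ called|;
    recall = tp/(tp+fn), precision = tp/(tp+fp).  Arguments may be VCF paths
    or iterables of (chrom, pos, ref, alt) keys.  Empty denominators leave
    the corresponding metric undefined (value None).
    """
    t, c = _as_key_set(truth), _as_key_set(called)
    tp = len(t & c)
    fp = len(c - t)
    fn = len(t - c)
    recall = tp / (tp + fn) if (tp + fn) else None
    precision = tp / (tp + fp) if (tp + fp) else None
    return {
        "recall": MetricObservation("recall", recall),
        "precision": MetricObservation("precision", precision),
        "tp": MetricObservation("tp", float(tp)),
        "fp": MetricObservation("fp", float(fp)),
        "fn": MetricObservation("fn", float(fn)),
    }


def hash_artifact(path: str | Path) -> str:
    """Streamed SHA-256 hex digest of a file's bytes (``IO_MISSING`` if absent)."""
    p = Path(path)
    if not p.is_file():
        raise KitError(f"file not found: {p}", code="IO_MISSING")
    h = hashlib.sha256()
    with open(p, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# kit execution
# --------------------------------------------------------------------------

class StepRunner(Protocol):
    """Contract for executing the pipeline under verification.

    Given role-named input paths (``reference``, ``reads``), the BCO's
    non-default parameters, an output directory and a seed, the runner
    produces a VCF of called variants and returns its path.  Two bundled
    implementations exist: the fixture forge's naive pileup caller
    (:class:`bcokit.forge.NaivePileupRunner`) and :class:`ShellRunner`.
    """

    def __call__(self, inputs: Mapping[str, Path], params: Mapping[str, str],
                 out_dir: Path, seed: int) -> Path: ...


class ShellRunner:
    """Run a shell-command template, e.g. built from a BCO execution domain.

    The template is formatted with the role-named input paths, ``{out}``
    (the expected output VCF path), ``{seed}`` and any parameters, then
    executed.  Non-zero exit raises ``RUNNER_FAILURE`` with captured output.
    """

    def __init__(self, template: str):
        self.template = template

    def __call__(self, inputs: Mapping[str, Path], params: Mapping[str, str],
                 out_dir: Path, seed: int) -> Path:
        out = Path(out_dir) / "calls.vcf"
        mapping: dict[str, Any] = {k: str(v) for k, v in inputs.items()}
        mapping.update(params)
        mapping["out"] = str(out)
        mapping["seed"] = str(seed)
        try:
            cmd = self.template.format(**mapping)
        except KeyError as exc:
            raise KitError(f"unresolved template placeholder {exc}",
                           code="RUNNER_FAILURE") from exc
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise KitError(
                f"runner command failed ({proc.returncode}): {proc.stderr[-2000:]}",
                code="RUNNER_FAILURE")
        if not out.is_file():
            raise KitError("runner produced no output VCF",
                           code="RUNNER_FAILURE")
        return out


_ROLE_BY_SUFFIX = {
    ".fasta": "reference", ".fa": "reference", ".fna": "reference",
    ".fastq": "reads", ".fq": "reads",
}


def _role_of(ref: FileRef) -> str:
    name = ref.filename or Path(ref.uri).name
    return _ROLE_BY_SUFFIX.get(Path(name).suffix.lower(), Path(name).stem)


def _local_path(ref: FileRef, base: Optional[Path]) -> Path:
    uri = ref.uri
    if uri.startswith("file://"):
        return Path(uri[len("file://"):])
    p = Path(ref.filename or uri)
    if not p.is_absolute() and base is not None:
        p = base / p
    return p


def collect_bco_params(bco: BcoEnvelope) -> dict[str, str]:
    """Flatten the parametric domain into a param→value map (all steps)."""
    params: dict[str, str] = {}
    if bco.parametric is not None:
        for p in bco.parametric.parameters:
            params[p.param] = p.value
    return params


def run_kit(bco: BcoEnvelope, case: VerificationCase, runner: StepRunner,
            *, replicates: int = 1, seed: int = 0,
            work_dir: str | Path = ".", case_dir: str | Path | None = None,
            ) -> VerificationReport:
    """Run a verification kit end-to-end against a BCO.

    Before execution, every referenced kit file must exist (``IO_MISSING``)
    and match any recorded sha256 (``CHECKSUM_MISMATCH``).  The runner is
    invoked once per replicate with seed ``seed + i``; called variants are
    compared against the truth VCF, per-replicate metrics are stored, and
    the replicate-mean of each metric is judged against the merged
    tolerances (the BCO's error domain, overridden per metric by the case's
    expected ranges).  Deterministic runners with a fixed seed make the
    whole run bit-reproducible.
    """
    base = Path(case_dir) if case_dir is not None else None
    if case.truth is None:
        raise KitError("verification case has no truth VCF", code="IO_MISSING")
    pairs: list[tuple[FileRef, Path]] = [
        (ref, _local_path(ref, base)) for ref in case.inputs]
    truth_path = _local_path(case.truth, base)
    pairs.append((case.truth, truth_path))
    paths: dict[str, Path] = {_role_of(ref): p for ref, p in pairs[:-1]}
    for ref, p in pairs:
        if not p.is_file():
            raise KitError(f"kit file missing: {p}", code="IO_MISSING")
        if ref.sha256 is not None and hash_artifact(p) != ref.sha256:
            raise KitError(f"checksum mismatch for {p}",
                           code="CHECKSUM_MISMATCH")

    params = collect_bco_params(bco)
    truth_keys = variant_keys_from_vcf(truth_path)

    per_replicate: list[dict[str, Optional[float]]] = []
    work = Path(work_dir)
    for i in range(replicates):
        rep_dir = work / f"replicate_{i}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        try:
            called_vcf = runner(paths, params, rep_dir, seed + i)
        except KitError:
            raise
        except Exception as exc:
            raise KitError(f"runner raised: {exc!r}",
                           code="RUNNER_FAILURE") from exc
        metrics = compare_variant_sets(truth_keys,
                                       variant_keys_from_vcf(called_vcf))
        per_replicate.append({m: o.value for m, o in metrics.items()})

    # replicate mean; undefined if any replicate left the metric undefined
    names = per_replicate[0].keys() if per_replicate else []
    observations = []
    for name in names:
        vals = [r[name] for r in per_replicate]
        mean = None if any(v is None for v in vals) else sum(vals) / len(vals)
        observations.append(MetricObservation(name, mean))

    merged: dict[str, ToleranceRange] = {}
    if bco.error is not None:
        for tol in bco.error.all_ranges():
            merged[tol.metric] = tol
    for tol in case.expected:
        merged[tol.metric] = tol
    report = evaluate_error_domain(
        ErrorDomain(empirical=list(merged.values())), observations)
    report.replicate_count = replicates
    report.per_replicate = per_replicate
    return report
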