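"""Fixture forge: deterministic toy pipelines with known ground truth.

Everything a verification kit needs can be fabricated offline: a uniform
random genome, a haplotype with planted single-nucleotide mutations, simulated
reads from that haplotype (with optional per-base substitution errors), a
naive pileup variant caller, and a complete, valid, sealed BCO describing the
forge → simulate → call pipeline.  Every output is a pure function of its
arguments including the seed, so end-to-end runs are bit-reproducible.

Reads record their true placement in the read id (``|pos=<1-based start>``)
and the caller uses it directly — no alignment step.  The artifact under
test is the BCO machinery, not an aligner, and planting is haploid, so at
zero error rate every planted SNP is recovered exactly.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import canonical, lifecycle
from .errors import ForgeBoundsError, LineageError
from .model import (
    PAV_ROLES, BcoEnvelope, Contributor, DescriptionDomain, Endpoint, EnvVar,
    ErrorDomain, ExecutionDomain, ExtensionDomain, ExtensionEntry, FileRef,
    IoDomain, Parameter, ParametricDomain, PipelineStep, Prerequisite,
    ProvenanceDomain, Status, ToleranceRange, UsabilityDomain, Xref,
)
from .verify import VerificationCase, hash_artifact

__all__ = [
    "ToyGenome", "PlantedVariant", "PlantedTruth", "Read", "ReadSet",
    "forge_genome_and_truth", "simulate_reads", "naive_pileup_call",
    "write_fasta", "read_fasta", "write_fastq", "read_fastq",
    "write_vcf", "forge_toy_bco", "NaivePileupRunner",
    "forge_minimal_envelope", "random_envelope",
    "FaultCase", "FAULT_CODES", "one_fault_cases",
]

_BASES = "ACGT"
_CONTIG = "toy"


@dataclass
class ToyGenome:
    sequence: str
    seed: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PlantedVariant:
    pos: int      # 1-based
    ref: str
    alt: str


@dataclass
class PlantedTruth:
    variants: list[PlantedVariant] = field(default_factory=list)

    def keys(self, contig: str = _CONTIG) -> list[tuple[str, int, str, str]]:
        return [(contig, v.pos, v.ref, v.alt) for v in self.variants]


@dataclass
class Read:
    id: str
    sequence: str
    qualities: str
    pos: int      # true 1-based leftmost placement on the haplotype


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 0


# --------------------------------------------------------------------------
# genome / truth / reads
# --------------------------------------------------------------------------

def forge_genome_and_truth(
    length: int, n_mut: int, seed: int, *, edge_margin: int = 100,
) -> tuple[ToyGenome, str, PlantedTruth]:
    """Uniform random genome plus a haplotype with ``n_mut`` planted SNPs.

    Mutated positions are distinct and drawn from the interior of the genome
    (at least ``edge_margin`` bases from either end when space allows), where
    simulated read coverage is at its nominal depth; alt always differs from
    ref.  Byte-identical outputs for equal arguments.
    """
    if n_mut < 0 or n_mut > length:
        raise ForgeBoundsError(
            f"cannot plant {n_mut} mutations in a genome of length {length}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    genome = "".join(_BASES[c] for c in codes)

    margin = edge_margin if length - 2 * edge_margin >= n_mut else 0
    lo, hi = margin + 1, length - margin          # inclusive, 1-based
    positions = np.sort(rng.choice(
        np.arange(lo, hi + 1), size=n_mut, replace=False))
    offsets = rng.integers(1, 4, size=n_mut)       # never the ref base

    hap = list(genome)
    variants = []
    for pos, off in zip(positions, offsets):
        ref = genome[pos - 1]
        alt = _BASES[(_BASES.index(ref) + int(off)) % 4]
        hap[pos - 1] = alt
        variants.append(PlantedVariant(pos=int(pos), ref=ref, alt=alt))
    return ToyGenome(sequence=genome, seed=seed), "".join(hap), PlantedTruth(variants)


def simulate_reads(hap: str, coverage: float, read_length: int,
                   error_rate: float, seed: int) -> ReadSet:
    """Uniformly placed reads from a haplotype with per-base substitution
    errors at ``error_rate``.  Read count = ceil(coverage × L / read_length);
    constant quality 'I' (Phred 40)."""
    length = len(hap)
    if read_length > length or read_length <= 0:
        raise ForgeBoundsError(
            f"read length {read_length} incompatible with genome length {length}")
    if not (0.0 <= error_rate < 1.0):
        raise ForgeBoundsError(f"error rate {error_rate} outside [0, 1)")
    n_reads = math.ceil(coverage * length / read_length)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    hap_codes = np.frombuffer(hap.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    qual = "I" * read_length
    reads: list[Read] = []
    for i, start in enumerate(starts):
        seg = lut[hap_codes[start:start + read_length]].copy()
        if error_rate > 0.0:
            mask = rng.random(read_length) < error_rate
            n_err = int(mask.sum())
            if n_err:
                seg[mask] = (seg[mask] + rng.integers(1, 4, size=n_err)) % 4
        seq = "".join(_BASES[c] for c in seg)
        pos = int(start) + 1
        reads.append(Read(id=f"read{i}|pos={pos}", sequence=seq,
                          qualities=qual, pos=pos))
    return ReadSet(reads=reads, read_length=read_length, coverage=coverage,
                   error_rate=error_rate, seed=seed)


def naive_pileup_call(genome: ToyGenome, reads: ReadSet, *,
                      min_depth: int = 4, min_alt_fraction: float = 0.7,
                      ) -> list[PlantedVariant]:
    """Pileup caller over true read placements.

    Per position: count base occurrences across covering reads; call the
    most frequent base as alt when depth ≥ ``min_depth``, the base differs
    from the reference, it is the unique maximum (ties → no call) and its
    fraction of the depth is ≥ ``min_alt_fraction``.  Output sorted by
    position.
    """
    length = genome.length
    counts = np.zeros((length, 4), dtype=np.int32)
    lut = {b: i for i, b in enumerate(_BASES)}
    for read in reads.reads:
        start0 = read.pos - 1
        for offset, base in enumerate(read.sequence):
            counts[start0 + offset, lut[base]] += 1
    depth = counts.sum(axis=1)
    calls: list[PlantedVariant] = []
    candidates = np.nonzero(depth >= min_depth)[0]
    for p0 in candidates:
        row = counts[p0]
        top = int(row.max())
        if (row == top).sum() != 1:
            continue                      # tie → reference
        alt = _BASES[int(row.argmax())]
        ref = genome.sequence[p0]
        if alt == ref:
            continue
        if top / int(depth[p0]) >= min_alt_fraction:
            calls.append(PlantedVariant(pos=int(p0) + 1, ref=ref, alt=alt))
    return calls


# --------------------------------------------------------------------------
# file I/O  (FASTA/FASTQ via Biopython; VCF as minimal v4.2 text)
# --------------------------------------------------------------------------

def write_fasta(path: str | Path, name: str, sequence: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO.FastaIO import FastaWriter
    from Bio.SeqRecord import SeqRecord
    with open(path, "w", encoding="ascii") as fh:
        FastaWriter(fh, wrap=70).write_file(
            [SeqRecord(Seq(sequence), id=name, description="")])


def read_fasta(path: str | Path) -> tuple[str, str]:
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq)


def write_fastq(path: str | Path, reads: ReadSet) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for r in reads.reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.qualities}\n")


def read_fastq(path: str | Path) -> ReadSet:
    """Load a forge FASTQ; true placements are recovered from ``|pos=`` tags."""
    from Bio import SeqIO
    reads: list[Read] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        pos = int(rec.id.rsplit("|pos=", 1)[1]) if "|pos=" in rec.id else 0
        qual = "".join(chr(q + 33) for q in
                       rec.letter_annotations["phred_quality"])
        reads.append(Read(id=rec.id, sequence=str(rec.seq),
                          qualities=qual, pos=pos))
    rl = len(reads[0].sequence) if reads else 0
    return ReadSet(reads=reads, read_length=rl)


def write_vcf(path: str | Path, variants: list[PlantedVariant], *,
              contig: str = _CONTIG, contig_length: int = 0) -> None:
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={contig},length={contig_length}>",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for v in sorted(variants, key=lambda x: x.pos):
        lines.append(f"{contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.")
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")


class NaivePileupRunner:
    """Bundled :class:`~bcokit.verify.StepRunner`: the forge's pileup caller.

    Reads the reference FASTA and the origin-tagged FASTQ, calls variants
    with the ``depth`` / ``alt_fraction`` parameters from the BCO's
    parametric domain, and writes ``calls.vcf``.  Fully deterministic.
    """

    def __call__(self, inputs, params, out_dir, seed) -> Path:
        name, ref_seq = read_fasta(inputs["reference"])
        reads = read_fastq(inputs["reads"])
        calls = naive_pileup_call(
            ToyGenome(sequence=ref_seq), reads,
            min_depth=int(params.get("depth", 4)),
            min_alt_fraction=float(params.get("alt_fraction", 0.7)))
        out = Path(out_dir) / "calls.vcf"
        write_vcf(out, calls, contig=name, contig_length=len(ref_seq))
        return out


# --------------------------------------------------------------------------
# complete BCO fixtures
# --------------------------------------------------------------------------

_TS = "2024-01-15T12:00:00Z"
_TS2 = "2024-01-16T09:30:00Z"
#: A real, checksum-valid ORCID shape used in fixtures.
_FIXTURE_ORCID = "https://orcid.org/0000-0002-1825-0097"


def forge_minimal_envelope() -> BcoEnvelope:
    """The minimal complete, valid, deterministic BCO fixture (unsealed).

    Two chained pipeline steps, one parameter, one contributor — every
    required domain present, every invariant satisfied by construction.
    """
    return BcoEnvelope(
        object_id="https://example.org/bco/minimal-0001",
        bco_type="general",
        spec_version="https://w3id.org/biocompute/1.3.0",
        provenance=ProvenanceDomain(
            name="Minimal toy pipeline",
            version="1.0.0",
            inheritance=[],
            status=Status.PUBLISHED,
            contributors=[Contributor(
                name="Ada Example", affiliation="Example Institute",
                email="ada@example.org", orcid=_FIXTURE_ORCID,
                contribution=["authoredBy", "curatedBy"])],
            license="CC-BY-4.0",
            created=_TS, modified=_TS2),
        usability=UsabilityDomain(statements=[
            "Toy two-step pipeline used to exercise BCO validation."]),
        description=DescriptionDomain(
            keywords=["toy", "validation"],
            xrefs=[Xref(namespace="taxonomy", ids=["562"])],
            platform="local",
            steps=[
                PipelineStep(
                    number=1, name="filter", description="filter raw reads",
                    version="0.1.0",
                    inputs=[FileRef(uri="file://data/raw.fastq")],
                    outputs=[FileRef(uri="file://work/filtered.fastq")]),
                PipelineStep(
                    number=2, name="call", description="call variants",
                    version="0.2.0",
                    inputs=[FileRef(uri="file://work/filtered.fastq")],
                    outputs=[FileRef(uri="file://work/calls.vcf")]),
            ]),
        execution=ExecutionDomain(
            scripts=["https://example.org/pipelines/toy.sh"],
            script_driver="shell",
            software_prerequisites=[
                Prerequisite(name="toycaller", version="0.2.0",
                             uri="https://example.org/toycaller")],
            external_data_endpoints=[
                Endpoint(name="reference", uri="https://example.org/ref")],
            environment_variables=[EnvVar(key="THREADS", value="1")]),
        parametric=ParametricDomain(parameters=[
            Parameter(param="min_qual", value="30", step=2)]),
        io=IoDomain(
            inputs=[FileRef(uri="file://data/raw.fastq",
                            filename="raw.fastq")],
            outputs=[FileRef(uri="file://work/calls.vcf",
                             filename="calls.vcf")]),
    )


def forge_toy_bco(seed: int, out_dir: str | Path, *,
                  length: int = 10_000, n_mut: int = 10,
                  coverage: float = 30.0, read_length: int = 100,
                  error_rate: float = 0.0,
                  ) -> tuple[BcoEnvelope, VerificationCase]:
    """Forge a complete verification kit on disk plus its sealed BCO.

    Writes ``ref.fasta``, ``hap.fasta``, ``reads.fastq``, ``truth.vcf``,
    ``bco.json`` and ``case.json`` under ``out_dir``.  The BCO describes the
    three-step forge → simulate → call pipeline with ``depth=4`` and
    ``alt_fraction=0.7`` in its parametric domain, sha256 checksums on the
    kit files, and recall/precision tolerances of [0.9, 1.0] in its error
    domain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, hap, truth = forge_genome_and_truth(length, n_mut, seed)
    reads = simulate_reads(hap, coverage, read_length, error_rate, seed + 1)

    ref_path = out / "ref.fasta"
    hap_path = out / "hap.fasta"
    reads_path = out / "reads.fastq"
    truth_path = out / "truth.vcf"
    write_fasta(ref_path, _CONTIG, genome.sequence)
    write_fasta(hap_path, f"{_CONTIG}_hap", hap)
    write_fastq(reads_path, reads)
    write_vcf(truth_path, truth.variants, contig=_CONTIG, contig_length=length)

    def fr(p: Path) -> FileRef:
        return FileRef(uri=p.name, filename=p.name, sha256=hash_artifact(p),
                       size_bytes=p.stat().st_size)

    tol = [ToleranceRange(metric="recall", min=0.9, max=1.0),
           ToleranceRange(metric="precision", min=0.9, max=1.0)]
    env = BcoEnvelope(
        object_id=f"https://example.org/bco/toy-kit-{seed}",
        bco_type="general",
        spec_version="https://w3id.org/biocompute/1.3.0",
        provenance=ProvenanceDomain(
            name="Toy verification-kit pipeline",
            version="1.0.0", inheritance=[], status=Status.PUBLISHED,
            contributors=[Contributor(
                name="Fixture Forge", orcid=_FIXTURE_ORCID,
                contribution=["authoredBy", "createdWith"])],
            license="CC0-1.0", created=_TS, modified=_TS),
        usability=UsabilityDomain(statements=[
            "Verify that a re-execution of the toy variant-calling pipeline "
            "recovers the planted SNPs within the stated tolerances.",
            f"Kit forged with seed {seed}: {length} bp genome, {n_mut} "
            f"planted SNPs, {coverage}x simulated coverage, "
            f"per-base error rate {error_rate}."]),
        description=DescriptionDomain(
            keywords=["verification-kit", "variant-calling", "simulated-reads"],
            xrefs=[Xref(namespace="vcf", ids=["4.2"])],
            platform="local",
            steps=[
                PipelineStep(
                    number=1, name="forge_genome_and_truth",
                    description="random genome + haplotype with planted SNPs",
                    version="1.0.0", inputs=[],
                    outputs=[FileRef(uri="ref.fasta"),
                             FileRef(uri="hap.fasta"),
                             FileRef(uri="truth.vcf")]),
                PipelineStep(
                    number=2, name="simulate_reads",
                    description="uniform reads from the haplotype",
                    version="1.0.0",
                    inputs=[FileRef(uri="hap.fasta")],
                    outputs=[FileRef(uri="reads.fastq")]),
                PipelineStep(
                    number=3, name="naive_pileup_call",
                    description="pileup caller over true placements",
                    version="1.0.0",
                    inputs=[FileRef(uri="ref.fasta"),
                            FileRef(uri="reads.fastq")],
                    outputs=[FileRef(uri="calls.vcf")]),
            ]),
        execution=ExecutionDomain(
            scripts=["bco forge --seed {seed} && bco verify-run bco.json case.json"],
            script_driver="shell",
            software_prerequisites=[
                Prerequisite(name="bcokit", version="0.1.0"),
                Prerequisite(name="python", version="3.11")],
            external_data_endpoints=[],
            environment_variables=[]),
        parametric=ParametricDomain(parameters=[
            Parameter(param="length", value=str(length), step=1),
            Parameter(param="n_mut", value=str(n_mut), step=1),
            Parameter(param="coverage", value=str(coverage), step=2),
            Parameter(param="read_length", value=str(read_length), step=2),
            Parameter(param="error_rate", value=str(error_rate), step=2),
            Parameter(param="depth", value="4", step=3),
            Parameter(param="alt_fraction", value="0.7", step=3)]),
        io=IoDomain(
            inputs=[],
            outputs=[fr(ref_path), fr(reads_path), fr(truth_path),
                     FileRef(uri="calls.vcf", filename="calls.vcf")]),
        error=ErrorDomain(empirical=list(tol),
                          algorithmic=[ToleranceRange(metric="fp",
                                                      min=0.0, max=1.0)]),
    )
    sealed = canonical.seal_envelope(env)
    case = VerificationCase(inputs=[fr(ref_path), fr(reads_path)],
                            truth=fr(truth_path), expected=list(tol))
    (out / "bco.json").write_text(canonical.emit_json(sealed), encoding="utf-8")
    from .verify import case_to_json
    (out / "case.json").write_text(case_to_json(case), encoding="utf-8")
    return sealed, case


# --------------------------------------------------------------------------
# random envelopes (round-trip / diff / signature property material)
# --------------------------------------------------------------------------

def _random_json(rng: random.Random, depth: int = 0):
    kinds = ["str", "int", "float", "bool", "null"]
    if depth < 2:
        kinds += ["dict", "list"]
    kind = rng.choice(kinds)
    if kind == "str":
        return "".join(rng.choice("abcdefgh-_ ") for _ in range(rng.randint(1, 12)))
    if kind == "int":
        return rng.randint(-1000, 1000)
    if kind == "float":
        return round(rng.uniform(-100, 100), 6)
    if kind == "bool":
        return rng.random() < 0.5
    if kind == "null":
        return None
    if kind == "dict":
        return {f"k{j}": _random_json(rng, depth + 1)
                for j in range(rng.randint(1, 3))}
    return [_random_json(rng, depth + 1) for _ in range(rng.randint(1, 3))]


def _random_orcid(rng: random.Random) -> str:
    from .model import _orcid_check_char  # reuse the model's check-digit rule
    base = "".join(rng.choice("0123456789") for _ in range(15))
    full = base + _orcid_check_char(base)
    return "https://orcid.org/" + "-".join(
        full[i:i + 4] for i in range(0, 16, 4))


def random_envelope(seed: int) -> BcoEnvelope:
    """A random, structurally valid BCO: consistent dataflow, resolvable
    parameters, valid ORCIDs — plus random extension payloads and unknown
    (preserved) members.  Deterministic in ``seed``."""
    rng = random.Random(seed)
    n_steps = rng.randint(1, 4)
    ext_inputs = [f"file://data/in{j}.dat" for j in range(rng.randint(1, 2))]
    pool = list(ext_inputs)
    steps = []
    for n in range(1, n_steps + 1):
        ins = rng.sample(pool, k=min(len(pool), rng.randint(1, 2)))
        outs = [f"file://work/s{n}_o{j}.dat" for j in range(rng.randint(1, 2))]
        steps.append(PipelineStep(
            number=n, name=f"step{n}", description=f"synthetic step {n}",
            version=f"{rng.randint(0, 3)}.{rng.randint(0, 9)}.{rng.randint(0, 9)}",
            inputs=[FileRef(uri=u) for u in ins],
            outputs=[FileRef(uri=u) for u in outs]))
        pool.extend(outs)

    contributors = []
    for j in range(rng.randint(1, 3)):
        roles = ["authoredBy"] if j == 0 else [rng.choice(sorted(PAV_ROLES))]
        if rng.random() < 0.5:
            roles.append(rng.choice(sorted(PAV_ROLES)))
        contributors.append(Contributor(
            name=f"Contributor {j}",
            affiliation=rng.choice([None, "Example Lab"]),
            orcid=_random_orcid(rng) if rng.random() < 0.6 else None,
            contribution=sorted(set(roles))))

    params = []
    seen_pairs = set()
    for _ in range(rng.randint(0, 3)):
        key = (f"p{rng.randint(0, 5)}", rng.randint(1, n_steps))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        params.append(Parameter(param=key[0], value=str(rng.randint(0, 99)),
                                step=key[1]))

    env = BcoEnvelope(
        object_id=f"https://example.org/bco/rand-{seed}-{rng.randint(0, 10**6)}",
        bco_type=rng.choice(["general", "antimicrobial-resistance"]),
        spec_version="https://w3id.org/biocompute/1.3.0",
        provenance=ProvenanceDomain(
            name=f"Random pipeline {seed}",
            version=f"{rng.randint(0, 3)}.{rng.randint(0, 9)}.{rng.randint(0, 9)}",
            inheritance=[],
            status=rng.choice(list(Status)),
            contributors=contributors,
            license=rng.choice(["CC-BY-4.0", "MIT",
                                "https://example.org/license"]),
            created="2021-03-01T08:00:00Z",
            modified=f"2021-03-{rng.randint(2, 28):02d}T08:00:00Z"),
        usability=UsabilityDomain(statements=[
            f"synthetic statement {j}" for j in range(rng.randint(1, 3))]),
        description=DescriptionDomain(
            keywords=[f"kw{j}" for j in range(rng.randint(0, 3))],
            xrefs=[Xref(namespace="pubmed", ids=[str(rng.randint(1, 10**7))])]
            if rng.random() < 0.5 else [],
            platform=rng.choice([None, "local", "cloud"]),
            steps=steps),
        execution=ExecutionDomain(
            scripts=[f"https://example.org/run{rng.randint(0, 9)}.sh"],
            script_driver=rng.choice(["shell", "manual"]),
            software_prerequisites=[
                Prerequisite(name=f"tool{j}",
                             version=f"{rng.randint(0, 9)}.{rng.randint(0, 9)}")
                for j in range(rng.randint(0, 2))],
            external_data_endpoints=[],
            environment_variables=[
                EnvVar(key=f"VAR{j}", value=str(rng.randint(0, 9)))
                for j in range(rng.randint(0, 2))]),
        parametric=ParametricDomain(parameters=params)
        if (params or rng.random() < 0.5) else None,
        io=IoDomain(
            inputs=[FileRef(uri=u, filename=u.rsplit("/", 1)[-1])
                    for u in ext_inputs],
            outputs=[FileRef(uri=pool[-1],
                             sha256="ab" * 32 if rng.random() < 0.5 else None)]),
    )
    if rng.random() < 0.6:
        env.extension = ExtensionDomain(entries=[
            ExtensionEntry(schema_ref="https://example.org/ext-schema",
                           payload=_random_json(rng))
            for _ in range(rng.randint(1, 2))])
    if rng.random() < 0.5:
        env.error = ErrorDomain(empirical=[
            ToleranceRange(metric="recall", min=round(rng.uniform(0.5, 0.9), 3),
                           max=1.0)])
    if rng.random() < 0.5:
        env.extra["x_custom"] = _random_json(rng)
    if rng.random() < 0.3:
        env.usability.extra["x_note"] = _random_json(rng)
    return env


# --------------------------------------------------------------------------
# one-fault fixture suite
# --------------------------------------------------------------------------

@dataclass
class FaultCase:
    """A fixture violating exactly one documented invariant.

    ``kind`` is ``"validate"`` (an envelope whose validation must yield
    exactly one ERROR with ``code``) or ``"raise"`` (a zero-argument action
    that must raise an exception carrying ``code``).
    """

    code: str
    kind: str
    envelope: Optional[BcoEnvelope] = None
    action: Optional[Callable[[], object]] = None


def _mutate(fn: Callable[[BcoEnvelope], None]) -> BcoEnvelope:
    env = forge_minimal_envelope()
    fn(env)
    return env


def one_fault_cases() -> list[FaultCase]:
    """The one-fault fixture suite: each case violates exactly one invariant."""
    cases: list[FaultCase] = []

    def v(code: str, fn: Callable[[BcoEnvelope], None]) -> None:
        cases.append(FaultCase(code=code, kind="validate", envelope=_mutate(fn)))

    v("USABILITY_EMPTY",
      lambda e: setattr(e.usability, "statements", []))
    v("PARAM_DANGLING_STEP",
      lambda e: e.parametric.parameters.__setitem__(
          0, Parameter(param="min_qual", value="30", step=7)))
    v("DATAFLOW_FORWARD_REF",
      lambda e: e.description.steps[0].inputs.append(
          FileRef(uri="file://work/calls.vcf")))
    v("ORCID_INVALID",
      lambda e: setattr(e.provenance.contributors[0], "orcid",
                        "https://orcid.org/0000-0002-1825-0096"))
    v("PROV_TIME_ORDER",
      lambda e: setattr(e.provenance, "modified", "2020-01-01T00:00:00Z"))
    v("STEPS_NONCONTIGUOUS",
      lambda e: e.description.steps.append(PipelineStep(
          number=4, name="stray", description="mis-numbered step",
          version="0.1.0",
          inputs=[FileRef(uri="file://work/calls.vcf")],
          outputs=[FileRef(uri="file://work/extra.txt")])))
    v("PARAM_DUPLICATE",
      lambda e: e.parametric.parameters.append(
          Parameter(param="min_qual", value="31", step=2)))
    v("VERSION_PARSE",
      lambda e: setattr(e.provenance, "version", "1.2"))
    v("CONTRIB_NO_AUTHOR",
      lambda e: setattr(e.provenance.contributors[0], "contribution",
                        ["curatedBy"]))

    def illegal_transition():
        env = _mutate(lambda e: setattr(e.provenance, "status", Status.OBSOLETE))
        return lifecycle.transition_status(env, Status.PUBLISHED)

    def dangling_ancestor():
        env = _mutate(lambda e: setattr(
            e.provenance, "inheritance",
            ["https://example.org/bco/not-stored"]))
        return lifecycle.build_lineage(env, lifecycle.BcoRepository())

    def inheritance_cycle():
        a = forge_minimal_envelope()
        b = forge_minimal_envelope()
        b.object_id = "https://example.org/bco/minimal-0002"
        a.provenance.inheritance = [b.object_id]
        b.provenance.inheritance = [a.object_id]
        repo = lifecycle.BcoRepository()
        repo.store[a.object_id] = a      # direct: cycle fixtures stay unsealed
        repo.store[b.object_id] = b
        return lifecycle.build_lineage(a, repo)

    cases.append(FaultCase(code="ILLEGAL_TRANSITION", kind="raise",
                           action=illegal_transition))
    cases.append(FaultCase(code="DANGLING_ANCESTOR", kind="raise",
                           action=dangling_ancestor))
    cases.append(FaultCase(code="CYCLE", kind="raise",
                           action=inheritance_cycle))
    return cases


FAULT_CODES = tuple(c.code for c in one_fault_cases())
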