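# Methods

This note documents the models, conventions and design choices behind
`bcokit`: what each component assumes, which knobs matter, and what the
synthetic fixtures do and do not show about real data.

## The document model

A BCO is held as plain dataclasses mirroring its JSON structure.  The model
is deliberately tolerant: any parseable document — including an invalid one —
can be represented, validated, diffed and re-emitted.  Validation
(`validate_envelope`) is a pure function returning findings with stable
codes; it never raises, and zero ERROR findings is the definition of a valid
document.  Parsing errors (malformed JSON, duplicate member names) are the
serializer's concern and are exceptions, because no partial result exists.

Conventions fixed here because the JSON format alone does not fix them:

- **Timestamps** are ISO 8601 UTC with seconds precision
  (`2024-01-15T12:00:00Z`); comparison is chronological after parsing, so an
  equivalent `+00:00` offset form is accepted on input.
- **Versions** are semantic versions `major.minor.patch` (pre-release/build
  suffixes are accepted and ignored for ordering).
- **ORCIDs** are accepted bare (`0000-0002-1825-0097`) or as an
  `https://orcid.org/` URI and checked with the ISO 7064 mod 11-2 check
  character.  They are normalized to URI form *at parse time*, not merely at
  emit time, so that parse∘emit is the identity on the model — an envelope
  built in memory with a bare ORCID will round-trip into URI form once.
- **Dataflow identity** of files is exact URI string match, no
  normalization.  Determinism is worth more than cleverness here: a
  validator that second-guesses URI equivalence would report differently on
  different platforms.
- The legal values of the top-level `bco_type` are not enumerated anywhere
  authoritative; it is treated as a free controlled token (non-empty).
- Unknown members at any level are preserved through round-trips and flagged
  as WARNING `UNKNOWN_FIELD` — forward compatibility with later revisions of
  the format.

## Canonical bytes and the seal

The digital signature is a *content digest*, not a public-key signature:
SHA-256 over canonical bytes defined as UTF-8, object members in
lexicographic code-point order, no insignificant whitespace, numbers in
shortest round-trip decimal form, and the `digital_signature` member itself
excluded.  A digest gives integrity and identity; anyone can recompute it,
no key infrastructure is needed, and a detached public-key signature over
the same canonical bytes remains a clean extension point.  The non-canonical
pretty emitter exists for humans and never feeds the digest.

## Lifecycle policy

The status enum and its transition table are a policy choice of this
package (the underlying format names a "status" field without enumerating
it):

```
DRAFT → IN_REVIEW → {DRAFT, PUBLISHED};  PUBLISHED → {SUSPENDED, OBSOLETE};
SUSPENDED → {PUBLISHED, OBSOLETE};  OBSOLETE is terminal.
```

PUBLISHED objects are immutable — any content change must derive a child.
Derivation is single-parent per event; the inheritance list records the
linear chain, not a DAG, matching the snapshot-iteration workflow the format
is meant to capture.  Children get a fresh object id minted as a UUIDv4
under a configurable namespace.

Edit classes are a pure function of which domains changed:
`description`/`execution` → STRUCTURAL (major bump), `parametric`/`io`/
`error` → PARAMETRIC (minor bump), everything else (usability wording,
provenance metadata, extensions) → EDITORIAL (patch bump).  Classifying
`io` and `error` as parametric rather than structural is a judgement call:
they change what the run consumes and what counts as acceptable, but not
the computation's shape.

## Verification kits

A kit is inputs + truth VCF + expected tolerances.  `run_kit` checks file
existence and recorded sha256 checksums *before* any execution, invokes a
runner per replicate (seed + replicate index), compares the called VCF
against the truth by exact `(chrom, pos, ref, alt)` key, and judges the
replicate-mean of each metric against merged tolerances (the BCO's error
domain, overridden per metric by the case).  Choices worth knowing:

- Bounds are inclusive, and undefined metrics (e.g. precision with an empty
  call set) **fail** rather than pass — fail-safe for regulatory use.
- Indels are not left-normalized; two representations of the same indel
  compare unequal.  SNP-only fixtures sidestep this; it is a real limitation
  on real call sets.
- The empirical/algorithmic split in the error domain is descriptive only;
  both lists are evaluated identically.
- Per-replicate metrics are stored in the report, so calibrating tolerance
  ranges from larger replicate campaigns can be layered on top; the package
  does not itself do that calibration.
- The runner is a contract (input paths + parameters + out dir + seed →
  VCF path).  Two implementations ship: the forge's naive caller, and a
  shell-command template.  Arbitrary workflow-engine execution is out of
  scope on purpose — verification stays desk-scale and hermetic.

## Diff and repeat-equivalence

Diffing flattens the canonical trees (signature excluded) into leaf
path→value maps and compares them; output is ordered by path.  Lists are
compared positionally except contributors (keyed by name) and parameters
(keyed by `(param, step)`), so reordering those does not drown a reviewer in
noise; keying silently falls back to positional when keys are missing or
duplicated, keeping the diff total.  Each difference is classed by its
owning top-level member.  `repeat_equivalent` is true iff all classes are
within {PROVENANCE_ONLY, USABILITY_ONLY}.  The extension domain and unknown
custom members are conservatively classed STRUCTURAL: content the tool
cannot prove inert is treated as changing the computation.  Top-level
`object_id`/`bco_type`/`spec_version` are classed PROVENANCE_ONLY — two
sealed copies of the same analysis under different ids remain
repeat-equivalent.

## The fixture forge

The forge emulates, at toy scale, the shape of a consensus variant-calling
pipeline: reference genome → reads → list of SNPs versus the reference.  It
generates a uniform random genome, plants `n_mut` distinct SNPs (alt ≠ ref),
simulates uniformly placed fixed-length reads from the mutated haplotype
with per-base substitution errors, and calls variants with a pileup rule
(depth ≥ 4, unique top base ≠ ref, alt fraction ≥ 0.7, ties → no call).

Default kit conditions: 10 000 bp genome, 10 SNPs, 30× coverage, 100 bp
reads, error rate 0 (the error-tolerance variant uses 0.01), quality
constant `I` (Phred 40), FASTA wrapped at 70 columns, VCF v4.2 with a
minimal header.  At 30× the expected interior depth is ~30, so the
depth-4 threshold is effectively never binding and error-free recall and
precision are exactly 1.0.

Two deliberate simplifications, and what they mean:

- **Reads carry their true placement** in the read id and the caller uses it
  directly — there is no alignment step.  The artifact under test is the BCO
  machinery, not an aligner; this keeps end-to-end runs in seconds and
  deterministic.  Consequently, passing kits say nothing about alignment
  error on real data.
- **Planting is haploid and interior.**  Every read comes from the single
  mutated haplotype, so the 0.7 alt-fraction threshold is trivially met at
  zero error.  SNPs are planted at least one read length from the genome
  ends (when space allows), because uniformly placed reads give the
  outermost bases sub-nominal depth; without the margin, an edge-planted SNP
  can fall below the depth threshold and the exact-recall property would
  hold only for most seeds rather than all.  Diploid genotypes, indels and
  quality-dependent error models are out of scope.

Everything the forge emits is a pure function of its arguments including the
seed (NumPy `default_rng`), which is what makes kit runs bit-reproducible.

`random_envelope` generates structurally valid envelopes with randomized
content — chained dataflow, resolvable parameters, checksum-valid ORCIDs,
random extension payloads and unknown preserved members — used for
round-trip, digest and diff property testing.  `one_fault_cases` builds the
single-invariant-violation suite: nine validator fixtures and three
lifecycle actions (illegal transition, dangling ancestor, inheritance
cycle), each producing exactly its designated code.

## Problem sizes and numerical notes

Test and acceptance workloads are sized for interactive turnaround: 100
random envelopes for round-trip/digest properties, 200 random step graphs
(≤ 8 steps, ≤ 4 files per step) against the brute-force dataflow oracle,
1 000 random ORCID bases against an independent closed-form mod 11-2 check,
the 10 kb / 10-SNP / 30× kit for the end-to-end loop, and a 5-generation
chain plus the exhaustive 5×5 transition matrix for the lifecycle.  The
digest cross-check uses a from-scratch pure-Python SHA-256 so the oracle
shares no code with `hashlib`.  Floating-point metrics are compared exactly
where the arithmetic is exact (counts and ratios of small integers) and
within standard tolerances elsewhere.
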