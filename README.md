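# bcokit

A toolkit for **BioCompute Objects (BCOs)** — JSON documents that snapshot a
complete high-throughput-sequencing (HTS) analysis so that a reviewer,
regulator or collaborator can see exactly *what* was computed, *how*, *by
whom*, *with which parameters*, and *within what acceptable error*.

A BCO gathers the analysis into domains: **provenance** (name, semantic
version, inheritance chain, review status, contributors with PAV roles and
ORCIDs, license, timestamps), **usability** (intended-use statements),
**description** (keywords, cross-references, ordered pipeline steps with
declared inputs/outputs), **execution** (scripts, drivers, software
prerequisites with versions, environment), **parametric** (parameters changed
from default, per step), **io** (input/output files with checksums),
**extension** (foreign-standard payloads) and **error** (named metrics with
acceptable ranges).

`bcokit` provides, for such documents:

- a typed in-memory model and a validator that reports every violated
  invariant as a stable finding code (`USABILITY_EMPTY`,
  `DATAFLOW_FORWARD_REF`, `ORCID_INVALID`, ...) and never raises on bad
  content;
- **canonical serialization and sealing**: canonical bytes are UTF-8 with
  lexicographic member order, no insignificant whitespace and shortest-form
  numbers, with the signature member excluded; the *digital signature* is the
  SHA-256 digest of those bytes, so it is invariant to member order and
  whitespace and sensitive to any single field change;
- a **provenance lifecycle**: published BCOs are immutable; refinements
  derive a child whose inheritance records the parent and whose version is
  bumped by edit class (editorial → patch, parametric → minor, structural →
  major), with a fixed status-transition table and lineage reconstruction
  over a repository of sealed documents;
- a **verification kit** evaluator: run a pipeline on packaged inputs with
  known ground truth, compare called variants against the truth VCF by exact
  (chrom, pos, ref, alt) identity — recall = tp/(tp+fn),
  precision = tp/(tp+fp) — and pass iff every metric lies inside its
  inclusive tolerance range;
- a **structured diff** with *repeat-equivalence*: two BCOs are
  repeat-equivalent iff they differ only in provenance/usability, i.e. the
  described computation is unchanged;
- a **fixture forge** that fabricates toy genomes, planted SNPs, simulated
  reads, a naive pileup caller and complete sealed BCOs — deterministic in
  the seed, so everything above is testable entirely offline.

## Worked example

Forge a verification kit (10 kb genome, 10 planted SNPs, 30× reads at 1%
per-base error) and verify its BCO end to end:

```bash
python examples/03_forge_and_verify.py
```

```
forged kit under kit/: BCO https://example.org/bco/toy-kit-42
  recall     observed 1.000  range [0.90, 1.00]  pass
  precision  observed 1.000  range [0.90, 1.00]  pass
  fp         observed 0.000  range [0.00, 1.00]  pass
overall: PASS over 2 replicates
```

Recall and precision of 1.0 mean the bundled caller recovered all ten
planted SNPs with no spurious calls; `fp` is the raw false-positive count
judged against the BCO's algorithmic error tolerance.  The same flow is
available from the shell:

```bash
bco forge --seed 42 --out-dir kit        # writes ref.fasta, reads.fastq,
                                         #   truth.vcf, bco.json, case.json
bco validate kit/bco.json                # exit 0 = valid
bco verify-sig kit/bco.json              # exit 0 = seal intact
bco verify-run kit/bco.json kit/case.json   # exit 0 = all metrics in range
bco diff a.json b.json                   # exit 0 = repeat-equivalent, 3 = not
bco lineage tip.json --repo store/       # root-first inheritance chain
```

Exit codes across all commands: 0 success/pass, 1 validation or verification
failure, 2 execution/I-O error, 3 non-equivalent diff.  `--json` on any
reporting command emits the machine-readable report instead of the table.

Other example scripts: `examples/01_build_validate_seal.py` (sealing and
tamper detection), `examples/02_lifecycle.py` (derivation, version bumps,
lineage), `examples/04_diff.py` (diff classes and repeat-equivalence).

## Layout

```
src/bcokit/         model, canonical, lifecycle, verify, diff, forge, cli
tests/              pytest suite (unit, property and acceptance tests)
examples/           narrative scripts, one per capability
docs/methods.md     models, conventions and design decisions
scripts/acceptance.py
```
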