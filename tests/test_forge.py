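"""Fixture forge: determinism, read simulation statistics, naive caller."""

import math

import numpy as np
import pytest

from bcokit import canonical, forge
from bcokit.errors import ForgeBoundsError
from bcokit.model import validate_envelope
from bcokit.verify import compare_variant_sets


def test_genome_and_truth_shapes():
    genome, hap, truth = forge.forge_genome_and_truth(10_000, 10, seed=42)
    assert genome.length == len(hap) == 10_000
    assert len(truth.variants) == 10
    positions = [v.pos for v in truth.variants]
    assert len(set(positions)) == 10
    assert all(1 <= p <= 10_000 for p in positions)
    for v in truth.variants:
        assert v.alt != v.ref
        assert genome.sequence[v.pos - 1] == v.ref
        assert hap[v.pos - 1] == v.alt


def test_zero_mutations_leaves_haplotype_identical():
    genome, hap, truth = forge.forge_genome_and_truth(500, 0, seed=1)
    assert hap == genome.sequence
    assert truth.variants == []


def test_forge_bounds_checked():
    with pytest.raises(ForgeBoundsError):
        forge.forge_genome_and_truth(10, 11, seed=0)
    with pytest.raises(ForgeBoundsError):
        forge.simulate_reads("ACGT" * 10, 5, 100, 0.0, seed=0)
    with pytest.raises(ForgeBoundsError):
        forge.simulate_reads("ACGT" * 100, 5, 10, 1.5, seed=0)


def test_same_seed_byte_identical_outputs(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    forge.forge_toy_bco(7, d1, length=2000, coverage=10)
    forge.forge_toy_bco(7, d2, length=2000, coverage=10)
    for name in ("ref.fasta", "hap.fasta", "reads.fastq", "truth.vcf",
                 "bco.json", "case.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_read_count_follows_coverage_formula():
    reads = forge.simulate_reads("A" * 10_000, 30, 100, 0.0, seed=5)
    assert len(reads.reads) == math.ceil(30 * 10_000 / 100) == 3000


def test_error_free_reads_are_exact_substrings():
    _, hap, _ = forge.forge_genome_and_truth(2000, 5, seed=9)
    reads = forge.simulate_reads(hap, 5, 80, 0.0, seed=10)
    for r in reads.reads[:50]:
        assert hap[r.pos - 1: r.pos - 1 + 80] == r.sequence


def test_error_rate_within_binomial_bound():
    """Total mismatches vs the haplotype lie within 3 binomial standard
    deviations of rate x total bases."""
    _, hap, _ = forge.forge_genome_and_truth(5000, 0, seed=3)
    rate = 0.01
    reads = forge.simulate_reads(hap, 20, 100, rate, seed=4)
    total_bases = sum(len(r.sequence) for r in reads.reads)
    mismatches = sum(
        sum(a != b for a, b in zip(r.sequence, hap[r.pos - 1: r.pos - 1 + 100]))
        for r in reads.reads)
    mean = rate * total_bases
    sd = math.sqrt(total_bases * rate * (1 - rate))
    assert abs(mismatches - mean) <= 3 * sd


def test_caller_recovers_planted_snps_exactly_at_zero_error():
    genome, hap, truth = forge.forge_genome_and_truth(10_000, 10, seed=42)
    reads = forge.simulate_reads(hap, 30, 100, 0.0, seed=43)
    calls = forge.naive_pileup_call(genome, reads)
    assert [(v.pos, v.ref, v.alt) for v in calls] == \
        [(v.pos, v.ref, v.alt) for v in truth.variants]


def test_caller_depth_threshold():
    genome = forge.ToyGenome(sequence="ACGTACGTAC")
    reads = forge.ReadSet(reads=[
        forge.Read(id=f"r{i}|pos=1", sequence="GCGT", qualities="IIII", pos=1)
        for i in range(3)])
    # depth 3 at every covered position: never called
    assert forge.naive_pileup_call(genome, reads) == []


def test_caller_tie_goes_to_reference():
    genome = forge.ToyGenome(sequence="AAAA")
    reads = forge.ReadSet(reads=(
        [forge.Read(id=f"g{i}|pos=2", sequence="G", qualities="I", pos=2)
         for i in range(2)] +
        [forge.Read(id=f"t{i}|pos=2", sequence="T", qualities="I", pos=2)
         for i in range(2)]))
    assert forge.naive_pileup_call(genome, reads) == []


def test_caller_empty_readset():
    genome, _, _ = forge.forge_genome_and_truth(100, 0, seed=0)
    assert forge.naive_pileup_call(genome, forge.ReadSet()) == []


def test_recall_non_increasing_with_error_rate():
    """Mean recall over 10 seeds never rises as the read error rate does."""
    rates = [0.0, 0.01, 0.05, 0.1]
    mean_recalls = []
    for rate in rates:
        recalls = []
        for seed in range(10):
            genome, hap, truth = forge.forge_genome_and_truth(
                2000, 8, seed=seed)
            reads = forge.simulate_reads(hap, 20, 50, rate, seed=seed + 100)
            calls = forge.naive_pileup_call(genome, reads)
            m = compare_variant_sets(
                truth.keys(), [("toy", v.pos, v.ref, v.alt) for v in calls])
            recalls.append(m["recall"].value)
        mean_recalls.append(np.mean(recalls))
    assert all(a >= b - 1e-12 for a, b in zip(mean_recalls, mean_recalls[1:]))
    assert mean_recalls[0] == 1.0


def test_fasta_fastq_roundtrip(tmp_path):
    genome, hap, _ = forge.forge_genome_and_truth(300, 3, seed=2)
    forge.write_fasta(tmp_path / "g.fasta", "toy", genome.sequence)
    name, seq = forge.read_fasta(tmp_path / "g.fasta")
    assert (name, seq) == ("toy", genome.sequence)
    # 70-column wrapping
    lines = (tmp_path / "g.fasta").read_text().splitlines()
    assert max(len(l) for l in lines[1:]) == 70

    reads = forge.simulate_reads(hap, 3, 50, 0.0, seed=6)
    forge.write_fastq(tmp_path / "r.fastq", reads)
    again = forge.read_fastq(tmp_path / "r.fastq")
    assert [(r.id, r.sequence, r.pos) for r in again.reads] == \
        [(r.id, r.sequence, r.pos) for r in reads.reads]


def test_toy_bco_is_valid_sealed_and_complete(toy_kit):
    env, case, kit_dir = toy_kit
    assert validate_envelope(env).ok
    assert canonical.verify_seal(env)
    assert len(env.description.steps) == 3
    params = {(p.param, p.step) for p in env.parametric.parameters}
    assert ("depth", 3) in params and ("alt_fraction", 3) in params
    assert {t.metric for t in env.error.all_ranges()} >= {"recall", "precision"}
    for name in ("ref.fasta", "reads.fastq", "truth.vcf", "bco.json",
                 "case.json"):
        assert (kit_dir / name).is_file()
    assert case.truth.sha256 is not None


def test_random_envelopes_are_valid():
    for seed in range(30):
        report = validate_envelope(forge.random_envelope(seed))
        assert report.ok, (seed, report.codes())
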