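"""Error-domain evaluation, variant-set comparison and kit execution."""

import random
import sys

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcokit import forge, verify
from bcokit.errors import KitError
from bcokit.model import ErrorDomain, ToleranceRange
from bcokit.verify import (
    MetricObservation, ShellRunner, compare_variant_sets,
    evaluate_error_domain, evaluate_metric, hash_artifact, run_kit,
    variant_keys_from_vcf,
)

from ._sha256_ref import sha256_hex


# ---------------------------------------------------------------- metrics

@pytest.mark.parametrize("value,lo,hi,ok", [
    (0.95, 0.90, 1.00, True),
    (0.90, 0.90, 1.00, True),     # inclusive lower bound
    (1.00, 0.90, 1.00, True),     # inclusive upper bound
    (0.899, 0.90, 1.00, False),
])
def test_evaluate_metric_inclusive_bounds(value, lo, hi, ok):
    out = evaluate_metric(MetricObservation("recall", value),
                          ToleranceRange("recall", lo, hi))
    assert out.passed is ok


def test_undefined_metric_fails_safe():
    out = evaluate_metric(MetricObservation("recall", None),
                          ToleranceRange("recall", 0.0, 1.0))
    assert not out.passed and out.code == "MET_UNDEFINED"


def test_metric_name_mismatch_raises():
    with pytest.raises(KitError) as exc:
        evaluate_metric(MetricObservation("recall", 1.0),
                        ToleranceRange("precision", 0.0, 1.0))
    assert exc.value.code == "METRIC_MISMATCH"


def test_error_domain_conjunction_and_missing_metric():
    ed = ErrorDomain(empirical=[ToleranceRange("recall", 0.9, 1.0),
                                ToleranceRange("precision", 0.9, 1.0)],
                     algorithmic=[ToleranceRange("fp", 0.0, 1.0)])
    obs = [MetricObservation("recall", 0.95),
           MetricObservation("precision", 0.5)]
    rep = evaluate_error_domain(ed, obs)
    assert not rep.overall
    by = {o.metric: o for o in rep.outcomes}
    assert by["recall"].passed
    assert not by["precision"].passed and by["precision"].code == "OUT_OF_RANGE"
    assert not by["fp"].passed and by["fp"].code == "MISSING_METRIC"


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 0.3)), max_size=5),
       st.lists(st.floats(0, 1), max_size=5))
def test_widening_tolerances_is_monotone(ranges, values):
    """Widening any tolerance range never turns a pass into a fail."""
    tols = [ToleranceRange(f"m{i}", lo, min(1.0, lo + w))
            for i, (lo, w) in enumerate(ranges)]
    obs = [MetricObservation(f"m{i}", v) for i, v in enumerate(values)]
    before = evaluate_error_domain(ErrorDomain(empirical=tols), obs)
    wide = [ToleranceRange(t.metric, t.min - 0.5, t.max + 0.5) for t in tols]
    after = evaluate_error_domain(ErrorDomain(empirical=wide), obs)
    for b, a in zip(before.outcomes, after.outcomes):
        assert not (b.passed and not a.passed)


# ---------------------------------------------------------------- variants

def _metrics(truth, called):
    return {k: o.value for k, o in compare_variant_sets(truth, called).items()}


def test_identical_sets_perfect_scores():
    keys = [("toy", p, "A", "G") for p in (5, 9, 14, 20, 31)]
    m = _metrics(keys, keys)
    assert m["recall"] == 1.0 and m["precision"] == 1.0
    assert m["tp"] == 5 and m["fp"] == 0 and m["fn"] == 0


def test_partial_overlap_arithmetic():
    truth = [("toy", p, "A", "G") for p in range(1, 11)]
    called = truth[:8] + [("toy", 99, "C", "T"), ("toy", 100, "C", "T")]
    m = _metrics(truth, called)
    assert m["recall"] == pytest.approx(0.8)
    assert m["precision"] == pytest.approx(0.8)


def test_empty_called_set_leaves_precision_undefined():
    truth = [("toy", 3, "A", "G")]
    m = _metrics(truth, [])
    assert m["recall"] == 0.0 and m["precision"] is None


@settings(max_examples=150, derandomize=True)
@given(st.sets(st.tuples(st.just("toy"), st.integers(1, 40),
                         st.sampled_from("ACGT"), st.sampled_from("ACGT"))),
       st.sets(st.tuples(st.just("toy"), st.integers(1, 40),
                         st.sampled_from("ACGT"), st.sampled_from("ACGT"))))
def test_confusion_counts_partition_both_sets(truth, called):
    """tp + fn = |truth| and tp + fp = |called| on all inputs, and the counts
    agree with brute-force set intersection over (chrom, pos, ref, alt)."""
    m = _metrics(truth, called)
    assert m["tp"] + m["fn"] == len(truth)
    assert m["tp"] + m["fp"] == len(called)
    assert m["tp"] == len(set(truth) & set(called))


def test_vcf_roundtrip_through_pysam(tmp_path):
    variants = [forge.PlantedVariant(pos=p, ref="A", alt="G")
                for p in (4, 17, 30)]
    path = tmp_path / "x.vcf"
    forge.write_vcf(path, variants, contig="toy", contig_length=50)
    assert variant_keys_from_vcf(path) == [("toy", p, "A", "G")
                                           for p in (4, 17, 30)]


def test_malformed_vcf_raises_parse_code(tmp_path):
    bad = tmp_path / "bad.vcf"
    bad.write_text("not a vcf at all\n")
    with pytest.raises(KitError) as exc:
        variant_keys_from_vcf(bad)
    assert exc.value.code == "VCF_PARSE"


# ---------------------------------------------------------------- hashing

def test_hash_artifact_matches_independent_sha256(tmp_path):
    empty = tmp_path / "empty.bin"
    empty.write_bytes(b"")
    assert hash_artifact(empty) == sha256_hex(b"")
    f = tmp_path / "f.bin"
    f.write_bytes(b"ACGT" * 100)
    assert hash_artifact(f) == sha256_hex(b"ACGT" * 100)
    g = tmp_path / "renamed.bin"
    g.write_bytes(b"ACGT" * 100)
    assert hash_artifact(g) == hash_artifact(f)
    h = tmp_path / "h.bin"
    h.write_bytes(b"ACGT" * 99 + b"ACGA")
    assert hash_artifact(h) != hash_artifact(f)


def test_hash_missing_file():
    with pytest.raises(KitError) as exc:
        hash_artifact("/no/such/file")
    assert exc.value.code == "IO_MISSING"


# ---------------------------------------------------------------- run_kit

def test_run_kit_passes_on_error_free_fixture(toy_kit, tmp_path):
    env, case, kit_dir = toy_kit
    rep = run_kit(env, case, forge.NaivePileupRunner(), replicates=2,
                  seed=7, work_dir=tmp_path, case_dir=kit_dir)
    assert rep.overall
    assert rep.replicate_count == 2
    assert rep.per_replicate[0] == rep.per_replicate[1]


def test_run_kit_tightened_tolerance_fails(tmp_path):
    kit = tmp_path / "kit"
    env, case = forge.forge_toy_bco(11, kit, length=4000, coverage=3,
                                    error_rate=0.1)
    case.expected = [ToleranceRange("recall", 1.0, 1.0)]
    rep = run_kit(env, case, forge.NaivePileupRunner(), seed=3,
                  work_dir=tmp_path / "w", case_dir=kit)
    # at 3x coverage with read errors, some planted SNPs fall below the
    # caller's depth threshold: a perfect-recall requirement must fail
    assert not rep.overall


def test_run_kit_missing_input_never_invokes_runner(toy_kit, tmp_path):
    env, case, kit_dir = toy_kit
    import copy
    broken = copy.deepcopy(case)
    broken.inputs[1].uri = "gone.fastq"
    broken.inputs[1].filename = "gone.fastq"
    invoked = []

    def runner(inputs, params, out_dir, seed):
        invoked.append(True)

    with pytest.raises(KitError) as exc:
        run_kit(env, broken, runner, work_dir=tmp_path, case_dir=kit_dir)
    assert exc.value.code == "IO_MISSING"
    assert not invoked


def test_run_kit_checksum_mismatch(toy_kit, tmp_path):
    env, case, kit_dir = toy_kit
    import copy
    bad = copy.deepcopy(case)
    bad.inputs[0].sha256 = "0" * 64
    with pytest.raises(KitError) as exc:
        run_kit(env, bad, forge.NaivePileupRunner(),
                work_dir=tmp_path, case_dir=kit_dir)
    assert exc.value.code == "CHECKSUM_MISMATCH"


def test_shell_runner_executes_template(toy_kit, tmp_path):
    env, case, kit_dir = toy_kit
    script = tmp_path / "cp_truth.py"
    script.write_text(
        "import shutil, sys; shutil.copy(sys.argv[1], sys.argv[2])\n")
    runner = ShellRunner(
        f"{sys.executable} {script} {kit_dir / 'truth.vcf'} {{out}}")
    rep = run_kit(env, case, runner, work_dir=tmp_path / "w",
                  case_dir=kit_dir)
    assert rep.overall     # copying the truth scores perfectly, by definition


def test_shell_runner_failure_is_reported(toy_kit, tmp_path):
    env, case, kit_dir = toy_kit
    runner = ShellRunner(f"{sys.executable} -c 'import_sys_exit_1'")
    with pytest.raises(KitError) as exc:
        run_kit(env, case, runner, work_dir=tmp_path / "w", case_dir=kit_dir)
    assert exc.value.code == "RUNNER_FAILURE"


def test_case_json_roundtrip(toy_kit):
    _, case, _ = toy_kit
    again = verify.case_from_json(verify.case_to_json(case))
    assert [r.uri for r in again.inputs] == [r.uri for r in case.inputs]
    assert again.truth.sha256 == case.truth.sha256
    assert [(t.metric, t.min, t.max) for t in again.expected] == \
        [(t.metric, t.min, t.max) for t in case.expected]
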