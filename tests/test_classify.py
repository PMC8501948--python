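"""Read classification, signature logic, and outcome-report arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pegkit import (
    ClassifyParams,
    ReadCall,
    ReadClassifier,
    SimulationConfig,
    align_read,
    apply_edit,
    build_pegrna,
    classify_read,
    classify_reads,
    edit_signature,
    generate_reads,
    make_ptd_allele,
    revcomp,
    summarize,
)
from pegkit.classify import EmptyReportError, ReadTooShortError, TRUTH_TO_CALL
from pegkit.editsim import random_design_case


# -- alignment -------------------------------------------------------------


def test_align_identity_has_no_ops():
    ops = align_read("ACGTACGT", "ACGTACGT")
    assert [o for o in ops if o.kind != "match"] == []


def test_align_single_insertion_reported_as_one_op():
    ref = "AAAACCCCGGGGTTTT"
    read = ref[:8] + "TAG" + ref[8:]
    ops = [o for o in align_read(read, ref) if o.kind == "ins"]
    assert len(ops) == 1
    assert ops[0].length == 3
    assert ops[0].seq == "TAG"
    assert ops[0].target_pos == 8


def test_align_rejects_empty_input():
    with pytest.raises(ValueError):
        align_read("", "ACGT")


# -- signature -------------------------------------------------------------


def test_signature_toy_concatenation(toy_pegrna, toy_edit):
    sig = edit_signature(toy_pegrna, toy_edit)
    assert sig.startswith("GCAAT")  # full PBS + inserted T ...
    assert sig == "GCAA" + "T" + "GTC"  # PBS + alt + 3 nt homology


def test_signature_spans_deletion_junction(toy_locus, toy_site):
    from pegkit import parse_label

    edit = parse_label("+1–3 GTC del", toy_site, toy_locus)
    peg = build_pegrna(toy_locus, edit, toy_site, pbs_len=4, rt_homology_len=5)
    sig = edit_signature(peg, edit)
    # deleted GTC absent: PBS followed directly by downstream homology
    assert sig == "GCAA" + "AGG"
    assert sig not in toy_locus.sequence


def test_signature_min_length_guard(toy_locus, toy_site):
    from pegkit import EditSpec

    edit = EditSpec("substitution", 17, toy_locus.sequence[17], "A")
    peg = build_pegrna(toy_locus, edit, toy_site, pbs_len=4, rt_homology_len=5)
    with pytest.raises(ValueError, match="too short"):
        edit_signature(peg, edit, flank=0, downstream=1)


# -- per-read classification ----------------------------------------------


def test_classify_branches_on_constructed_alleles(toy_locus, toy_edit, toy_pegrna):
    from pegkit import simulate_flap

    clf = ReadClassifier(toy_locus, toy_edit, toy_pegrna,
                         ClassifyParams(min_read_len=10))
    assert clf.call("wt", toy_locus.sequence).label == "WT"
    correct = simulate_flap(toy_locus, toy_pegrna)
    assert clf.call("ok", correct).label == "correct_PE"
    ptd = make_ptd_allele(toy_locus, toy_edit, toy_pegrna, dup_len=5)
    call = clf.call("ptd", ptd.sequence)
    assert call.label == "PTD"
    assert call.extra_ins_len == 5
    assert call.has_signature


def test_classify_handles_reverse_complement_reads(toy_locus, toy_edit, toy_pegrna):
    from pegkit import simulate_flap

    clf = ReadClassifier(toy_locus, toy_edit, toy_pegrna,
                         ClassifyParams(min_read_len=10))
    correct = simulate_flap(toy_locus, toy_pegrna)
    assert clf.call("rc", revcomp(correct)).label == "correct_PE"


def test_classify_tolerates_stray_substitution_errors(toy_locus, toy_edit, toy_pegrna):
    from pegkit import simulate_flap

    clf = ReadClassifier(toy_locus, toy_edit, toy_pegrna,
                         ClassifyParams(min_read_len=10))
    wt = toy_locus.sequence
    noisy_wt = wt[:2] + ("A" if wt[2] != "A" else "C") + wt[3:]
    assert clf.call("nwt", noisy_wt).label == "WT"
    correct = simulate_flap(toy_locus, toy_pegrna)
    pos = len(correct) - 3
    noisy_corr = correct[:pos] + ("A" if correct[pos] != "A" else "C") + correct[pos + 1:]
    assert clf.call("ncorr", noisy_corr).label == "correct_PE"


def test_classify_short_read_filtered(toy_locus, toy_edit, toy_pegrna):
    with pytest.raises(ReadTooShortError):
        classify_read("ACGT", toy_locus, toy_edit, toy_pegrna)
    calls, n_filtered = classify_reads(
        [("r1", "ACGT"), ("r2", toy_locus.sequence)],
        toy_locus, toy_edit, toy_pegrna,
    )
    assert n_filtered == 1
    assert len(calls) == 1


def test_readcall_invariants_enforced():
    with pytest.raises(ValueError):
        ReadCall("r", "correct_PE", has_signature=False)
    with pytest.raises(ValueError):
        ReadCall("r", "PTD", has_signature=False)


def test_substring_ptd_rule_agrees_on_clean_ptds(toy_locus, toy_edit, toy_pegrna):
    clf = ReadClassifier(toy_locus, toy_edit, toy_pegrna,
                         ClassifyParams(min_read_len=10, ptd_rule="substring"))
    for dup in (3, 4, 5):
        ptd = make_ptd_allele(toy_locus, toy_edit, toy_pegrna, dup_len=dup)
        assert clf.call(f"ptd{dup}", ptd.sequence).label == "PTD"


# -- oracle equivalence and mixture recovery --------------------------------


def test_truth_table_reproduced_on_error_free_reads():
    rng = np.random.default_rng(2024)
    locus, edit, site, pbs, rth = random_design_case(rng)
    peg = build_pegrna(locus, edit, site, pbs, rth)
    cfg = SimulationConfig(
        fractions={"correct": 0.4, "WT": 0.3, "PTD": 0.2, "indel": 0.1},
        n_reads=1500, per_base_error=0.0, seed=8, ptd_dup_range=(3, rth),
    )
    recs, truth = generate_reads(locus, edit, peg, cfg)
    calls, n_filtered = classify_reads(
        ((r.id, str(r.seq)) for r in recs), locus, edit, peg
    )
    assert n_filtered == 0
    tm = dict(zip(truth.read_id, truth.label))
    assert all(c.label == TRUTH_TO_CALL[tm[c.read_id]] for c in calls)


def test_classification_total_and_deterministic(toy_locus, toy_edit, toy_pegrna):
    cfg = SimulationConfig(
        fractions={"correct": 0.4, "WT": 0.3, "PTD": 0.2, "indel": 0.1},
        n_reads=300, per_base_error=0.005, seed=3,
    )
    recs, _ = generate_reads(toy_locus, toy_edit, toy_pegrna, cfg)
    reads = [(r.id, str(r.seq)) for r in recs]
    a, _ = classify_reads(reads, toy_locus, toy_edit, toy_pegrna)
    b, _ = classify_reads(reads, toy_locus, toy_edit, toy_pegrna)
    assert a == b
    assert all(c.label in ("WT", "correct_PE", "PTD", "indel_other") for c in a)


# -- report arithmetic ------------------------------------------------------


def test_summarize_worked_example():
    calls = (
        [ReadCall(f"c{i}", "correct_PE", True) for i in range(50)]
        + [ReadCall(f"w{i}", "WT", False) for i in range(30)]
        + [ReadCall(f"p{i}", "PTD", True) for i in range(15)]
        + [ReadCall(f"i{i}", "indel_other", False) for i in range(5)]
    )
    rep = summarize(calls)
    assert rep.pct_correct == 50.0
    assert rep.pct_wt == 30.0
    assert rep.pct_unintended == 20.0
    assert rep.pct_ptd == 15.0
    assert rep.pct_indel == 5.0
    assert rep.pct_any_intended == 65.0


def test_summarize_degenerate_inputs():
    rep = summarize([ReadCall(f"w{i}", "WT", False) for i in range(7)])
    assert rep.pct_wt == 100.0
    assert rep.pct_correct == rep.pct_ptd == rep.pct_indel == 0.0
    assert rep.pct_any_intended == 0.0
    rep = summarize([ReadCall(f"c{i}", "correct_PE", True) for i in range(3)])
    assert rep.pct_any_intended == 100.0
    with pytest.raises(EmptyReportError):
        summarize([])


@settings(max_examples=300, deadline=None)
@given(
    n_correct=st.integers(0, 50),
    n_wt=st.integers(0, 50),
    n_ptd=st.integers(0, 50),
    n_indel=st.integers(0, 50),
)
def test_report_identities_hold_on_any_call_multiset(n_correct, n_wt, n_ptd, n_indel):
    if n_correct + n_wt + n_ptd + n_indel == 0:
        return
    calls = (
        [ReadCall(f"c{i}", "correct_PE", True) for i in range(n_correct)]
        + [ReadCall(f"w{i}", "WT", False) for i in range(n_wt)]
        + [ReadCall(f"p{i}", "PTD", True) for i in range(n_ptd)]
        + [ReadCall(f"i{i}", "indel_other", False) for i in range(n_indel)]
    )
    rep = summarize(calls)
    assert rep.pct_unintended == 100.0 - rep.pct_correct - rep.pct_wt
    assert rep.pct_indel == rep.pct_unintended - rep.pct_ptd
    assert rep.pct_any_intended >= rep.pct_correct
    assert rep.pct_any_intended >= rep.pct_ptd
    assert 0.0 <= rep.pct_any_intended <= 100.0
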